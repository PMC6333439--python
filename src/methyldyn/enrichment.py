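"""Interval overlap, region extension, lowly-methylated-region masking,
hypergeometric motif enrichment, signal meta-profiles and the two-sample
tests used throughout the pipeline.

All intervals are 0-based half-open; two intervals overlap iff
startA < endB and startB < endA (so abutting intervals do not overlap),
the "minimum of one base" rule.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Iterable, Sequence

import numpy as np
import pandas as pd
from scipy import stats
from statsmodels.stats.multitest import multipletests

from ._sitesum import SiteIndex
from .core import RegionSet, SampleMethylome, context_mask
from .motifs import MotifHit


def overlaps(a: tuple[str, int, int], b: tuple[str, int, int]) -> bool:
    """Half-open single-pair overlap test (>= 1 shared base)."""
    return a[0] == b[0] and a[1] < b[2] and b[1] < a[2]


def _interval_arrays(regions: Sequence[tuple[str, int, int]]):
    by_chrom: dict[str, list[tuple[int, int]]] = {}
    for chrom, start, end in regions:
        by_chrom.setdefault(chrom, []).append((start, end))
    out = {}
    for chrom, ivs in by_chrom.items():
        arr = np.array(sorted(ivs), dtype=np.int64)
        out[chrom] = (arr[:, 0], np.maximum.accumulate(arr[:, 1]))
    return out


def overlap_flags(set_a: RegionSet, set_b: RegionSet) -> np.ndarray:
    """Per-interval-of-A boolean: does it overlap any interval of B?

    Uses sorted starts with a running-maximum end, equivalent to the
    brute-force double loop.
    """
    idx = _interval_arrays(set_b.intervals)
    flags = np.zeros(len(set_a), dtype=bool)
    for i, (chrom, start, end) in enumerate(set_a.intervals):
        entry = idx.get(chrom)
        if entry is None:
            continue
        starts, cummax_end = entry
        j = np.searchsorted(starts, end, side="left")  # B starts < A end
        flags[i] = j > 0 and cummax_end[j - 1] > start
    return flags


def overlap_count(set_a: RegionSet, set_b: RegionSet) -> dict:
    flags = overlap_flags(set_a, set_b)
    return {"flags": flags, "n_overlapping": int(flags.sum()), "n_total": len(set_a)}


def extend_sites(
    sites: Iterable[tuple[str, int]], pad: int = 250,
    chrom_sizes: dict[str, int] | None = None, name: str = "extended",
) -> RegionSet:
    """Extend 1-based site positions by ``pad`` bp both ways into
    half-open intervals (length 2*pad + 1), clipped at chromosome bounds
    when sizes are given."""
    intervals = []
    for chrom, pos in sites:
        start = max(pos - 1 - pad, 0)
        end = pos + pad
        if chrom_sizes is not None and chrom in chrom_sizes:
            end = min(end, chrom_sizes[chrom])
        intervals.append((chrom, start, end))
    return RegionSet(name, intervals)


def extend_from_center(
    regions: RegionSet, pad: int = 250,
    chrom_sizes: dict[str, int] | None = None,
) -> RegionSet:
    """Replace each interval by center +/- pad (half-open), the
    preprocessing applied to background region sets before enrichment."""
    intervals = []
    for chrom, start, end in regions.intervals:
        center = (start + end) // 2
        lo = max(center - pad, 0)
        hi = center + pad
        if chrom_sizes is not None and chrom in chrom_sizes:
            hi = min(hi, chrom_sizes[chrom])
        intervals.append((chrom, lo, hi))
    return RegionSet(f"{regions.name}_center±{pad}", intervals)


def lowly_methylated_regions(
    methylome: SampleMethylome, max_level: float = 0.5, min_cg: int = 4
) -> RegionSet:
    """Windowed stand-in for unmethylated/lowly-methylated region calling.

    Maximal runs of at least ``min_cg`` consecutive covered CG sites, each
    with per-site level <= ``max_level``, are merged into regions (from
    the first site to the last, half-open).  Used to mask pre-existing
    lowly methylated regions before demethylation analyses.
    """
    df = methylome.df
    mask = context_mask(df, "CG") & (df["cov"].to_numpy() > 0)
    sub = df.loc[mask, ["chrom", "pos", "mc", "cov"]].sort_values(["chrom", "pos"])
    intervals = []
    for chrom, grp in sub.groupby("chrom", sort=False):
        low = (grp["mc"] / grp["cov"] <= max_level).to_numpy()
        pos = grp["pos"].to_numpy()
        i = 0
        while i < len(low):
            if low[i]:
                j = i
                while j + 1 < len(low) and low[j + 1]:
                    j += 1
                if j - i + 1 >= min_cg:
                    intervals.append((str(chrom), int(pos[i]) - 1, int(pos[j])))
                i = j + 1
            else:
                i += 1
    return RegionSet(f"{methylome.sample_id}_LMR", intervals)


def mask_regions(peaks: RegionSet, mask: RegionSet) -> RegionSet:
    """Remove peaks overlapping (>= 1 bp) any masking region."""
    flags = overlap_flags(peaks, mask)
    kept = [iv for iv, f in zip(peaks.intervals, flags) if not f]
    scores = (
        [s for s, f in zip(peaks.scores, flags) if not f]
        if peaks.scores is not None else None
    )
    return RegionSet(f"{peaks.name}_masked", kept, scores)


@dataclass
class EnrichmentResult:
    motif_id: str
    k: int  # foreground regions overlapping >= 1 hit
    n: int  # foreground size
    K: int  # background regions overlapping >= 1 hit
    N: int  # background size
    p: float
    q: float
    direction: str  # enriched / depleted

    @property
    def significant(self) -> bool:
        return self.q < 1e-5


def _hits_to_regions(hits: Sequence[MotifHit], name: str) -> RegionSet:
    return RegionSet(name, [(h.chrom, h.start, h.end) for h in hits])


def hypergeometric_enrichment(
    foreground: RegionSet, background: RegionSet,
    hits_per_motif: dict[str, Sequence[MotifHit] | RegionSet],
    q_threshold: float = 1e-5,
) -> list[EnrichmentResult]:
    """Motif enrichment of a foreground region set against a background.

    Per motif, k of n foreground and K of N background regions overlap at
    least one motif hit; the hypergeometric upper tail
    P[X >= k | N, K, n] tests enrichment and the lower tail
    P[X <= k] depletion — the smaller one is reported with its direction,
    and BH adjustment runs across motifs.  Callers wanting the
    center +/- 250 bp background convention apply
    :func:`extend_from_center` beforehand.
    """
    if len(background) == 0:
        raise ValueError("background region set is empty")
    if len(foreground) == 0:
        raise ValueError("foreground region set is empty")
    n, N = len(foreground), len(background)
    rows = []
    for motif_id, hits in hits_per_motif.items():
        hit_regions = hits if isinstance(hits, RegionSet) else _hits_to_regions(hits, motif_id)
        k = int(overlap_flags(foreground, hit_regions).sum())
        K = int(overlap_flags(background, hit_regions).sum())
        p_enr = float(stats.hypergeom.sf(k - 1, N, K, n))
        p_dep = float(stats.hypergeom.cdf(k, N, K, n))
        if p_enr <= p_dep:
            rows.append((motif_id, k, K, p_enr, "enriched"))
        else:
            rows.append((motif_id, k, K, p_dep, "depleted"))
    pvals = np.array([r[3] for r in rows])
    _, qvals, _, _ = multipletests(pvals, alpha=q_threshold, method="fdr_bh")
    return [
        EnrichmentResult(mid, k, n, K, N, p, float(q), direction)
        for (mid, k, K, p, direction), q in zip(rows, qvals)
    ]


def signal_profile(
    track: RegionSet, anchors: Sequence[tuple[str, int]],
    halfwidth: int = 3000, bin_bp: int = 50,
) -> pd.DataFrame:
    """Mean per-base track signal in offset bins around anchor sites.

    ``track`` is a bedGraph-like scored RegionSet (piecewise-constant
    per-base signal, 0 where uncovered); ``anchors`` are 1-based site
    positions.  Bins of ``bin_bp`` tile [-halfwidth, +halfwidth); the mean
    over anchors of the per-bin average signal is returned.
    """
    if len(anchors) == 0:
        raise ValueError("no anchor sites supplied")
    if track.scores is None:
        raise ValueError("track needs per-interval scores")
    by_chrom: dict[str, tuple[np.ndarray, np.ndarray, np.ndarray]] = {}
    for (chrom, start, end), score in zip(track.intervals, track.scores):
        by_chrom.setdefault(chrom, []).append((start, end, score))
    for chrom in list(by_chrom):
        arr = sorted(by_chrom[chrom])
        by_chrom[chrom] = (
            np.array([a[0] for a in arr], dtype=np.int64),
            np.array([a[1] for a in arr], dtype=np.int64),
            np.array([a[2] for a in arr], dtype=float),
        )
    n_bins = (2 * halfwidth) // bin_bp
    acc = np.zeros(n_bins)
    for chrom, pos in anchors:
        center = pos - 1  # 0-based
        entry = by_chrom.get(chrom)
        per_bin = np.zeros(n_bins)
        if entry is not None:
            starts, ends, scores = entry
            w_lo, w_hi = center - halfwidth, center + halfwidth
            j0 = np.searchsorted(ends, w_lo, side="right")
            j1 = np.searchsorted(starts, w_hi, side="left")
            for j in range(j0, j1):
                lo = max(starts[j], w_lo)
                hi = min(ends[j], w_hi)
                if lo >= hi:
                    continue
                b0 = (lo - w_lo) // bin_bp
                b1 = (hi - 1 - w_lo) // bin_bp
                for b in range(b0, b1 + 1):
                    seg_lo = max(lo, w_lo + b * bin_bp)
                    seg_hi = min(hi, w_lo + (b + 1) * bin_bp)
                    per_bin[b] += scores[j] * (seg_hi - seg_lo)
        acc += per_bin / bin_bp
    offsets = np.arange(n_bins) * bin_bp - halfwidth + bin_bp // 2
    return pd.DataFrame({"offset": offsets, "mean_signal": acc / len(anchors)})


def ranksum(group_a, group_b) -> tuple[float, float]:
    """Two-sided Wilcoxon rank-sum test (normal approximation)."""
    stat, p = stats.ranksums(np.asarray(group_a, dtype=float),
                             np.asarray(group_b, dtype=float))
    return float(stat), float(p)


def fisher_2x2(a: int, b: int, c: int, d: int) -> tuple[float, float]:
    """Two-sided Fisher exact test on table ((a, b), (c, d))."""
    odds, p = stats.fisher_exact([[a, b], [c, d]])
    return float(odds), float(p)
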