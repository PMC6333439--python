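"""Pairwise differential methylation calling and the transition-vector
kinetics encoding for an ordered sample series.

A site differentially methylated between two samples of a T-sample series
is summarised by a vector of T-1 elements, one per consecutive transition.
A hypomethylation call between samples d transitions apart contributes the
weight w(d) = round(-1/d, 2) (so -1, -0.5, -0.33 for d = 1, 2, 3) to every
transition it spans and 0 elsewhere; a site's kinetics vector is the
element-wise minimum over all of its calls' contribution vectors.  The
minimum is idempotent (duplicate calls change nothing) and monotone
(additional calls only deepen elements).

The pairwise caller is a site-level two-sided Fisher exact test with
Benjamini-Hochberg control, a deliberately assumption-light replacement
for smoothed beta-binomial callers; the encoding is agnostic to where the
calls come from.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Iterable, Sequence

import numpy as np
import pandas as pd
from scipy.special import gammaln
from statsmodels.stats.multitest import multipletests

from ._sitesum import SiteIndex
from .core import RegionSet, SampleMethylome, SeriesDesign, context_mask

SITE_KEY = ["chrom", "pos", "strand"]


def transition_weight(d: int) -> float:
    """Per-transition weight for a call spanning d transitions."""
    if d < 1:
        raise ValueError("transition distance must be >= 1")
    return round(-1.0 / d, 2)


def fisher_exact_twosided(mc_a, cov_a, mc_b, cov_b) -> np.ndarray:
    """Vectorised two-sided Fisher exact p for 2x2 tables
    (mc_a, cov_a - mc_a; mc_b, cov_b - mc_b).

    Two-sided p sums the hypergeometric pmf over all tables with the same
    margins whose probability does not exceed the observed one (with the
    conventional 1 + 1e-7 relative slack for float ties).
    """
    mc_a = np.asarray(mc_a, dtype=np.int64)
    cov_a = np.asarray(cov_a, dtype=np.int64)
    mc_b = np.asarray(mc_b, dtype=np.int64)
    cov_b = np.asarray(cov_b, dtype=np.int64)
    k = mc_a + mc_b
    lo = np.maximum(0, k - cov_b)
    hi = np.minimum(k, cov_a)
    lens = hi - lo + 1
    site = np.repeat(np.arange(len(k)), lens)
    # flattened support values lo[i] .. hi[i] per site
    starts = np.concatenate(([0], np.cumsum(lens)))[:-1]
    x = np.arange(lens.sum()) - np.repeat(starts, lens) + np.repeat(lo, lens)
    n1 = np.repeat(cov_a, lens)
    n2 = np.repeat(cov_b, lens)
    kk = np.repeat(k, lens)

    def logpmf(x, n1, n2, k):
        return (
            gammaln(n1 + 1) - gammaln(x + 1) - gammaln(n1 - x + 1)
            + gammaln(n2 + 1) - gammaln(k - x + 1) - gammaln(n2 - k + x + 1)
            - (gammaln(n1 + n2 + 1) - gammaln(k + 1) - gammaln(n1 + n2 - k + 1))
        )

    lp = logpmf(x, n1, n2, kk)
    lp_obs = logpmf(mc_a, cov_a, cov_b, k)
    gate = lp <= np.repeat(lp_obs, lens) + np.log1p(1e-7)
    p = np.bincount(site[gate], weights=np.exp(lp[gate]), minlength=len(k))
    return np.minimum(p, 1.0)


@dataclass
class PairwiseCalls:
    """Fisher-exact differential-methylation results for one ordered pair."""

    earlier_sample: str
    later_sample: str
    table: pd.DataFrame  # tested sites with p, q, direction, significant

    @property
    def calls(self) -> pd.DataFrame:
        return self.table.loc[self.table["significant"]]

    def hypo_sites(self) -> set[tuple[str, int, str]]:
        """Sites called hypomethylated in the later sample."""
        sub = self.table.loc[self.table["significant"] & (self.table["direction"] == "hypo")]
        return set(map(tuple, sub[SITE_KEY].itertuples(index=False)))


def call_dms_pair(
    earlier: SampleMethylome, later: SampleMethylome,
    fdr: float = 0.1, min_cov: int = 5, context: str = "CG",
) -> PairwiseCalls:
    """Site-level differential methylation between two samples.

    Sites of the chosen context covered by at least ``min_cov`` reads in
    both samples are tested with a two-sided Fisher exact test on
    (mc, cov - mc) counts; BH adjustment runs across all tested sites and
    calls are made at q < fdr.  Direction is hypo when the later sample's
    level is below the earlier one's.
    """
    a = earlier.df.loc[context_mask(earlier.df, context)]
    b = later.df.loc[context_mask(later.df, context)]
    merged = a.merge(b, on=SITE_KEY, suffixes=("_a", "_b"))
    merged = merged.loc[
        (merged["cov_a"] >= min_cov) & (merged["cov_b"] >= min_cov)
    ].reset_index(drop=True)
    if len(merged) == 0:
        table = merged.assign(p=[], q=[], direction=[], significant=[])
        return PairwiseCalls(earlier.sample_id, later.sample_id, table)
    p = fisher_exact_twosided(
        merged["mc_a"].to_numpy(), merged["cov_a"].to_numpy(),
        merged["mc_b"].to_numpy(), merged["cov_b"].to_numpy(),
    )
    rej, q, _, _ = multipletests(p, alpha=fdr, method="fdr_bh")
    level_a = merged["mc_a"] / merged["cov_a"]
    level_b = merged["mc_b"] / merged["cov_b"]
    direction = np.where(level_b < level_a, "hypo",
                         np.where(level_b > level_a, "hyper", "none"))
    table = merged.assign(
        level_a=level_a, level_b=level_b, p=p, q=q,
        direction=direction, significant=rej & (direction != "none"),
    )
    return PairwiseCalls(earlier.sample_id, later.sample_id, table)


def encode_kinetics(
    calls: Iterable[PairwiseCalls | tuple], design: SeriesDesign
) -> pd.DataFrame:
    """Combine hypomethylation calls into per-site kinetics vectors.

    ``calls`` items are either :class:`PairwiseCalls` (their hypo-direction
    significant sites are used) or explicit tuples
    ``(earlier_sample, later_sample, sites)`` with sites an iterable of
    (chrom, pos, strand).  Returns a DataFrame indexed by site with one
    column per transition (v1..v{T-1}); sites with no calls do not appear.
    """
    nt = design.n_transitions
    cols = [f"v{i}" for i in range(1, nt + 1)]
    frames = []
    for item in calls:
        if isinstance(item, PairwiseCalls):
            earlier, later = item.earlier_sample, item.later_sample
            sites = item.hypo_sites()
        else:
            earlier, later, sites = item
            sites = set(tuple(s) for s in sites)
        i, j = design.index(earlier), design.index(later)
        if i == j:
            raise ValueError(f"call between identical samples {earlier!r}")
        if i > j:
            raise ValueError(
                f"call order contradicts series: {earlier!r} is after {later!r}"
            )
        w = transition_weight(j - i)
        contrib = np.zeros(nt)
        contrib[i:j] = w
        if not sites:
            continue
        frame = pd.DataFrame(sorted(sites), columns=SITE_KEY)
        for c, val in zip(cols, contrib):
            frame[c] = val
        frames.append(frame)
    if not frames:
        empty_index = pd.MultiIndex.from_arrays([[], [], []], names=SITE_KEY)
        return pd.DataFrame(columns=cols, index=empty_index)
    allcalls = pd.concat(frames, ignore_index=True)
    return allcalls.groupby(SITE_KEY, sort=True)[cols].min()


def group_by_kinetics(vectors: pd.DataFrame, min_size: int = 100) -> pd.DataFrame:
    """Group kinetics vectors by exact pattern identity.

    Returns one row per distinct pattern with its size, a ``displayed``
    flag (size strictly greater than ``min_size``, the robustness filter)
    and a ``category`` rank.  Patterns are ordered earliest-demethylating
    first: ascending lexicographic order of the vector read left to right,
    so a more negative early element ranks before a later one.
    """
    patterns = [tuple(row) for row in vectors.to_numpy()]
    counts: dict[tuple, int] = {}
    for pat in patterns:
        counts[pat] = counts.get(pat, 0) + 1
    ordered = sorted(counts)
    rows = [
        (rank, pat, counts[pat], counts[pat] > min_size)
        for rank, pat in enumerate(ordered)
    ]
    out = pd.DataFrame(rows, columns=["category", "pattern", "size", "displayed"])
    return out


def assign_categories(vectors: pd.DataFrame, groups: pd.DataFrame) -> pd.Series:
    """Per-site category id from a :func:`group_by_kinetics` table."""
    lookup = {pat: cat for cat, pat in zip(groups["category"], groups["pattern"])}
    return pd.Series(
        [lookup[tuple(row)] for row in vectors.to_numpy()],
        index=vectors.index, name="category",
    )


def tss_distance_fraction(
    sites: Sequence[tuple[str, int]] | pd.DataFrame, genes, cutoff: int = 2500
) -> float:
    """Fraction of sites strictly more than ``cutoff`` bp from the nearest
    TSS (distance minimised over genes on the same chromosome; sites on a
    chromosome without any annotated gene count as distal)."""
    if isinstance(sites, pd.DataFrame):
        sites = list(zip(sites["chrom"], sites["pos"]))
    if len(sites) == 0:
        raise ValueError("no sites supplied")
    tss_by_chrom: dict[str, np.ndarray] = {}
    for g in genes:
        tss_by_chrom.setdefault(g.chrom, []).append(g.tss)
    tss_by_chrom = {c: np.sort(np.asarray(v)) for c, v in tss_by_chrom.items()}
    n_far = 0
    for chrom, pos in sites:
        tss = tss_by_chrom.get(chrom)
        if tss is None:
            n_far += 1
            continue
        i = np.searchsorted(tss, pos)
        cand = []
        if i < len(tss):
            cand.append(abs(int(tss[i]) - pos))
        if i > 0:
            cand.append(abs(int(tss[i - 1]) - pos))
        if min(cand) > cutoff:
            n_far += 1
    return n_far / len(sites)


def dms_set_overlap(
    set_a: Iterable[tuple], set_b: Iterable[tuple]
) -> dict[str, float]:
    """Shared-site count and Jaccard index by exact (chrom, pos, strand)
    identity."""
    sa, sb = set(map(tuple, set_a)), set(map(tuple, set_b))
    shared = len(sa & sb)
    union = len(sa | sb)
    return {
        "n_a": len(sa), "n_b": len(sb), "shared": shared,
        "jaccard": shared / union if union else float("nan"),
    }


def level_distribution_at_regions(
    methylome: SampleMethylome, regions: RegionSet, context: str = "CG"
) -> pd.Series:
    """Per-region weighted level distribution; regions with no covered
    site are excluded."""
    index = SiteIndex(methylome.df, context_mask(methylome.df, context))
    vals = {}
    for i, (chrom, start, end) in enumerate(regions.intervals):
        mc, cov = index.pooled(chrom, start + 1, end)  # half-open -> 1-based
        if cov > 0:
            vals[i] = mc / cov
    return pd.Series(vals, dtype=float, name=f"{methylome.sample_id}:{regions.name}")
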