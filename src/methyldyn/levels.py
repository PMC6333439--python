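"""Non-conversion estimation and weighted methylation levels.

A "level" throughout this package is the weighted methylation level of a
site set: pooled methylated reads divided by pooled total reads
(sum mc / sum cov), the standard WGBS summary.  Reported levels are raw
fractions; the bisulfite non-conversion rate is not subtracted — it is
used only by the binomial site caller.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy import stats
from statsmodels.stats.multitest import multipletests

from .core import SampleMethylome, context_class_array, context_mask


@dataclass
class NonConversionEstimate:
    """Failure-to-convert rate from an unmethylated lambda spike-in.

    dcm-methylated CAG/CTG positions are excluded before pooling, since
    lambda DNA from dcm+ E. coli carries genuine methylation there.
    """

    rate: float
    n_sites_used: int
    n_sites_excluded: int


@dataclass
class LevelSummary:
    sample_id: str
    selector: str
    level: float | None  # None when no covered matching site
    mc_total: int
    cov_total: int
    reason: str | None = None


def nonconversion_rate(lambda_methylome: SampleMethylome) -> NonConversionEstimate:
    """Pool mc/cov over all lambda cytosines outside CAG/CTG contexts."""
    df = lambda_methylome.df
    excluded = df["context"].isin(["CAG", "CTG"]).to_numpy()
    kept = df.loc[~excluded]
    cov_total = int(kept["cov"].sum())
    if cov_total == 0:
        raise ValueError(
            "no covered lambda site left after excluding CAG/CTG contexts"
        )
    rate = float(kept["mc"].sum()) / cov_total
    return NonConversionEstimate(rate, int((~excluded).sum()), int(excluded.sum()))


def global_level(methylome: SampleMethylome, selector: str) -> LevelSummary:
    """Weighted level over covered sites matching a context selector
    ("CG", "CH" or a trinucleotide such as "CAC")."""
    df = methylome.df
    mask = context_mask(df, selector) & (df["cov"].to_numpy() > 0)
    mc = int(df.loc[mask, "mc"].sum())
    cov = int(df.loc[mask, "cov"].sum())
    if cov == 0:
        return LevelSummary(methylome.sample_id, selector, None, 0, 0,
                            reason="no covered site matches selector")
    return LevelSummary(methylome.sample_id, selector, mc / cov, mc, cov)


def subcontext_fraction(
    methylome: SampleMethylome, sub: str, parent: str = "CH",
    weighting: str = "reads",
    calls: np.ndarray | None = None,
) -> float | None:
    """Fraction of parent-class methylation attributable to one
    trinucleotide subclass.

    ``weighting="reads"`` (default) weights by methylated-read counts:
    sum mc at sub-context sites over sum mc at parent-class sites.
    ``weighting="sites"`` counts binomially called methylated sites
    instead and requires ``calls`` (a per-site boolean from
    :func:`binomial_site_calls`).

    Returns None when the parent class carries no methylation.
    """
    df = methylome.df
    pmask = context_mask(df, parent)
    smask = context_mask(df, sub)
    if (smask & ~pmask).any():
        raise ValueError(f"{sub} is not a subclass of {parent}")
    if weighting == "reads":
        denom = int(df.loc[pmask, "mc"].sum())
        num = int(df.loc[smask, "mc"].sum())
    elif weighting == "sites":
        if calls is None:
            raise ValueError("site weighting needs per-site calls")
        calls = np.asarray(calls, dtype=bool)
        denom = int((pmask & calls).sum())
        num = int((smask & calls).sum())
    else:
        raise ValueError(f"unknown weighting {weighting!r}")
    if denom == 0:
        return None
    return num / denom


def binomial_site_calls(
    methylome: SampleMethylome, nonconv_rate: float, fdr: float = 0.01
) -> np.ndarray:
    """Per-site methylated calls against the non-conversion null.

    For every covered site the one-sided binomial tail
    P[X >= mc | n = cov, p = nonconv_rate] is computed; Benjamini-Hochberg
    is applied separately within the CG and CH context classes (their base
    rates differ by orders of magnitude) and sites with adjusted p < fdr
    are flagged.  Uncovered sites are never called.
    """
    if not (0 <= nonconv_rate < 1):
        raise ValueError("non-conversion rate must be in [0, 1)")
    df = methylome.df
    mc = df["mc"].to_numpy()
    cov = df["cov"].to_numpy()
    cclass = context_class_array(df["context"])
    pvals = np.ones(len(df))
    covered = cov > 0
    # P[X >= mc] = sf(mc - 1); mc = 0 gives 1 by construction
    pvals[covered] = stats.binom.sf(mc[covered] - 1, cov[covered], nonconv_rate)
    calls = np.zeros(len(df), dtype=bool)
    for cls in ("CG", "CH"):
        sel = covered & (cclass == cls)
        if sel.sum() == 0:
            continue
        rej, _, _, _ = multipletests(pvals[sel], alpha=fdr, method="fdr_bh")
        calls[sel] = rej
    return calls
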