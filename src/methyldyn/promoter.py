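"""Promoter mCG levels, hyper-methylation calling and distance-resolved
mCG-change vs expression-change correlation around the TSS.

A promoter is the TSS +/- 500 bp window (1001 bp, both endpoints
inclusive); a promoter is called hyper-methylated when its weighted mCG
increases by strictly more than 0.1 between an early and a late sample.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats

from ._sitesum import SiteIndex
from .core import GeneModel, SampleMethylome, context_mask

PROMOTER_HALFWIDTH = 500
HYPER_DELTA_THRESHOLD = 0.1


@dataclass
class PromoterLevel:
    gene_id: str
    mcg: float | None
    cov_total: int
    clipped: bool = False  # window truncated at a chromosome edge


def promoter_level(
    methylome: SampleMethylome, gene: GeneModel,
    halfwidth: int = PROMOTER_HALFWIDTH, index: SiteIndex | None = None,
) -> PromoterLevel:
    """Weighted mCG over CG-context sites in TSS +/- halfwidth
    (inclusive); missing when no CG site is covered."""
    if index is None:
        index = SiteIndex(methylome.df, context_mask(methylome.df, "CG"))
    lo = gene.tss - halfwidth
    clipped = lo < 1
    mc, cov = index.pooled(gene.chrom, max(lo, 1), gene.tss + halfwidth)
    return PromoterLevel(gene.gene_id, mc / cov if cov > 0 else None, cov, clipped)


def promoter_levels(
    methylome: SampleMethylome, genes: list[GeneModel],
    halfwidth: int = PROMOTER_HALFWIDTH,
) -> pd.Series:
    """Promoter mCG for many genes (NaN where missing)."""
    index = SiteIndex(methylome.df, context_mask(methylome.df, "CG"))
    vals = {
        g.gene_id: (
            lambda pl: np.nan if pl.mcg is None else pl.mcg
        )(promoter_level(methylome, g, halfwidth, index))
        for g in genes
    }
    return pd.Series(vals, name=methylome.sample_id)


def call_hyper_promoters(
    early: pd.Series, late: pd.Series, threshold: float = HYPER_DELTA_THRESHOLD
) -> pd.DataFrame:
    """Hyper-mCG calls on genes with non-missing promoter levels in both
    samples.  ``is_hyper`` is strict: delta must exceed the threshold."""
    shared = early.dropna().index.intersection(late.dropna().index)
    delta = late.loc[shared] - early.loc[shared]
    # strict inequality with a float-tie guard so delta == threshold never calls
    is_hyper = (delta > threshold) & ~np.isclose(delta, threshold)
    return pd.DataFrame({"delta": delta, "is_hyper": is_hyper})


def three_way_promoter_groups(
    ascl1_calls: pd.DataFrame, bam_calls: pd.DataFrame
) -> pd.Series:
    """Partition hyper promoters into Ascl1-only / BAM-only / both.

    Genes hyper in neither condition are excluded from the output.
    """
    shared = ascl1_calls.index.intersection(bam_calls.index)
    a = ascl1_calls.loc[shared, "is_hyper"]
    b = bam_calls.loc[shared, "is_hyper"]
    group = pd.Series(index=shared, dtype=object)
    group[a & b] = "both"
    group[a & ~b] = "Ascl1-only"
    group[~a & b] = "BAM-only"
    return group.dropna()


def distance_resolved_correlation(
    early: SampleMethylome, late: SampleMethylome, genes: list[GeneModel],
    expression_logfc: pd.Series, window_bp: int = 5000, bin_bp: int = 200,
    min_cov: int = 1, min_genes: int = 20, method: str = "spearman",
) -> pd.DataFrame:
    """Correlation of per-bin mCG change with expression log fold change.

    Bins of ``bin_bp`` tile [-window_bp, +window_bp) around each TSS in
    transcriptional orientation (negative offsets upstream).  Per gene and
    bin, delta mCG = late - early weighted CG level; per bin, the delta is
    correlated with ``expression_logfc`` across genes with at least
    ``min_cov`` total reads in both samples in that bin.  Bins informative
    for fewer than ``min_genes`` genes get a missing r.
    """
    idx_e = SiteIndex(early.df, context_mask(early.df, "CG"))
    idx_l = SiteIndex(late.df, context_mask(late.df, "CG"))
    offsets = np.arange(-window_bp, window_bp, bin_bp)
    corr_fn = stats.spearmanr if method == "spearman" else stats.pearsonr
    gene_ids = [g.gene_id for g in genes if g.gene_id in expression_logfc.index]
    genes = [g for g in genes if g.gene_id in expression_logfc.index]
    delta = np.full((len(genes), len(offsets)), np.nan)
    for gi, gene in enumerate(genes):
        sign = 1 if gene.strand == "+" else -1
        for bi, off in enumerate(offsets):
            # transcriptional offsets [off, off+bin_bp) mapped to genomic
            g1 = gene.tss + sign * off
            g2 = gene.tss + sign * (off + bin_bp - 1)
            lo, hi = min(g1, g2), max(g1, g2)
            mce, cove = idx_e.pooled(gene.chrom, lo, hi)
            mcl, covl = idx_l.pooled(gene.chrom, lo, hi)
            if cove >= min_cov and covl >= min_cov:
                delta[gi, bi] = mcl / covl - mce / cove
    fc = expression_logfc.loc[gene_ids].to_numpy(dtype=float)
    rows = []
    for bi, off in enumerate(offsets):
        ok = ~np.isnan(delta[:, bi]) & ~np.isnan(fc)
        if ok.sum() < min_genes:
            rows.append((off + bin_bp // 2, np.nan, np.nan, int(ok.sum())))
            continue
        if np.ptp(delta[ok, bi]) == 0 or np.ptp(fc[ok]) == 0:
            # constant input: correlation undefined
            rows.append((off + bin_bp // 2, np.nan, np.nan, int(ok.sum())))
            continue
        r, p = corr_fn(delta[ok, bi], fc[ok])
        rows.append((off + bin_bp // 2, float(r), float(p), int(ok.sum())))
    return pd.DataFrame(rows, columns=["offset", "r", "p", "n_genes"])
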