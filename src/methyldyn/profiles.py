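"""Gene-body methylation and flank-normalized metagene profiles.

The metagene profile scales each gene body to a fixed number of
equal-fraction bins (TSS to TES in transcriptional orientation) and adds
fixed-width flanking windows on both sides; every bin holds a weighted
methylation level, and the profile is normalized by the pooled level of
the flanking regions (100 kb on each side by default).  Flank
normalization removes the genome-wide baseline so that profiles from
samples with very different global levels are comparable.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats
from scipy.cluster.hierarchy import average, leaves_list
from sklearn.cluster import KMeans

from ._sitesum import SiteIndex
from .core import GeneModel, SampleMethylome, context_mask


def gene_body_level(
    methylome: SampleMethylome, gene: GeneModel, context: str = "CH",
    index: SiteIndex | None = None,
) -> float | None:
    """Weighted level over sites between TSS and TES (inclusive);
    None when no covered site falls in the body."""
    if index is None:
        index = SiteIndex(methylome.df, context_mask(methylome.df, context))
    mc, cov = index.pooled(gene.chrom, gene.start, gene.end)
    return mc / cov if cov > 0 else None


def gene_body_levels(
    methylome: SampleMethylome, genes: list[GeneModel], context: str = "CH"
) -> pd.Series:
    """Weighted body level for many genes at once (NaN where no covered
    site); builds the site index a single time."""
    index = SiteIndex(methylome.df, context_mask(methylome.df, context))
    vals = {}
    for gene in genes:
        mc, cov = index.pooled(gene.chrom, gene.start, gene.end)
        vals[gene.gene_id] = mc / cov if cov > 0 else np.nan
    return pd.Series(vals, name=methylome.sample_id)


@dataclass
class MetaProfile:
    gene_id: str
    bins: np.ndarray          # raw levels, NaN where bin has no coverage
    flank_mean: float | None  # pooled level over both flanks
    normalized: np.ndarray | None  # bins / flank_mean, None if flank_mean in {0, None}
    n_flank_bins: int
    n_body_bins: int


def _bin_assign(pos, gene: GeneModel, body_bins: int, flank_bp: int, flank_bins: int):
    """Bin index in transcriptional orientation, -1 outside the window."""
    binw = flank_bp / flank_bins
    if gene.strand == "+":
        d = pos - gene.tss
        body_len = gene.tes - gene.tss + 1
    else:
        d = gene.tss - pos
        body_len = gene.tss - gene.tes + 1
    out = np.full(pos.shape, -1, dtype=np.int64)
    up = (d >= -flank_bp) & (d < 0)
    out[up] = np.minimum(((d[up] + flank_bp) / binw).astype(np.int64), flank_bins - 1)
    body = (d >= 0) & (d < body_len)
    out[body] = flank_bins + np.minimum(
        (d[body] * body_bins // body_len).astype(np.int64), body_bins - 1
    )
    down = (d >= body_len) & (d < body_len + flank_bp)
    out[down] = flank_bins + body_bins + np.minimum(
        ((d[down] - body_len) / binw).astype(np.int64), flank_bins - 1
    )
    return out, body_len


def metagene_profile(
    methylome: SampleMethylome, gene: GeneModel, context: str = "CH",
    body_bins: int = 60, flank_bp: int = 100_000, flank_bins: int = 20,
    index: SiteIndex | None = None,
) -> MetaProfile:
    """Flank-normalized metagene profile for one gene.

    When the flanks carry no methylation (or no coverage) the raw profile
    is still returned and ``normalized`` is None.
    """
    if flank_bp <= 0:
        raise ValueError("flank_bp must be positive")
    if index is None:
        index = SiteIndex(methylome.df, context_mask(methylome.df, context))
    lo, hi = gene.start - flank_bp, gene.end + flank_bp
    pos, mc, cov = index.sites(gene.chrom, lo, hi)
    nbins = 2 * flank_bins + body_bins
    assign, _ = _bin_assign(pos, gene, body_bins, flank_bp, flank_bins)
    keep = assign >= 0
    mc_bins = np.bincount(assign[keep], weights=mc[keep], minlength=nbins)
    cov_bins = np.bincount(assign[keep], weights=cov[keep], minlength=nbins)
    with np.errstate(invalid="ignore", divide="ignore"):
        raw = np.where(cov_bins > 0, mc_bins / np.maximum(cov_bins, 1), np.nan)
    flank_sel = np.zeros(nbins, dtype=bool)
    flank_sel[:flank_bins] = True
    flank_sel[flank_bins + body_bins:] = True
    fcov = cov_bins[flank_sel].sum()
    fmc = mc_bins[flank_sel].sum()
    flank_mean = fmc / fcov if fcov > 0 else None
    normalized = raw / flank_mean if flank_mean else None
    return MetaProfile(gene.gene_id, raw, flank_mean, normalized, flank_bins, body_bins)


def build_profile_matrix(
    methylome: SampleMethylome, genes: list[GeneModel], context: str = "CH",
    body_bins: int = 60, flank_bp: int = 100_000, flank_bins: int = 20,
    max_missing_frac: float = 0.30,
) -> pd.DataFrame:
    """Genes x bins matrix of flank-normalized levels, complete after
    imputation.

    Genes shorter than ``body_bins`` bp, genes without a positive flank
    level, and genes with more than ``max_missing_frac`` empty bins are
    dropped; the remaining missing bins are imputed with the gene's own
    mean normalized level (gene-local, so no cross-gene leakage).
    """
    index = SiteIndex(methylome.df, context_mask(methylome.df, context))
    rows, ids = [], []
    for gene in genes:
        if gene.length < body_bins:
            continue
        prof = metagene_profile(
            methylome, gene, context, body_bins, flank_bp, flank_bins, index=index
        )
        if prof.normalized is None:
            continue
        vec = prof.normalized
        missing = np.isnan(vec)
        if missing.mean() > max_missing_frac:
            continue
        if missing.any():
            vec = np.where(missing, np.nanmean(vec), vec)
        rows.append(vec)
        ids.append(gene.gene_id)
    nbins = 2 * flank_bins + body_bins
    cols = [f"bin{i}" for i in range(nbins)]
    if not rows:
        return pd.DataFrame(columns=cols)
    return pd.DataFrame(np.vstack(rows), index=ids, columns=cols)


def kmeans_profiles(
    matrix: pd.DataFrame, k: int = 20, seed: int = 0, n_init: int = 10
) -> tuple[pd.Series, np.ndarray]:
    """K-means on a complete profile matrix with stable relabeling.

    Clusters are renumbered 0..k-1 in decreasing size order (ties broken
    by the original label) so that runs with the same seed are identical
    and labels are comparable across invocations.
    """
    if k < 1:
        raise ValueError("k must be >= 1")
    if k > len(matrix):
        raise ValueError(f"k = {k} exceeds the {len(matrix)} available genes")
    if matrix.isna().any().any():
        raise ValueError("profile matrix must be complete (impute first)")
    km = KMeans(n_clusters=k, random_state=seed, n_init=n_init)
    raw = km.fit_predict(matrix.to_numpy())
    sizes = np.bincount(raw, minlength=k)
    order = np.lexsort((np.arange(k), -sizes))  # decreasing size, stable
    remap = np.empty(k, dtype=int)
    remap[order] = np.arange(k)
    labels = pd.Series(remap[raw], index=matrix.index, name="cluster")
    centroids = km.cluster_centers_[order]
    return labels, centroids


def sample_correlation_cluster(
    genebody_levels: pd.DataFrame, method: str = "spearman"
) -> tuple[pd.DataFrame, list[str], np.ndarray]:
    """Correlation matrix and average-linkage dendrogram over samples.

    ``genebody_levels`` is genes x samples; correlations use
    pairwise-complete genes.  Samples with fewer than 3 non-missing genes
    are excluded with a warning.  Returns (correlation matrix, sample ids
    in dendrogram leaf order, linkage matrix).
    """
    ok = genebody_levels.notna().sum(axis=0) >= 3
    if (~ok).any():
        warnings.warn(
            f"excluding samples with <3 non-missing genes: {list(genebody_levels.columns[~ok])}"
        )
    data = genebody_levels.loc[:, ok]
    if data.shape[1] < 2:
        raise ValueError("need at least two usable samples")
    corr = data.corr(method=method)
    dist = 1.0 - corr.to_numpy()
    iu = np.triu_indices_from(dist, k=1)
    linkage = average(dist[iu])
    order = [corr.columns[i] for i in leaves_list(linkage)]
    return corr, order, linkage


def length_vs_mch(
    genes: list[GeneModel], normalized_levels: pd.Series, n_bins: int = 10
) -> pd.DataFrame:
    """Mean flank-normalized body mCH per log10 gene-length bin."""
    lengths = pd.Series({g.gene_id: g.length for g in genes})
    shared = lengths.index.intersection(normalized_levels.dropna().index)
    lengths = lengths.loc[shared]
    vals = normalized_levels.loc[shared]
    logl = np.log10(lengths.to_numpy(dtype=float))
    if n_bins == 1:
        edges = np.array([logl.min(), logl.max()])
    else:
        edges = np.linspace(logl.min(), logl.max(), n_bins + 1)
    which = np.clip(np.digitize(logl, edges[1:-1]), 0, n_bins - 1)
    out = []
    for b in range(n_bins):
        sel = which == b
        out.append(
            (b, 10 ** edges[b], 10 ** edges[b + 1], int(sel.sum()),
             float(vals.to_numpy()[sel].mean()) if sel.any() else np.nan)
        )
    return pd.DataFrame(out, columns=["bin", "length_lo", "length_hi", "n_genes", "mean_level"])


def mch_expression_correlation(
    genebody_mch: pd.Series, expression: pd.Series, min_genes: int = 10
) -> tuple[float | None, float | None]:
    """Spearman correlation between gene-body mCH and expression over
    genes present (non-missing) in both; (None, None) when undefined."""
    shared = genebody_mch.dropna().index.intersection(expression.dropna().index)
    if len(shared) < min_genes:
        raise ValueError(f"only {len(shared)} genes shared; need >= {min_genes}")
    x = genebody_mch.loc[shared].to_numpy(dtype=float)
    y = expression.loc[shared].to_numpy(dtype=float)
    if np.ptp(x) == 0 or np.ptp(y) == 0:
        return None, None
    r, p = stats.spearmanr(x, y)
    return float(r), float(p)
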