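"""Methylome-transcriptome integration: ranking genes by early gene-body
mCH, enrichment of differential-expression categories along the ranking,
and expression-stratified mCH trajectories."""

from __future__ import annotations

import numpy as np
import pandas as pd
from scipy import stats

from .enrichment import ranksum

DE_LABELS = ("up", "down", "static")


def rank_by_early_mch(early_mch: pd.Series) -> list[str]:
    """Gene ids sorted by descending normalized gene-body mCH; ties broken
    by gene id so the ranking is a pure function of the values."""
    clean = early_mch.dropna()
    order = sorted(clean.index, key=lambda g: (-clean[g], g))
    return list(order)


def rank_enrichment(
    ranking: list[str], labels: pd.Series, bin_size: int = 200
) -> pd.DataFrame:
    """Hypergeometric enrichment of DE categories in consecutive rank bins.

    For each bin of ``bin_size`` consecutive ranks and each of the "down"
    and "up" categories, the upper-tail hypergeometric p-value for
    overrepresentation relative to the labeled universe is computed
    (population = labeled genes in the ranking, successes = genes of that
    category, draws = labeled genes in the bin).  A bin without labeled
    genes gets p = 1.
    """
    labels = labels.dropna()
    labeled = [g for g in ranking if g in labels.index]
    N = len(labeled)
    totals = {lab: int((labels.loc[labeled] == lab).sum()) for lab in ("down", "up")}
    rows = []
    for b, start in enumerate(range(0, len(ranking), bin_size)):
        genes = ranking[start : start + bin_size]
        in_bin = labels.reindex([g for g in genes if g in labels.index])
        n_draw = len(in_bin)
        row = {"bin": b, "rank_start": start, "n_genes": len(genes), "n_labeled": n_draw}
        for lab in ("down", "up"):
            k = int((in_bin == lab).sum())
            p = float(stats.hypergeom.sf(k - 1, N, totals[lab], n_draw)) if n_draw else 1.0
            row[f"k_{lab}"] = k
            row[f"p_{lab}"] = p
            row[f"neglog10p_{lab}"] = -np.log10(max(p, 1e-300))
        rows.append(row)
    return pd.DataFrame(rows)


def stratified_mch_trajectories(
    genebody_mch: pd.DataFrame, labels: pd.Series, expression: pd.DataFrame,
    bin_edges=(0, 1, 2, 3, 4, 5, np.inf), active_rpkm: float | None = None,
) -> pd.DataFrame:
    """Mean gene-body mCH per (expression bin x DE label x timepoint).

    Expression is averaged across the series (arithmetic mean of RPKM over
    timepoints, then log2(RPKM + 1)) and genes fall into half-open
    [lo, hi) bins of that quantity.  With ``active_rpkm`` set, genes whose
    mean RPKM is not strictly above the cutoff are excluded first (the
    "actively expressed" filter, RPKM > 3 in the reference analyses).
    Empty (bin, label) combinations are omitted.
    """
    shared = genebody_mch.index.intersection(labels.dropna().index).intersection(
        expression.index
    )
    mch = genebody_mch.loc[shared]
    lab = labels.loc[shared]
    mean_rpkm = expression.loc[shared].mean(axis=1)
    if active_rpkm is not None:
        keep = mean_rpkm > active_rpkm
        mch, lab, mean_rpkm = mch.loc[keep], lab.loc[keep], mean_rpkm.loc[keep]
    logexpr = np.log2(mean_rpkm + 1)
    edges = np.asarray(bin_edges, dtype=float)
    rows = []
    for b in range(len(edges) - 1):
        in_bin = (logexpr >= edges[b]) & (logexpr < edges[b + 1])
        for label in sorted(lab.unique()):
            sel = in_bin & (lab == label)
            if not sel.any():
                continue
            means = mch.loc[sel].mean(axis=0)
            row = {"expr_bin_lo": edges[b], "expr_bin_hi": edges[b + 1],
                   "label": label, "n_genes": int(sel.sum())}
            row.update({tp: float(means[tp]) for tp in mch.columns})
            rows.append(row)
    return pd.DataFrame(rows)


def group_effect_compare(values_by_label: dict[str, np.ndarray]) -> pd.DataFrame:
    """Pairwise two-sided rank-sum tests between labeled value groups."""
    labs = sorted(values_by_label)
    rows = []
    for i, a in enumerate(labs):
        for b in labs[i + 1:]:
            stat, p = ranksum(values_by_label[a], values_by_label[b])
            rows.append((a, b, stat, p))
    return pd.DataFrame(rows, columns=["group_a", "group_b", "statistic", "p"])


def zscore_rows(matrix: pd.DataFrame) -> pd.DataFrame:
    """Per-gene z-score across samples (heatmap normalization)."""
    mu = matrix.mean(axis=1)
    sd = matrix.std(axis=1, ddof=0).replace(0, np.nan)
    return matrix.sub(mu, axis=0).div(sd, axis=0)
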