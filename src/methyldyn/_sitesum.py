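"""Internal per-chromosome index for O(log n) pooled-count queries."""

from __future__ import annotations

import numpy as np
import pandas as pd


class SiteIndex:
    """Sorted position index with cumulative mc/cov sums per chromosome.

    Positions are 1-based; queries use inclusive 1-based bounds.  Rows with
    cov = 0 contribute nothing to pooled counts by construction.
    """

    def __init__(self, df: pd.DataFrame, mask: np.ndarray | None = None):
        if mask is not None:
            df = df.loc[mask]
        self._chrom: dict[str, tuple[np.ndarray, np.ndarray, np.ndarray, np.ndarray, np.ndarray]] = {}
        for chrom, sub in df.groupby("chrom", sort=False):
            order = np.argsort(sub["pos"].to_numpy(), kind="stable")
            pos = sub["pos"].to_numpy()[order]
            mc = sub["mc"].to_numpy()[order]
            cov = sub["cov"].to_numpy()[order]
            self._chrom[str(chrom)] = (
                pos,
                mc,
                cov,
                np.concatenate(([0], np.cumsum(mc))),
                np.concatenate(([0], np.cumsum(cov))),
            )

    def pooled(self, chrom: str, lo: int, hi: int) -> tuple[int, int]:
        """(sum mc, sum cov) over sites with lo <= pos <= hi."""
        entry = self._chrom.get(chrom)
        if entry is None or hi < lo:
            return 0, 0
        pos, _, _, cmc, ccov = entry
        i = np.searchsorted(pos, lo, side="left")
        j = np.searchsorted(pos, hi, side="right")
        return int(cmc[j] - cmc[i]), int(ccov[j] - ccov[i])

    def sites(self, chrom: str, lo: int, hi: int):
        """(positions, mc, cov) arrays for sites with lo <= pos <= hi."""
        entry = self._chrom.get(chrom)
        if entry is None:
            return (np.empty(0, dtype=np.int64),) * 3
        pos, mc, cov, _, _ = entry
        i = np.searchsorted(pos, lo, side="left")
        j = np.searchsorted(pos, hi, side="right")
        return pos[i:j], mc[i:j], cov[i:j]


def pooled_level(mc: int, cov: int) -> float | None:
    return mc / cov if cov > 0 else None
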