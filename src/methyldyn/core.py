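"""Core domain types shared across the package.

Coordinate conventions
----------------------
Per-cytosine tables (allc style) use 1-based positions of the cytosine on
its own strand; all interval collections (``RegionSet``) use 0-based
half-open BED coordinates.  Conversion between the two dialects happens
only through :func:`pos_to_interval` / :func:`interval_to_pos`.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

ALLC_COLUMNS = ["chrom", "pos", "strand", "context", "mc", "cov"]


def pos_to_interval(pos: int) -> tuple[int, int]:
    """1-based position -> 0-based half-open single-base interval."""
    return (pos - 1, pos)


def interval_to_pos(start: int, end: int) -> int:
    """0-based half-open single-base interval -> 1-based position."""
    if end - start != 1:
        raise ValueError(f"interval ({start},{end}) is not a single base")
    return start + 1


def normalize_chrom(name: str) -> str:
    """Strip a leading 'chr' prefix.  Never applied implicitly: chromosome
    matching throughout the package is exact string equality."""
    return name[3:] if name.startswith("chr") else name


def classify_context(context: str) -> tuple[str, str]:
    """Classify a strand-resolved trinucleotide into (class, subclass).

    The class is decided by the second base alone: CG when it is G, CH when
    it is one of A/C/T (the 'H' degenerate code), and "ambiguous" when it
    is N.  The subclass is the literal trinucleotide.

    Raises ``ValueError`` if the first base is not C.
    """
    if not context or context[0] != "C":
        raise ValueError(f"context {context!r} does not start with C")
    second = context[1] if len(context) > 1 else "N"
    if second == "G":
        return "CG", context
    if second in "ACT":
        return "CH", context
    return "ambiguous", context


def context_class_array(contexts: pd.Series | np.ndarray) -> np.ndarray:
    """Vectorised context class for an array of trinucleotides."""
    second = pd.Series(np.asarray(contexts, dtype=object)).str.slice(1, 2)
    out = np.where(
        second == "G", "CG", np.where(second.isin(list("ACT")), "CH", "ambiguous")
    )
    return out.astype(object)


def context_mask(df: pd.DataFrame, selector: str) -> np.ndarray:
    """Boolean mask of rows matching a context selector.

    ``selector`` is ``"CG"``, ``"CH"`` or a literal trinucleotide such as
    ``"CAC"``.
    """
    if selector in ("CG", "CH"):
        return np.asarray(context_class_array(df["context"]) == selector)
    return np.asarray(df["context"] == selector)


@dataclass
class SampleMethylome:
    """Per-cytosine methylation counts for one sample.

    ``df`` holds one row per (chrom, pos, strand) with columns
    chrom, pos (1-based), strand, context (strand-resolved trinucleotide),
    mc (methylated reads) and cov (total reads).  Rows with cov = 0 are
    retained but ignored by every level computation.
    """

    sample_id: str
    df: pd.DataFrame
    genome_id: str = ""

    def __post_init__(self) -> None:
        df = self.df.reset_index(drop=True)
        missing = [c for c in ALLC_COLUMNS if c not in df.columns]
        if missing:
            raise ValueError(f"methylome table missing columns {missing}")
        if (df["mc"] < 0).any() or (df["cov"] < 0).any():
            raise ValueError("negative counts in methylome table")
        bad = df["mc"] > df["cov"]
        if bad.any():
            i = int(np.nonzero(bad.to_numpy())[0][0])
            raise ValueError(
                f"mc > cov at {df.at[i, 'chrom']}:{df.at[i, 'pos']}"
            )
        key = df[["chrom", "pos", "strand"]]
        if key.duplicated().any():
            dup = key[key.duplicated()].iloc[0]
            raise ValueError(
                f"duplicate site {dup['chrom']}:{dup['pos']}({dup['strand']})"
            )
        self.df = df

    def __len__(self) -> int:
        return len(self.df)

    def subset(self, mask: np.ndarray) -> "SampleMethylome":
        return SampleMethylome(self.sample_id, self.df.loc[mask].copy(), self.genome_id)


@dataclass
class SeriesDesign:
    """Temporal ordering of samples; T samples define T-1 transitions
    indexed 1..T-1."""

    ordered_samples: list[str]

    def __post_init__(self) -> None:
        if len(self.ordered_samples) < 2:
            raise ValueError("a series needs at least two samples")
        if len(set(self.ordered_samples)) != len(self.ordered_samples):
            raise ValueError("duplicate sample in series")

    @property
    def n_transitions(self) -> int:
        return len(self.ordered_samples) - 1

    def index(self, sample_id: str) -> int:
        try:
            return self.ordered_samples.index(sample_id)
        except ValueError:
            raise KeyError(f"sample {sample_id!r} not in series") from None


@dataclass
class GeneModel:
    """A gene with strand-resolved TSS/TES stored as genomic coordinates."""

    gene_id: str
    chrom: str
    strand: str
    tss: int
    tes: int

    def __post_init__(self) -> None:
        if self.strand not in "+-":
            raise ValueError(f"bad strand {self.strand!r}")
        if self.strand == "+" and self.tss > self.tes:
            raise ValueError(f"{self.gene_id}: + strand gene with tss > tes")
        if self.strand == "-" and self.tss < self.tes:
            raise ValueError(f"{self.gene_id}: - strand gene with tss < tes")

    @property
    def start(self) -> int:
        """Leftmost genomic coordinate (1-based)."""
        return min(self.tss, self.tes)

    @property
    def end(self) -> int:
        """Rightmost genomic coordinate (1-based)."""
        return max(self.tss, self.tes)

    @property
    def length(self) -> int:
        return self.end - self.start + 1


@dataclass
class RegionSet:
    """Named collection of 0-based half-open intervals with optional scores."""

    name: str
    intervals: list[tuple[str, int, int]]
    scores: list[float] | None = None

    def __post_init__(self) -> None:
        for chrom, start, end in self.intervals:
            if start >= end:
                raise ValueError(f"empty/inverted interval {chrom}:{start}-{end}")
        if self.scores is not None and len(self.scores) != len(self.intervals):
            raise ValueError("scores length mismatch")

    def __len__(self) -> int:
        return len(self.intervals)

    def to_frame(self) -> pd.DataFrame:
        df = pd.DataFrame(self.intervals, columns=["chrom", "start", "end"])
        if self.scores is not None:
            df["score"] = self.scores
        return df


@dataclass
class LoadReport:
    """Bookkeeping from reading an allc table."""

    n_rows: int = 0
    n_dropped_ambiguous: int = 0
    warnings: list[str] = field(default_factory=list)
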