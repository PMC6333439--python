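"""Readers and writers for the on-disk formats: allc per-cytosine tables,
BED region sets, gene tables, expression matrices and MEME minimal PWMs."""

from __future__ import annotations

import io as _io
from dataclasses import dataclass

import numpy as np
import pandas as pd

from .core import ALLC_COLUMNS, GeneModel, LoadReport, RegionSet, SampleMethylome

_ALLC_DTYPES = {"chrom": str, "pos": np.int64, "strand": str,
                "context": str, "mc": np.int64, "cov": np.int64}


def _looks_like_header(first_line: str) -> bool:
    fields = first_line.rstrip("\n").split("\t")
    if len(fields) < 6:
        return True
    try:
        int(fields[1]); int(fields[4]); int(fields[5])
    except ValueError:
        return True
    return False


def read_allc(path, sample_id: str | None = None, genome_id: str = "",
              return_report: bool = False):
    """Read an allc-style TSV (chrom, pos, strand, context, mc, cov).

    A header line is auto-detected.  An optional 7th binary "methylated
    call" column is ignored.  Rows whose context starts with N are dropped
    and counted in the load report; mc > cov or duplicate sites raise.
    """
    with open(path) as fh:
        first = fh.readline()
        if not first:
            raise ValueError(f"{path}: empty file")
        header = _looks_like_header(first)
    try:
        df = pd.read_csv(path, sep="\t", header=0 if header else None, dtype=str)
    except Exception as exc:  # pragma: no cover - pandas error passthrough
        raise ValueError(f"{path}: cannot parse as TSV: {exc}") from exc
    if header:
        df = df.rename(columns={c: c.strip().lower() for c in df.columns})
        missing = [c for c in ALLC_COLUMNS if c not in df.columns]
        if missing:
            raise ValueError(f"{path}: missing columns {missing}")
        df = df[ALLC_COLUMNS]
    else:
        if df.shape[1] < 6:
            raise ValueError(f"{path}: expected >= 6 columns, found {df.shape[1]}")
        df = df.iloc[:, :6]  # optional 7th methylated-call column ignored
        df.columns = ALLC_COLUMNS
    for col in ("pos", "mc", "cov"):
        converted = pd.to_numeric(df[col], errors="coerce")
        bad = converted.isna()
        if bad.any():
            line = int(np.nonzero(bad.to_numpy())[0][0]) + (2 if header else 1)
            raise ValueError(f"{path}: malformed {col!r} field at line {line}")
        df[col] = converted.astype(np.int64)
    report = LoadReport(n_rows=len(df))
    amb = df["context"].str.startswith("N")
    if amb.any():
        report.n_dropped_ambiguous = int(amb.sum())
        df = df.loc[~amb].reset_index(drop=True)
    meth = SampleMethylome(sample_id or str(path), df[ALLC_COLUMNS], genome_id)
    return (meth, report) if return_report else meth


def write_allc(methylome: SampleMethylome, path, calls=None) -> None:
    """Write an allc TSV; ``calls`` (optional boolean per-site array) is
    emitted as the 7th binary methylated-call column."""
    df = methylome.df[ALLC_COLUMNS].copy()
    if calls is not None:
        df["methylated"] = np.asarray(calls).astype(int)
    df.to_csv(path, sep="\t", header=False, index=False)


def exclude_sites(methylome: SampleMethylome, mask: RegionSet) -> SampleMethylome:
    """Drop sites falling inside a mask (e.g. positions flagged as
    potential variants upstream).  Mask intervals are 0-based half-open;
    a site at 1-based pos p is removed when some interval covers p-1."""
    by_chrom: dict[str, list[tuple[int, int]]] = {}
    for chrom, start, end in mask.intervals:
        by_chrom.setdefault(chrom, []).append((start, end))
    keep = np.ones(len(methylome.df), dtype=bool)
    for chrom, ivs in by_chrom.items():
        arr = np.array(sorted(ivs), dtype=np.int64)
        starts, ends = arr[:, 0], np.maximum.accumulate(arr[:, 1])
        rows = methylome.df["chrom"] == chrom
        pos0 = methylome.df.loc[rows, "pos"].to_numpy() - 1
        j = np.searchsorted(starts, pos0, side="right")
        covered = (j > 0) & (ends[np.clip(j - 1, 0, None)] > pos0)
        keep[np.nonzero(rows.to_numpy())[0][covered]] = False
    return methylome.subset(keep)


def read_regions(path, name: str | None = None) -> RegionSet:
    """Read a BED3+ file into a RegionSet (0-based half-open, verbatim).

    Column 5 (BED score) is kept when present and numeric.
    """
    rows, scores = [], []
    any_score = False
    with open(path) as fh:
        for ln, line in enumerate(fh, 1):
            line = line.rstrip("\n")
            if not line or line.startswith(("#", "track", "browser")):
                continue
            fields = line.split("\t")
            if len(fields) < 3:
                raise ValueError(f"{path}:{ln}: fewer than 3 BED columns")
            try:
                start, end = int(fields[1]), int(fields[2])
            except ValueError:
                raise ValueError(f"{path}:{ln}: non-integer coordinates") from None
            if start >= end:
                raise ValueError(f"{path}:{ln}: start >= end ({start} >= {end})")
            rows.append((fields[0], start, end))
            if len(fields) >= 5:
                try:
                    scores.append(float(fields[4]))
                    any_score = True
                except ValueError:
                    scores.append(float("nan"))
            else:
                scores.append(float("nan"))
    return RegionSet(name or str(path), rows, scores if any_score else None)


def write_regions(regions: RegionSet, path) -> None:
    with open(path, "w") as fh:
        for i, (chrom, start, end) in enumerate(regions.intervals):
            if regions.scores is not None:
                fh.write(f"{chrom}\t{start}\t{end}\t{regions.name}\t{regions.scores[i]}\n")
            else:
                fh.write(f"{chrom}\t{start}\t{end}\n")


def read_genes(path) -> list[GeneModel]:
    """Read a gene table TSV with columns gene_id, chrom, strand, tss, tes."""
    df = pd.read_csv(path, sep="\t", dtype={"gene_id": str, "chrom": str, "strand": str})
    need = ["gene_id", "chrom", "strand", "tss", "tes"]
    missing = [c for c in need if c not in df.columns]
    if missing:
        raise ValueError(f"{path}: missing columns {missing}")
    return [
        GeneModel(r.gene_id, r.chrom, r.strand, int(r.tss), int(r.tes))
        for r in df.itertuples()
    ]


def write_genes(genes: list[GeneModel], path) -> None:
    pd.DataFrame(
        [(g.gene_id, g.chrom, g.strand, g.tss, g.tes) for g in genes],
        columns=["gene_id", "chrom", "strand", "tss", "tes"],
    ).to_csv(path, sep="\t", index=False)


def read_expression(path) -> pd.DataFrame:
    """Read a gene x sample expression matrix (TSV, first column gene_id)."""
    df = pd.read_csv(path, sep="\t", index_col=0)
    df.index = df.index.astype(str)
    return df


@dataclass
class PWM:
    """Position probability matrix over (A, C, G, T) with a 0-order
    background; rows sum to 1 within 1e-6."""

    motif_id: str
    matrix: np.ndarray  # width x 4
    background: np.ndarray | None = None

    def __post_init__(self) -> None:
        self.matrix = np.asarray(self.matrix, dtype=float)
        if self.matrix.ndim != 2 or self.matrix.shape[1] != 4:
            raise ValueError(f"{self.motif_id}: PWM must be width x 4")
        if (self.matrix < 0).any():
            raise ValueError(f"{self.motif_id}: negative PWM entry")
        sums = self.matrix.sum(axis=1)
        if np.abs(sums - 1).max() > 1e-6:
            raise ValueError(f"{self.motif_id}: PWM rows do not sum to 1")
        if self.background is None:
            self.background = np.full(4, 0.25)
        self.background = np.asarray(self.background, dtype=float)
        if abs(self.background.sum() - 1) > 1e-6:
            raise ValueError(f"{self.motif_id}: background does not sum to 1")

    @property
    def width(self) -> int:
        return self.matrix.shape[0]


def read_pwm(path, renormalize: bool = True) -> list[PWM]:
    """Read MEME minimal motif format.

    Recognises ``MOTIF`` blocks with ``letter-probability matrix`` sections
    and an optional ``Background letter frequencies`` line.  With
    ``renormalize`` (default) rows are rescaled to sum to exactly 1;
    without it, rows off by more than 1e-6 raise.
    """
    with open(path) as fh:
        lines = fh.readlines()
    background = None
    motifs: list[PWM] = []
    i = 0
    while i < len(lines):
        line = lines[i].strip()
        if line.startswith("Background letter frequencies"):
            vals = lines[i + 1].split()
            background = np.array([float(vals[j]) for j in (1, 3, 5, 7)])
            i += 2
            continue
        if line.startswith("MOTIF"):
            parts = line.split()
            motif_id = parts[1] if len(parts) > 1 else f"motif{len(motifs) + 1}"
            j = i + 1
            while j < len(lines) and "letter-probability matrix" not in lines[j]:
                j += 1
            if j == len(lines):
                raise ValueError(f"{path}: MOTIF {motif_id} lacks a probability matrix")
            rows = []
            j += 1
            while j < len(lines):
                fields = lines[j].split()
                if len(fields) != 4:
                    break
                try:
                    rows.append([float(x) for x in fields])
                except ValueError:
                    break
                j += 1
            mat = np.array(rows, dtype=float)
            if mat.size == 0:
                raise ValueError(f"{path}: MOTIF {motif_id} has an empty matrix")
            if (mat < 0).any():
                raise ValueError(f"{path}: MOTIF {motif_id} has a negative entry")
            sums = mat.sum(axis=1)
            if renormalize:
                mat = mat / sums[:, None]
            elif np.abs(sums - 1).max() > 1e-6:
                raise ValueError(f"{path}: MOTIF {motif_id} rows do not sum to 1")
            motifs.append(PWM(motif_id, mat, background))
            i = j
            continue
        i += 1
    if not motifs:
        raise ValueError(f"{path}: no MOTIF blocks found")
    return motifs


def write_pwm(pwms: list[PWM], path) -> None:
    """Write MEME minimal motif format."""
    with open(path, "w") as fh:
        fh.write("MEME version 4\n\nALPHABET= ACGT\n\nstrands: + -\n\n")
        bg = pwms[0].background
        fh.write("Background letter frequencies\n")
        fh.write(f"A {bg[0]:.5f} C {bg[1]:.5f} G {bg[2]:.5f} T {bg[3]:.5f}\n\n")
        for pwm in pwms:
            fh.write(f"MOTIF {pwm.motif_id}\n")
            fh.write(
                f"letter-probability matrix: alength= 4 w= {pwm.width} "
                f"nsites= 20 E= 0\n"
            )
            for row in pwm.matrix:
                fh.write(" ".join(f"{x:.6f}" for x in row) + "\n")
            fh.write("\n")


def read_fasta(path) -> dict[str, str]:
    """Read a (small) FASTA into a dict of upper-case sequences."""
    seqs: dict[str, list[str]] = {}
    name = None
    with open(path) as fh:
        for line in fh:
            line = line.strip()
            if line.startswith(">"):
                name = line[1:].split()[0]
                seqs[name] = []
            elif name is not None:
                seqs[name].append(line.upper())
    return {k: "".join(v) for k, v in seqs.items()}
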