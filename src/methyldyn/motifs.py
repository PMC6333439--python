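"""PWM scanning with exact log-odds p-values.

Scoring follows the FIMO convention: a width-w window scores
sum_i log2(pwm[i][base_i] / background[base_i]); both strands are scanned
and windows containing N are skipped.  The p-value of a score is the
exact probability that a width-w sequence drawn from the 0-order
background scores at least as high, computed by dynamic programming over
the score distribution discretised to a 1e-3 bit grid.  Zero matrix
entries are floored at 1e-4 before taking log-odds.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .io import PWM

SCORE_GRID_BITS = 1e-3
ZERO_FLOOR = 1e-4
_BASE_INDEX = {"A": 0, "C": 1, "G": 2, "T": 3}


@dataclass
class MotifHit:
    chrom: str
    start: int  # 0-based half-open
    end: int
    strand: str
    score: float  # log2 odds, bits
    p: float


def _log_odds(pwm: PWM) -> np.ndarray:
    mat = np.maximum(pwm.matrix, ZERO_FLOOR)
    return np.log2(mat / pwm.background[None, :])


def _int_scores(pwm: PWM) -> np.ndarray:
    """Log-odds matrix on the integer score grid."""
    return np.rint(_log_odds(pwm) / SCORE_GRID_BITS).astype(np.int64)


def score_pvalue_table(pwm: PWM) -> tuple[np.ndarray, np.ndarray, int]:
    """Exact survival function of the background score distribution.

    Returns (grid_scores_offsetted_sf, min_total, max_total): ``sf[s]`` is
    P[score >= (s + min_total) * grid] for a background-generated
    width-mer.
    """
    scores = _int_scores(pwm)
    mins = scores.min(axis=1)
    maxs = scores.max(axis=1)
    min_total, max_total = int(mins.sum()), int(maxs.sum())
    size = max_total - min_total + 1
    dist = np.zeros(size)
    dist[0] = 1.0  # running distribution over (partial score - partial min)
    width = 0
    for i in range(pwm.width):
        row = scores[i] - mins[i]
        new = np.zeros(size)
        for b in range(4):
            s = int(row[b])
            new[s:] += dist[: size - s if s else size] * pwm.background[b]
        dist = new
        width += 1
    sf = np.cumsum(dist[::-1])[::-1]
    return sf, min_total, max_total


def pwm_pvalue(pwm: PWM, score_bits: float) -> float:
    """Exact background p-value of a (float) bit score."""
    sf, min_total, max_total = score_pvalue_table(pwm)
    s = int(np.rint(score_bits / SCORE_GRID_BITS)) - min_total
    if s <= 0:
        return 1.0
    if s >= len(sf):
        return 0.0
    return float(sf[s])


_COMPLEMENT = np.array([3, 2, 1, 0])


def _encode(sequence: str) -> np.ndarray:
    arr = np.frombuffer(sequence.upper().encode(), dtype=np.uint8)
    out = np.full(arr.shape, -1, dtype=np.int64)
    for base, idx in _BASE_INDEX.items():
        out[arr == ord(base)] = idx
    return out


def scan_pwm(
    sequence: str, pwm: PWM, p_threshold: float = 1e-5,
    chrom: str = "", offset: int = 0,
) -> list[MotifHit]:
    """Scan both strands of a sequence and return hits with p < threshold.

    ``offset`` shifts reported coordinates (0-based) for scanning a
    sub-sequence of a chromosome.  Windows containing non-ACGT letters are
    skipped; a PWM wider than the sequence yields no hits.
    """
    w = pwm.width
    enc = _encode(sequence)
    n = len(enc) - w + 1
    if n <= 0:
        return []
    sf, min_total, _ = score_pvalue_table(pwm)
    int_scores = _int_scores(pwm)
    # threshold on the integer grid: smallest integer score with p < threshold
    below = np.nonzero(sf < p_threshold)[0]
    if len(below) == 0:
        return []
    min_int = int(below[0])  # offset units above min_total

    hits: list[MotifHit] = []
    lod = _log_odds(pwm)
    valid = enc >= 0
    ok_window = np.ones(n, dtype=bool)
    for i in range(w):
        ok_window &= valid[i : i + n]
    rc_scores = int_scores[::-1][:, _COMPLEMENT]
    rc_lod = lod[::-1][:, _COMPLEMENT]
    for strand, iscore, flod in (("+", int_scores, lod), ("-", rc_scores, rc_lod)):
        total = np.zeros(n, dtype=np.int64)
        safe = np.where(valid, enc, 0)
        for i in range(w):
            total += iscore[i][safe[i : i + n]]
        passing = np.nonzero(ok_window & (total - min_total >= min_int))[0]
        for pos in passing:
            s = int(total[pos]) - min_total
            p = float(sf[s]) if s < len(sf) else 0.0
            bits = float(sum(flod[i][enc[pos + i]] for i in range(w)))
            hits.append(MotifHit(chrom, offset + pos, offset + pos + w, strand, bits, p))
    hits.sort(key=lambda h: (h.start, h.strand))
    return hits


def scan_genome(
    sequences: dict[str, str], pwm: PWM, p_threshold: float = 1e-5
) -> list[MotifHit]:
    """Scan every chromosome of a genome dict."""
    hits: list[MotifHit] = []
    for chrom, seq in sequences.items():
        hits.extend(scan_pwm(seq, pwm, p_threshold, chrom=chrom))
    return hits
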