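"""PWM motif scanning with exact tail p-values.

A position frequency matrix (JASPAR-style counts) becomes a PWM by
pseudocount-normalizing each column; windows of a sequence are scored by
the log2 likelihood ratio against a 0-order background. Significance is the
exact probability, under that background, of a score at least as large —
obtained by dynamic programming over the distribution of the *discretized*
score (the scanner scores windows with the same discretized matrix, so DP
p-values are exact for the scores it reports; this is the convention of
standard PWM scanners).
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Iterable, Sequence

import numpy as np

ALPHABET = "ACGT"
_INDEX = {c: i for i, c in enumerate(ALPHABET)}
_COMPLEMENT = np.array([3, 2, 1, 0])  # A<->T, C<->G
UNIFORM_BG = np.full(4, 0.25)

#: number of integer score levels across the achievable score range
N_SCORE_BINS = 1000


@dataclass(frozen=True)
class PWM:
    """Column-stochastic motif model over {A, C, G, T}."""

    matrix: np.ndarray            # (width, 4) probabilities per position
    background: np.ndarray        # (4,) 0-order background
    pseudocount: float = 0.1
    name: str | None = None

    def __post_init__(self) -> None:
        m = np.asarray(self.matrix, float)
        if m.ndim != 2 or m.shape[1] != 4:
            raise ValueError("PWM matrix must have shape (width, 4)")
        if not np.allclose(m.sum(axis=1), 1.0, atol=1e-9):
            raise ValueError("each PWM column must sum to 1")
        bg = np.asarray(self.background, float)
        if bg.shape != (4,) or not np.isclose(bg.sum(), 1.0, atol=1e-9):
            raise ValueError("background must be a length-4 probability vector")

    @property
    def width(self) -> int:
        return self.matrix.shape[0]

    @classmethod
    def from_counts(
        cls,
        counts: np.ndarray,
        background: np.ndarray | None = None,
        pseudocount: float = 0.1,
        name: str | None = None,
    ) -> "PWM":
        """Build from a (width, 4) count matrix with additive pseudocount."""
        counts = np.asarray(counts, float)
        if np.any(counts < 0):
            raise ValueError("counts must be non-negative")
        m = counts + pseudocount
        m = m / m.sum(axis=1, keepdims=True)
        bg = UNIFORM_BG if background is None else np.asarray(background, float)
        return cls(matrix=m, background=bg, pseudocount=pseudocount, name=name)

    def reverse_complement(self) -> "PWM":
        return PWM(
            matrix=self.matrix[::-1, _COMPLEMENT].copy(),
            background=self.background,
            pseudocount=self.pseudocount,
            name=self.name,
        )

    def llr_matrix(self) -> np.ndarray:
        """(width, 4) log2 likelihood-ratio scores."""
        return np.log2(self.matrix / self.background[None, :])


@dataclass(frozen=True)
class MotifHit:
    position: int           # 0-based offset of the window on the input sequence
    strand: str             # '+' or '-'
    score: float            # log2 likelihood ratio (bits)
    p_value: float

    def __post_init__(self) -> None:
        if not (0 < self.p_value <= 1):
            raise ValueError("p-value must lie in (0, 1]")


def read_jaspar(path: str) -> list[PWM]:
    """Read JASPAR plain-text PFMs (via Biopython's motif parser)."""
    from Bio import motifs as bio_motifs

    out = []
    with open(path) as fh:
        for m in bio_motifs.parse(fh, "jaspar"):
            counts = np.array([[m.counts[b][i] for b in ALPHABET] for i in range(m.length)])
            out.append(PWM.from_counts(counts, name=m.matrix_id or m.name))
    return out


def discretize_scores(pwm: PWM, n_bins: int = N_SCORE_BINS) -> tuple[np.ndarray, float, float]:
    """Map the LLR matrix to integers.

    Each entry is rounded to the nearest multiple of
    ``eps = score_range / n_bins`` where the range spans the minimum to
    maximum achievable window score. Returns (int_matrix, eps, offset) with
    entries shifted so the per-position minimum is 0.
    """
    llr = pwm.llr_matrix()
    lo = llr.min(axis=1).sum()
    hi = llr.max(axis=1).sum()
    rng = hi - lo
    if rng <= 0:  # uninformative matrix: all scores identical
        return np.zeros_like(llr, dtype=np.int64), 1.0, float(lo)
    eps = rng / n_bins
    ints = np.rint(llr / eps).astype(np.int64)
    shift = ints.min(axis=1)
    return ints - shift[:, None], eps, float((shift * eps).sum())


def score_distribution(int_matrix: np.ndarray, background: np.ndarray) -> np.ndarray:
    """Exact pmf of the integer window score under the 0-order background.

    Classic convolution DP: one pass per motif position over the current
    support. Index i of the result is P(score == i).
    """
    max_total = int(int_matrix.max(axis=1).sum())
    pmf = np.zeros(max_total + 1)
    pmf[0] = 1.0
    top = 0
    for row in int_matrix:
        new = np.zeros(max_total + 1)
        for base in range(4):
            s = int(row[base])
            new[s : top + s + 1] += background[base] * pmf[: top + 1]
        pmf = new
        top += int(row.max())
    return pmf


def _tail(pmf: np.ndarray) -> np.ndarray:
    """tail[i] = P(score >= i)."""
    return np.cumsum(pmf[::-1])[::-1]


def _encode(sequence: str) -> np.ndarray:
    """Sequence to integer codes; anything outside ACGT becomes -1."""
    arr = np.frombuffer(sequence.upper().encode("ascii"), dtype=np.uint8)
    codes = np.full(arr.size, -1, dtype=np.int8)
    for c, i in _INDEX.items():
        codes[arr == ord(c)] = i
    return codes


def scan_motifs(
    sequence: str,
    pwm: PWM,
    p_threshold: float = 1e-4,
    both_strands: bool = True,
    n_bins: int = N_SCORE_BINS,
) -> list[MotifHit]:
    """Scan a sequence for PWM matches with exact p < ``p_threshold``.

    Windows containing non-ACGT characters are skipped. The reverse strand
    is scanned with the reverse-complement matrix (its own exact score
    distribution, since the background need not be strand-symmetric). A PWM
    wider than the sequence yields an empty result. Hits are sorted by
    position, forward strand first at equal positions.
    """
    codes = _encode(sequence)
    w = pwm.width
    if codes.size < w:
        return []

    hits: list[MotifHit] = []
    strands = [("+", pwm)]
    if both_strands:
        strands.append(("-", pwm.reverse_complement()))
    n_windows = codes.size - w + 1
    # windows free of N (or other non-ACGT)
    bad = (codes < 0).astype(int)
    bad_cum = np.concatenate([[0], np.cumsum(bad)])
    clean = (bad_cum[w:] - bad_cum[:-w]) == 0

    for strand, mat in strands:
        ints, eps, offset = discretize_scores(mat, n_bins)
        tail = _tail(score_distribution(ints, mat.background))
        safe = np.where(codes < 0, 0, codes)
        # integer score per window via strided sum
        iscore = np.zeros(n_windows, dtype=np.int64)
        for j in range(w):
            iscore += ints[j, safe[j : j + n_windows]]
        pvals = tail[iscore]
        for pos in np.nonzero(clean & (pvals < p_threshold))[0]:
            hits.append(
                MotifHit(
                    position=int(pos),
                    strand=strand,
                    score=float(iscore[pos] * eps + offset),
                    p_value=float(pvals[pos]),
                )
            )
    hits.sort(key=lambda h: (h.position, h.strand))
    return hits
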