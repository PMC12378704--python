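"""Position-specific similarity matrix (PSSM) construction and scoring.

Each alignment column yields, per nucleotide, a log2 ratio of the observed
column frequency (gaps excluded) to a uniform background of 0.25. A
sequence's score S is the sum of the strictly positive per-column values
along its row: negative positions are disregarded so that long matches are
not penalized for occasional low-scoring columns, and gaps contribute
nothing (no gap penalties).
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .msa import Alignment

BASES = "ACGT"
_BASE_INDEX = {b: i for i, b in enumerate(BASES)}


@dataclass
class PSSM:
    """Per-column nucleotide frequencies and log-ratio scores.

    Attributes
    ----------
    freqs : (width, 4) array
        Observed A/C/G/T proportions per column, gaps excluded.
    scores : (width, 4) array
        log2((count_b + pseudocount) / (n_nongap + 4*pseudocount) / background_b).
    all_gap : (width,) bool array
        Columns with no residues; their scores are zero and flagged here.
    """

    freqs: np.ndarray
    scores: np.ndarray
    pseudocount: float
    background: np.ndarray = field(
        default_factory=lambda: np.full(4, 0.25)
    )
    all_gap: np.ndarray = field(default_factory=lambda: np.zeros(0, dtype=bool))

    @property
    def width(self) -> int:
        return self.scores.shape[0]

    def consensus(self) -> str:
        """Highest-frequency base per column (ties broken A<C<G<T)."""
        return "".join(BASES[i] for i in self.freqs.argmax(axis=1))


@dataclass(frozen=True)
class SeqScore:
    """Positive-sum PSSM score and the number of contributing columns."""

    value: float
    positions_used: int


def build_pssm(
    aln: Alignment,
    pseudocount: float = 0.25,
    background: np.ndarray | None = None,
) -> PSSM:
    """Column frequencies and log2-ratio scores from an alignment.

    Frequencies are computed over non-gap characters only. A column that is
    entirely gaps gets zero scores and is flagged in ``all_gap``.
    """
    if not aln.rows:
        raise ValueError("alignment is empty")
    bg = np.full(4, 0.25) if background is None else np.asarray(background, float)
    mat = np.frombuffer(
        "".join(aln.rows).encode(), dtype="S1"
    ).reshape(len(aln.rows), aln.width)
    counts = np.zeros((aln.width, 4))
    for b, k in _BASE_INDEX.items():
        counts[:, k] = (mat == b.encode()).sum(axis=0)
    n_nongap = counts.sum(axis=1)
    all_gap = n_nongap == 0
    denom = np.where(all_gap, 1.0, n_nongap)
    freqs = counts / denom[:, None]
    with np.errstate(divide="ignore"):
        scores = np.log2(
            (counts + pseudocount)
            / (n_nongap + 4 * pseudocount)[:, None]
            / bg[None, :]
        )
    scores[all_gap] = 0.0
    scores[np.isneginf(scores)] = -np.inf  # pseudocount 0 with zero count
    freqs[all_gap] = 0.0
    return PSSM(freqs=freqs, scores=scores, pseudocount=pseudocount,
                background=bg, all_gap=all_gap)


def score_aligned_row(pssm: PSSM, row: str) -> SeqScore:
    """Positive-sum score of one gapped row against the matrix.

    Gap columns contribute 0; so do columns where the residue's score is
    negative. The result is therefore always >= 0.
    """
    if len(row) != pssm.width:
        raise ValueError(
            f"row width {len(row)} != PSSM width {pssm.width}"
        )
    total, used = 0.0, 0
    for i, ch in enumerate(row):
        if ch == "-":
            continue
        s = pssm.scores[i, _BASE_INDEX[ch]]
        if s > 0:
            total += s
            used += 1
    return SeqScore(float(total), used)


def score_sliding(pssm: PSSM, seq: str) -> SeqScore:
    """Best positive-sum score over every offset of ``seq`` against the matrix.

    The sequence may overhang either end of the matrix; out-of-matrix
    positions contribute 0. Used to score arbitrary (e.g. G4 control)
    sequences that were never part of the alignment.
    """
    if not seq:
        raise ValueError("empty sequence")
    idx = np.array([_BASE_INDEX[c] for c in seq])
    n, w = len(seq), pssm.width
    pos = np.clip(pssm.scores, 0.0, None)
    best_val, best_used = 0.0, 0
    for offset in range(-(n - 1), w):
        j0 = max(0, -offset)
        j1 = min(n, w - offset)
        if j0 >= j1:
            continue
        cols = np.arange(j0, j1) + offset
        vals = pos[cols, idx[j0:j1]]
        val = float(vals.sum())
        if val > best_val:
            best_val, best_used = val, int((vals > 0).sum())
    return SeqScore(best_val, best_used)


def max_column_consensus(pssm: PSSM) -> np.ndarray:
    """Maximum column frequency rescaled to percent (100 = fully conserved)."""
    return pssm.freqs.max(axis=1) * 100.0
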