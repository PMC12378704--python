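"""Multiple sequence alignment of motif matches, grouped by chromosome and strand.

Matches are extended by up to three reference nucleotides on each side (in
motif orientation) before alignment, so that conserved context just outside
the core motif contributes to the similarity matrix.

Two engines are provided behind one interface:

* ``builtin`` — a deterministic progressive aligner (pairwise global
  alignment under match +1 / mismatch -1 / gap -2, UPGMA guide tree on a
  shared k-mer distance). It needs no external binary and is the default.
* ``external`` — delegates to ``mafft`` via subprocess over FASTA streams.
"""

from __future__ import annotations

import shutil
import subprocess
import tempfile
from dataclasses import dataclass

import numpy as np
from scipy.cluster.hierarchy import linkage
from scipy.spatial.distance import squareform

from .genome import GenomeSeq, reverse_complement
from .scanner import MotifMatch

MATCH_SCORE = 1.0
MISMATCH_SCORE = -1.0
GAP_SCORE = -2.0


@dataclass(frozen=True)
class FlankedSeq:
    """A motif match plus its immediate sequence context.

    ``full_seq`` = flank5 + match.seq + flank3, all in motif orientation.
    Flanks are truncated at chromosome ends, so they may be shorter than
    the requested width.
    """

    match: MotifMatch
    flank5: str
    flank3: str

    @property
    def full_seq(self) -> str:
        return self.flank5 + self.match.seq + self.flank3

    @property
    def id(self) -> str:
        return self.match.name


def extract_flanked(match: MotifMatch, genome: GenomeSeq, flank: int = 3) -> FlankedSeq:
    """Attach up to ``flank`` reference bases on each side, in motif orientation.

    For a minus-strand match the 5' flank (in motif orientation) lies
    3' of the interval on the reference, reverse-complemented.
    """
    contig = genome[match.chrom]
    if not (0 <= match.start <= match.end <= len(contig)):
        raise ValueError(
            f"match {match.name} outside contig bounds (length {len(contig)})"
        )
    left = contig[max(match.start - flank, 0) : match.start]
    right = contig[match.end : match.end + flank]
    if match.strand == "+":
        return FlankedSeq(match, left, right)
    return FlankedSeq(match, reverse_complement(right), reverse_complement(left))


@dataclass
class Alignment:
    """Gapped rows of equal width; de-gapping row i recovers input i."""

    rows: list[str]
    row_ids: list[str]
    engine: str = "builtin"

    def __post_init__(self) -> None:
        widths = {len(r) for r in self.rows}
        if len(widths) > 1:
            raise ValueError(f"ragged alignment, widths {sorted(widths)}")

    @property
    def width(self) -> int:
        return len(self.rows[0]) if self.rows else 0

    def degapped(self, i: int) -> str:
        return self.rows[i].replace("-", "")

    def to_fasta(self, path: str) -> None:
        with open(path, "w") as fh:
            for rid, row in zip(self.row_ids, self.rows):
                fh.write(f">{rid}\n{row}\n")


def _kmer_set(seq: str, k: int = 3) -> frozenset:
    if len(seq) < k:
        return frozenset(seq)
    return frozenset(seq[i : i + k] for i in range(len(seq) - k + 1))


def _guide_order(seqs: list[str]) -> list[tuple[int, int]]:
    """UPGMA join order over shared-k-mer distances.

    Returns linkage-style merge pairs referring to leaves 0..n-1 and
    internal nodes n, n+1, ... in creation order.
    """
    n = len(seqs)
    sets = [_kmer_set(s) for s in seqs]
    dist = np.zeros((n, n))
    for i in range(n):
        for j in range(i + 1, n):
            union = len(sets[i] | sets[j])
            jac = len(sets[i] & sets[j]) / union if union else 1.0
            dist[i, j] = dist[j, i] = 1.0 - jac
    Z = linkage(squareform(dist, checks=False), method="average")
    return [(int(a), int(b)) for a, b, _, _ in Z]


def _profile_align(A: list[str], B: list[str]) -> tuple[list[str], list[str]]:
    """Global alignment of two profiles (lists of equal-width gapped rows).

    Column-column score is the mean pairwise substitution score over
    non-gap residues; residue-against-gap pairs contribute 0, and aligning
    any column against a new gap costs GAP_SCORE. Ties in the traceback
    prefer diagonal, then a gap in B, then a gap in A — fixed so the
    aligner is deterministic.
    """
    wa, wb = len(A[0]), len(B[0])

    def base_counts(rows: list[str]) -> np.ndarray:
        mat = np.frombuffer("".join(rows).encode(), dtype="S1").reshape(
            len(rows), -1
        )
        return np.stack(
            [(mat == b).sum(axis=0) for b in (b"A", b"C", b"G", b"T")], axis=1
        ).astype(float)

    Ca, Cb = base_counts(A), base_counts(B)
    na, nb = Ca.sum(axis=1), Cb.sum(axis=1)
    pairs = np.outer(na, nb)
    match = Ca @ Cb.T
    # mean pairwise score over residue pairs: matches +1, mismatches -1
    with np.errstate(invalid="ignore", divide="ignore"):
        sub = np.where(
            pairs > 0,
            (match * MATCH_SCORE + (pairs - match) * MISMATCH_SCORE) / pairs,
            0.0,
        )

    S = np.empty((wa + 1, wb + 1))
    T = np.zeros((wa + 1, wb + 1), dtype=np.int8)  # 0 diag, 1 up(gap in B), 2 left
    S[:, 0] = np.arange(wa + 1) * GAP_SCORE
    S[0, :] = np.arange(wb + 1) * GAP_SCORE
    T[1:, 0] = 1
    T[0, 1:] = 2
    for i in range(1, wa + 1):
        for j in range(1, wb + 1):
            diag = S[i - 1, j - 1] + sub[i - 1, j - 1]
            up = S[i - 1, j] + GAP_SCORE
            left = S[i, j - 1] + GAP_SCORE
            best = max(diag, up, left)
            S[i, j] = best
            T[i, j] = 0 if best == diag else (1 if best == up else 2)
    # traceback -> per-profile column index lists with -1 for new gaps
    ia, ib = wa, wb
    pathA: list[int] = []
    pathB: list[int] = []
    while ia > 0 or ib > 0:
        t = T[ia, ib]
        if t == 0:
            ia -= 1
            ib -= 1
            pathA.append(ia)
            pathB.append(ib)
        elif t == 1:
            ia -= 1
            pathA.append(ia)
            pathB.append(-1)
        else:
            ib -= 1
            pathA.append(-1)
            pathB.append(ib)
    pathA.reverse()
    pathB.reverse()
    newA = ["".join(r[i] if i >= 0 else "-" for i in pathA) for r in A]
    newB = ["".join(r[j] if j >= 0 else "-" for j in pathB) for r in B]
    return newA, newB


def _align_builtin(seqs: list[str]) -> list[str]:
    n = len(seqs)
    if n == 1:
        return list(seqs)
    # each node: (rows, original row indices)
    nodes: dict[int, tuple[list[str], list[int]]] = {
        i: ([s], [i]) for i, s in enumerate(seqs)
    }
    nxt = n
    for a, b in _guide_order(seqs):
        rowsA, idxA = nodes.pop(a)
        rowsB, idxB = nodes.pop(b)
        newA, newB = _profile_align(rowsA, rowsB)
        nodes[nxt] = (newA + newB, idxA + idxB)
        nxt += 1
    rows, idx = nodes.popitem()[1]
    ordered = [None] * n
    for row, i in zip(rows, idx):
        ordered[i] = row
    return ordered  # type: ignore[return-value]


def _align_external(seqs: list[str], ids: list[str], binary: str = "mafft") -> list[str]:
    if shutil.which(binary) is None:
        raise RuntimeError(
            f"external alignment engine '{binary}' not found on PATH; "
            "re-run with --engine builtin"
        )
    with tempfile.NamedTemporaryFile("w", suffix=".fa", delete=False) as fh:
        for i, s in enumerate(seqs):
            fh.write(f">s{i}\n{s}\n")
        inpath = fh.name
    res = subprocess.run(
        [binary, "--auto", "--quiet", inpath],
        capture_output=True, text=True, check=True,
    )
    rows: dict[int, str] = {}
    cur = None
    for line in res.stdout.splitlines():
        if line.startswith(">"):
            cur = int(line[2:])
            rows[cur] = ""
        elif cur is not None:
            rows[cur] += line.strip().upper()
    return [rows[i] for i in range(len(seqs))]


def align_group(seqs: list[FlankedSeq], engine: str = "builtin") -> Alignment:
    """Align one (chromosome, strand) group of flanked matches.

    Input order is preserved in the output rows; the builtin engine is
    deterministic given that order.
    """
    if not seqs:
        raise ValueError("cannot align an empty group")
    strings = [s.full_seq for s in seqs]
    ids = [s.id for s in seqs]
    if engine == "builtin":
        rows = _align_builtin(strings)
    elif engine == "external":
        rows = _align_external(strings, ids)
    else:
        raise ValueError(f"unknown engine {engine!r}; use 'builtin' or 'external'")
    aln = Alignment(rows, ids, engine=engine)
    for i, s in enumerate(strings):
        if aln.degapped(i) != s:
            raise AssertionError(f"row {ids[i]} does not de-gap to its input")
    return aln


def group_matches(
    seqs: list[FlankedSeq], group_all: bool = False
) -> dict[tuple[str, str], list[FlankedSeq]]:
    """Partition flanked matches into (chromosome, strand) groups.

    ``group_all`` collapses everything into a single group, useful for
    small fixtures.
    """
    if group_all:
        return {("all", "."): list(seqs)}
    groups: dict[tuple[str, str], list[FlankedSeq]] = {}
    for s in seqs:
        groups.setdefault((s.match.chrom, s.match.strand), []).append(s)
    for key in groups:
        groups[key].sort(key=lambda s: s.match.start)
    return groups
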