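"""Genome-wide scan for C-rich i-motif candidate sequences.

The default pattern is (C3 N1-12)3 C3: four runs of three cytosines
separated by loops of 1-12 arbitrary bases. Both strands are scanned; the
reverse strand is searched on the reverse complement of each chromosome and
hits are mapped back into reference coordinates. Matching is
non-overlapping, leftmost and greedy — the semantics of standard regex
engines.
"""

from __future__ import annotations

import re
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .genome import GenomeSeq, reverse_complement


@dataclass(frozen=True)
class MotifPattern:
    """Parameters of the tandem C-run motif (C3 N1-12)3 C3 by default."""

    run_base: str = "C"
    run_len: int = 3
    n_runs: int = 4
    loop_min: int = 1
    loop_max: int = 12

    def __post_init__(self) -> None:
        if self.run_len < 1:
            raise ValueError("run_len must be >= 1")
        if not (1 <= self.loop_min <= self.loop_max):
            raise ValueError("need 1 <= loop_min <= loop_max")
        if self.n_runs < 2:
            raise ValueError("n_runs must be >= 2")
        if self.run_base not in "ACGT":
            raise ValueError("run_base must be one of A/C/G/T")

    def regex(self) -> re.Pattern:
        run = self.run_base * self.run_len
        loop = f"[ACGT]{{{self.loop_min},{self.loop_max}}}"
        return re.compile(f"(?:{run}{loop}){{{self.n_runs - 1}}}{run}")


def match_length_bounds(pattern: MotifPattern) -> tuple[int, int]:
    """Shortest and longest string the pattern can match.

    min = n_runs*run_len + (n_runs-1)*loop_min and analogously for max; the
    default pattern gives (15, 48).
    """
    core = pattern.n_runs * pattern.run_len
    n_loops = pattern.n_runs - 1
    return core + n_loops * pattern.loop_min, core + n_loops * pattern.loop_max


@dataclass(frozen=True)
class MotifMatch:
    """One motif hit in 0-based half-open reference coordinates.

    ``seq`` is given in motif orientation: for strand "-" it is the reverse
    complement of the reference slice [start, end).
    """

    chrom: str
    start: int
    end: int
    strand: str
    seq: str

    def __post_init__(self) -> None:
        if self.end - self.start != len(self.seq):
            raise ValueError("interval length must equal sequence length")
        if self.strand not in "+-":
            raise ValueError("strand must be '+' or '-'")

    @property
    def name(self) -> str:
        return f"{self.chrom}:{self.start}-{self.end}({self.strand})"


def scan_motifs(genome: GenomeSeq, pattern: MotifPattern | None = None) -> list[MotifMatch]:
    """Find every non-overlapping, leftmost, greedy motif match on both strands.

    Reverse-strand hits are located on the reverse complement and reported
    in reference coordinates (start_ref = L - end_rc). Matches are returned
    sorted by (chrom, start, strand). The pattern only admits A/C/G/T, so
    any match spanning an N is impossible by construction.
    """
    if pattern is None:
        pattern = MotifPattern()
    rx = pattern.regex()
    out: list[MotifMatch] = []
    for chrom in genome.chrom_names:
        fwd = genome[chrom]
        L = len(fwd)
        for m in rx.finditer(fwd):
            out.append(MotifMatch(chrom, m.start(), m.end(), "+", m.group()))
        rc = reverse_complement(fwd)
        for m in rx.finditer(rc):
            out.append(
                MotifMatch(chrom, L - m.end(), L - m.start(), "-", m.group())
            )
    out.sort(key=lambda h: (h.chrom, h.start, h.strand))
    return out


def summarize_matches(matches: list[MotifMatch]) -> pd.DataFrame:
    """Per-chromosome, per-strand counts plus length mean/median/sd.

    Returns one row per (chrom, strand) and a final "total" row. On empty
    input the total row carries count 0 and NaN statistics.
    """
    if not matches:
        return pd.DataFrame(
            [{"chrom": "total", "strand": ".", "count": 0,
              "mean_len": np.nan, "median_len": np.nan, "sd_len": np.nan}]
        )
    df = pd.DataFrame(
        {
            "chrom": [m.chrom for m in matches],
            "strand": [m.strand for m in matches],
            "length": [len(m.seq) for m in matches],
        }
    )
    per = (
        df.groupby(["chrom", "strand"], as_index=False)["length"]
        .agg(count="size", mean_len="mean", median_len="median", sd_len="std")
    )
    total = pd.DataFrame(
        [{"chrom": "total", "strand": ".", "count": len(df),
          "mean_len": df.length.mean(), "median_len": df.length.median(),
          "sd_len": df.length.std()}]
    )
    return pd.concat([per, total], ignore_index=True)


def matches_to_bed(matches: list[MotifMatch], path: str) -> None:
    """Write matches as BED6 (score column is a placeholder 0)."""
    with open(path, "w") as fh:
        for m in matches:
            fh.write(f"{m.chrom}\t{m.start}\t{m.end}\t{m.seq}\t0\t{m.strand}\n")


def matches_from_bed(path: str) -> list[MotifMatch]:
    out = []
    with open(path) as fh:
        for line in fh:
            if not line.strip():
                continue
            chrom, start, end, name, _score, strand = line.rstrip("\n").split("\t")[:6]
            out.append(MotifMatch(chrom, int(start), int(end), strand, name))
    return out
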