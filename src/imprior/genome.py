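"""Genome sequences with strand-aware coordinate handling.

DNA is held as plain uppercase strings over {A,C,G,T,N}; coordinates are
0-based half-open in reference orientation throughout the library, and only
converted to 1-based in human-readable reports.
"""

from __future__ import annotations

from dataclasses import dataclass, field

from pyfaidx import Fasta

VALID_ALPHABET = frozenset("ACGTN")

_COMPLEMENT = str.maketrans("ACGTN", "TGCAN")

#: Canonical human chromosome names (UCSC style), the default scan universe.
CANONICAL_CHROMS = tuple(f"chr{i}" for i in list(range(1, 23)) + ["X", "Y"])


def reverse_complement(seq: str) -> str:
    """Reverse complement of a DNA string (N maps to N)."""
    return seq.translate(_COMPLEMENT)[::-1]


def validate_sequence(seq: str, name: str = "sequence") -> None:
    """Raise ValueError on any character outside {A,C,G,T,N}."""
    bad = set(seq) - VALID_ALPHABET
    if bad:
        raise ValueError(
            f"{name} contains characters outside the A/C/G/T/N alphabet: "
            f"{sorted(bad)}"
        )


@dataclass
class GenomeSeq:
    """Named chromosome sequences.

    Parameters
    ----------
    sequences
        Mapping of chromosome name to uppercase DNA string.
    """

    sequences: dict[str, str] = field(default_factory=dict)

    def __post_init__(self) -> None:
        for name, seq in self.sequences.items():
            validate_sequence(seq, name)

    @property
    def chrom_names(self) -> list[str]:
        return list(self.sequences)

    def __getitem__(self, chrom: str) -> str:
        return self.sequences[chrom]

    def __contains__(self, chrom: str) -> bool:
        return chrom in self.sequences

    def fetch(self, chrom: str, start: int, end: int, strand: str = "+") -> str:
        """Subsequence in the requested orientation; clips to contig bounds."""
        seq = self.sequences[chrom]
        piece = seq[max(start, 0) : min(end, len(seq))]
        return reverse_complement(piece) if strand == "-" else piece

    @classmethod
    def from_fasta(
        cls, path: str, chroms: list[str] | None = None
    ) -> "GenomeSeq":
        """Load (a subset of) a FASTA file.

        Parameters
        ----------
        chroms
            Optional whitelist of record names; default = every record.
        """
        fa = Fasta(path, rebuild=False, as_raw=True, sequence_always_upper=True)
        names = [n for n in fa.keys() if chroms is None or n in chroms]
        return cls({name: str(fa[name][:]) for name in names})

    def to_fasta(self, path: str, width: int = 70) -> None:
        with open(path, "w") as fh:
            for name, seq in self.sequences.items():
                fh.write(f">{name}\n")
                for i in range(0, len(seq), width):
                    fh.write(seq[i : i + width] + "\n")
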