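"""Synthetic genomes, gene tracks and control sets for end-to-end testing.

The generator implants motif instances drawn from the i-motif grammar
(C3 N1-12)3 C3 into a background engineered to contain no spurious hits on
either strand (no CCC and no GGG runs), and emits the ground truth as a
BED table. Implants are sampled in a "safe" mode — loop edges avoid C/G
and loops avoid CC/GG — and are buffered by a single A/T base on each
side, so the scanner's greedy leftmost semantics recover every implant at
exactly its recorded coordinates.

This emulates the combinatorial structure of real C-rich loci, not the
base composition or repeat landscape of a real genome.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from .genome import GenomeSeq, reverse_complement
from .scanner import MotifPattern


def _rng(seed_or_rng) -> np.random.Generator:
    if isinstance(seed_or_rng, np.random.Generator):
        return seed_or_rng
    return np.random.default_rng(seed_or_rng)


def _safe_loop(length: int, rng: np.random.Generator) -> str:
    """Loop with no C/G at either edge and no CC/GG inside.

    Keeps the implant's C-runs exactly the four designed ones on both
    strands, which makes greedy matching unambiguous.
    """
    bases = "ACGT"
    while True:
        loop = "".join(bases[i] for i in rng.integers(4, size=length))
        if length >= 1 and (loop[0] in "CG" or loop[-1] in "CG"):
            continue
        if "CC" in loop or "GG" in loop:
            continue
        return loop


def sample_im_like(
    loop_lengths: list[int] | None = None,
    rng: np.random.Generator | int = 0,
    pattern: MotifPattern | None = None,
    safe: bool = True,
    loop_template: list[str] | None = None,
) -> str:
    """One motif instance: n_runs C-runs joined by loops.

    ``loop_lengths`` fixes the three loop lengths (default: uniform over
    [loop_min, loop_max]); ``loop_template`` fixes the loop strings
    themselves, which is how narrow-consensus implant families are built.
    """
    pattern = pattern or MotifPattern()
    rng = _rng(rng)
    run = pattern.run_base * pattern.run_len
    n_loops = pattern.n_runs - 1
    if loop_template is not None:
        loops = list(loop_template)
    else:
        if loop_lengths is None:
            loop_lengths = list(
                rng.integers(pattern.loop_min, pattern.loop_max + 1, size=n_loops)
            )
        if safe:
            loops = [_safe_loop(L, rng) for L in loop_lengths]
        else:
            loops = [
                "".join("ACGT"[i] for i in rng.integers(4, size=L))
                for L in loop_lengths
            ]
    parts = [run]
    for loop in loops:
        parts.append(loop)
        parts.append(run)
    return "".join(parts)


def sample_g4_like(rng: np.random.Generator | int = 0, **kw) -> str:
    """A G-rich (G3 N1-12)3 G3 instance — the reverse-complement grammar."""
    return reverse_complement(sample_im_like(rng=_rng(rng), **kw))


def ccc_free_background(
    length: int, rng: np.random.Generator, forbid_ggg: bool = True
) -> str:
    """Uniform DNA with no CCC (and by default no GGG) substring.

    Per-position sampling with a two-base memory: after two consecutive
    C's (or G's) the offending base is excluded, so no third can appear.
    """
    out = np.empty(length, dtype="U1")
    bases = "ACGT"
    last2 = ""
    for i in range(length):
        excl = ""
        if last2 == "CC":
            excl = "C"
        elif forbid_ggg and last2 == "GG":
            excl = "G"
        choices = bases.replace(excl, "") if excl else bases
        b = choices[rng.integers(len(choices))]
        out[i] = b
        last2 = (last2 + b)[-2:]
    return "".join(out)


@dataclass
class FixtureSpec:
    """Parameters of one synthetic fixture genome."""

    genome_length: int = 20_000
    n_implants: int = 20
    chrom: str = "chrS"
    background: str = "ccc_free"       # "ccc_free" | "uniform"
    minus_fraction: float = 0.5        # implants placed on the reverse strand
    rng_seed: int = 0
    implant_seqs: list[str] | None = None   # override the iM-grammar sampler
    gene_track: bool = True
    immune_implant_frac: float = 0.5   # implants covered by an "immune" gene


@dataclass
class SimulatedFixture:
    genome: GenomeSeq
    truth: pd.DataFrame                 # chrom,start,end,seq,strand (motif orientation)
    genes_gtf: list[str] = field(default_factory=list)  # GTF lines
    immune_genes: list[str] = field(default_factory=list)
    housekeeping_genes: list[str] = field(default_factory=list)

    def write(self, outdir: str | Path) -> dict[str, Path]:
        outdir = Path(outdir)
        outdir.mkdir(parents=True, exist_ok=True)
        paths = {
            "fasta": outdir / "genome.fa",
            "truth": outdir / "truth.bed",
            "gtf": outdir / "genes.gtf",
            "immune": outdir / "immune_genes.txt",
            "housekeeping": outdir / "housekeeping_genes.txt",
        }
        self.genome.to_fasta(str(paths["fasta"]))
        with open(paths["truth"], "w") as fh:
            for _, r in self.truth.iterrows():
                fh.write(f"{r.chrom}\t{r.start}\t{r.end}\t{r.seq}\t0\t{r.strand}\n")
        with open(paths["gtf"], "w") as fh:
            fh.writelines(line + "\n" for line in self.genes_gtf)
        paths["immune"].write_text("".join(g + "\n" for g in self.immune_genes))
        paths["housekeeping"].write_text(
            "".join(g + "\n" for g in self.housekeeping_genes)
        )
        return paths


def _gtf_line(chrom, source, feature, start0, end0, strand, attrs) -> str:
    # GTF is 1-based inclusive
    attr_str = " ".join(f'{k} "{v}";' for k, v in attrs.items())
    return "\t".join(
        [chrom, source, feature, str(start0 + 1), str(end0), ".", strand, ".",
         attr_str]
    )


def simulate_genome(spec: FixtureSpec) -> SimulatedFixture:
    """Build a fixture genome with implanted motifs and a toy gene track.

    Implants occupy one slot per equal-length genome segment (uniform
    offset within the slot), separated by at least one forced A/T buffer
    base on each side so no implant interacts with its neighborhood under
    greedy matching. Half of the implants (``minus_fraction``) are placed
    as their reverse complement and recorded with strand "-".
    """
    rng = np.random.default_rng(spec.rng_seed)
    n = spec.n_implants
    if spec.implant_seqs is not None:
        implants = list(spec.implant_seqs)
        n = len(implants)
    else:
        implants = [sample_im_like(rng=rng) for _ in range(n)]
    max_len = max((len(s) for s in implants), default=0)
    # each slot needs the implant, its buffers, and a reserved implant-free
    # tail where toy housekeeping genes can live
    if n and spec.genome_length < n * (max_len + 130):
        raise ValueError(
            f"genome of {spec.genome_length} bp too short for {n} implants"
        )

    if spec.background == "ccc_free":
        seq = list(ccc_free_background(spec.genome_length, rng))
    elif spec.background == "uniform":
        seq = ["ACGT"[i] for i in rng.integers(4, size=spec.genome_length)]
    else:
        raise ValueError(f"unknown background {spec.background!r}")

    records = []
    if n:
        slot = spec.genome_length // n
        n_minus = int(round(spec.minus_fraction * n))
        strands = np.array(["-"] * n_minus + ["+"] * (n - n_minus))
        rng.shuffle(strands)
        at = "AT"
        for i, (imp, strand) in enumerate(zip(implants, strands)):
            lo = i * slot + 1
            hi = (i + 1) * slot - len(imp) - 120
            start = int(rng.integers(lo, hi))
            end = start + len(imp)
            placed = imp if strand == "+" else reverse_complement(imp)
            seq[start:end] = list(placed)
            seq[start - 1] = at[rng.integers(2)]
            if end < spec.genome_length:
                seq[end] = at[rng.integers(2)]
            records.append(
                {"chrom": spec.chrom, "start": start, "end": end,
                 "seq": imp, "strand": strand}
            )
    genome = GenomeSeq({spec.chrom: "".join(seq)})
    truth = pd.DataFrame(
        records, columns=["chrom", "start", "end", "seq", "strand"]
    )

    gtf: list[str] = []
    immune: list[str] = []
    housekeeping: list[str] = []
    if spec.gene_track and n:
        n_immune = int(round(spec.immune_implant_frac * n))
        pick = rng.permutation(n)[:n_immune]
        for i, rec in enumerate(records):
            sym = f"IMM{i}" if i in pick else f"GENE{i}"
            gstart = max(rec["start"] - 50, 0)
            gend = min(rec["end"] + 50, spec.genome_length)
            attrs = {"gene_id": sym, "gene_name": sym,
                     "gene_type": "protein_coding"}
            gtf.append(_gtf_line(spec.chrom, "sim", "gene", gstart, gend, "+", attrs))
            tattrs = dict(attrs, transcript_id=sym + ".1")
            gtf.append(
                _gtf_line(spec.chrom, "sim", "transcript", gstart, gend, "+", tattrs)
            )
            # two terminal exons; the implant itself sits in the intron
            gtf.append(
                _gtf_line(spec.chrom, "sim", "exon", gstart, gstart + 10, "+", tattrs)
            )
            gtf.append(
                _gtf_line(spec.chrom, "sim", "exon", gend - 10, gend, "+", tattrs)
            )
            if i in pick:
                immune.append(sym)
        # housekeeping genes in the reserved implant-free slot tails
        for i in range(min(n, 5)):
            sym = f"HK{i}"
            gstart = (i + 1) * (spec.genome_length // n) - 60
            gend = gstart + 30
            attrs = {"gene_id": sym, "gene_name": sym,
                     "gene_type": "protein_coding"}
            gtf.append(_gtf_line(spec.chrom, "sim", "gene", gstart, gend, "+", attrs))
            housekeeping.append(sym)
    return SimulatedFixture(genome, truth, gtf, immune, housekeeping)
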