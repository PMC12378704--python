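"""End-to-end orchestration: scan -> align -> score -> select -> annotate -> validate.

Every stage writes a re-loadable artifact into the output directory and
the final JSON report carries per-stage counts plus the full configuration
(and its hash) for provenance.
"""

from __future__ import annotations

import hashlib
import json
import logging
import time
from dataclasses import asdict, dataclass, field
from pathlib import Path

import yaml

from . import annotation as ann
from . import msa, pssm, scanner, significance, validation
from .genome import GenomeSeq

logger = logging.getLogger(__name__)


@dataclass
class PipelineConfig:
    fasta: str = ""
    gtf: str | None = None
    positives_fasta: str | None = None
    negatives_fasta: str | None = None
    immune_genes: str | None = None
    housekeeping_genes: str | None = None
    outdir: str = "imprior_out"
    chroms: list[str] | None = None
    loop_min: int = 1
    loop_max: int = 12
    flank: int = 3
    engine: str = "builtin"
    group_all: bool = False
    pseudocount: float = 0.25
    permutations: int = 1000
    q_threshold: float = 0.05
    top_frac: float = 0.05
    promoter_upstream: int = 2000
    promoter_downstream: int = 200
    jaccard_k: int = 3
    seed: int = 0

    @classmethod
    def from_yaml(cls, path: str) -> "PipelineConfig":
        with open(path) as fh:
            raw = yaml.safe_load(fh) or {}
        unknown = set(raw) - set(cls.__dataclass_fields__)
        if unknown:
            raise ValueError(f"unknown config keys: {sorted(unknown)}")
        return cls(**raw)

    def hash(self) -> str:
        return hashlib.sha256(
            json.dumps(asdict(self), sort_keys=True).encode()
        ).hexdigest()[:12]


class StageError(RuntimeError):
    def __init__(self, stage: str, code: str, message: str):
        super().__init__(f"[{stage}:{code}] {message}")
        self.stage = stage
        self.code = code


def _read_fasta_seqs(path: str) -> list[str]:
    from Bio import SeqIO

    return [str(r.seq).upper() for r in SeqIO.parse(path, "fasta")]


def run_pipeline(config: PipelineConfig) -> dict:
    """Run all stages in order; returns the report dict (also written to disk)."""
    out = Path(config.outdir)
    out.mkdir(parents=True, exist_ok=True)
    report: dict = {"config": asdict(config), "config_hash": config.hash(),
                    "stages": {}}

    def stage(name):
        t0 = time.time()
        logger.info("stage %s started", name)
        return t0

    # ---- scan ----------------------------------------------------------
    t0 = stage("scan")
    if not config.fasta or not Path(config.fasta).exists():
        raise StageError("scan", "missing_input",
                         f"genome FASTA not found: {config.fasta!r}")
    genome = GenomeSeq.from_fasta(config.fasta, chroms=config.chroms)
    pattern = scanner.MotifPattern(loop_min=config.loop_min,
                                   loop_max=config.loop_max)
    matches = scanner.scan_motifs(genome, pattern)
    scanner.matches_to_bed(matches, str(out / "matches.bed"))
    scanner.summarize_matches(matches).to_csv(
        out / "match_summary.tsv", sep="\t", index=False
    )
    report["stages"]["scan"] = {
        "n_matches": len(matches), "seconds": round(time.time() - t0, 2)
    }

    # ---- align + pssm --------------------------------------------------
    t0 = stage("align")
    flanked = [msa.extract_flanked(m, genome, config.flank) for m in matches]
    groups = msa.group_matches(flanked, group_all=config.group_all)
    aln_dir = out / "alignments"
    aln_dir.mkdir(exist_ok=True)
    pssms, rows_by_group, matches_by_group = {}, {}, {}
    for key, seqs in sorted(groups.items()):
        aln = msa.align_group(seqs, engine=config.engine)
        aln.to_fasta(str(aln_dir / f"{key[0]}_{key[1].replace('-', 'minus')}.fa"))
        pssms[key] = pssm.build_pssm(aln, pseudocount=config.pseudocount)
        rows_by_group[key] = aln.rows
        matches_by_group[key] = [s.match for s in seqs]
    report["stages"]["align"] = {
        "n_groups": len(groups), "engine": config.engine,
        "seconds": round(time.time() - t0, 2),
    }

    # ---- score + select ------------------------------------------------
    t0 = stage("score")
    cands = significance.score_candidates(
        pssms, rows_by_group, matches_by_group,
        B=config.permutations, seed=config.seed,
    )
    selected = significance.select_candidates(
        cands, q_threshold=config.q_threshold, top_frac=config.top_frac
    )
    df = significance.candidates_to_frame(cands)
    df.to_csv(out / "scores.tsv", sep="\t", index=False)
    df[df.selected].to_csv(out / "selected.tsv", sep="\t", index=False)
    report["stages"]["score"] = {
        "n_scored": len(cands),
        "n_q_pass": int((df.q < config.q_threshold).sum()),
        "n_selected": len(selected),
        "seconds": round(time.time() - t0, 2),
    }

    # ---- annotate ------------------------------------------------------
    if config.gtf is not None:
        t0 = stage("annotate")
        if not Path(config.gtf).exists():
            raise StageError("annotate", "missing_input",
                             f"GTF not found: {config.gtf!r} (--gtf)")
        genes = ann.GeneModelSet.from_gtf(config.gtf)
        immune = _read_symbols(config.immune_genes)
        hk = _read_symbols(config.housekeeping_genes)
        annotated = ann.annotate_candidates(
            selected, genes,
            promoter_window=(config.promoter_upstream, config.promoter_downstream),
            immune_set=immune, housekeeping_set=hk,
        )
        adf = ann.annotated_to_frame(annotated)
        adf.to_csv(out / "annotated.tsv", sep="\t", index=False)
        report["stages"]["annotate"] = {
            "n_annotated": len(annotated),
            "n_correct": int((adf["mode"] == "correct").sum()),
            "regions": adf.region.value_counts().to_dict(),
            "seconds": round(time.time() - t0, 2),
        }
        if immune and hk:
            enr = ann.gene_class_enrichment(
                annotated, immune, hk, background_genes=set(genes.genes.symbol)
            )
            report["stages"]["annotate"]["enrichment"] = {
                "odds_ratio": enr.odds_ratio, "p": enr.p,
                "ci95": list(enr.ci95), "degenerate": enr.degenerate,
            }

    # ---- validate ------------------------------------------------------
    if config.positives_fasta and config.negatives_fasta:
        t0 = stage("validate")
        controls = validation.ControlSets(
            positives=_read_fasta_seqs(config.positives_fasta),
            negatives_g4=_read_fasta_seqs(config.negatives_fasta),
        )
        cand_seqs = [c.match.seq for c in selected]
        res = validation.classify_by_similarity(
            cand_seqs, controls, metric="jaccard", k=config.jaccard_k
        )
        report["stages"]["validate"] = {
            "n_candidates": len(cand_seqs),
            "n_labeled_positive": int((res.label == "positive").sum())
            if len(res) else 0,
            "seconds": round(time.time() - t0, 2),
        }

    with open(out / "report.json", "w") as fh:
        json.dump(report, fh, indent=2)
    return report


def _read_symbols(path: str | None) -> set[str]:
    if path is None:
        return set()
    return {
        line.strip() for line in Path(path).read_text().splitlines() if line.strip()
    }
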