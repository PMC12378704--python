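"""Gene-level annotation of selected candidates and gene-class enrichment.

Candidates overlapping a gene body are labeled mode="correct"; all others
are assigned their nearest gene (mode="nearest") with the gap distance in
bp. Each candidate also gets one genic region by fixed precedence
promoter > 5'UTR > 3'UTR > exon > intron > distal_intergenic, where the
promoter is a strand-aware window around the annotated TSS (default
2000 bp upstream, 200 bp downstream).
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
import pyranges as pr
from scipy import stats
from scipy.stats.contingency import odds_ratio as _odds_ratio

from .significance import ScoredCandidate

logger = logging.getLogger(__name__)

REGION_PRECEDENCE = (
    "promoter", "5UTR", "3UTR", "exon", "intron", "distal_intergenic"
)


@dataclass
class GeneModelSet:
    """Gene spans plus exon/UTR intervals, 0-based half-open.

    ``genes`` columns: gene_id, symbol, chrom, start, end, strand, type.
    ``features`` columns: chrom, start, end, feature (exon/5UTR/3UTR), gene_id.
    """

    genes: pd.DataFrame
    features: pd.DataFrame

    @classmethod
    def from_gtf(cls, path: str) -> "GeneModelSet":
        df = pr.read_gtf(path).df
        gene_rows = df[df.Feature == "gene"]
        genes = pd.DataFrame(
            {
                "gene_id": gene_rows.gene_id.values,
                "symbol": gene_rows.get("gene_name", gene_rows.gene_id).values,
                "chrom": gene_rows.Chromosome.astype(str).values,
                "start": gene_rows.Start.values,
                "end": gene_rows.End.values,
                "strand": gene_rows.Strand.astype(str).values,
                "type": df.get("gene_type", pd.Series(["protein_coding"] * len(df)))[
                    gene_rows.index
                ].values,
            }
        )
        feat_map = {
            "exon": "exon",
            "five_prime_utr": "5UTR",
            "three_prime_utr": "3UTR",
            "UTR5": "5UTR",
            "UTR3": "3UTR",
        }
        feat_rows = df[df.Feature.isin(feat_map)]
        features = pd.DataFrame(
            {
                "chrom": feat_rows.Chromosome.astype(str).values,
                "start": feat_rows.Start.values,
                "end": feat_rows.End.values,
                "feature": feat_rows.Feature.map(feat_map).values,
                "gene_id": feat_rows.gene_id.values,
            }
        )
        return cls(genes, features)


@dataclass
class AnnotatedCandidate:
    candidate: ScoredCandidate
    gene_symbol: str | None
    mode: str                  # "correct" | "nearest"
    distance: float            # bp gap, 0 iff mode == "correct"; NaN if no gene
    region: str
    gene_class: str = "other"  # "immune" | "housekeeping" | "other"


def _promoter_intervals(genes: pd.DataFrame, upstream: int, downstream: int) -> pd.DataFrame:
    plus = genes.strand == "+"
    tss = np.where(plus, genes.start, genes.end)
    start = np.where(plus, tss - upstream, tss - downstream)
    end = np.where(plus, tss + downstream, tss + upstream)
    return pd.DataFrame(
        {"chrom": genes.chrom, "start": np.maximum(start, 0), "end": end}
    )


def _overlaps_any(chrom: str, start: int, end: int, ivs: pd.DataFrame) -> bool:
    sub = ivs[ivs.chrom == chrom]
    return bool(((sub.start < end) & (sub.end > start)).any())


def annotate_candidates(
    candidates: list[ScoredCandidate],
    genes: GeneModelSet,
    promoter_window: tuple[int, int] = (2000, 200),
    immune_set: set[str] | None = None,
    housekeeping_set: set[str] | None = None,
) -> list[AnnotatedCandidate]:
    """Assign gene, annotation mode, genic region and gene class.

    Gene-body overlap and nearest-gene lookup run through pyranges; the
    region label is then decided by the fixed precedence order. Candidates
    on chromosomes absent from the gene set are labeled distal_intergenic
    with undefined distance.
    """
    if not candidates:
        return []
    immune_set = immune_set or set()
    housekeeping_set = housekeeping_set or set()
    up, down = promoter_window

    g = genes.genes
    cand_df = pd.DataFrame(
        {
            "Chromosome": [c.match.chrom for c in candidates],
            "Start": [c.match.start for c in candidates],
            "End": [c.match.end for c in candidates],
            "idx": np.arange(len(candidates)),
        }
    )
    gene_pr = pr.PyRanges(
        pd.DataFrame(
            {
                "Chromosome": g.chrom,
                "Start": g.start,
                "End": g.end,
                "symbol": g.symbol,
                "gene_start": g.start,
                "gene_end": g.end,
            }
        )
    )
    cand_pr = pr.PyRanges(cand_df)

    # gene-body overlaps; if several genes overlap keep the leftmost-start one
    joined = cand_pr.join(gene_pr).df if len(g) else pd.DataFrame()
    overlap_gene: dict[int, str] = {}
    if len(joined):
        joined = joined.sort_values(["idx", "gene_start"])
        for idx, sym in joined.groupby("idx")["symbol"].first().items():
            overlap_gene[int(idx)] = sym

    nearest = (
        cand_pr.nearest(gene_pr).df if len(g) else pd.DataFrame()
    )
    nearest_info: dict[int, tuple[str, int]] = {}
    if len(nearest):
        for _, r in nearest.iterrows():
            gap = 0
            if r.End <= r.gene_start:
                gap = int(r.gene_start - r.End)
            elif r.gene_end <= r.Start:
                gap = int(r.Start - r.gene_end)
            nearest_info[int(r.idx)] = (r.symbol, gap)

    promoters = _promoter_intervals(g, up, down) if len(g) else pd.DataFrame(
        columns=["chrom", "start", "end"]
    )
    feats = genes.features
    utr5 = feats[feats.feature == "5UTR"]
    utr3 = feats[feats.feature == "3UTR"]
    exons = feats[feats.feature == "exon"]
    gene_bodies = g.rename(columns={"chrom": "chrom"})[["chrom", "start", "end"]]

    out: list[AnnotatedCandidate] = []
    known_chroms = set(g.chrom)
    for i, c in enumerate(candidates):
        chrom, start, end = c.match.chrom, c.match.start, c.match.end
        if chrom not in known_chroms:
            logger.warning(
                "candidate %s on chromosome absent from gene models", c.match.name
            )
            out.append(
                AnnotatedCandidate(c, None, "nearest", float("nan"),
                                   "distal_intergenic")
            )
            continue
        if i in overlap_gene:
            symbol, mode, dist = overlap_gene[i], "correct", 0.0
        else:
            symbol, gap = nearest_info[i]
            mode, dist = "nearest", float(gap)
        if _overlaps_any(chrom, start, end, promoters):
            region = "promoter"
        elif _overlaps_any(chrom, start, end, utr5):
            region = "5UTR"
        elif _overlaps_any(chrom, start, end, utr3):
            region = "3UTR"
        elif _overlaps_any(chrom, start, end, exons):
            region = "exon"
        elif mode == "correct":
            region = "intron"
        else:
            region = "distal_intergenic"
        if symbol in immune_set:
            klass = "immune"
        elif symbol in housekeeping_set:
            klass = "housekeeping"
        else:
            klass = "other"
        out.append(AnnotatedCandidate(c, symbol, mode, dist, region, klass))
    return out


@dataclass
class FisherResult:
    odds_ratio: float
    ci95: tuple[float, float]
    p: float
    table: np.ndarray = field(default_factory=lambda: np.zeros((2, 2), int))
    degenerate: bool = False


def fisher_exact_2x2(table, compute_ci: bool = True) -> FisherResult:
    """Two-sided Fisher exact test with conditional-MLE odds ratio and CI.

    A zero margin makes the test degenerate: p = 1 and the odds ratio is
    undefined (NaN, flagged). ``compute_ci=False`` skips the (relatively
    costly) test-inversion confidence interval.
    """
    t = np.asarray(table, dtype=int)
    if t.shape != (2, 2) or (t < 0).any():
        raise ValueError("need a 2x2 table of non-negative counts")
    if t.sum() == 0:
        raise ValueError("table has no observations")
    margins = [t[0].sum(), t[1].sum(), t[:, 0].sum(), t[:, 1].sum()]
    if 0 in margins:
        return FisherResult(float("nan"), (float("nan"), float("nan")), 1.0,
                            t, degenerate=True)
    _, p = stats.fisher_exact(t, alternative="two-sided")
    res = _odds_ratio(t)  # conditional MLE
    if compute_ci:
        ci = res.confidence_interval(0.95)
        bounds = (float(ci.low), float(ci.high))
    else:
        bounds = (float("nan"), float("nan"))
    return FisherResult(float(res.statistic), bounds, float(p), t)


def gene_class_enrichment(
    annotated: list[AnnotatedCandidate],
    immune_set: set[str],
    housekeeping_set: set[str],
    background_genes: set[str],
) -> FisherResult:
    """Immune-vs-housekeeping enrichment among candidate-associated genes.

    Rows: immune / housekeeping gene class; columns: gene hit by a
    candidate vs background-only. Gene symbol universes are deduplicated
    by construction (sets).
    """
    if not immune_set or not housekeeping_set:
        raise ValueError("immune and housekeeping sets must be non-empty")
    cand_genes = {a.gene_symbol for a in annotated if a.gene_symbol}
    bg_only = set(background_genes) - cand_genes
    table = [
        [len(cand_genes & immune_set), len(bg_only & immune_set)],
        [len(cand_genes & housekeeping_set), len(bg_only & housekeeping_set)],
    ]
    return fisher_exact_2x2(table)


def annotated_to_frame(annotated: list[AnnotatedCandidate]) -> pd.DataFrame:
    return pd.DataFrame(
        {
            "chrom": [a.candidate.match.chrom for a in annotated],
            "start": [a.candidate.match.start for a in annotated],
            "end": [a.candidate.match.end for a in annotated],
            "strand": [a.candidate.match.strand for a in annotated],
            "gene_symbol": [a.gene_symbol for a in annotated],
            "mode": [a.mode for a in annotated],
            "distance": [a.distance for a in annotated],
            "region": [a.region for a in annotated],
            "gene_class": [a.gene_class for a in annotated],
        }
    )
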