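"""Gene annotation, region precedence and Fisher enrichment."""

import numpy as np
import pandas as pd
import pytest

from _oracles import fisher_two_sided
from imprior.annotation import (
    AnnotatedCandidate,
    GeneModelSet,
    annotate_candidates,
    fisher_exact_2x2,
    gene_class_enrichment,
)
from imprior.scanner import MotifMatch
from imprior.significance import NullDistribution, ScoredCandidate
from imprior.pssm import SeqScore


def _cand(chrom, start, end=None):
    end = end if end is not None else start + 15
    return ScoredCandidate(
        match=MotifMatch(chrom, start, end, "+", "C" * (end - start)),
        score=SeqScore(1.0, 1),
        null=NullDistribution(2, 0.0, 1.0),
        p=0.01, p_empirical=0.01, q=0.01, z=1.0,
    )


def _genes(rows, features=None):
    genes = pd.DataFrame(
        rows, columns=["gene_id", "symbol", "chrom", "start", "end", "strand", "type"]
    )
    feats = pd.DataFrame(
        features or [], columns=["chrom", "start", "end", "feature", "gene_id"]
    )
    return GeneModelSet(genes, feats)


class TestAnnotate:
    def test_intronic_candidate_is_correct_mode(self):
        gm = _genes(
            [("g1", "G1", "c", 1000, 5000, "+", "pc")],
            [("c", 1000, 1200, "exon", "g1"), ("c", 4800, 5000, "exon", "g1")],
        )
        (a,) = annotate_candidates([_cand("c", 3000)], gm, promoter_window=(50, 10))
        assert (a.mode, a.distance, a.region, a.gene_symbol) == (
            "correct", 0.0, "intron", "G1",
        )

    def test_upstream_candidate_nearest_with_distance(self):
        gm = _genes([("g1", "G1", "c", 10_000, 12_000, "+", "pc")])
        (a,) = annotate_candidates(
            [_cand("c", 9485, 9500)], gm, promoter_window=(100, 0)
        )
        assert a.mode == "nearest"
        assert a.distance == 500.0
        assert a.region == "distal_intergenic"

    def test_promoter_precedence_over_exon(self):
        # candidate overlaps an exon of A and the promoter window of B
        gm = _genes(
            [
                ("a", "A", "c", 1000, 2000, "+", "pc"),
                ("b", "B", "c", 3100, 4000, "+", "pc"),
                ("d", "D", "c", 9000, 9500, "+", "pc"),
            ],
            [("c", 1000, 2000, "exon", "a")],
        )
        (a,) = annotate_candidates(
            [_cand("c", 1900, 1930)], gm, promoter_window=(2000, 200)
        )
        assert a.region == "promoter"
        assert a.mode == "correct"

    def test_utr_precedence(self):
        gm = _genes(
            [("g1", "G1", "c", 1000, 5000, "+", "pc")],
            [
                ("c", 1000, 1300, "exon", "g1"),
                ("c", 1000, 1100, "5UTR", "g1"),
                ("c", 4800, 5000, "3UTR", "g1"),
            ],
        )
        got = annotate_candidates(
            [_cand("c", 1050, 1070), _cand("c", 4850, 4870), _cand("c", 1150, 1170)],
            gm, promoter_window=(10, 5),
        )
        assert [a.region for a in got] == ["5UTR", "3UTR", "exon"]

    def test_unknown_chromosome_flagged_distal(self, caplog):
        gm = _genes([("g1", "G1", "c", 0, 100, "+", "pc")])
        (a,) = annotate_candidates([_cand("other", 10)], gm)
        assert a.region == "distal_intergenic"
        assert np.isnan(a.distance)

    def test_every_candidate_gets_one_mode_and_region(self, rng):
        genes = [
            (f"g{i}", f"G{i}", "c", int(s), int(s) + 300, "+", "pc")
            for i, s in enumerate(sorted(rng.integers(0, 50_000, size=30)))
        ]
        gm = _genes(genes)
        cands = [_cand("c", int(s)) for s in rng.integers(0, 50_000, size=40)]
        got = annotate_candidates(cands, gm)
        assert len(got) == 40
        for a in got:
            assert a.mode in ("correct", "nearest")
            assert a.region in (
                "promoter", "5UTR", "3UTR", "exon", "intron", "distal_intergenic"
            )

    def test_nearest_distance_matches_brute_force(self, rng):
        starts = np.sort(rng.integers(0, 100_000, size=50))
        genes = [
            (f"g{i}", f"G{i}", "c", int(s), int(s) + int(rng.integers(50, 500)),
             "+", "pc")
            for i, s in enumerate(starts)
        ]
        gm = _genes(genes)
        cands = [_cand("c", int(s)) for s in rng.integers(0, 100_000, size=60)]
        got = annotate_candidates(cands, gm, promoter_window=(1, 1))
        for a in got:
            s, e = a.candidate.match.start, a.candidate.match.end
            gaps = []
            for _, _, _, gs, ge, _, _ in genes:
                if gs < e and ge > s:
                    gaps.append(0)
                elif e <= gs:
                    gaps.append(gs - e)
                else:
                    gaps.append(s - ge)
            assert a.distance == min(gaps)
            assert (a.distance == 0) == (a.mode == "correct")


class TestFisher:
    def test_symmetric_table(self):
        r = fisher_exact_2x2([[10, 10], [10, 10]])
        assert r.odds_ratio == pytest.approx(1.0)
        assert r.p == pytest.approx(1.0)

    def test_diagonal_table_exact_p(self):
        r = fisher_exact_2x2([[5, 0], [0, 5]])
        assert r.p == pytest.approx(2 / 252)

    def test_transpose_invariance(self, rng):
        for _ in range(20):
            t = rng.integers(0, 15, size=(2, 2))
            if 0 in [t[0].sum(), t[1].sum(), t[:, 0].sum(), t[:, 1].sum()]:
                continue
            assert fisher_exact_2x2(t).p == pytest.approx(
                fisher_exact_2x2(t.T).p
            )

    def test_matches_enumeration_on_random_tables(self, rng):
        for _ in range(200):
            t = rng.integers(0, 12, size=(2, 2))
            if 0 in [t[0].sum(), t[1].sum(), t[:, 0].sum(), t[:, 1].sum()]:
                continue
            assert fisher_exact_2x2(t).p == pytest.approx(
                fisher_two_sided(t), rel=1e-6
            )

    def test_zero_margin_degenerate(self):
        r = fisher_exact_2x2([[0, 0], [3, 4]])
        assert r.degenerate and r.p == 1.0 and np.isnan(r.odds_ratio)

    def test_empty_table_rejected(self):
        with pytest.raises(ValueError):
            fisher_exact_2x2([[0, 0], [0, 0]])


class TestEnrichment:
    def _annotated(self, symbols):
        out = []
        for i, sym in enumerate(symbols):
            c = _cand("c", 100 * i)
            out.append(AnnotatedCandidate(c, sym, "correct", 0.0, "intron"))
        return out

    def test_background_proportion_gives_or_near_one(self):
        immune = {f"I{i}" for i in range(20)}
        hk = {f"H{i}" for i in range(20)}
        cand = self._annotated([f"I{i}" for i in range(5)] + [f"H{i}" for i in range(5)])
        r = gene_class_enrichment(cand, immune, hk, immune | hk)
        assert 0.3 < r.odds_ratio < 3.0
        assert r.p > 0.5

    def test_immune_only_candidates_enriched(self):
        immune = {f"I{i}" for i in range(12)}
        hk = {f"H{i}" for i in range(12)}
        cand = self._annotated(sorted(immune))
        r = gene_class_enrichment(cand, immune, hk, immune | hk)
        assert np.isinf(r.odds_ratio)
        assert r.p < 0.01

    def test_empty_class_set_rejected(self):
        with pytest.raises(ValueError):
            gene_class_enrichment([], set(), {"H"}, {"H"})

    def test_no_candidates_degenerate_table(self):
        r = gene_class_enrichment([], {"I"}, {"H"}, {"I", "H"})
        assert r.degenerate
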