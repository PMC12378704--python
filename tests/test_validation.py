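"""Similarity triage, rank-sum test, negative generation and the classifier."""

import itertools

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from _oracles import levenshtein_dp, wilcoxon_exact
from imprior.synthetic import sample_g4_like, sample_im_like
from imprior.validation import (
    ControlSets,
    classify_by_similarity,
    extract_features,
    feature_table,
    generate_negative_sequences,
    jaccard_kmer,
    levenshtein,
    train_and_evaluate_classifier,
    wilcoxon_rank_sum,
)

dna = st.text(alphabet="ACGT", min_size=0, max_size=25)


class TestLevenshtein:
    def test_identity(self):
        assert levenshtein("CCCA", "CCCA") == 0

    def test_single_substitution(self):
        assert levenshtein("CCCA", "CCCG") == 1

    def test_matches_dp_oracle_on_random_pairs(self, rng):
        for _ in range(200):
            a = "".join("ACGT"[i] for i in rng.integers(4, size=rng.integers(0, 20)))
            b = "".join("ACGT"[i] for i in rng.integers(4, size=rng.integers(0, 20)))
            assert levenshtein(a, b) == levenshtein_dp(a, b)

    @given(dna, dna, dna)
    @settings(max_examples=60, deadline=None)
    def test_metric_axioms(self, a, b, c):
        assert levenshtein(a, b) == levenshtein(b, a)
        assert (levenshtein(a, b) == 0) == (a == b)
        assert levenshtein(a, c) <= levenshtein(a, b) + levenshtein(b, c)


class TestJaccard:
    def test_identical(self):
        assert jaccard_kmer("CCCAT", "CCCAT") == 1.0

    def test_hand_example(self):
        # {CCC, CCA} vs {CCC}: intersection 1, union 2
        assert jaccard_kmer("CCCA", "CCCC") == 0.5

    def test_disjoint(self):
        assert jaccard_kmer("AAAA", "GGGG") == 0.0

    def test_too_short_rejected(self):
        with pytest.raises(ValueError):
            jaccard_kmer("AC", "ACGT")

    @given(st.text(alphabet="ACGT", min_size=3, max_size=25),
           st.text(alphabet="ACGT", min_size=3, max_size=25))
    @settings(max_examples=60, deadline=None)
    def test_bounded_and_one_iff_equal_sets(self, a, b):
        j = jaccard_kmer(a, b)
        assert 0.0 <= j <= 1.0
        ka = {a[i:i + 3] for i in range(len(a) - 2)}
        kb = {b[i:i + 3] for i in range(len(b) - 2)}
        assert (j == 1.0) == (ka == kb)


class TestClassifyBySimilarity:
    def _controls(self, rng):
        pos = [sample_im_like(rng=rng) for _ in range(20)]
        neg = [sample_g4_like(rng=rng) for _ in range(20)]
        return ControlSets(positives=pos, negatives_g4=neg)

    def test_identical_to_positive_is_positive(self, rng):
        controls = self._controls(rng)
        df = classify_by_similarity([controls.positives[0]], controls)
        assert df.label.iloc[0] == "positive"

    def test_crich_vs_grich_fixture_perfect_roc(self, rng):
        controls = self._controls(rng)
        cands = [sample_im_like(rng=rng) for _ in range(30)]
        decoys = [sample_g4_like(rng=rng) for _ in range(30)]
        df = classify_by_similarity(
            cands + decoys, controls,
            truth_labels=[1] * 30 + [0] * 30,
        )
        assert (df.label[:30] == "positive").all()
        assert df.attrs["auc"] == 1.0
        assert 0.0 < df.attrs["cutoff"] < 1.0

    def test_tie_breaks_negative(self):
        controls = ControlSets(positives=["AAAT"], negatives_g4=["AAAG"])
        # candidate AAAA is equidistant (Jaccard) from both controls
        df = classify_by_similarity(["AAAA"], controls)
        assert df.label.iloc[0] == "negative"

    def test_levenshtein_metric_route(self, rng):
        controls = self._controls(rng)
        df = classify_by_similarity(
            [controls.positives[0]], controls, metric="levenshtein"
        )
        assert df.sim_pos.iloc[0] == 0  # negated distance to itself
        assert df.label.iloc[0] == "positive"

    def test_empty_candidates_empty_output(self, rng):
        assert len(classify_by_similarity([], self._controls(rng))) == 0


class TestWilcoxon:
    def test_complete_separation_small(self):
        W, p = wilcoxon_rank_sum([1, 2], [3, 4])
        assert W == 0
        assert p == pytest.approx(1 / 3)

    def test_identical_samples(self):
        _, p = wilcoxon_rank_sum([1.0, 1.0], [1.0, 1.0])
        assert p == 1.0

    def test_same_multiset_p_near_one(self):
        _, p = wilcoxon_rank_sum([1, 2, 3, 4, 5], [1, 2, 3, 4, 5])
        assert p > 0.9

    def test_matches_exact_enumeration_small_samples(self, rng):
        for _ in range(500):
            n = int(rng.integers(1, 6))
            m = int(rng.integers(1, 6))
            if n + m > 10:
                continue
            x = rng.normal(size=n)
            y = rng.normal(size=m)
            W, p = wilcoxon_rank_sum(x, y)
            W_o, p_o = wilcoxon_exact(x, y)
            assert W == pytest.approx(W_o)
            assert p == pytest.approx(p_o)

    def test_empty_sample_rejected(self):
        with pytest.raises(ValueError):
            wilcoxon_rank_sum([], [1.0])


class TestNegativeGeneration:
    def test_no_ccc_and_length_range(self):
        seqs = generate_negative_sequences(n=300, rng=3)
        assert len(seqs) == 300
        for s in seqs:
            assert "CCC" not in s
            assert 15 <= len(s) <= 50

    def test_deterministic(self):
        assert generate_negative_sequences(50, rng=9) == generate_negative_sequences(
            50, rng=9
        )

    def test_lengths_cover_range(self):
        lens = {len(s) for s in generate_negative_sequences(2000, rng=1)}
        assert lens == set(range(15, 51))


class TestFeatures:
    def test_pure_c(self):
        f = extract_features("CCCC")
        assert f.freq_C == 1.0 and f.length == 4

    def test_uniform(self):
        f = extract_features("ACGT")
        assert all(f[f"freq_{b}"] == 0.25 for b in "ACGT")

    def test_frequencies_sum_to_one(self, rng):
        for _ in range(200):
            s = "".join("ACGT"[i] for i in rng.integers(4, size=rng.integers(1, 60)))
            f = extract_features(s)
            assert f[["freq_A", "freq_C", "freq_G", "freq_T"]].sum() == pytest.approx(1.0)

    def test_non_acgt_rejected(self):
        with pytest.raises(ValueError):
            extract_features("ACGN")


class TestClassifier:
    def _dataset(self, rng, n=300):
        pos = [sample_im_like(rng=rng) for _ in range(n)]
        neg = generate_negative_sequences(n, rng=rng)
        X = feature_table(pos + neg)
        y = [1] * n + [0] * n
        return X, y

    def test_separable_fixture_high_accuracy(self, rng):
        X, y = self._dataset(rng)
        rep = train_and_evaluate_classifier(X, y, n_trees=100, rng_seed=0)
        assert rep.accuracy >= 0.95
        assert rep.auc >= 0.99
        assert rep.feature_importance.index[0] == "freq_C"
        assert rep.chosen_mtry in range(1, 6)

    def test_permuted_labels_near_chance(self, rng):
        X, y = self._dataset(rng, n=120)
        y_perm = list(rng.permutation(y))
        rep = train_and_evaluate_classifier(X, y_perm, n_trees=100, rng_seed=0)
        assert abs(rep.accuracy - 0.5) < 0.12

    def test_reproducible_at_fixed_seed(self, rng):
        X, y = self._dataset(rng, n=60)
        a = train_and_evaluate_classifier(X, y, n_trees=50, rng_seed=4)
        b = train_and_evaluate_classifier(X, y, n_trees=50, rng_seed=4)
        assert a.accuracy == b.accuracy and a.auc == b.auc
        assert (a.confusion == b.confusion).all()

    def test_single_class_rejected(self):
        X = feature_table(["ACGTACGTACGTACG"] * 10)
        with pytest.raises(ValueError):
            train_and_evaluate_classifier(X, [1] * 10)
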