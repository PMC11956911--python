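"""Cosine retrieval, precision@class-fraction, MRR, balanced resampling."""

import math

import numpy as np
import pytest
from scipy import stats

from attnrank.retrieval import (
    LabeledEmbeddingSet,
    balanced_subsample_eval,
    compare_methods,
    cosine_retrieval,
    evaluate,
    precision_at_class_fraction,
    reciprocal_rank,
)
from attnrank.synthetic import FixtureSpec, gaussian_class_embeddings


def toy_set(embeddings, labels=None, ids=None):
    m = len(embeddings)
    return LabeledEmbeddingSet(
        embeddings=np.asarray(embeddings, dtype=float),
        labels=np.asarray(labels if labels is not None else ["c"] * m),
        ids=np.asarray(ids if ids is not None else [f"s{i:03d}" for i in range(m)]),
    )


class TestCosineRetrieval:
    def test_duplicate_embedding_ranked_first(self, rng):
        emb = rng.standard_normal((5, 4))
        emb[3] = emb[0]
        ranking = cosine_retrieval(toy_set(emb), 0)
        assert ranking[0] == 3

    def test_orthogonal_vectors_fall_to_id_tie_break(self):
        emb = np.eye(4)
        ranking = cosine_retrieval(toy_set(emb, ids=["d", "c", "b", "a"]), 0)
        # all similarities zero -> ascending id order: a(3), b(2), c(1)
        assert ranking.tolist() == [3, 2, 1]

    def test_matches_brute_force_oracle(self, rng):
        emb = rng.standard_normal((20, 8))
        eset = toy_set(emb)
        for q in (0, 7, 19):
            sims = {
                i: float(
                    emb[i] @ emb[q] / (np.linalg.norm(emb[i]) * np.linalg.norm(emb[q]))
                )
                for i in range(20)
                if i != q
            }
            expected = sorted(sims, key=lambda i: (-sims[i], str(eset.ids[i])))
            assert cosine_retrieval(eset, q).tolist() == expected

    def test_zero_norm_embedding_names_the_id(self):
        emb = np.ones((3, 2))
        emb[1] = 0.0
        with pytest.raises(ValueError, match="s001"):
            cosine_retrieval(toy_set(emb), 0)

    def test_duplicate_ids_rejected(self):
        with pytest.raises(ValueError, match="duplicate"):
            toy_set(np.ones((2, 2)), ids=["x", "x"])


class TestPrecision:
    def test_class_of_eleven_retrieves_one(self, rng):
        emb = rng.standard_normal((15, 4))
        labels = ["a"] * 11 + ["b"] * 4
        p = precision_at_class_fraction(toy_set(emb, labels), 0, 0.10)
        assert p in (0.0, 1.0)  # r = max(1, ceil(0.1 * 10)) = 1

    def test_perfect_separation_gives_one_everywhere(self):
        eset = gaussian_class_embeddings(
            FixtureSpec(class_count=3, class_size=10, class_separation=200, d=8, seed=0)
        )
        table = evaluate(eset)
        assert table.mean_precision == 1.0

    def test_singleton_class_query_is_an_error_but_batch_skips(self, rng):
        emb = rng.standard_normal((5, 3))
        labels = ["a", "a", "a", "a", "lone"]
        eset = toy_set(emb, labels)
        with pytest.raises(ValueError, match="singleton"):
            precision_at_class_fraction(eset, 4)
        table = evaluate(eset)  # skips the singleton query, keeps the rest
        assert table.n_queries == 4

    def test_label_shuffle_drives_precision_to_prevalence(self, rng):
        eset = gaussian_class_embeddings(
            FixtureSpec(class_count=2, class_size=25, class_separation=50, d=8, seed=3)
        )
        shuffled_means = []
        for _ in range(60):
            perm = rng.permutation(eset.m)
            shuffled_means.append(
                evaluate(
                    LabeledEmbeddingSet(eset.embeddings, eset.labels[perm], eset.ids)
                ).mean_precision
            )
        prevalence = (25 - 1) / (50 - 1)
        assert abs(np.mean(shuffled_means) - prevalence) < 0.03


class TestMeanReciprocalRank:
    def test_arithmetic_on_known_first_hit_ranks(self):
        # first same-class hits at ranks 1, 2 and 4 -> (1 + 1/2 + 1/4)/3
        eset = toy_set(np.eye(5), labels=["a", "a", "b", "b", "b"])
        rr = [
            reciprocal_rank(eset, 0, ranking=np.array([1, 2, 3, 4])),
            reciprocal_rank(eset, 2, ranking=np.array([0, 3, 1, 4])),
            reciprocal_rank(eset, 0, ranking=np.array([2, 3, 4, 1])),
        ]
        assert np.mean(rr) == pytest.approx((1 + 0.5 + 0.25) / 3)

    def test_no_same_class_candidate_is_an_error(self):
        eset = toy_set(np.eye(3), labels=["a", "b", "b"])
        with pytest.raises(ValueError, match="no same-class"):
            reciprocal_rank(eset, 0)

    def test_perfectly_clustered_mrr_is_one(self):
        eset = gaussian_class_embeddings(
            FixtureSpec(class_count=3, class_size=8, class_separation=200, d=8, seed=1)
        )
        assert evaluate(eset).mean_rr == 1.0

    def test_exchangeable_null_matches_analytic_expectation(self, rng):
        # 2 classes of 13: P(first hit at rank r) follows the negative
        # hypergeometric law; compare shuffled MRR to its closed form
        c, m = 13, 26
        same, other = c - 1, m - c
        p_first = []
        for r in range(1, other + 2):
            num = math.comb(other, r - 1) * math.factorial(r - 1) * same
            den = math.perm(m - 1, r)
            p_first.append(num / den)
        expected = sum(p / r for r, p in enumerate(p_first, start=1))
        eset = gaussian_class_embeddings(
            FixtureSpec(class_count=2, class_size=13, class_separation=40, d=6, seed=2)
        )
        means = []
        for _ in range(200):
            perm = rng.permutation(m)
            means.append(
                evaluate(LabeledEmbeddingSet(eset.embeddings, eset.labels[perm], eset.ids)).mean_rr
            )
        assert abs(np.mean(means) - expected) < 0.02

    def test_invariance_under_rotation_and_rescale(self, rng):
        eset = gaussian_class_embeddings(
            FixtureSpec(class_count=3, class_size=6, class_separation=4, d=8, seed=5)
        )
        q, _ = np.linalg.qr(rng.standard_normal((8, 8)))
        transformed = LabeledEmbeddingSet(3.7 * eset.embeddings @ q, eset.labels, eset.ids)
        a, b = evaluate(eset), evaluate(transformed)
        assert a.mean_rr == pytest.approx(b.mean_rr, abs=1e-12)
        assert a.mean_precision == pytest.approx(b.mean_precision, abs=1e-12)


class TestBalancedSubsampleEval:
    def test_whole_set_single_round_equals_plain_eval(self):
        eset = gaussian_class_embeddings(
            FixtureSpec(class_count=3, class_size=7, class_separation=6, d=8, seed=4)
        )
        rounds = balanced_subsample_eval(eset, class_size=7, n_rounds=1, seed=0)
        plain = evaluate(eset)
        assert rounds.mean_precision == pytest.approx(plain.mean_precision)
        assert rounds.mean_mrr == pytest.approx(plain.mean_rr)

    def test_seed_determinism(self):
        eset = gaussian_class_embeddings(
            FixtureSpec(class_count=3, class_size=12, class_separation=6, d=8, seed=4)
        )
        a = balanced_subsample_eval(eset, class_size=6, n_rounds=5, seed=11)
        b = balanced_subsample_eval(eset, class_size=6, n_rounds=5, seed=11)
        np.testing.assert_array_equal(a.precision_rounds, b.precision_rounds)
        np.testing.assert_array_equal(a.mrr_rounds, b.mrr_rounds)

    def test_deficient_classes_listed(self):
        eset = gaussian_class_embeddings(
            FixtureSpec(class_count=2, class_size=4, class_separation=6, d=8, seed=4)
        )
        with pytest.raises(ValueError, match="class_size=9"):
            balanced_subsample_eval(eset, class_size=9)

    def test_standard_error_formula(self):
        eset = gaussian_class_embeddings(
            FixtureSpec(class_count=3, class_size=12, class_separation=3, d=8, seed=4)
        )
        rounds = balanced_subsample_eval(eset, class_size=6, n_rounds=12, seed=0)
        assert rounds.se_precision == pytest.approx(
            rounds.precision_rounds.std(ddof=1) / np.sqrt(12)
        )

    def test_tight_clusters_reach_subhalfmilli_standard_error(self):
        # at strong separation the per-round metrics saturate, reproducing
        # the reporting granularity where all standard errors sit below 5e-4
        eset = gaussian_class_embeddings(
            FixtureSpec(class_count=4, class_size=30, class_separation=50, d=16, seed=6)
        )
        rounds = balanced_subsample_eval(eset, class_size=15, n_rounds=50, seed=0)
        assert rounds.se_precision < 0.0005
        assert rounds.se_mrr < 0.0005


class TestCompareMethods:
    def test_identical_vectors_degenerate_p_one(self):
        a = np.full(10, 0.5)
        comp = compare_methods(a, a)
        assert comp.degenerate and comp.p_value == 1.0 and comp.stars == ""

    def test_complete_separation_attains_minimal_p(self):
        a = np.arange(10, 20, dtype=float)
        b = np.arange(10, dtype=float)
        comp = compare_methods(a, b)
        # exact two-sided MWU: all a above all b -> p = 2 / C(20, 10)
        assert comp.p_value == pytest.approx(2 / math.comb(20, 10))
        assert comp.stars == "***"

    def test_star_thresholds_track_p_value(self, rng):
        for _ in range(20):
            a = rng.standard_normal(8) + rng.uniform(0, 2)
            b = rng.standard_normal(8)
            comp = compare_methods(a, b)
            expected = (
                "***" if comp.p_value < 0.01
                else "**" if comp.p_value < 0.05
                else "*" if comp.p_value < 0.10
                else ""
            )
            assert comp.stars == expected

    def test_matches_scipy_directly(self, rng):
        a, b = rng.standard_normal(15), rng.standard_normal(15) + 0.5
        comp = compare_methods(a, b)
        ref = stats.mannwhitneyu(a, b, alternative="two-sided", method="exact")
        assert comp.p_value == pytest.approx(float(ref.pvalue))

    def test_too_few_rounds_rejected(self):
        with pytest.raises(ValueError, match="at least two"):
            compare_methods(np.array([1.0]), np.array([1.0, 2.0]))
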