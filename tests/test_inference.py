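import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

from foodtrace import (
    SalesMatrix,
    SourceAttribution,
    likelihood_scores,
    ml_estimate,
    score,
    spearman_scores,
    suspect_set,
    to_consumption_model,
)

from conftest import random_sales


def brute_force_likelihood(model, cases):
    """Direct product of probabilities, no log space (oracle)."""
    out = np.ones(model.n_products)
    for r in cases:
        out *= model.probs[:, model.region_index(r)]
    return out


class TestLikelihoodScores:
    def test_uniform_two_region_product(self):
        sm = SalesMatrix(["k"], ["a", "b"], np.array([[1.0, 1.0]]))
        sv = likelihood_scores(to_consumption_model(sm), ["a", "a", "b"])
        assert sv.raw[0] == pytest.approx(0.125, abs=1e-15)

    def test_structural_zero_excludes_exactly(self, toy_model):
        # product k is sold only in region a; a case in b excludes it
        sv = likelihood_scores(toy_model, ["b"])
        assert sv.raw[0] == 0.0
        assert sv.normalized[0] == 0.0

    def test_normalized_ratio_toy(self):
        sm = SalesMatrix(["k", "l"], ["a", "b"],
                         np.array([[1.0, 0.0], [0.5, 0.5]]))
        sv = likelihood_scores(to_consumption_model(sm), ["a", "a"])
        assert dict(zip(sv.product_ids, sv.normalized)) == \
            pytest.approx({"k": 1.0, "l": 0.25})

    def test_unknown_region_raises(self, toy_model):
        with pytest.raises(KeyError, match="zz"):
            likelihood_scores(toy_model, ["a", "zz"])

    def test_empty_cases_raises(self, toy_model):
        with pytest.raises(ValueError, match="empty"):
            likelihood_scores(toy_model, [])

    def test_all_excluded_flags_degenerate(self):
        # region c exists but no product is sold there
        sm = SalesMatrix(["k", "l"], ["a", "b", "c"],
                         np.array([[1.0, 0.0, 0.0], [0.0, 1.0, 0.0]]))
        sv = likelihood_scores(to_consumption_model(sm), ["c"])
        assert sv.degenerate
        assert np.all(sv.normalized == 0.0)

    @settings(deadline=None, derandomize=True, max_examples=60)
    @given(st.integers(2, 10), st.integers(1, 10), st.integers(0, 10_000))
    def test_log_space_equals_brute_force(self, n_products, m, seed):
        """On small instances with probabilities >= 0.01 the log-space
        path matches the direct product within 1e-10 relative error."""
        rng = np.random.default_rng(seed)
        values = rng.uniform(1.0, 100.0, size=(n_products, 4))
        sm = SalesMatrix([f"p{i}" for i in range(n_products)],
                         list("abcd"), values)
        model = to_consumption_model(sm)
        cases = list(rng.choice(list("abcd"), size=m))
        sv = likelihood_scores(model, cases)
        oracle = brute_force_likelihood(model, cases)
        np.testing.assert_allclose(sv.raw, oracle, rtol=1e-10)
        np.testing.assert_allclose(sv.normalized, oracle / oracle.max(),
                                   rtol=1e-10)

    def test_no_underflow_at_m_100(self, paper_like_sales):
        """At m=100 raw products underflow but ratios stay exact."""
        model = to_consumption_model(paper_like_sales)
        from foodtrace import generate_outbreak
        ob = generate_outbreak(model, "loc00", 100, seed=3)
        sv = likelihood_scores(model, ob.case_locations)
        assert sv.normalized.max() == 1.0
        assert not sv.degenerate

    def test_depends_only_on_counts(self, toy_model):
        cases = ["a", "b", "a", "c", "b"]
        sv1 = likelihood_scores(toy_model, cases)
        sv2 = likelihood_scores(toy_model, cases[::-1])
        np.testing.assert_array_equal(sv1.normalized, sv2.normalized)


class TestMLEstimate:
    def test_unique_argmax(self):
        sm = SalesMatrix(["k", "l"], ["a", "b"],
                         np.array([[1.0, 0.0], [0.5, 0.5]]))
        est = ml_estimate(likelihood_scores(to_consumption_model(sm), ["a"]))
        assert est.product == "k"
        assert not est.is_tie

    def test_identical_products_tie(self, identical_pair_sales):
        model = to_consumption_model(identical_pair_sales)
        from foodtrace import generate_outbreak
        ob = generate_outbreak(model, "dup_a", 30, seed=8)
        est = ml_estimate(likelihood_scores(model, ob.case_locations))
        assert set(est.products) >= {"dup_a", "dup_b"}
        assert est.product is None

    def test_degenerate_marker(self):
        sm = SalesMatrix(["k"], ["a", "b"], np.array([[1.0, 0.0]]))
        sv = likelihood_scores(to_consumption_model(sm), ["b"])
        est = ml_estimate(sv)
        assert est.degenerate
        assert est.product is None


class TestSuspectSet:
    def test_threshold_membership(self):
        sm = SalesMatrix(["k", "l", "j"], ["a", "b"],
                         np.array([[1.0, 0.0], [0.5, 0.5], [0.1, 0.9]]))
        model = to_consumption_model(sm)
        sv = likelihood_scores(model, ["a", "a", "a"])
        # normalized: k=1, l=0.125, j=0.001
        assert suspect_set(sv, 1 / 32).members == {"k", "l"}

    def test_threshold_one_keeps_tied_max(self, identical_pair_sales):
        model = to_consumption_model(identical_pair_sales)
        from foodtrace import generate_outbreak
        ob = generate_outbreak(model, "dup_b", 20, seed=2)
        sv = likelihood_scores(model, ob.case_locations)
        members = suspect_set(sv, 1.0).members
        assert members >= {"dup_a", "dup_b"}

    @pytest.mark.parametrize("bad", [0.0, -0.5, 1.5])
    def test_threshold_range(self, bad, toy_model):
        sv = likelihood_scores(toy_model, ["a"])
        with pytest.raises(ValueError):
            suspect_set(sv, bad)

    def test_monotone_in_threshold(self, paper_like_sales):
        model = to_consumption_model(paper_like_sales)
        from foodtrace import generate_outbreak
        ob = generate_outbreak(model, "nat07", 10, seed=6)
        sv = likelihood_scores(model, ob.case_locations)
        thresholds = [1 / 256, 1 / 64, 1 / 16, 1 / 4, 1.0]
        sets = [suspect_set(sv, t).members for t in thresholds]
        for smaller_t, larger_t in zip(sets, sets[1:]):
            assert larger_t <= smaller_t

    def test_max_product_always_member(self, toy_model):
        sv = likelihood_scores(toy_model, ["a", "a"])
        top = ml_estimate(sv).products[0]
        for t in (1 / 256, 0.5, 1.0):
            assert top in suspect_set(sv, t)


class TestSpearmanScores:
    def test_perfect_rank_agreement(self):
        regions = [f"r{i}" for i in range(5)]
        sm = SalesMatrix(["k"], regions, np.array([[1.0, 2, 3, 4, 5]]))
        # counts 0,1,2,3,4: strictly increasing with sales
        cases = [r for i, r in enumerate(regions) for _ in range(i)]
        sv = spearman_scores(sm, cases)
        assert sv.raw[0] == pytest.approx(1.0)

    def test_perfect_reversal(self):
        regions = [f"r{i}" for i in range(5)]
        sm = SalesMatrix(["k"], regions, np.array([[5.0, 4, 3, 2, 1]]))
        cases = [r for i, r in enumerate(regions) for _ in range(i)]
        sv = spearman_scores(sm, cases)
        assert sv.raw[0] == pytest.approx(-1.0)

    def test_matches_scipy_oracle(self):
        from scipy import stats
        sales = random_sales(4, 60, seed=3)
        rng = np.random.default_rng(4)
        cases = list(rng.choice(sales.region_ids, size=30))
        sv = spearman_scores(sales, cases)
        counts = np.zeros(60)
        for c in cases:
            counts[sales.region_index(c)] += 1
        for i in range(4):
            rho, _ = stats.spearmanr(sales.values[i], counts)
            assert sv.raw[i] == pytest.approx(rho, abs=1e-12)

    def test_null_correlation_near_zero(self):
        """Random sales vs random counts over 200 regions: |rho| small."""
        hits = 0
        n_seeds = 40
        for seed in range(n_seeds):
            sales = random_sales(1, 200, seed=seed)
            rng = np.random.default_rng(seed + 500)
            cases = list(rng.choice(sales.region_ids, size=100))
            sv = spearman_scores(sales, cases)
            hits += abs(sv.raw[0]) <= 0.2
        assert hits >= 0.9 * n_seeds

    def test_constant_row_scored_minus_one_with_warning(self):
        sm = SalesMatrix(["flat", "k"], ["a", "b", "c"],
                         np.array([[2.0, 2.0, 2.0], [1.0, 2.0, 3.0]]))
        with pytest.warns(UserWarning, match="flat"):
            sv = spearman_scores(sm, ["a", "b", "b", "c", "c", "c"])
        assert sv.raw[0] == -1.0

    def test_normalized_in_unit_interval_with_max_one(self, paper_like_sales):
        rng = np.random.default_rng(0)
        cases = list(rng.choice(paper_like_sales.region_ids, size=20))
        sv = spearman_scores(paper_like_sales, cases)
        assert sv.normalized.min() >= 0.0
        assert sv.normalized.max() == pytest.approx(1.0)


class TestDispatchAndModelAPI:
    def test_dispatch_matches_direct(self, toy_sales, toy_model):
        cases = ["a", "b"]
        sv = score(toy_model, toy_sales, cases, "likelihood")
        np.testing.assert_array_equal(
            sv.normalized, likelihood_scores(toy_model, cases).normalized)
        sv2 = score(None, toy_sales, cases, "spearman")
        np.testing.assert_array_equal(
            sv2.normalized, spearman_scores(toy_sales, cases).normalized)

    def test_unknown_method(self, toy_sales, toy_model):
        with pytest.raises(ValueError, match="unknown method"):
            score(toy_model, toy_sales, ["a"], "bayes")

    def test_fit_results_and_summary(self, paper_like_sales):
        from foodtrace import generate_outbreak
        model = to_consumption_model(paper_like_sales)
        ob = generate_outbreak(model, "reg12", 25, seed=1)
        res = SourceAttribution(paper_like_sales, ob.case_locations).fit()
        assert res.ml_estimate.product == "reg12"
        assert "reg12" in res.summary()
        frame = res.to_frame()
        assert frame.iloc[0]["product_id"] == "reg12"
        assert frame.iloc[0]["normalized"] == 1.0

    def test_from_dataframe(self, toy_sales):
        frame = toy_sales.to_frame()
        res = SourceAttribution.from_dataframe(frame, ["c"]).fit()
        assert res.ml_estimate.product == "j"
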