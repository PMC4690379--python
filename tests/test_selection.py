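"""OLS fitting, AICc, candidate sets, ranking, weights and evidence ratios."""

import math

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings, strategies as st

import ectosize as es
from ectosize import published
from ectosize.exceptions import CollinearityError, InsufficientDataError


class TestOlsFit:
    def test_matches_hand_solved_normal_equations(self):
        """3 points, 1 predictor: solve the 2x2 normal equations by hand."""
        y = np.array([1.0, 2.0, 3.0])
        x = np.array([1.0, 2.0, 4.0])
        # normal equations: [n, Sx; Sx, Sxx] [a, b]^T = [Sy, Sxy]^T
        A = np.array([[3.0, x.sum()], [x.sum(), (x * x).sum()]])
        rhs = np.array([y.sum(), (x * y).sum()])
        a, b = np.linalg.solve(A, rhs)
        rss = float(np.sum((y - a - b * x) ** 2))
        fit = es.ols_fit(y, x[:, None])
        assert fit.coefficients["intercept"] == pytest.approx(a, abs=1e-10)
        assert fit.coefficients["x1"] == pytest.approx(b, abs=1e-10)
        assert fit.sigma2_ml == pytest.approx(rss / 3, abs=1e-12)

    def test_row_permutation_leaves_fit_unchanged(self, rng):
        y = rng.normal(size=20)
        X = pd.DataFrame(rng.normal(size=(20, 2)), columns=["a", "b"])
        perm = rng.permutation(20)
        f1 = es.ols_fit(y, X)
        f2 = es.ols_fit(y[perm], X.iloc[perm])
        assert f1.aicc == pytest.approx(f2.aicc, abs=1e-9)
        assert f1.r2 == pytest.approx(f2.r2, abs=1e-12)

    def test_noise_free_fit_flagged_perfect_not_numeric(self):
        x = np.arange(10.0)
        fit = es.ols_fit(2 * x + 1, x[:, None])
        assert fit.perfect_fit
        assert fit.r2 == pytest.approx(1.0)
        assert math.isinf(fit.loglik)

    def test_collinear_design_names_dependent_column(self):
        x = np.arange(12.0)
        X = pd.DataFrame({"a": x, "twice_a": 2 * x})
        with pytest.raises(CollinearityError, match="twice_a"):
            es.ols_fit(np.sin(x), X)

    def test_k_counts_intercept_slopes_and_variance(self, rng):
        X = pd.DataFrame(rng.normal(size=(14, 2)), columns=["u", "v"])
        fit = es.ols_fit(rng.normal(size=14), X)
        assert fit.K == 4

    def test_too_few_sites_rejected_or_aicc_undefined(self, rng):
        with pytest.raises(InsufficientDataError):
            es.ols_fit(rng.normal(size=2), rng.normal(size=(2, 1)))
        # fit determined but the AICc correction denominator vanishes
        fit = es.ols_fit(rng.normal(size=4), rng.normal(size=(4, 1)))
        assert math.isnan(fit.aicc)
        with pytest.raises(ValueError, match="undefined"):
            es.rank_models([fit, fit])


class TestAICc:
    def test_reproduces_best_body_size_model_value(self):
        """The study's best model: loglik -16.177, K=3, n=14 gives 40.754."""
        assert es.aicc(-16.177, 3, 14) == pytest.approx(40.754, abs=1e-9)

    def test_correction_vanishes_at_large_n(self):
        assert es.aicc(-10.0, 3, 10**6) - (2 * 10 + 2 * 3) < 2.5e-5

    def test_boundary_rejected(self):
        with pytest.raises(ValueError):
            es.aicc(-10.0, 3, 4)


class TestCandidateSets:
    def test_eleven_models_each(self):
        size, cond = es.default_candidate_sets()
        assert len(size) == 11 and len(cond) == 11

    def test_no_duplicate_predictor_sets(self):
        size, _ = es.default_candidate_sets()
        sets = [frozenset(m.predictors) for m in size]
        assert len(set(sets)) == 11

    def test_bio4_model_carries_both_seasonality_hypotheses(self):
        size, _ = es.default_candidate_sets()
        bio4 = next(m for m in size if m.predictors == ("BIO4",))
        tags = dict(bio4.hypothesis_tags)
        assert tags["starvation-resistance"] == "+"
        assert tags["growing-season-length"] == "-"


class TestRanking:
    def _published_table(self):
        labels, vals = published.body_size_labels_aicc()
        return es.selection_table_from_aicc(labels, vals)

    def test_published_body_size_weights(self):
        tbl = self._published_table()
        assert tbl.frame.loc[0, "model"] == "BIO4"
        assert tbl.frame.loc[0, "weight"] == pytest.approx(0.974, abs=5e-4)
        assert tbl.frame["weight"].sum() == pytest.approx(1.0, abs=1e-12)

    def test_delta_nondecreasing_and_zero_at_top(self):
        tbl = self._published_table()
        d = tbl.frame["delta"].to_numpy()
        assert d[0] == 0.0
        assert np.all(np.diff(d) >= 0)

    def test_equal_aicc_models_share_weight(self):
        tbl = es.selection_table_from_aicc(["A", "B"], [10.0, 10.0])
        np.testing.assert_allclose(tbl.frame["weight"], [0.5, 0.5])

    def test_weights_invariant_to_aicc_location_shift(self):
        labels, vals = published.body_size_labels_aicc()
        t1 = es.selection_table_from_aicc(labels, vals)
        t2 = es.selection_table_from_aicc(labels, [v + 123.4 for v in vals])
        np.testing.assert_allclose(t1.frame["weight"], t2.frame["weight"])
        np.testing.assert_allclose(t1.frame["delta"], t2.frame["delta"])

    def test_rank_models_invariant_to_input_order(self, rng):
        y = rng.normal(size=14)
        X = pd.DataFrame(rng.normal(size=(14, 3)), columns=["BIO1", "BIO4", "BIO12"])
        fits = [
            es.ols_fit(y, X[["BIO4"]], label="BIO4"),
            es.ols_fit(y, X[["BIO1"]], label="BIO1"),
            es.ols_fit(y, X[["BIO1", "BIO4"]], label="BIO1+BIO4"),
        ]
        t1 = es.rank_models(fits)
        t2 = es.rank_models(fits[::-1])
        pd.testing.assert_frame_equal(t1.frame, t2.frame)

    def test_fits_on_different_n_rejected(self, rng):
        f1 = es.ols_fit(rng.normal(size=14), rng.normal(size=(14, 1)), label="a")
        f2 = es.ols_fit(rng.normal(size=12), rng.normal(size=(12, 1)), label="b")
        with pytest.raises(ValueError, match="different"):
            es.rank_models([f1, f2])

    @given(st.lists(st.floats(-50, 50), min_size=2, max_size=8, unique=True))
    @settings(deadline=None, max_examples=50)
    def test_weights_always_sum_to_one(self, vals):
        labels = [f"m{i}" for i in range(len(vals))]
        tbl = es.selection_table_from_aicc(labels, vals)
        assert tbl.frame["weight"].sum() == pytest.approx(1.0, abs=1e-12)


class TestEvidenceRatios:
    def test_self_ratio_is_one(self):
        labels, vals = published.body_size_labels_aicc()
        tbl = es.selection_table_from_aicc(labels, vals)
        assert tbl.evidence_ratio("BIO4", "BIO4") == pytest.approx(1.0)

    def test_reciprocity(self):
        labels, vals = published.body_size_labels_aicc()
        tbl = es.selection_table_from_aicc(labels, vals)
        fwd = tbl.evidence_ratio("BIO4", "BIO1+BIO4")
        back = tbl.evidence_ratio("BIO1+BIO4", "BIO4")
        assert fwd * back == pytest.approx(1.0, rel=1e-12)

    def test_underflowing_weight_yields_infinity_not_exception(self):
        tbl = es.selection_table_from_aicc(["a", "b"], [0.0, 5000.0])
        assert math.isinf(tbl.evidence_ratio("a", "b"))

    def test_computed_from_deltas_not_rounded_weights(self):
        """exp(Delta/2) gives 61.9; rounded weights would give 0.974/0.016 = 60.9."""
        labels, vals = published.body_size_labels_aicc()
        tbl = es.selection_table_from_aicc(labels, vals)
        r = tbl.evidence_ratio("BIO4", "BIO1+BIO4")
        assert r == pytest.approx(61.9, abs=0.05)
        assert abs(r - 0.974 / 0.016) > 0.5


class TestSummedWeights:
    def test_constructed_three_model_table(self):
        # weights 0.5/0.3/0.2 from deltas 0, 2 ln(5/3), 2 ln(5/2)
        deltas = [0.0, 2 * math.log(5 / 3), 2 * math.log(5 / 2)]
        tbl = es.selection_table_from_aicc(["BIO4", "BIO1", "BIO4+BIO12"], deltas)
        assert tbl.summed_weight("BIO4") == pytest.approx(0.7, abs=1e-12)

    def test_variable_in_every_or_no_model(self):
        tbl = es.selection_table_from_aicc(["BIO4", "BIO4+BIO12"], [1.0, 3.0])
        assert tbl.summed_weight("BIO4") == pytest.approx(1.0)
        assert tbl.summed_weight("NDVI") == 0.0

    def test_unknown_variable_rejected(self):
        tbl = es.selection_table_from_aicc(["BIO4", "BIO1"], [1.0, 2.0])
        with pytest.raises(KeyError):
            tbl.summed_weight("BIO99")


class TestFunctionalForms:
    def test_quadratic_signal_is_flagged(self, rng):
        x = np.linspace(-2, 2, 30)
        y = 1 + x**2 + rng.normal(0, 0.05, 30)
        rep = es.compare_functional_forms(y, x)
        assert rep["quadratic_improves"]

    def test_linear_signal_is_not_flagged(self, rng):
        """y linear in x with the noise orthogonalised against x^2."""
        x = np.linspace(-2, 2, 60)
        e = rng.normal(0, 0.3, 60)
        q = np.column_stack([np.ones(60), x, x**2])
        e = e - q @ np.linalg.lstsq(q, e, rcond=None)[0]
        rep = es.compare_functional_forms(3 + 2 * x + e, x)
        assert not rep["quadratic_improves"]

    def test_report_always_contains_both_variances(self, rng):
        x = np.linspace(0, 1, 20)
        rep = es.compare_functional_forms(rng.normal(size=20), x)
        assert "sigma2_linear" in rep and "sigma2_quadratic" in rep


class TestSelectorEstimator:
    def test_fits_all_candidates_on_simulated_data(self, darwinii_design, darwinii_summaries):
        sel = es.AICcModelSelector().fit(darwinii_design, darwinii_summaries["mean_svl_mm"])
        assert len(sel.table_) == 11
        assert set(sel.results_) == {m.label for m in es.default_candidate_sets()[0]}

    def test_bio4_effect_positive_in_best_models(self, darwinii_design, darwinii_summaries):
        """Generated with beta_bio4 > 0, every fitted BIO4 slope is positive."""
        sel = es.AICcModelSelector().fit(darwinii_design, darwinii_summaries["mean_svl_mm"])
        for fit in sel.results_.values():
            if "BIO4" in fit.predictors:
                assert fit.coefficients["BIO4"] > 0

    def test_bio4_only_model_usually_top_ranked(self):
        """With a strong BIO4 effect the single-predictor BIO4 model leads the
        ranking in most replicates (supersets can only beat it when sampling
        noise at n = 14 mimics a real extra effect)."""
        import ectosize as es
        from ectosize.pipeline import COLUMN_TO_PREDICTOR

        top = 0
        n_rep = 30
        for s in range(n_rep):
            spec = es.darwinii_like_scenario(seed=20_000 + s)
            sites, ind = es.simulate_tables(spec)
            means = (
                ind[ind["stage"] == "adult"].groupby("site_id")["svl_mm"].mean()
            )
            X = (
                sites.set_index("site_id")[["bio1", "bio4", "bio12", "ndvi"]]
                .rename(columns=COLUMN_TO_PREDICTOR)
                .loc[means.index]
            )
            sel = es.AICcModelSelector().fit(X, means.to_numpy())
            top += sel.best_model_ == "BIO4"
        assert top >= 0.7 * n_rep

    def test_render_clamps_negative_r2_but_frame_keeps_it(self):
        labels, vals = published.body_size_labels_aicc()
        tbl = es.selection_table_from_aicc(labels, vals, r2_adj=[0.876] + [-0.1] * 10)
        text = tbl.render(hide_below=0.0, clamp_negative_r2=True)
        assert "-0.1" not in text and "0.000" in text
        assert (tbl.frame["r2_adj"] < 0).any()

    def test_render_hides_small_weights_with_caption(self):
        labels, vals = published.body_size_labels_aicc()
        tbl = es.selection_table_from_aicc(labels, vals)
        text = tbl.render(hide_below=0.01)
        assert "not shown" in text
        assert len([ln for ln in text.splitlines() if ln.startswith("BIO")]) == 3
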