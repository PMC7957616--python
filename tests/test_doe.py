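"""Box-Behnken construction, quadratic fit, ANOVA and optimization."""

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st
from scipy import special

from licoqams import study_data as sd
from licoqams.doe import (FactorDef, anova, bbd_design, fit_quadratic,
                          fit_stats, model_matrix, optimize_in_box,
                          quadratic_response, stationary_point)

coef_strategy = st.lists(st.floats(-2, 2), min_size=10, max_size=10)


class TestDesignConstruction:
    def test_decoded_rows_match_study_runs(self, study_design):
        assert study_design.natural_matrix() == \
            pytest.approx(np.array(sd.BBD_RUNS_NATURAL, dtype=float))

    def test_run_count_and_center_replicates(self, study_design):
        assert study_design.n_runs == 17
        center = (study_design.coded_matrix == 0).all(axis=1)
        assert center.sum() == 5

    def test_linear_columns_orthogonal(self, study_design):
        X = study_design.coded_matrix
        for i in range(3):
            for j in range(i + 1, 3):
                assert X[:, i] @ X[:, j] == 0

    def test_column_sums_of_squares(self, study_design):
        M = model_matrix(study_design.coded_matrix)
        for j in (1, 2, 3):  # linear columns
            assert (M[:, j] ** 2).sum() == 8
        for j in (4, 5, 6):  # pairwise products
            assert (M[:, j] ** 2).sum() == 4

    def test_non_three_factor_rejected(self):
        with pytest.raises(ValueError, match="3-factor"):
            bbd_design([FactorDef("a", 0, 1), FactorDef("b", 0, 1)])


class TestCoding:
    def test_center_encodes_to_zero(self, study_design):
        assert study_design.encode((20, 30, 40)) == pytest.approx([0, 0, 0])

    def test_reported_optimum_water_coordinate(self):
        f = FactorDef("water content (%)", 30, 10)
        assert f.encode(29.84) == pytest.approx(-0.016)

    @given(st.tuples(st.floats(-1, 1), st.floats(-1, 1), st.floats(-1, 1)))
    @settings(max_examples=50, deadline=None, derandomize=True)
    def test_decode_encode_round_trip(self, coded):
        design = bbd_design([FactorDef(n, c, s) for n, c, s in sd.BBD_FACTORS])
        nat = design.decode(coded)
        assert design.encode(nat) == pytest.approx(np.asarray(coded), abs=1e-9)


class TestQuadraticFit:
    def test_interaction_coefficients_equal_four_run_contrasts(self, study_model):
        """On the orthogonal design, bAC is the AC-block contrast /4 and
        matches the published -0.020 exactly (likewise BC, AB)."""
        z = sd.BBD_RESPONSES
        assert study_model.coef("AC") == pytest.approx((z[4] - z[5] - z[6] + z[7]) / 4)
        assert study_model.coef("AC") == pytest.approx(-0.020)
        assert study_model.coef("BC") == pytest.approx((z[8] - z[9] - z[10] + z[11]) / 4)
        assert study_model.coef("BC") == pytest.approx(0.025)
        assert study_model.coef("AB") == pytest.approx(0.005)

    def test_linear_coefficients_equal_eight_run_contrasts(self, study_model):
        z = sd.BBD_RESPONSES
        bA = (-z[0] + z[1] - z[2] + z[3] - z[4] + z[5] - z[6] + z[7]) / 8
        assert study_model.coef("A") == pytest.approx(bA)
        assert study_model.coef("A") == pytest.approx(0.0125)

    def test_remaining_coefficients_at_display_rounding(self, study_model):
        published = dict(zip(("Intercept", "A", "B", "C", "AB", "AC", "BC",
                              "A2", "B2", "C2"), sd.PUBLISHED_QUADRATIC_COEFS))
        for term in ("Intercept", "B", "C", "C2"):
            got = study_model.coef(term)
            assert got == pytest.approx(published[term], abs=0.005)

    def test_agrees_with_statsmodels_ols(self, study_design):
        statsmodels = pytest.importorskip("statsmodels.api")
        X = model_matrix(study_design.coded_matrix)
        ref = statsmodels.OLS(sd.BBD_RESPONSES, X).fit()
        model = fit_quadratic(study_design, sd.BBD_RESPONSES)
        assert model.coefficients == pytest.approx(ref.params, rel=1e-9)

    @given(coef_strategy)
    @settings(max_examples=50, deadline=None, derandomize=True)
    def test_zero_noise_parameter_recovery(self, truth):
        design = bbd_design([FactorDef(n, c, s) for n, c, s in sd.BBD_FACTORS])
        y = model_matrix(design.coded_matrix) @ np.array(truth)
        model = fit_quadratic(design, y)
        assert model.coefficients == pytest.approx(np.array(truth), abs=1e-8)

    def test_fitted_plus_residual_and_orthogonality(self, study_model):
        assert study_model.fitted_values + study_model.residuals == \
            pytest.approx(sd.BBD_RESPONSES)
        X = model_matrix(study_model.design.coded_matrix)
        assert X.T @ study_model.residuals == pytest.approx(np.zeros(10), abs=1e-10)

    def test_length_mismatch_rejected(self, study_design):
        with pytest.raises(ValueError, match="17-run"):
            fit_quadratic(study_design, np.ones(5))


class TestAnova:
    def test_pure_error_from_center_replicates(self, study_model):
        t = anova(study_model).table
        assert t.loc["Pure Error", "sum_sq"] == pytest.approx(0.00108, abs=1e-10)
        assert t.loc["Pure Error", "df"] == 4

    def test_partial_ss_for_linear_term_matches_contrast_identity(self, study_model):
        t = anova(study_model).table
        # partial SS of an orthogonal column is beta^2 * sum(x^2) = beta^2 * 8
        assert t.loc["A", "sum_sq"] == pytest.approx(0.00125, abs=1e-10)
        assert t.loc["A", "sum_sq"] == \
            pytest.approx(study_model.coef("A") ** 2 * 8, abs=1e-12)

    def test_model_f_and_significance(self, study_model):
        t = anova(study_model).table
        assert t.loc["Model", "F"] == pytest.approx(21.91, abs=0.01)
        assert t.loc["Model", "p"] < 0.001

    def test_lack_of_fit_tested_against_pure_error(self, study_model):
        t = anova(study_model).table
        assert t.loc["Lack of Fit", "F"] == pytest.approx(5.8, abs=0.01)
        assert t.loc["Lack of Fit", "p"] == pytest.approx(0.0612, abs=5e-4)

    def test_ss_and_df_additivity(self, study_model):
        t = anova(study_model).table
        assert t.loc["Model", "sum_sq"] + t.loc["Residual", "sum_sq"] == \
            pytest.approx(t.loc["Cor Total", "sum_sq"], abs=1e-10)
        assert t.loc["Lack of Fit", "sum_sq"] + t.loc["Pure Error", "sum_sq"] \
            == pytest.approx(t.loc["Residual", "sum_sq"], abs=1e-10)
        assert t.loc["Model", "df"] + t.loc["Residual", "df"] == \
            t.loc["Cor Total", "df"]
        assert t.loc["Lack of Fit", "df"] + t.loc["Pure Error", "df"] == \
            t.loc["Residual", "df"]

    @given(coef_strategy, st.integers(0, 2 ** 31 - 1))
    @settings(max_examples=25, deadline=None, derandomize=True)
    def test_additivity_on_noisy_fits(self, truth, seed):
        design = bbd_design([FactorDef(n, c, s) for n, c, s in sd.BBD_FACTORS])
        rng = np.random.default_rng(seed)
        y = model_matrix(design.coded_matrix) @ np.array(truth) \
            + rng.normal(0, 0.02, 17)
        t = anova(fit_quadratic(design, y)).table
        assert t.loc["Model", "sum_sq"] + t.loc["Residual", "sum_sq"] == \
            pytest.approx(t.loc["Cor Total", "sum_sq"], abs=1e-10)

    def test_p_values_match_independent_f_tail(self, study_model):
        """Upper-tail probabilities recomputed from the regularized
        incomplete beta function agree with the table's p column."""
        t = anova(study_model).table
        for name in ("Model", "A", "BC", "A2", "Lack of Fit"):
            F = t.loc[name, "F"]
            d1 = t.loc[name, "df"]
            d2 = 4 if name == "Lack of Fit" else t.loc["Residual", "df"]
            p_ref = special.betainc(d2 / 2, d1 / 2, d2 / (d2 + d1 * F))
            assert t.loc[name, "p"] == pytest.approx(p_ref, rel=1e-9)

    def test_fit_statistics(self, study_model):
        av = anova(study_model)
        assert av.r_squared == pytest.approx(0.9657, abs=5e-5)
        assert av.adj_r_squared == pytest.approx(0.9216, abs=5e-5)
        r2, adj = fit_stats(av, n=17, p_terms=9)
        assert (r2, adj) == (av.r_squared, av.adj_r_squared)
        # algebraic identity: R^2 = 1 - SSE/SS_total
        t = av.table
        assert r2 == pytest.approx(
            1 - t.loc["Residual", "sum_sq"] / t.loc["Cor Total", "sum_sq"])

    def test_perfect_fit_r2(self, study_design):
        y = model_matrix(study_design.coded_matrix) @ np.arange(10, dtype=float)
        av = anova(fit_quadratic(study_design, y))
        assert av.r_squared == pytest.approx(1.0)
        assert av.adj_r_squared == pytest.approx(1.0)


class TestStochasticRecovery:
    def test_coefficients_unbiased_over_1000_noisy_refits(self, study_design):
        """With i.i.d. noise at the replicate scale, refitted coefficients
        average to the truth within Monte-Carlo error."""
        truth = sd.PUBLISHED_QUADRATIC_COEFS
        X = model_matrix(study_design.coded_matrix)
        mean_y = X @ truth
        rng = np.random.default_rng(2024)
        n_rep, sigma = 1000, 0.02
        est = np.empty((n_rep, 10))
        for i in range(n_rep):
            est[i] = fit_quadratic(
                study_design, mean_y + rng.normal(0, sigma, 17)).coefficients
        # se of the mean estimate per coefficient is <= sigma/sqrt(n_rep)
        bias = est.mean(axis=0) - truth
        assert np.abs(bias).max() < 5 * sigma / np.sqrt(n_rep)


class TestOptimization:
    def test_stationary_point_matches_reported_optimum(self, study_model):
        opt = stationary_point(study_model)
        assert opt.hessian_definiteness == "max"
        assert np.round(opt.natural_point, 2) == \
            pytest.approx([20.40, 29.84, 41.19])
        assert round(opt.predicted_response, 2) == 0.95

    def test_concave_separable_quadratic_peaks_at_origin(self, study_design):
        # z = 2 - A^2 - B^2 - C^2
        coefs = np.array([2.0, 0, 0, 0, 0, 0, 0, -1.0, -1.0, -1.0])
        y = model_matrix(study_design.coded_matrix) @ coefs
        opt = stationary_point(fit_quadratic(study_design, y))
        assert opt.coded_point == pytest.approx(np.zeros(3), abs=1e-9)
        assert opt.predicted_response == pytest.approx(2.0)
        assert opt.hessian_definiteness == "max"

    def test_singular_hessian_suggests_box_search(self, study_design):
        coefs = np.array([1.0, 0.1, 0, 0, 0, 0, 0, 0, 0, 0])  # no curvature
        y = model_matrix(study_design.coded_matrix) @ coefs
        with pytest.raises(np.linalg.LinAlgError, match="optimize_in_box"):
            stationary_point(fit_quadratic(study_design, y))

    def test_box_optimum_equals_interior_stationary_point(self, study_model):
        sp = stationary_point(study_model)
        box = optimize_in_box(study_model)
        assert not box.clipped_to_box
        assert box.coded_point == pytest.approx(sp.coded_point, abs=1e-9)
        assert box.predicted_response == pytest.approx(sp.predicted_response)

    def test_convex_direction_clips_to_boundary(self, study_design):
        coefs = np.array([0.0, 0.5, 0, 0, 0, 0, 0, 1.0, -0.5, -0.5])
        y = model_matrix(study_design.coded_matrix) @ coefs
        opt = optimize_in_box(fit_quadratic(study_design, y))
        assert opt.clipped_to_box
        assert abs(opt.coded_point[0]) == pytest.approx(1.0)

    @given(st.lists(st.floats(-1, 1), min_size=10, max_size=10),
           st.integers(0, 10_000))
    @settings(max_examples=15, deadline=None, derandomize=True)
    def test_box_optimum_beats_dense_grid(self, coefs, seed):
        design = bbd_design([FactorDef(n, c, s) for n, c, s in sd.BBD_FACTORS])
        rng = np.random.default_rng(seed)
        beta = np.array(coefs)
        beta[7:] = -np.abs(beta[7:]) - 0.1  # concave in each square term
        y = model_matrix(design.coded_matrix) @ beta
        model = fit_quadratic(design, y)
        opt = optimize_in_box(model)
        grid_pts = rng.uniform(-1, 1, size=(500, 3))
        grid_best = (model_matrix(grid_pts) @ model.coefficients).max()
        assert opt.predicted_response >= grid_best - 1e-9
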