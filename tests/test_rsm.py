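import numpy as np
import pytest

import extractopt as eo
from extractopt.rsm import (
    QuadraticModel,
    anova_to_frame,
    anova_to_text,
    design_matrix,
    significance_marks,
    surface_grid,
    term_names,
)

# published second-order coefficients, rounded as printed
PUBLISHED_COEFS = [13.01, 0.17, 0.055, 0.11, -0.28, -0.083, 0.045, -0.095,
                   -0.055, -0.22, 0.058, -0.33, -0.32, -0.13, -0.86]


class TestFitQuadratic:
    def test_intercept_and_linear_terms_match_published(self, refit_model):
        coef = refit_model.coef_vector()
        assert round(coef[0], 2) == 13.01
        assert np.allclose(coef[1:5], [0.17, 0.055, 0.11, -0.28], atol=0.005)

    def test_all_coefficients_match_published_rounding(self, refit_model):
        assert np.allclose(refit_model.coef_vector(), PUBLISHED_COEFS, atol=0.005)

    def test_noiseless_recovery(self, factors, rng):
        beta = rng.normal(0, 1, 15)
        truth = QuadraticModel.from_coef_vector(beta, 4)
        spec = eo.SurfaceSpec(model=truth, noise_sd=0.0, n_center=6, seed=0)
        table = eo.simulate_bbd_experiment(factors, spec)
        refit = eo.fit_quadratic(table, "composite")
        assert np.allclose(refit.coef_vector(), beta, atol=1e-10)

    def test_constant_response(self, factors):
        points = eo.build_bbd(factors, 6)
        table = eo.ExperimentTable(
            factors=factors,
            run_ids=list(range(1, 31)),
            coded=np.array([p.coded for p in points]),
            yields={"a": np.full(30, 7.5)},
            composite=np.full(30, 7.5),
        )
        m = eo.fit_quadratic(table, "composite")
        assert m.intercept == pytest.approx(7.5, abs=1e-10)
        assert np.allclose(m.coef_vector()[1:], 0.0, atol=1e-10)

    def test_rank_deficiency_names_aliased_terms(self, factors):
        # two identical columns: interactions alias
        coded = np.zeros((20, 4))
        coded[:, 0] = np.tile([-1, 1], 10)
        coded[:, 1] = coded[:, 0]
        table = eo.ExperimentTable(
            factors=factors,
            run_ids=list(range(20)),
            coded=coded,
            yields={"a": np.arange(20.0)},
            composite=np.arange(20.0),
        )
        with pytest.raises(ValueError, match="rank deficient"):
            eo.fit_quadratic(table, "composite")

    def test_too_few_runs(self, factors):
        table = eo.ExperimentTable(
            factors=factors,
            run_ids=[1, 2],
            coded=np.array([[1.0, 0, 0, 0], [0, 1.0, 0, 0]]),
            yields={"a": np.array([1.0, 2.0])},
            composite=np.array([1.0, 2.0]),
        )
        with pytest.raises(ValueError, match="at least 15"):
            eo.fit_quadratic(table, "composite")


class TestPredictQuadratic:
    def test_center_point_returns_intercept(self, refit_model):
        assert eo.predict_quadratic(refit_model, np.zeros(4)) == pytest.approx(
            refit_model.intercept
        )

    def test_all_high_corner_sums_printed_coefficients(self):
        # direct arithmetic over the printed, rounded coefficients
        printed = QuadraticModel.from_coef_vector(np.array(PUBLISHED_COEFS), 4)
        assert eo.predict_quadratic(printed, np.ones(4)) == pytest.approx(
            sum(PUBLISHED_COEFS), abs=1e-12
        )
        assert sum(PUBLISHED_COEFS) == pytest.approx(11.075)

    def test_residual_ss_consistency(self, refit_model, table2, anova):
        pred = refit_model.predict(table2.coded)
        resid = table2.composite - pred
        assert float(resid @ resid) == pytest.approx(anova.residual.ss, rel=1e-9)

    def test_dimension_mismatch(self, refit_model):
        with pytest.raises(ValueError, match="dimension"):
            refit_model.predict(np.zeros(3))

    def test_quadratic_form_agrees_with_predict(self, refit_model, rng):
        B, b = refit_model.quadratic_form()
        for _ in range(10):
            x = rng.uniform(-1, 1, 4)
            via_form = refit_model.intercept + b @ x + x @ B @ x
            assert via_form == pytest.approx(refit_model.predict(x), abs=1e-12)


class TestAnova:
    def test_r_squared_family_matches_published(self, anova):
        assert anova.r2 == pytest.approx(0.9913, abs=0.002)
        assert anova.adj_r2 == pytest.approx(0.9832, abs=0.002)
        assert anova.pred_r2 == pytest.approx(0.9641, abs=0.002)

    def test_model_f(self, anova):
        assert anova.model_row.f == pytest.approx(121.9277, abs=0.5)
        assert anova.model_row.df == 14

    def test_lack_of_fit(self, anova):
        lof = anova.lack_of_fit
        assert lof.df == 10
        assert anova.pure_error.df == 5
        assert lof.f == pytest.approx(0.82, abs=0.02)
        assert lof.p == pytest.approx(0.6322, abs=0.002)

    def test_x4_squared_partial_ss(self, anova):
        row = anova.row("ethanol_concentration^2")
        assert row.ss == pytest.approx(5.0848, abs=0.005)

    def test_published_term_table(self, anova, factors):
        published = {
            "extraction_time": 0.3385,
            "extraction_temperature": 0.0363,
            "liquid_solid_ratio": 0.1508,
            "ethanol_concentration": 0.9443,
            "extraction_time*extraction_temperature": 0.0278,
            "extraction_time*liquid_solid_ratio": 0.0080,
            "extraction_time*ethanol_concentration": 0.0362,
            "extraction_temperature*liquid_solid_ratio": 0.0122,
            "extraction_temperature*ethanol_concentration": 0.2022,
            "liquid_solid_ratio*ethanol_concentration": 0.0135,
            "extraction_time^2": 0.7355,
            "extraction_temperature^2": 0.7052,
            "liquid_solid_ratio^2": 0.1103,
            "ethanol_concentration^2": 5.0848,
        }
        for term, ss in published.items():
            assert anova.row(term).ss == pytest.approx(ss, abs=0.005), term

    def test_ss_and_df_additivity(self, anova):
        assert anova.model_row.ss + anova.residual.ss == pytest.approx(
            anova.total_ss, rel=1e-6
        )
        assert anova.model_row.df + anova.residual.df == anova.total_df
        assert anova.lack_of_fit.ss + anova.pure_error.ss == pytest.approx(
            anova.residual.ss, rel=1e-6
        )

    def test_linear_term_ss_equals_contrast_formula(self, anova, table2):
        # orthogonal-column oracle: SS_i = (sum x_i y)^2 / sum x_i^2
        y = table2.composite
        names = [f.name for f in table2.factors]
        for i, name in enumerate(names):
            x = table2.coded[:, i]
            expected = (x @ y) ** 2 / (x @ x)
            assert anova.row(name).ss == pytest.approx(expected, rel=1e-9)

    def test_pred_r2_not_above_r2(self, factors, rng):
        for seed in range(5):
            beta = rng.normal(0, 1, 15)
            spec = eo.SurfaceSpec(
                model=eo.QuadraticModel.from_coef_vector(beta, 4),
                noise_sd=0.5,
                n_center=6,
                seed=seed,
            )
            table = eo.simulate_bbd_experiment(factors, spec)
            a = eo.anova_quadratic(eo.fit_quadratic(table), table)
            assert a.pred_r2 <= a.r2

    def test_noiseless_fit_is_perfect(self, factors, rng):
        beta = rng.normal(0, 1, 15)
        spec = eo.SurfaceSpec(
            model=eo.QuadraticModel.from_coef_vector(beta, 4),
            noise_sd=0.0, n_center=6, seed=1,
        )
        table = eo.simulate_bbd_experiment(factors, spec)
        a = eo.anova_quadratic(eo.fit_quadratic(table), table)
        assert a.r2 == pytest.approx(1.0, abs=1e-12)
        assert a.residual.ss == pytest.approx(0.0, abs=1e-12)

    def test_no_replicates_drops_lack_of_fit(self, factors):
        points = eo.build_bbd(factors, 1)
        coded = np.array([p.coded for p in points])
        rng = np.random.default_rng(0)
        y = rng.normal(0, 1, len(points))
        table = eo.ExperimentTable(
            factors=factors,
            run_ids=list(range(len(points))),
            coded=coded,
            yields={"a": y},
            composite=y,
        )
        a = eo.anova_quadratic(eo.fit_quadratic(table), table)
        assert a.lack_of_fit is None
        assert any("lack-of-fit" in w for w in a.warnings)

    def test_degenerate_pure_error_flags_infinite_f(self, factors, rng):
        points = eo.build_bbd(factors, 6)
        coded = np.array([p.coded for p in points])
        y = rng.normal(0, 1, 24)
        resp = np.concatenate([y, np.full(6, 5.0)])  # identical replicates
        table = eo.ExperimentTable(
            factors=factors,
            run_ids=list(range(30)),
            coded=coded,
            yields={"a": resp},
            composite=resp,
        )
        a = eo.anova_quadratic(eo.fit_quadratic(table), table)
        assert np.isinf(a.lack_of_fit.f)
        assert a.lack_of_fit.p == 0.0
        assert any("degenerate pure error" in w for w in a.warnings)


class TestSignificanceMarks:
    @pytest.mark.parametrize(
        "p,mark",
        [
            (0.011, "*"),
            (0.0228, "*"),
            (0.5, ""),
            (0.0005, "***"),
            (0.002, "**"),
            (0.05, ""),
            (0.01, "*"),
            (0.001, "**"),
        ],
    )
    def test_thresholds(self, p, mark):
        assert significance_marks(p) == mark

    def test_invalid_p(self):
        with pytest.raises(ValueError):
            significance_marks(1.5)

    def test_anova_rows_carry_marks(self, anova):
        assert anova.row("extraction_temperature").mark == "*"
        assert anova.row("ethanol_concentration").mark == "***"
        assert anova.row("extraction_time*liquid_solid_ratio").mark == ""


class TestReports:
    def test_frame_has_expected_sources(self, anova):
        df = anova_to_frame(anova)
        assert list(df["source"])[:2] == ["model", "extraction_time"]
        assert "lack of fit" in set(df["source"])

    def test_text_report_contains_fit_stats(self, anova):
        text = anova_to_text(anova)
        assert "R^2           0.9913" in text
        assert "Predicted R^2 0.9641" in text

    def test_surface_grid_shape_and_center(self, refit_model):
        df = surface_grid(refit_model, 0, 3, step=0.5)
        assert len(df) == 25
        center = df[(df.xi == 0) & (df.xj == 0)]["predicted"].iloc[0]
        assert center == pytest.approx(refit_model.intercept)

    def test_term_names_order(self):
        names = term_names(["a", "b"])
        assert names == ["intercept", "a", "b", "a*b", "a^2", "b^2"]

    def test_design_matrix_width(self):
        D = design_matrix(np.zeros((5, 4)))
        assert D.shape == (5, 15)
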