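"""OLS fitting on coded factors, elimination, intervals and prediction."""

import numpy as np
import pandas as pd
import pytest
from scipy import stats

import aqbd
from aqbd import ModelSpec, ResponseModel, Term


def _linfit(design, y, **kw):
    return ResponseModel(y, design, ModelSpec.linear(design.factor_names), **kw).fit()


class TestFit:
    def test_noise_free_truth_is_interpolated_exactly(self, toy_design):
        c = toy_design.coded
        y = 2 + 3 * c["x1"] - c["x2"]
        res = _linfit(toy_design, y)
        assert np.allclose(res.params.to_numpy(), [2, 3, -1])
        assert np.allclose(res.resid, 0)

    def test_matches_hand_solved_normal_equations(self):
        # 4 runs, intercept + slope on a single coded factor:
        # XtX = [[4, 0], [0, 4]], Xty = [sum y, sum x*y]
        design = aqbd.DesignMatrix(
            pd.DataFrame({"x1": [-1.0, -1.0, 1.0, 1.0]}),
            [aqbd.FactorSpec("x1", -1, 1)],
        )
        y = np.array([1.0, 2.0, 5.0, 4.0])
        res = _linfit(design, y)
        assert np.allclose(res.params.to_numpy(), [y.sum() / 4, (y * [-1, -1, 1, 1]).sum() / 4])

    def test_coefficients_equal_half_difference_of_means(self, screening, screening_fits):
        # on an orthogonal two-level design each linear coefficient is an
        # independent contrast: half the mean response difference at +1 vs −1
        design, responses = screening
        coded = design.coded
        for name, res in screening_fits.items():
            y = responses[name]
            for f in design.factor_names:
                half_diff = (y[coded[f] > 0.5].mean() - y[coded[f] < -0.5].mean()) / 2
                assert res.params[f] == pytest.approx(half_diff, abs=1e-10)

    def test_residuals_orthogonal_to_model_columns(self, screening_fits):
        for res in screening_fits.values():
            X = res.model.exog.to_numpy()
            assert np.allclose(X.T @ res.resid.to_numpy(), 0, atol=1e-8)

    def test_quadratic_terms_on_two_level_design_rejected_by_name(self, screening):
        design, responses = screening
        spec = ModelSpec(
            [Term((f,)) for f in design.factor_names]
            + [Term(("buffer_mM", "buffer_mM")), Term(("buffer_pH", "buffer_pH"))]
        )
        with pytest.raises(ValueError, match="buffer_pH\\^2"):
            ResponseModel(responses["T"], design, spec).fit()

    def test_adding_a_term_never_increases_sse(self, rsm):
        design, responses = rsm
        y = responses["R3"]
        base = ModelSpec.linear(design.factor_names)
        sse_base = ResponseModel(y, design, base).fit().ss_resid
        for extra in (("temperature_C", "temperature_C"),
                      ("temperature_C", "methanol_pct")):
            spec = ModelSpec(list(base.terms[1:]) + [Term(extra)])
            sse = ResponseModel(y, design, spec).fit().ss_resid
            assert sse <= sse_base + 1e-10


class TestBackwardElimination:
    def test_all_significant_terms_survive(self, toy_design):
        rng = np.random.default_rng(0)
        c = toy_design.coded
        y = 2 + 3 * c["x1"] - 2 * c["x2"] + rng.normal(0, 1e-4, 4)
        res = _linfit(toy_design, y)
        reduced = res.backward_eliminate(alpha=0.05)
        assert reduced.spec == res.spec

    def test_spurious_terms_dropped_at_high_signal_to_noise(self):
        # truth y = 1 + 2·x1; x2 and x1·x2 are spurious
        design = aqbd.generate_fractional_factorial(2, 0, 4)
        spec = ModelSpec([Term(("x1",)), Term(("x2",)), Term(("x1", "x2"))])
        # each spurious term survives a step with ~alpha probability, so the
        # joint exact-recovery rate is about (1 - 0.05)^2 ~ 0.90
        drops = 0
        n_rep = 200
        for seed in range(n_rep):
            rng = np.random.default_rng(seed)
            c = design.coded
            y = 1 + 2 * c["x1"] + rng.normal(0, 0.05, len(c))
            res = ResponseModel(y, design, spec).fit().backward_eliminate(0.05)
            kept = set(res.spec.term_names)
            if kept == {"intercept", "x1"}:
                drops += 1
        assert drops >= 0.85 * n_rep
        assert "x1" in res.spec.term_names  # the real effect is never lost

    def test_reduced_r2_never_exceeds_full(self, rsm_full_fits, rsm_reduced_fits):
        for name in rsm_full_fits:
            assert rsm_reduced_fits[name].rsquared <= rsm_full_fits[name].rsquared + 1e-12

    def test_hierarchy_keeps_parents_of_retained_interactions(self, rsm_reduced_fits):
        for res in rsm_reduced_fits.values():
            for t in res.spec.terms:
                for parent in t.parents():
                    assert parent in res.spec.terms

    def test_elimination_log_records_removals(self, rsm_full_fits):
        red = rsm_full_fits["R5"].backward_eliminate(0.05)
        assert len(red.elimination_log) == len(rsm_full_fits["R5"].params) - len(red.params)


class TestConfidenceIntervals:
    def test_zero_noise_gives_zero_half_widths(self, toy_design):
        c = toy_design.coded
        y = 1 + c["x1"]
        res = ResponseModel(y, toy_design, ModelSpec([Term(("x1",))])).fit()
        assert np.allclose(res.conf_int(0.95)["half_width"], 0, atol=1e-12)

    def test_half_width_linear_in_residual_scale(self, toy_design):
        c = toy_design.coded
        e = np.array([1.0, -1.0, -1.0, 1.0])  # orthogonal to intercept and x1
        spec = ModelSpec([Term(("x1",))])
        y1 = 1 + c["x1"] + 0.1 * e
        y2 = 1 + c["x1"] + 0.2 * e
        h1 = ResponseModel(y1, toy_design, spec).fit().conf_int(0.95)["half_width"]
        h2 = ResponseModel(y2, toy_design, spec).fit().conf_int(0.95)["half_width"]
        assert np.allclose(2 * h1, h2)

    def test_interval_matches_hand_t_computation(self):
        # 5 runs, intercept + slope; compare with explicit t-quantile formula
        design = aqbd.DesignMatrix(
            pd.DataFrame({"x1": [-1.0, -0.5, 0.0, 0.5, 1.0]}),
            [aqbd.FactorSpec("x1", -1, 1)],
        )
        y = np.array([0.9, 1.6, 2.1, 2.4, 3.1])
        res = ResponseModel(y, design, ModelSpec([Term(("x1",))])).fit()
        x = design.coded["x1"].to_numpy()
        X = np.column_stack([np.ones(5), x])
        b = np.linalg.solve(X.T @ X, X.T @ y)
        s2 = ((y - X @ b) ** 2).sum() / 3
        se = np.sqrt(s2 * np.diag(np.linalg.inv(X.T @ X)))
        t = stats.t.ppf(0.975, 3)
        assert np.allclose(res.conf_int(0.95)["half_width"], t * se)

    def test_invalid_level_rejected(self, screening_fits):
        with pytest.raises(ValueError):
            screening_fits["T"].conf_int(1.5)


class TestPrediction:
    def test_saturated_model_reproduces_observations(self, toy_design):
        c = toy_design.coded
        y = np.array([1.0, 2.0, 3.0, 5.0])
        spec = ModelSpec([Term(("x1",)), Term(("x2",)), Term(("x1", "x2"))])
        res = ResponseModel(y, toy_design, spec).fit()
        pred = res.predict(c)
        assert np.allclose(pred.mean, y)

    def test_center_prediction_equals_intercept(self, screening_fits):
        res = screening_fits["R1"]
        pred = res.predict(np.zeros((1, 6)))
        assert pred.mean[0] == pytest.approx(res.params["intercept"])

    def test_extrapolation_flagged_not_rejected(self, screening_fits):
        pred = screening_fits["T"].predict(np.full((1, 6), 1.5))
        assert pred.extrapolated[0]
        pred_in = screening_fits["T"].predict(np.zeros((1, 6)))
        assert not pred_in.extrapolated[0]

    def test_predictive_variance_decomposition(self, rsm_full_fits):
        res = rsm_full_fits["T"]
        pred = res.predict(np.zeros((1, 3)))
        assert pred.se_obs[0] ** 2 == pytest.approx(res.scale + pred.se_mean[0] ** 2)

    def test_natural_unit_prediction_round_trip(self, rsm_full_fits):
        res = rsm_full_fits["R5"]
        p_coded = res.predict(np.zeros((1, 3)))
        p_nat = res.predict(
            {"temperature_C": 48.5, "methanol_pct": 39.0, "gradient_slope": 2.2},
            natural=True,
        )
        assert p_nat.mean[0] == pytest.approx(p_coded.mean[0])


class TestParameterRecovery:
    def test_estimates_converge_to_truth_as_noise_vanishes(self, rsm):
        design, _ = rsm
        spec = ModelSpec.full_quadratic(design.factor_names)
        rng = np.random.default_rng(42)
        truth = pd.Series(rng.normal(0, 1, len(spec)), index=spec.term_names)
        X = spec.model_matrix(design.coded).to_numpy()
        errs = []
        for sd in (1e-1, 1e-3):
            y = X @ truth.to_numpy() + rng.normal(0, sd, len(X))
            res = ResponseModel(y, design, spec).fit()
            errs.append(np.abs(res.params - truth).max())
        assert errs[1] < errs[0]
        assert errs[1] < 1e-2

    def test_interval_coverage_is_nominal(self, rsm):
        # 95% t-intervals under Gaussian noise: pooled coverage over seeded
        # replicates should sit at 95% up to Monte-Carlo error
        design, _ = rsm
        spec = ModelSpec.full_quadratic(design.factor_names)
        truth = np.linspace(-1, 1, len(spec))
        X = spec.model_matrix(design.coded).to_numpy()
        rng = np.random.default_rng(7)
        hits = total = 0
        for _ in range(500):
            y = X @ truth + rng.normal(0, 0.05, len(X))
            ci = ResponseModel(y, design, spec).fit().conf_int(0.95)
            hits += int(((ci["low"] <= truth) & (truth <= ci["high"])).sum())
            total += len(truth)
        assert abs(hits / total - 0.95) < 0.02
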