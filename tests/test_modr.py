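"""Monte-Carlo design spaces: probabilities, maps, optima, branches."""

import numpy as np
import pandas as pd
import pytest
from scipy import stats

import aqbd
from aqbd import (
    Criterion,
    CriterionSet,
    GridSpec,
    McSettings,
    ModelSpec,
    ResponseModel,
    Term,
    branch_regions,
    default_criteria,
    find_optimum,
    modr_map,
    pass_probability,
)
from aqbd.modr import EmptyModrError


def _line_fit(n=200, noise=0.3, seed=0, name="y"):
    """y = x + N(0, noise²) on a dense single-factor design; with large n
    the coefficient uncertainty is negligible and the fitted RMSE ≈ noise."""
    rng = np.random.default_rng(seed)
    x = np.linspace(-1, 1, n)
    design = aqbd.DesignMatrix(
        pd.DataFrame({"x1": x}), [aqbd.FactorSpec("x1", -1, 1)]
    )
    y = x + rng.normal(0, noise, n)
    return ResponseModel(y, design, ModelSpec([Term(("x1",))]), name=name).fit()


@pytest.fixture(scope="module")
def slice_grid():
    # the printed optimum (34.0 %, 1.76 %/min) is a node of this grid
    return GridSpec(
        free={"methanol_pct": (32, 46, 57), "gradient_slope": (1.6, 2.8, 61)},
        fixed={"temperature_C": 54.7},
    )


class TestPassProbability:
    def test_degenerate_mc_equals_deterministic_membership(self, rsm_reduced_fits):
        settings = McSettings(
            seed=1, n_draws=200, coefficient_uncertainty=False,
            observation_noise=False,
        )
        crit = default_criteria()
        inside = {"temperature_C": 54.7, "methanol_pct": 34.0,
                  "gradient_slope": 1.76}
        outside = {"temperature_C": 54.7, "methanol_pct": 46.0,
                   "gradient_slope": 2.8}
        p_in, se_in = pass_probability(rsm_reduced_fits, inside, crit, settings)
        p_out, _ = pass_probability(rsm_reduced_fits, outside, crit, settings)
        assert (p_in, se_in) == (1.0, 0.0)
        assert p_out == 0.0

    def test_matches_normal_cdf_on_linear_toy(self):
        # P(y >= 0 | x0) = Phi(x0 / sigma) with coefficient uncertainty off
        res = _line_fit()
        sigma = res.rmse
        crit = CriterionSet({"y": Criterion("nlt", 0.0)})
        for x0 in (-0.3, 0.0, 0.25):
            settings = McSettings(seed=5, n_draws=100000,
                                  coefficient_uncertainty=False)
            p, se = pass_probability({"y": res}, {"x1": x0}, crit, settings)
            pred = res.predict([[x0]]).mean[0]
            expect = stats.norm.cdf(pred / sigma)
            assert abs(p - expect) <= 3 * max(se, 1e-3)

    def test_same_seed_same_probability(self, rsm_reduced_fits):
        crit = default_criteria()
        pt = {"temperature_C": 54.7, "methanol_pct": 35.0, "gradient_slope": 1.8}
        s = McSettings(seed=42, n_draws=2000)
        p1, _ = pass_probability(rsm_reduced_fits, pt, crit, s)
        p2, _ = pass_probability(rsm_reduced_fits, pt, crit, s)
        assert p1 == p2

    def test_seed_is_mandatory(self):
        with pytest.raises((TypeError, ValueError)):
            McSettings(seed=None)

    def test_settings_validation(self):
        with pytest.raises(ValueError):
            McSettings(seed=1, n_draws=10)
        with pytest.raises(ValueError):
            McSettings(seed=1, threshold=1.5)

    def test_criteria_far_from_predictions_saturate(self):
        res = _line_fit(noise=0.05)
        settings = McSettings(seed=3, n_draws=1000)
        easy = CriterionSet({"y": Criterion("nlt", -50.0)})
        hard = CriterionSet({"y": Criterion("nlt", 50.0)})
        p_easy, _ = pass_probability({"y": res}, {"x1": 0.5}, easy, settings)
        p_hard, _ = pass_probability({"y": res}, {"x1": 0.5}, hard, settings)
        assert p_easy == 1.0
        assert p_hard == 0.0


class TestModrMap:
    def test_threshold_monotonicity(self, rsm_reduced_fits, slice_grid):
        crit = default_criteria()
        lo = modr_map(rsm_reduced_fits, slice_grid, crit,
                      McSettings(seed=9, n_draws=500, threshold=0.90))
        hi = modr_map(rsm_reduced_fits, slice_grid, crit,
                      McSettings(seed=9, n_draws=500, threshold=0.99))
        assert not (hi.in_modr & ~lo.in_modr).any()

    def test_modr_within_deterministic_sweet_spot(self, rsm_reduced_fits, slice_grid):
        crit = default_criteria()
        mm = modr_map(rsm_reduced_fits, slice_grid, crit,
                      McSettings(seed=9, n_draws=500))
        ss = aqbd.sweet_spot_map(rsm_reduced_fits, slice_grid, crit)
        assert not (mm.in_modr & ~ss.table["all_met"]).any()

    def test_same_seed_bitwise_identical_map(self, rsm_reduced_fits, slice_grid):
        crit = default_criteria()
        s = McSettings(seed=17, n_draws=300)
        m1 = modr_map(rsm_reduced_fits, slice_grid, crit, s)
        m2 = modr_map(rsm_reduced_fits, slice_grid, crit, s)
        pd.testing.assert_frame_equal(m1.table, m2.table)

    def test_different_seeds_agree_within_mc_error(self, rsm_reduced_fits):
        crit = default_criteria()
        grid = GridSpec(
            free={"methanol_pct": (33, 38, 6), "gradient_slope": (1.7, 1.9, 5)},
            fixed={"temperature_C": 54.7},
        )
        m1 = modr_map(rsm_reduced_fits, grid, crit, McSettings(seed=1, n_draws=4000))
        m2 = modr_map(rsm_reduced_fits, grid, crit, McSettings(seed=2, n_draws=4000))
        se = np.sqrt(m1.table.mc_se**2 + m2.table.mc_se**2).to_numpy()
        diff = np.abs(m1.table.probability - m2.table.probability).to_numpy()
        assert np.all(diff <= 4 * np.maximum(se, 1e-3))

    def test_mc_error_halves_when_draws_quadruple(self):
        res = _line_fit()
        crit = CriterionSet({"y": Criterion("nlt", 0.0)})
        grid = GridSpec(free={"x1": (-0.5, 0.5, 11)})
        small = modr_map({"y": res}, grid, crit, McSettings(seed=4, n_draws=1000))
        large = modr_map({"y": res}, grid, crit, McSettings(seed=4, n_draws=4000))
        ratio = small.table.mc_se.mean() / large.table.mc_se.mean()
        assert ratio == pytest.approx(2.0, rel=0.25)

    def test_empty_grid_rejected(self, rsm_reduced_fits):
        with pytest.raises(ValueError):
            GridSpec(free={})


class TestFindOptimum:
    def test_half_plane_toy_optimum_and_robust_band(self):
        res = _line_fit(noise=0.05)
        crit = CriterionSet({"y": Criterion("nlt", 0.0)})
        grid = GridSpec(free={"x1": (-1, 1, 41)})
        mm = modr_map({"y": res}, grid, crit, McSettings(seed=6, n_draws=2000))
        opt = find_optimum(mm, {"y": res})
        # margin grows with x, so the optimum sits at the upper edge and the
        # robust interval is the in-MODR band up to that edge
        assert opt.settings["x1"] == pytest.approx(1.0)
        lo, hi = opt.robust["x1"]
        assert hi == pytest.approx(1.0)
        # the 99% boundary sits where Phi(x/sigma) = 0.99, x ≈ 2.33 sigma
        assert lo == pytest.approx(2.33 * res.rmse, abs=0.1)

    def test_study_optimum_in_positive_branch(self, rsm_reduced_fits, slice_grid):
        crit = default_criteria()
        mm = modr_map(rsm_reduced_fits, slice_grid, crit,
                      McSettings(seed=20, n_draws=4000))
        opt = find_optimum(mm, rsm_reduced_fits, branch="positive")
        assert opt.branch == "positive"
        assert 32.0 <= opt.settings["methanol_pct"] <= 35.7
        assert 1.60 <= opt.settings["gradient_slope"] <= 1.84
        lo, hi = opt.robust["methanol_pct"]
        assert lo <= opt.settings["methanol_pct"] <= hi

    def test_negative_branch_optimum_has_negative_prediction(self, rsm_reduced_fits):
        crit = default_criteria()
        grid = GridSpec(
            free={"methanol_pct": (32, 46, 29), "gradient_slope": (1.6, 2.8, 25)},
            fixed={"temperature_C": 47.9},
        )
        mm = modr_map(rsm_reduced_fits, grid, crit, McSettings(seed=21, n_draws=2000))
        opt = find_optimum(mm, rsm_reduced_fits, branch="negative")
        pred = rsm_reduced_fits["R5"].predict(
            pd.DataFrame([opt.settings]), natural=True
        ).mean[0]
        assert pred <= -1.8

    def test_empty_modr_raises_informative_error(self):
        res = _line_fit(noise=0.05)
        crit = CriterionSet({"y": Criterion("nlt", 50.0)})  # unattainable
        grid = GridSpec(free={"x1": (-1, 1, 11)})
        mm = modr_map({"y": res}, grid, crit, McSettings(seed=8, n_draws=500))
        with pytest.raises(EmptyModrError, match="threshold"):
            find_optimum(mm, {"y": res})


class TestBranchRegions:
    def test_constant_positive_model_yields_single_branch(self):
        res = _line_fit(noise=0.05)
        design = res.model.design
        y = 5.0 + 0.1 * design.coded["x1"]
        pos = ResponseModel(y, design, ModelSpec([Term(("x1",))]), name="R5").fit()
        regions = branch_regions(pos, GridSpec(free={"x1": (-1, 1, 21)}))
        assert set(regions["branch"]) == {"positive"}

    def test_study_optima_fall_in_opposite_branches(self, rsm_reduced_fits):
        r5 = rsm_reduced_fits["R5"]
        p1 = r5.predict({"temperature_C": 54.7, "methanol_pct": 34.0,
                         "gradient_slope": 1.76}, natural=True).mean[0]
        p2 = r5.predict({"temperature_C": 47.9, "methanol_pct": 42.0,
                         "gradient_slope": 2.64}, natural=True).mean[0]
        assert p1 > 0 > p2

    def test_partition_is_disjoint_cover(self, rsm_reduced_fits):
        grid = GridSpec(
            free={"methanol_pct": (32, 46, 15), "gradient_slope": (1.6, 2.8, 15)},
            fixed={"temperature_C": 48.5},
        )
        regions = branch_regions(rsm_reduced_fits["R5"], grid)
        assert len(regions) == grid.n_points
        assert regions["branch"].isin(["positive", "negative", "none"]).all()


class TestUncertaintySources:
    def test_jitter_widens_failure_near_boundary(self):
        res = _line_fit(noise=0.05)
        crit = CriterionSet({"y": Criterion("nlt", 0.0)})
        base = McSettings(seed=12, n_draws=8000, coefficient_uncertainty=False,
                          observation_noise=False)
        jit = McSettings(seed=12, n_draws=8000, coefficient_uncertainty=False,
                         observation_noise=False, jitter={"x1": 0.2})
        pt = {"x1": 0.05}
        p_base, _ = pass_probability({"y": res}, pt, crit, base)
        p_jit, _ = pass_probability({"y": res}, pt, crit, jit)
        assert p_base == 1.0
        assert 0.5 < p_jit < 1.0

    def test_per_cma_mode_bounds_joint_mode(self, rsm_reduced_fits):
        crit = default_criteria()
        pt = {"temperature_C": 54.7, "methanol_pct": 35.0, "gradient_slope": 1.8}
        joint = McSettings(seed=13, n_draws=4000, mode="joint")
        percma = McSettings(seed=13, n_draws=4000, mode="per_cma")
        p_joint, _ = pass_probability(rsm_reduced_fits, pt, crit, joint)
        p_percma, _ = pass_probability(rsm_reduced_fits, pt, crit, percma)
        assert p_joint <= p_percma + 1e-9
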