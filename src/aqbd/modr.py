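"""Monte-Carlo design spaces (method operable design regions).

A point on the sweet-spot boundary meets a criterion with only ~50%
probability once model and measurement uncertainty are acknowledged.  The
design space (MODR) therefore keeps only the points where *all* criteria
are met with high probability (default 99%) under a simulation of the
uncertainty sources:

* **coefficient uncertainty** — coefficient vectors drawn from the fitted
  multivariate normal N(b̂, s²(XᵀX)⁻¹), one realisation per draw per model;
* **observation noise** — an independent N(0, s²) replicate-error term per
  draw, so each draw is a new predicted observation;
* optional **setpoint jitter** — per-factor perturbation of the operating
  point, shared across responses within a draw (off by default).

Responses are treated as independently fitted models (no cross-response
covariance).  For a sign-branched response the branch is fixed per grid
point by the *nominal* prediction; a draw that flips to the other side
fails, since a consistent elution order is part of meeting the criterion.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Mapping

import numpy as np
import pandas as pd

from .criteria import SIGN_EPS, Criterion, CriterionSet, GridSpec
from .model import ResponseModelResults

__all__ = [
    "McSettings",
    "ModrMap",
    "OptimalPoint",
    "pass_probability",
    "modr_map",
    "find_optimum",
    "branch_regions",
]


@dataclass(frozen=True)
class McSettings:
    """Monte-Carlo simulation settings.

    ``seed`` is mandatory: an unseeded design-space computation is not
    reproducible and is refused.  ``mode`` is ``"joint"`` (probability that
    every CMA passes within the same draw, the default) or ``"per_cma"``
    (minimum of the per-CMA marginal pass probabilities).
    """

    seed: int
    n_draws: int = 10000
    threshold: float = 0.99
    coefficient_uncertainty: bool = True
    observation_noise: bool = True
    jitter: dict | None = None  # factor name -> half-width (natural units)
    jitter_dist: str = "uniform"  # or "normal" (half-width = 1 sd)
    mode: str = "joint"

    def __post_init__(self):
        if self.seed is None:
            raise ValueError("a seed is required for Monte-Carlo reproducibility")
        if self.n_draws < 100:
            raise ValueError("n_draws must be >= 100")
        if not 0 < self.threshold < 1:
            raise ValueError("threshold must be in (0, 1)")
        if self.mode not in ("joint", "per_cma"):
            raise ValueError(f"unknown mode {self.mode!r}")
        if self.jitter_dist not in ("uniform", "normal"):
            raise ValueError(f"unknown jitter distribution {self.jitter_dist!r}")


def _draw_coefficients(
    res: ResponseModelResults, n_draws: int, rng: np.random.Generator, enabled: bool
) -> np.ndarray:
    """(n_terms × n_draws) coefficient realisations."""
    b = res.params.to_numpy()
    if not enabled:
        return np.tile(b[:, None], (1, n_draws))
    cov = res.cov_params().to_numpy()
    return rng.multivariate_normal(b, cov, size=n_draws, method="cholesky").T


def _predict_draws(
    res: ResponseModelResults,
    natural_pts: pd.DataFrame,
    coefs: np.ndarray,
    rng: np.random.Generator,
    settings: McSettings,
    jitter_delta: np.ndarray | None,
) -> np.ndarray:
    """(n_points × n_draws) simulated new observations of one response."""
    n_draws = coefs.shape[1]
    specs = {f.name: f for f in res.model.design.factors}
    if jitter_delta is None:
        coded = pd.DataFrame(
            {k: specs[k].code(natural_pts[k]) for k in specs}, index=natural_pts.index
        )
        X = res.spec.model_matrix(coded).to_numpy()  # (m, p)
        pred = X @ coefs  # (m, n_draws)
    else:
        # perturbed coordinates per draw: coded[k] has shape (m, n_draws)
        coded = {}
        for j, k in enumerate(specs):
            nat = natural_pts[k].to_numpy()[:, None] + jitter_delta[None, :, j]
            coded[k] = specs[k].code(nat)
        m = len(natural_pts)
        pred = np.zeros((m, n_draws))
        for t, b_t in zip(res.spec.terms, coefs):
            col = np.ones((m, n_draws))
            for f in t.factors:
                col = col * coded[f]
            pred += col * b_t[None, :]
    if settings.observation_noise:
        pred = pred + rng.normal(0.0, res.rmse, size=pred.shape)
    return pred


def _jitter_deltas(
    settings: McSettings, factor_order: list[str], rng: np.random.Generator
) -> np.ndarray | None:
    if not settings.jitter:
        return None
    unknown = set(settings.jitter) - set(factor_order)
    if unknown:
        raise KeyError(f"jitter names unknown factor(s): {sorted(unknown)}")
    delta = np.zeros((settings.n_draws, len(factor_order)))
    for j, name in enumerate(factor_order):
        hw = settings.jitter.get(name, 0.0)
        if hw:
            if settings.jitter_dist == "uniform":
                delta[:, j] = rng.uniform(-hw, hw, settings.n_draws)
            else:
                delta[:, j] = rng.normal(0.0, hw, settings.n_draws)
    return delta


def _pass_matrix(
    results_map: Mapping[str, ResponseModelResults],
    natural_pts: pd.DataFrame,
    criteria: CriterionSet,
    branch: np.ndarray,
    settings: McSettings,
    rng: np.random.Generator,
    coefs: Mapping[str, np.ndarray],
) -> np.ndarray:
    """Per-point pass probability over draws for a block of points."""
    jitter_delta = _jitter_deltas(settings, list(natural_pts.columns), rng)
    m = len(natural_pts)
    if settings.mode == "joint":
        acc = np.ones((m, settings.n_draws), dtype=bool)
    else:
        per_cma = []
    for name, crit in criteria.items():
        pred = _predict_draws(
            results_map[name], natural_pts, coefs[name], rng, settings, jitter_delta
        )
        if crit.direction == "branched":
            pos = crit.passes(pred, "positive")
            neg = crit.passes(pred, "negative")
            ok = np.where((branch == "positive")[:, None], pos, neg)
            ok[branch == "none", :] = False
        else:
            ok = crit.passes(pred)
        if settings.mode == "joint":
            acc &= ok
        else:
            per_cma.append(ok.mean(axis=1))
    if settings.mode == "joint":
        return acc.mean(axis=1)
    return np.min(per_cma, axis=0)


def _nominal_branch(
    results_map: Mapping[str, ResponseModelResults],
    criteria: CriterionSet,
    natural_pts: pd.DataFrame,
) -> np.ndarray:
    branched = [r for r in criteria.branched_responses if r in results_map]
    branch = np.full(len(natural_pts), "positive", dtype=object)
    if branched:
        pred = results_map[branched[0]].predict(natural_pts, natural=True).mean
        branch = np.where(pred >= 0, "positive", "negative").astype(object)
        branch[np.abs(pred) < SIGN_EPS] = "none"
    return branch


def pass_probability(
    results_map: Mapping[str, ResponseModelResults],
    point: Mapping[str, float],
    criteria: CriterionSet,
    settings: McSettings,
    branch: str | None = None,
) -> tuple[float, float]:
    """Probability that all criteria are met at one natural-unit setting.

    Returns ``(probability, mc_standard_error)`` with the binomial standard
    error ``sqrt(p(1−p)/n_draws)``.  ``branch`` fixes the sign branch for
    branched responses; by default it is taken from the nominal prediction.
    """
    _check_models(results_map, criteria)
    pts = pd.DataFrame({k: [float(v)] for k, v in point.items()})
    rng = np.random.default_rng(settings.seed)
    coefs = {
        name: _draw_coefficients(
            results_map[name], settings.n_draws, rng, settings.coefficient_uncertainty
        )
        for name in criteria
    }
    if branch is None:
        br = _nominal_branch(results_map, criteria, pts)
    else:
        br = np.array([branch], dtype=object)
    p = float(_pass_matrix(results_map, pts, criteria, br, settings, rng, coefs)[0])
    se = float(np.sqrt(p * (1 - p) / settings.n_draws))
    return p, se


class ModrMap:
    """Estimated pass probability per grid point with the MODR flag.

    ``table`` columns: natural-unit factor columns, ``probability``,
    ``mc_se``, ``in_modr`` (probability ≥ threshold), ``branch``.
    """

    def __init__(
        self,
        table: pd.DataFrame,
        grid: GridSpec,
        criteria: CriterionSet,
        settings: McSettings,
    ):
        self.table = table
        self.grid = grid
        self.criteria = criteria
        self.settings = settings

    @property
    def in_modr(self) -> pd.Series:
        return self.table["in_modr"]

    def to_csv(self, path) -> None:
        self.table.to_csv(path, index=False)

    def __repr__(self) -> str:  # pragma: no cover - cosmetic
        return (
            f"<ModrMap {len(self.table)} points, "
            f"{self.table['in_modr'].mean():.1%} in MODR at "
            f"{self.settings.threshold:.0%}>"
        )


def _check_models(results_map, criteria):
    missing = set(criteria) - set(results_map)
    if missing:
        raise KeyError(f"no fitted model for criterion response(s): {sorted(missing)}")
    names = None
    for res in results_map.values():
        fn = tuple(res.model.design.factor_names)
        if names is None:
            names = fn
        elif fn != names:
            raise ValueError("models do not share a common factor space")


def modr_map(
    results_map: Mapping[str, ResponseModelResults],
    grid: GridSpec,
    criteria: CriterionSet,
    settings: McSettings,
    *,
    chunk_size: int = 512,
) -> ModrMap:
    """Monte-Carlo pass probability over a grid and the MODR flag.

    Coefficient realisations are drawn once per response and shared across
    grid points (points are evaluated under a common model-uncertainty
    ensemble); observation noise is independent per point and draw.  The
    grid is processed in chunks to bound memory.
    """
    _check_models(results_map, criteria)
    grid.validate_for(next(iter(results_map.values())).model.design.factor_names)
    if grid.n_points == 0:
        raise ValueError("empty grid")
    pts = grid.points()
    rng = np.random.default_rng(settings.seed)
    coefs = {
        name: _draw_coefficients(
            results_map[name], settings.n_draws, rng, settings.coefficient_uncertainty
        )
        for name in criteria
    }
    branch = _nominal_branch(results_map, criteria, pts)
    prob = np.empty(len(pts))
    for start in range(0, len(pts), chunk_size):
        sl = slice(start, start + chunk_size)
        prob[sl] = _pass_matrix(
            results_map, pts.iloc[sl], criteria, branch[sl], settings, rng, coefs
        )
    table = pts.copy()
    table["probability"] = prob
    table["mc_se"] = np.sqrt(prob * (1 - prob) / settings.n_draws)
    table["in_modr"] = prob >= settings.threshold
    table["branch"] = branch
    return ModrMap(table, grid, criteria, settings)


@dataclass
class OptimalPoint:
    """A recommended operating point with its per-factor robust ranges.

    ``robust`` maps factor name → (low, high): the maximal contiguous 1-D
    interval through the setpoint (all other factors clamped at the
    setpoint) that stays inside the MODR, mirroring the per-factor
    "robust from … to …" reporting convention.  Clamped grid factors get a
    degenerate interval at their fixed value.
    """

    settings: dict[str, float]
    probability: float
    mc_se: float
    robust: dict[str, tuple[float, float]]
    branch: str

    def to_json_obj(self) -> dict:
        return {
            "settings": {k: float(v) for k, v in self.settings.items()},
            "probability": float(self.probability),
            "mc_se": float(self.mc_se),
            "robust": {k: [float(a), float(b)] for k, (a, b) in self.robust.items()},
            "branch": self.branch,
        }


class EmptyModrError(RuntimeError):
    """No grid point reaches the probability threshold in the requested
    branch; widen the factor ranges or lower the threshold."""


def find_optimum(
    modr: ModrMap,
    results_map: Mapping[str, ResponseModelResults],
    branch: str = "positive",
) -> OptimalPoint:
    """Best operating point of a MODR branch and its robust ranges.

    The setpoint maximises the estimated pass probability; exact ties
    (common once the probability saturates at 1 over a plateau) are broken
    by maximising the minimum *standardised* criterion margin of the
    nominal predictions — each margin divided by the prediction standard
    error for a new observation, so margins are comparable across
    responses with different scales.  Robust ranges are axis-aligned
    slices through the setpoint along each free grid axis.
    """
    t = modr.table
    cand = t[(t["branch"] == branch) & t["in_modr"]]
    if cand.empty:
        raise EmptyModrError(
            f"MODR is empty in the {branch} branch at threshold "
            f"{modr.settings.threshold:.0%}; consider revising factor ranges "
            f"or the probability threshold"
        )
    best_p = cand["probability"].max()
    tied = cand[cand["probability"] == best_p]
    factor_cols = modr.grid.factor_names
    if len(tied) > 1:
        pts = tied[factor_cols]
        margins = np.full(len(tied), np.inf)
        for name, crit in modr.criteria.items():
            pr = results_map[name].predict(pts, natural=True)
            margins = np.minimum(margins, crit.margin(pr.mean, branch) / pr.se_obs)
        row = tied.iloc[int(np.argmax(margins))]
    else:
        row = tied.iloc[0]
    setting = {k: float(row[k]) for k in factor_cols}

    robust: dict[str, tuple[float, float]] = {}
    free = list(modr.grid.free)
    for name in free:
        others = [f for f in free if f != name]
        line = t
        for o in others:
            line = line[np.isclose(line[o], setting[o])]
        line = line.sort_values(name).reset_index(drop=True)
        ok = (line["in_modr"] & (line["branch"] == branch)).to_numpy()
        i0 = int(np.argmin(np.abs(line[name].to_numpy() - setting[name])))
        lo = hi = i0
        while lo > 0 and ok[lo - 1]:
            lo -= 1
        while hi < len(ok) - 1 and ok[hi + 1]:
            hi += 1
        robust[name] = (float(line[name].iloc[lo]), float(line[name].iloc[hi]))
    for name, val in modr.grid.fixed.items():
        robust[name] = (float(val), float(val))
    return OptimalPoint(
        settings=setting,
        probability=float(row["probability"]),
        mc_se=float(row["mc_se"]),
        robust=robust,
        branch=branch,
    )


def branch_regions(
    branched_results: ResponseModelResults, grid: GridSpec
) -> pd.DataFrame:
    """Partition a grid by the sign of the nominal branched-response
    prediction: ``"positive"``, ``"negative"`` or ``"none"`` (|pred| below
    numerical epsilon).  The regions are disjoint and cover the grid."""
    pts = grid.points()
    pred = branched_results.predict(pts, natural=True).mean
    out = pts.copy()
    branch = np.where(pred >= 0, "positive", "negative").astype(object)
    branch[np.abs(pred) < SIGN_EPS] = "none"
    out["prediction"] = pred
    out["branch"] = branch
    return out
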