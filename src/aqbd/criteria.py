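"""Acceptance criteria for method attributes and sweet-spot analysis.

Each critical method attribute (CMA) carries an acceptance criterion:
"not more than" (NMT) for the tailing factor, "not less than" (NLT) for
resolutions, and a sign-*branched* rule for a resolution whose peak pair can
swap elution order across the factor domain — positive branch: value ≥ a
positive threshold; negative branch: value ≤ the mirrored negative
threshold.  Boundary equality counts as a pass ("not less than 1.8"
includes 1.8).

The *sweet spot* is the region of factor space where the nominal model
predictions of every CMA meet their criteria simultaneously, obtained by
overlaying per-CMA pass/fail maps on a grid.
"""

from __future__ import annotations

import itertools
from dataclasses import dataclass, field
from typing import Mapping, Sequence

import numpy as np
import pandas as pd

from .model import ResponseModelResults

__all__ = [
    "Criterion",
    "CriterionSet",
    "GridSpec",
    "SweetSpotMap",
    "evaluate_criteria",
    "sweet_spot_map",
    "contour_slices",
    "default_criteria",
]

#: |nominal prediction| below this cannot be assigned a sign branch and
#: fails a branched criterion in both branches.
SIGN_EPS = 1e-12


@dataclass(frozen=True)
class Criterion:
    """Acceptance rule for one response.

    ``direction`` is ``"nmt"`` (pass iff value ≤ threshold), ``"nlt"``
    (pass iff value ≥ threshold) or ``"branched"`` (pass iff value ≥
    ``threshold`` in the positive branch, value ≤ ``neg_threshold`` in the
    negative branch).
    """

    direction: str
    threshold: float
    neg_threshold: float | None = None

    def __post_init__(self):
        if self.direction not in ("nmt", "nlt", "branched"):
            raise ValueError(f"unknown direction {self.direction!r}")
        if not np.isfinite(self.threshold):
            raise ValueError("threshold must be finite")
        if self.direction == "branched":
            if self.neg_threshold is None or not np.isfinite(self.neg_threshold):
                raise ValueError("branched criterion needs both thresholds")

    def passes(self, value, branch: str = "positive"):
        """Vectorised pass flags; equality counts as a pass."""
        v = np.asarray(value, dtype=float)
        if self.direction == "nmt":
            return v <= self.threshold
        if self.direction == "nlt":
            return v >= self.threshold
        if branch == "positive":
            return v >= self.threshold
        if branch == "negative":
            return v <= self.neg_threshold
        raise ValueError(f"unknown branch {branch!r}")

    def margin(self, value, branch: str = "positive"):
        """Signed distance to the threshold (positive = inside)."""
        v = np.asarray(value, dtype=float)
        if self.direction == "nmt":
            return self.threshold - v
        if self.direction == "nlt":
            return v - self.threshold
        return v - self.threshold if branch == "positive" else self.neg_threshold - v


class CriterionSet(dict):
    """Mapping response name → :class:`Criterion`."""

    @property
    def branched_responses(self) -> list[str]:
        return [k for k, c in self.items() if c.direction == "branched"]


def default_criteria(
    *,
    tailing_max: float = 3.2,
    resolution_min: float = 1.8,
    resolutions: Sequence[str] = ("R1", "R2", "R3", "R4"),
    branched: str | None = "R5",
) -> CriterionSet:
    """The stock criterion set of an impurity method: tailing factor NMT
    ``tailing_max``, every critical resolution NLT ``resolution_min`` and,
    when a sign-flipping resolution is named, the dual-branch rule
    (≥ ``resolution_min`` or ≤ −``resolution_min``)."""
    crit = CriterionSet({"T": Criterion("nmt", tailing_max)})
    for r in resolutions:
        crit[r] = Criterion("nlt", resolution_min)
    if branched:
        crit[branched] = Criterion("branched", resolution_min, -resolution_min)
    return crit


def evaluate_criteria(
    values: Mapping[str, float], criteria: CriterionSet, branch: str = "positive"
) -> dict[str, bool]:
    """Per-CMA pass flags for a single set of measured/predicted values."""
    missing = set(criteria) - set(values)
    if missing:
        raise KeyError(f"missing CMA value(s): {sorted(missing)}")
    return {k: bool(c.passes(values[k], branch)) for k, c in criteria.items()}


# ---------------------------------------------------------------------
# grids
# ---------------------------------------------------------------------

@dataclass
class GridSpec:
    """A rectangular evaluation grid over the model's factor space.

    ``free`` maps factor name → (low, high, n_points) in *natural* units;
    ``fixed`` clamps the remaining factors.  Together they must cover the
    model's factor set exactly.  The default slice used for plotting is
    101 × 101 over two free factors with the third clamped.
    """

    free: dict[str, tuple[float, float, int]]
    fixed: dict[str, float] = field(default_factory=dict)

    def __post_init__(self):
        if not self.free:
            raise ValueError("grid needs at least one free axis")
        for name, (lo, hi, n) in self.free.items():
            if n < 2:
                raise ValueError(f"free axis {name!r} needs >= 2 points")
            if not lo < hi:
                raise ValueError(f"free axis {name!r}: low must be < high")
        overlap = set(self.free) & set(self.fixed)
        if overlap:
            raise ValueError(f"factor(s) both free and fixed: {sorted(overlap)}")

    @property
    def factor_names(self) -> list[str]:
        return list(self.free) + list(self.fixed)

    @property
    def shape(self) -> tuple[int, ...]:
        return tuple(n for _, _, n in self.free.values())

    @property
    def n_points(self) -> int:
        return int(np.prod(self.shape))

    def axes(self) -> dict[str, np.ndarray]:
        return {
            name: np.linspace(lo, hi, n) for name, (lo, hi, n) in self.free.items()
        }

    def points(self) -> pd.DataFrame:
        """All grid points in natural units, free axes in row-major order
        (first free axis varies slowest)."""
        axes = self.axes()
        prod = list(itertools.product(*axes.values()))
        df = pd.DataFrame(prod, columns=list(axes))
        for name, val in self.fixed.items():
            df[name] = val
        return df

    def validate_for(self, factor_names: Sequence[str]) -> None:
        if set(self.factor_names) != set(factor_names):
            raise ValueError(
                f"grid covers {sorted(self.factor_names)} but models use "
                f"{sorted(factor_names)}"
            )


# ---------------------------------------------------------------------
# sweet spot
# ---------------------------------------------------------------------

class SweetSpotMap:
    """Per-grid-point CMA predictions, pass flags and overlay classes.

    ``table`` holds one row per grid point: the natural-unit factor columns,
    ``pred_<cma>`` and ``pass_<cma>`` per response, ``branch`` (the sign
    branch assigned from the nominal branched-response prediction),
    ``n_met`` and ``all_met``.
    """

    def __init__(self, table: pd.DataFrame, grid: GridSpec, criteria: CriterionSet):
        self.table = table
        self.grid = grid
        self.criteria = criteria

    @property
    def n_criteria(self) -> int:
        return len(self.criteria)

    @property
    def all_met(self) -> pd.Series:
        return self.table["all_met"]

    def to_csv(self, path) -> None:
        self.table.to_csv(path, index=False)

    def __repr__(self) -> str:  # pragma: no cover - cosmetic
        frac = self.table["all_met"].mean()
        return f"<SweetSpotMap {len(self.table)} points, {frac:.1%} all-met>"


def _check_shared_factors(results_map: Mapping[str, ResponseModelResults]):
    names = None
    for res in results_map.values():
        fn = tuple(res.model.design.factor_names)
        if names is None:
            names = fn
        elif fn != names:
            raise ValueError("models do not share a common factor space")
    return list(names)


def sweet_spot_map(
    results_map: Mapping[str, ResponseModelResults],
    grid: GridSpec,
    criteria: CriterionSet,
) -> SweetSpotMap:
    """Overlay nominal model predictions against all criteria on a grid.

    Branched responses are evaluated against the branch given by the sign
    of their own nominal prediction at each point; a prediction of exactly
    zero fails both branches.
    """
    factor_names = _check_shared_factors(results_map)
    grid.validate_for(factor_names)
    pts = grid.points()
    table = pts.copy()
    branch = np.full(len(pts), "positive", dtype=object)
    branched = [r for r in criteria.branched_responses if r in results_map]
    if branched:
        # branch follows the first branched response's nominal sign
        pred0 = results_map[branched[0]].predict(pts, natural=True).mean
        branch = np.where(pred0 >= 0, "positive", "negative").astype(object)
        zero = np.abs(pred0) < SIGN_EPS
    else:
        zero = np.zeros(len(pts), dtype=bool)

    n_met = np.zeros(len(pts), dtype=int)
    for name, crit in criteria.items():
        if name not in results_map:
            raise KeyError(f"no fitted model for criterion response {name!r}")
        pred = results_map[name].predict(pts, natural=True).mean
        if crit.direction == "branched":
            ok = np.where(
                branch == "positive",
                crit.passes(pred, "positive"),
                crit.passes(pred, "negative"),
            )
            ok = ok & ~zero
        else:
            ok = crit.passes(pred)
        table[f"pred_{name}"] = pred
        table[f"pass_{name}"] = ok
        n_met += ok.astype(int)
    table["branch"] = branch
    table["n_met"] = n_met
    table["all_met"] = n_met == len(criteria)
    return SweetSpotMap(table, grid, criteria)


def contour_slices(sweet_map: SweetSpotMap) -> pd.DataFrame:
    """Per-point overlay class labels for rendering a 2-D sweet-spot plot.

    Classes mirror the usual green / light-blue rendering: ``all_met``,
    ``one_failed`` and ``multi_failed``.  Requires a 2-D grid.
    """
    if len(sweet_map.grid.free) != 2:
        raise ValueError("contour slices require a 2-D grid")
    t = sweet_map.table
    n_failed = sweet_map.n_criteria - t["n_met"]
    labels = np.where(
        n_failed == 0, "all_met", np.where(n_failed == 1, "one_failed", "multi_failed")
    )
    out = t[list(sweet_map.grid.free)].copy()
    out["class"] = labels
    return out
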