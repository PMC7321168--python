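"""Bundled study datasets and a seeded synthetic response generator.

The package ships the two printed experimental tables of the ropinirole
impurity-method study verbatim — the 19-run, 6-factor resolution-IV
screening design and the 17-run, 3-factor face-centred central composite
design, each with the six measured attributes (tailing factor T and
resolutions R1–R5) — plus the spiked-recovery records used in accuracy
validation.  A handful of response entries are exactly 0.10, a
"no measurable separation" floor rather than a true measurement;
:func:`floor_mask` flags them, and they are otherwise kept as numeric
values.

The synthetic generator emulates what the analysis assumes the instrument
produces: a low-order polynomial surface in the coded factors plus
homoscedastic Gaussian replicate noise, with default truth surfaces taken
from full-model fits to the bundled tables so that simulations inherit the
study's structure — including the response (R5) whose sign flips across
the factor domain as two peaks swap elution order.
"""

from __future__ import annotations

from dataclasses import dataclass
from importlib import resources
from typing import Mapping

import numpy as np
import pandas as pd

from .design import DesignMatrix, FactorSpec
from .model import ResponseModel
from .terms import ModelSpec

__all__ = [
    "SCREENING_FACTORS",
    "RSM_FACTORS",
    "RESPONSES",
    "FLOOR_VALUE",
    "load_screening",
    "load_rsm",
    "load_recovery",
    "study_fixture",
    "floor_mask",
    "SyntheticTruth",
    "simulate_responses",
]

#: the six critical method attributes, in reporting order
RESPONSES = ["T", "R1", "R2", "R3", "R4", "R5"]

#: response entries equal to this value are a detection floor, not a
#: measurement (no measurable separation between the peak pair)
FLOOR_VALUE = 0.10

SCREENING_FACTORS = (
    FactorSpec("buffer_mM", 10, 40, "mM"),
    FactorSpec("buffer_pH", 2.0, 3.0, "pH"),
    FactorSpec("temperature_C", 35, 55, "°C"),
    FactorSpec("methanol_pct", 20, 40, "%"),
    FactorSpec("initial_b_pct", 5, 10, "%"),
    FactorSpec("gradient_slope", 0.8, 2.4, "%/min"),
)

RSM_FACTORS = (
    FactorSpec("temperature_C", 40, 57, "°C"),
    FactorSpec("methanol_pct", 32, 46, "%"),
    FactorSpec("gradient_slope", 1.6, 2.8, "%/min"),
)


def _read_dataset(name: str) -> pd.DataFrame:
    with resources.files("aqbd.datasets").joinpath(name).open() as fh:
        return pd.read_csv(fh)


def _load_table(name, factors):
    df = _read_dataset(name).set_index("run_id")
    design = DesignMatrix.from_natural(df[[f.name for f in factors]], factors)
    return design, df[RESPONSES].copy()


def load_screening() -> tuple[DesignMatrix, pd.DataFrame]:
    """The 19-run fractional-factorial screening study (16 + 3 centre)."""
    return _load_table("screening.csv", SCREENING_FACTORS)


def load_rsm() -> tuple[DesignMatrix, pd.DataFrame]:
    """The 17-run face-centred central composite study (8 + 6 + 3 centre)."""
    return _load_table("rsm.csv", RSM_FACTORS)


def load_recovery() -> pd.DataFrame:
    """Spiked-recovery records: impurity, level, added/found concentration
    (µg/mL) and the recovery percentage as originally reported."""
    return _read_dataset("recovery.csv")


def study_fixture(table_id: str):
    """Bundled study data by id: ``"screening"``, ``"rsm"`` or ``"recovery"``."""
    loaders = {"screening": load_screening, "rsm": load_rsm, "recovery": load_recovery}
    try:
        return loaders[table_id]()
    except KeyError:
        raise KeyError(
            f"unknown table id {table_id!r}; expected one of {sorted(loaders)}"
        ) from None


def floor_mask(responses: pd.DataFrame) -> pd.DataFrame:
    """Boolean mask of entries sitting at the no-separation floor value."""
    return responses == FLOOR_VALUE


# ---------------------------------------------------------------------
# synthetic responses
# ---------------------------------------------------------------------

@dataclass
class SyntheticTruth:
    """A known multi-response polynomial truth over a factor space.

    ``coefficients`` maps response name → Series of true coefficients
    indexed by term name (matching ``spec``); ``noise_sd`` maps response
    name → replicate standard deviation (≥ 0).
    """

    factors: tuple[FactorSpec, ...]
    spec: ModelSpec
    coefficients: Mapping[str, pd.Series]
    noise_sd: Mapping[str, float]

    def __post_init__(self):
        for name, sd in self.noise_sd.items():
            if sd < 0:
                raise ValueError(f"noise sd for {name!r} must be >= 0")
        for name, coef in self.coefficients.items():
            if list(coef.index) != self.spec.term_names:
                raise ValueError(
                    f"coefficients for {name!r} do not match the truth spec terms"
                )

    @classmethod
    def from_fits(cls, results_map) -> "SyntheticTruth":
        """Truth = the fitted surfaces; noise sd = each fit's RMSE."""
        first = next(iter(results_map.values()))
        return cls(
            factors=first.model.design.factors,
            spec=first.spec,
            coefficients={k: r.params.copy() for k, r in results_map.items()},
            noise_sd={k: r.rmse for k, r in results_map.items()},
        )

    @classmethod
    def from_fixture(cls, table_id: str = "rsm", *, center_noise: bool = True):
        """Truth surfaces from full-model fits to a bundled study table.

        With ``center_noise`` (default) the per-response noise sd is the
        pooled centre-replicate standard deviation of that table — the
        study's own estimate of replicate error — instead of each fit's
        RMSE.
        """
        design, responses = study_fixture(table_id)
        if table_id == "screening":
            spec = ModelSpec.linear(design.factor_names)
        else:
            spec = ModelSpec.full_quadratic(design.factor_names)
        fits = {
            name: ResponseModel(responses[name], design, spec, name=name).fit()
            for name in responses.columns
        }
        truth = cls.from_fits(fits)
        if center_noise:
            center = responses.loc[design.is_center]
            truth = cls(
                factors=truth.factors,
                spec=truth.spec,
                coefficients=truth.coefficients,
                noise_sd={k: float(center[k].std(ddof=1)) for k in responses},
            )
        return truth


def simulate_responses(
    design: DesignMatrix, truth: SyntheticTruth, seed: int
) -> pd.DataFrame:
    """Draw one response table for a design from a known truth.

    Response = truth polynomial at the coded settings + independent
    N(0, sd²) noise per run; identical seeds reproduce identical tables.
    The design must be codable under the truth's factor specs; a design
    with generic coded factor names (``x1`` …) of matching dimension is
    aligned to the truth's factors positionally.
    """
    names = [f.name for f in truth.factors]
    coded = design.coded
    if list(coded.columns) != names:
        if set(names) <= set(coded.columns):
            coded = coded[names]
        elif len(coded.columns) == len(names):
            coded = coded.set_axis(names, axis=1)
        else:
            raise ValueError(
                f"design factors {list(coded.columns)} cannot be matched to "
                f"truth factors {names}"
            )
    X = truth.spec.model_matrix(coded).to_numpy()
    rng = np.random.default_rng(seed)
    out = {}
    for name, coef in truth.coefficients.items():
        mean = X @ coef.to_numpy()
        sd = truth.noise_sd[name]
        out[name] = mean + (rng.normal(0.0, sd, len(mean)) if sd > 0 else 0.0)
    return pd.DataFrame(out, index=design.coded.index)
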