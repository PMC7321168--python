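"""Model validation statistics and method-validation summaries.

Functional access to the diagnostics carried by
:class:`~aqbd.model.ResponseModelResults` (R², adjusted R², PRESS/Q²,
regression ANOVA, lack-of-fit) plus the small summary statistics used in
method validation: percent relative standard deviation of replicate
injections and percent recovery of spiked impurities.

Q² here is the leave-one-out predicted coefficient of determination,
Q² = 1 − PRESS/SST with mean-corrected SST, and is deliberately not floored
at zero: a model that predicts held-out runs worse than the grand mean earns
a negative Q².
"""

from __future__ import annotations

import numpy as np
import pandas as pd

from .model import LackOfFit, ResponseModelResults

__all__ = [
    "r2_stats",
    "q2_press",
    "anova_regression",
    "lack_of_fit",
    "rsd",
    "percent_recovery",
    "diagnostics_table",
]


def r2_stats(results: ResponseModelResults) -> tuple[float, float]:
    """(R², adjusted R²) of a fit; requires non-zero response variance."""
    if results.ss_total <= 0:
        raise ValueError("response has zero total variance; R² is undefined")
    return results.rsquared, results.rsquared_adj


def q2_press(results: ResponseModelResults) -> tuple[float, float]:
    """(Q², PRESS) via the leverage shortcut for leave-one-out residuals."""
    return results.q2, results.press


def anova_regression(results: ResponseModelResults) -> float:
    """Overall regression F-test p-value."""
    return results.f_pvalue


def lack_of_fit(results: ResponseModelResults) -> LackOfFit:
    """Lack-of-fit F-test using replicate groups of the underlying design."""
    return results.lack_of_fit()


def rsd(values) -> float:
    """Percent relative standard deviation, 100·s/mean (sample sd, ddof=1)."""
    v = np.asarray(values, dtype=float)
    if v.size < 2:
        raise ValueError("RSD needs at least two replicates")
    m = v.mean()
    if m == 0:
        raise ValueError("RSD is undefined for zero mean")
    return float(100.0 * v.std(ddof=1) / m)


def percent_recovery(added: float, found: float) -> float:
    """Percent recovery of a spiked amount, 100·found/added to two decimals."""
    if added <= 0:
        raise ValueError("added concentration must be positive")
    return round(100.0 * found / added, 2)


def diagnostics_table(results_map: dict[str, ResponseModelResults]) -> pd.DataFrame:
    """One diagnostics row per response (R², R² adj., Q², ANOVA p, LoF p)."""
    rows = []
    for name, res in results_map.items():
        d = res.diagnostics()
        rows.append(
            {
                "response": name,
                "r2": d["r2"],
                "r2_adj": d["r2_adj"],
                "q2": d["q2"],
                "p_regression": d["anova_regression_p"],
                "p_lack_of_fit": d["lack_of_fit_p"],
            }
        )
    return pd.DataFrame(rows).set_index("response")
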