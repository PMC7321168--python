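"""Coded-factor multiple linear regression for design-of-experiments studies.

:class:`ResponseModel` pairs one measured response column (a critical method
attribute such as a tailing factor or a chromatographic resolution) with a
:class:`~aqbd.design.DesignMatrix` and a polynomial
:class:`~aqbd.terms.ModelSpec`; :meth:`ResponseModel.fit` performs ordinary
least squares on the coded model matrix and returns a
:class:`ResponseModelResults` carrying the estimates, their covariance, the
standard fit diagnostics (R², adjusted R², PRESS-based Q², regression ANOVA,
lack-of-fit against replicate pure error) and prediction with uncertainty.

Backward elimination of non-significant terms is exposed as a Results method
(:meth:`ResponseModelResults.backward_eliminate`) so a reduced model carries
its provenance: removal order and p-values are recorded on the reduced
results object.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
import statsmodels.api as sm
from scipy import stats

from .design import DesignMatrix
from .terms import ModelSpec, Term

__all__ = ["ResponseModel", "ResponseModelResults", "PredictionResult"]


class ResponseModel:
    """OLS model of one response over the coded factors of a design.

    Parameters
    ----------
    endog
        Measured response, one value per design run (Series or array).
    design
        The coded experimental design.
    spec
        Polynomial term list; defaults to the first-order screening model.
    name
        Response name used in reports.
    """

    def __init__(
        self,
        endog,
        design: DesignMatrix,
        spec: ModelSpec | None = None,
        name: str = "y",
    ):
        if spec is None:
            spec = ModelSpec.linear(design.factor_names)
        y = np.asarray(endog, dtype=float)
        if y.ndim != 1 or len(y) != design.n_runs:
            raise ValueError(
                f"response length {y.shape} does not match {design.n_runs} runs"
            )
        self.endog = pd.Series(y, index=design.coded.index, name=name)
        self.design = design
        self.spec = spec
        self.name = name
        self.exog = spec.model_matrix(design.coded)

    @classmethod
    def from_dataframe(
        cls,
        data: pd.DataFrame,
        response: str,
        design: DesignMatrix,
        spec: ModelSpec | None = None,
    ) -> "ResponseModel":
        return cls(data[response], design, spec, name=response)

    def fit(self) -> "ResponseModelResults":
        X = self.exog.to_numpy()
        n, p = X.shape
        if n < p:
            raise ValueError(
                f"model not estimable: {n} runs for {p} terms (need runs >= terms)"
            )
        rank = np.linalg.matrix_rank(X)
        if rank < p:
            bad = _inestimable_terms(self.exog)
            raise ValueError(
                f"model matrix is rank deficient (rank {rank} < {p} terms); "
                f"inestimable term(s): {bad} — the design does not support them"
            )
        ols = sm.OLS(self.endog.to_numpy(), X).fit()
        return ResponseModelResults(self, ols)


def _inestimable_terms(exog: pd.DataFrame) -> list[str]:
    """Greedily identify columns that are linearly dependent on earlier ones."""
    bad, kept = [], []
    for name in exog.columns:
        trial = kept + [name]
        if np.linalg.matrix_rank(exog[trial].to_numpy()) < len(trial):
            bad.append(name)
        else:
            kept.append(name)
    return bad


@dataclass
class PredictionResult:
    """Predictions with uncertainty at a set of factor settings.

    ``se_mean`` is the standard error of the fitted mean surface;
    ``se_obs`` adds the replicate noise, i.e. the standard error for a new
    single observation.  ``extrapolated`` flags points outside the coded
    [−1, +1] cube (allowed, but the model is unsupported there).
    """

    mean: np.ndarray
    se_mean: np.ndarray
    se_obs: np.ndarray
    extrapolated: np.ndarray

    def interval(self, level: float, df: int, kind: str = "obs"):
        se = self.se_obs if kind == "obs" else self.se_mean
        t = stats.t.ppf(0.5 * (1 + level), df)
        return self.mean - t * se, self.mean + t * se


class ResponseModelResults:
    """Fit results: coefficients, covariance, residual structure, diagnostics.

    Thin, immutable wrapper over a statsmodels OLS fit, with the
    DoE-specific quantities (leverage-based PRESS/Q², replicate lack-of-fit,
    hierarchy-aware backward elimination, coded-point prediction) layered on
    top.
    """

    def __init__(self, model: ResponseModel, ols, elimination_log=None):
        self.model = model
        self._ols = ols
        self.spec = model.spec
        self.elimination_log = list(elimination_log or [])

        X = model.exog.to_numpy()
        self._X = X
        self._xtx_inv = np.linalg.inv(X.T @ X)
        self.nobs = X.shape[0]
        self.df_model = X.shape[1] - 1
        self.df_resid = X.shape[0] - X.shape[1]
        self.params = pd.Series(ols.params, index=model.exog.columns)
        self.resid = pd.Series(ols.resid, index=model.exog.index)

    # -- basic quantities ---------------------------------------------
    @property
    def rmse(self) -> float:
        """Residual standard deviation, s = sqrt(SSE / df_resid); zero for
        a saturated (interpolating) fit."""
        return float(np.sqrt(self.scale))

    @property
    def scale(self) -> float:
        if self.df_resid == 0:
            return 0.0
        return float(self._ols.scale)

    def cov_params(self) -> pd.DataFrame:
        cov = self.scale * self._xtx_inv
        return pd.DataFrame(cov, index=self.params.index, columns=self.params.index)

    @property
    def bse(self) -> pd.Series:
        return pd.Series(np.sqrt(np.diag(self.cov_params())), index=self.params.index)

    @property
    def tvalues(self) -> pd.Series:
        return self.params / self.bse

    @property
    def pvalues(self) -> pd.Series:
        return pd.Series(
            2 * stats.t.sf(np.abs(self.tvalues), self.df_resid),
            index=self.params.index,
        )

    @property
    def leverage(self) -> pd.Series:
        """Diagonal of the hat matrix H = X (XᵀX)⁻¹ Xᵀ."""
        h = np.einsum("ij,jk,ik->i", self._X, self._xtx_inv, self._X)
        return pd.Series(h, index=self.model.exog.index)

    @property
    def fittedvalues(self) -> pd.Series:
        return self.model.endog - self.resid

    # -- goodness of fit ----------------------------------------------
    @property
    def ss_total(self) -> float:
        y = self.model.endog.to_numpy()
        return float(((y - y.mean()) ** 2).sum())

    @property
    def ss_resid(self) -> float:
        return float((self.resid.to_numpy() ** 2).sum())

    @property
    def rsquared(self) -> float:
        return 1.0 - self.ss_resid / self.ss_total

    @property
    def rsquared_adj(self) -> float:
        return 1.0 - (self.ss_resid / self.df_resid) / (self.ss_total / (self.nobs - 1))

    @property
    def press(self) -> float:
        """Prediction error sum of squares via the leverage shortcut:
        PRESS = Σ (eᵢ / (1 − hᵢ))², identical to refitting with each run
        left out in turn."""
        h = self.leverage.to_numpy()
        if np.any(h >= 1 - 1e-12):
            raise ValueError(
                "a run with leverage 1 is interpolated exactly; "
                "PRESS/Q² are undefined for this model"
            )
        e = self.resid.to_numpy()
        return float(((e / (1.0 - h)) ** 2).sum())

    @property
    def q2(self) -> float:
        """Predicted R²: Q² = 1 − PRESS/SST (may be negative)."""
        return 1.0 - self.press / self.ss_total

    @property
    def f_pvalue(self) -> float:
        """Regression ANOVA p-value (overall F test against intercept-only)."""
        ssr = self.ss_total - self.ss_resid
        if self.ss_resid <= 0:
            return 0.0  # saturated: explained everything
        f = (ssr / self.df_model) / (self.ss_resid / self.df_resid)
        return float(stats.f.sf(f, self.df_model, self.df_resid))

    def conf_int(self, level: float = 0.95) -> pd.DataFrame:
        """Per-term confidence intervals: estimate ± t(df, (1+level)/2)·se."""
        if not 0 < level < 1:
            raise ValueError("confidence level must be in (0, 1)")
        t = stats.t.ppf(0.5 * (1 + level), self.df_resid)
        half = t * self.bse
        return pd.DataFrame(
            {"estimate": self.params, "half_width": half,
             "low": self.params - half, "high": self.params + half}
        )

    # -- prediction ----------------------------------------------------
    def _points_to_exog(self, points) -> tuple[pd.DataFrame, np.ndarray]:
        names = self.model.design.factor_names
        if isinstance(points, pd.DataFrame):
            coded = points[names]
        elif isinstance(points, Mapping):
            coded = pd.DataFrame({k: np.atleast_1d(v) for k, v in points.items()})[names]
        else:
            arr = np.atleast_2d(np.asarray(points, dtype=float))
            if arr.shape[1] != len(names):
                raise ValueError(
                    f"points have {arr.shape[1]} coordinates, design has "
                    f"{len(names)} factors"
                )
            coded = pd.DataFrame(arr, columns=names)
        X = self.spec.model_matrix(coded).to_numpy()
        extrap = (coded.abs() > 1 + 1e-9).any(axis=1).to_numpy()
        return X, extrap

    def predict(self, points, *, natural: bool = False) -> PredictionResult:
        """Predict at coded factor settings (array, mapping or DataFrame).

        With ``natural=True`` the points are given in natural units and are
        coded through the design's factor specs first.  Points outside the
        coded cube are predicted but flagged as extrapolated.
        """
        if natural:
            points = self._code_natural(points)
        X, extrap = self._points_to_exog(points)
        mean = X @ self.params.to_numpy()
        v_mean = self.scale * np.einsum("ij,jk,ik->i", X, self._xtx_inv, X)
        return PredictionResult(
            mean=mean,
            se_mean=np.sqrt(v_mean),
            se_obs=np.sqrt(self.scale + v_mean),
            extrapolated=extrap,
        )

    def _code_natural(self, points) -> pd.DataFrame:
        specs = {f.name: f for f in self.model.design.factors}
        if isinstance(points, Mapping):
            points = pd.DataFrame({k: np.atleast_1d(v) for k, v in points.items()})
        elif not isinstance(points, pd.DataFrame):
            arr = np.atleast_2d(np.asarray(points, dtype=float))
            points = pd.DataFrame(arr, columns=list(specs))
        return pd.DataFrame({k: specs[k].code(points[k]) for k in specs})

    # -- lack of fit ----------------------------------------------------
    def lack_of_fit(self, decimals: int = 6) -> "LackOfFit":
        """Decompose SSE into pure replicate error and lack of fit.

        Replicate groups are runs with identical coded settings (after
        rounding); without at least one group of size ≥ 2 the test is not
        computable and a ``LackOfFit`` with ``available=False`` is returned.
        """
        groups = self.model.design.replicate_groups(decimals)
        y = self.model.endog
        ss_pe, df_pe = 0.0, 0
        for g in groups:
            if len(g) >= 2:
                vals = y.loc[g].to_numpy()
                ss_pe += float(((vals - vals.mean()) ** 2).sum())
                df_pe += len(g) - 1
        if df_pe == 0:
            return LackOfFit(available=False)
        ss_lof = self.ss_resid - ss_pe
        df_lof = self.df_resid - df_pe
        if df_lof <= 0:
            return LackOfFit(available=False, ss_pe=ss_pe, df_pe=df_pe)
        ms_pe = ss_pe / df_pe
        ms_lof = ss_lof / df_lof
        if ms_pe <= 0:
            f, p = np.inf, 0.0
        else:
            f = ms_lof / ms_pe
            p = float(stats.f.sf(f, df_lof, df_pe))
        return LackOfFit(True, f, p, ss_pe, df_pe, ms_pe, max(ss_lof, 0.0), df_lof, ms_lof)

    # -- model reduction ------------------------------------------------
    def backward_eliminate(
        self, alpha: float = 0.05, preserve_hierarchy: bool = True
    ) -> "ResponseModelResults":
        """Iteratively drop the single least significant removable term.

        At each step the term with the largest p-value above ``alpha`` is
        removed and the model refitted; the intercept and (with
        ``preserve_hierarchy``) any parent of a retained higher-order term
        are never candidates.  Returns new results for the reduced model
        (possibly intercept-only); the removal sequence is recorded in
        ``elimination_log``.
        """
        if self.df_resid < 1:
            raise ValueError("backward elimination needs residual df >= 1")
        res = self
        log: list[tuple[str, float]] = []
        while True:
            protected = {t.name for t in res.spec.protected()} if preserve_hierarchy \
                else {"intercept"}
            pvals = res.pvalues.drop(labels=[c for c in protected if c in res.pvalues])
            pvals = pvals[pvals > alpha]
            if pvals.empty:
                break
            worst = pvals.idxmax()
            log.append((worst, float(pvals[worst])))
            term = next(t for t in res.spec.terms if t.name == worst)
            new_spec = res.spec.drop(term)
            res = ResponseModel(
                self.model.endog, self.model.design, new_spec, name=self.model.name
            ).fit()
        return ResponseModelResults(res.model, res._ols, elimination_log=log)

    # -- reporting -------------------------------------------------------
    def diagnostics(self) -> dict:
        """Flat diagnostics record mirroring a DoE software model summary."""
        lof = self.lack_of_fit()
        out = {
            "response": self.model.name,
            "n_runs": int(self.nobs),
            "n_terms": len(self.params),
            "r2": self.rsquared,
            "r2_adj": self.rsquared_adj,
            "q2": self.q2,
            "press": self.press,
            "rmse": self.rmse,
            "anova_regression_p": self.f_pvalue,
            "lack_of_fit_p": lof.p if lof.available else None,
            "pure_error_df": lof.df_pe if lof.available else 0,
            "pure_error_ms": lof.ms_pe if lof.available else None,
        }
        return out

    def summary(self, level: float = 0.95) -> str:
        ci = self.conf_int(level)
        lines = [
            f"Response: {self.model.name}   runs: {self.nobs}   "
            f"terms: {len(self.params)}   df_resid: {self.df_resid}",
            f"R2 = {self.rsquared:.3f}   R2adj = {self.rsquared_adj:.3f}   "
            f"Q2 = {self.q2:.3f}   RMSE = {self.rmse:.4g}",
            f"regression p = {self.f_pvalue:.3g}",
        ]
        lof = self.lack_of_fit()
        if lof.available:
            lines.append(
                f"lack-of-fit p = {lof.p:.3f}   pure error MS = {lof.ms_pe:.3g} "
                f"(df {lof.df_pe})"
            )
        lines.append(f"{'term':<28}{'coef':>10}{'se':>10}{'p':>10}{'ci':>22}")
        for name in self.params.index:
            lines.append(
                f"{name:<28}{self.params[name]:>10.4f}{self.bse[name]:>10.4f}"
                f"{self.pvalues[name]:>10.3g}"
                f"   [{ci.loc[name, 'low']:.4f}, {ci.loc[name, 'high']:.4f}]"
            )
        if self.elimination_log:
            dropped = ", ".join(f"{n} (p={p:.2g})" for n, p in self.elimination_log)
            lines.append(f"eliminated: {dropped}")
        return "\n".join(lines)

    def to_report(self, level: float = 0.95) -> dict:
        """JSON-serialisable fit report."""
        ci = self.conf_int(level)
        return {
            "response": self.model.name,
            "terms": self.spec.to_json_obj(),
            "coefficients": {n: float(v) for n, v in self.params.items()},
            "intervals": {
                n: [float(ci.loc[n, "low"]), float(ci.loc[n, "high"])]
                for n in self.params.index
            },
            "level": level,
            "diagnostics": _jsonify(self.diagnostics()),
            "eliminated": [[n, p] for n, p in self.elimination_log],
        }


def _jsonify(d: dict) -> dict:
    out = {}
    for k, v in d.items():
        if isinstance(v, (np.floating, np.integer)):
            v = v.item()
        out[k] = v
    return out


@dataclass
class LackOfFit:
    """Lack-of-fit F-test against pure replicate error."""

    available: bool
    f: float = np.nan
    p: float = np.nan
    ss_pe: float = 0.0
    df_pe: int = 0
    ms_pe: float = np.nan
    ss_lof: float = np.nan
    df_lof: int = 0
    ms_lof: float = np.nan


def fit_responses(
    responses: pd.DataFrame,
    design: DesignMatrix,
    spec: ModelSpec,
    *,
    eliminate_alpha: float | None = None,
    preserve_hierarchy: bool = True,
) -> dict[str, ResponseModelResults]:
    """Fit one model per response column, optionally backward-eliminated."""
    out = {}
    for name in responses.columns:
        res = ResponseModel(responses[name], design, spec, name=name).fit()
        if eliminate_alpha is not None:
            res = res.backward_eliminate(eliminate_alpha, preserve_hierarchy)
        out[name] = res
    return out
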