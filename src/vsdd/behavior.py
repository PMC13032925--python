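"""Psychometric and chronometric behavioral analyses.

The choice of the first object is modeled as a logistic function of its
value, ``P = 1 / (1 + exp(-(b0 + b1*V)))``; the indifference point (the
value chosen with 50% probability, used as a risk-attitude index) is
``-b0/b1``. A second logistic adds the previous trial's second-object value
as a predictor to quantify the carry-over of recent reward history.
Button-release latency is regressed on object value by ordinary least
squares.

Session-level inference (the across-session mean slope and a two-sided
Wilcoxon signed-rank of per-session slopes against zero) is provided by
:func:`session_slope_summary`; the fitters themselves accept any trial
subset.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
import statsmodels.api as sm
from scipy import stats
from sklearn.base import BaseEstimator

from .exceptions import (
    InsufficientDataError,
    ParameterError,
    UndefinedIndifferenceError,
)
from .io import as_trial_frame

__all__ = [
    "LogisticFit",
    "LinearFit",
    "ChoiceLogistic",
    "PreviousValueLogistic",
    "LatencyRegression",
    "fit_choice_logistic",
    "risk_attitude",
    "fit_previous_value_logistic",
    "fit_latency_regression",
    "session_slope_summary",
]

MAX_IRLS_ITER = 25


@dataclass
class LogisticFit:
    beta: np.ndarray
    se: np.ndarray
    converged: bool
    n: int
    diagnostic: str = ""

    def predict(self, X: np.ndarray) -> np.ndarray:
        X = np.column_stack([np.ones(len(X)), np.atleast_2d(np.asarray(X, float).T).T])
        from scipy.special import expit

        return expit(X @ self.beta)


@dataclass
class LinearFit:
    slope: float
    intercept: float
    se_slope: float
    r2: float
    n: int


def _fit_logistic(y: np.ndarray, X: np.ndarray) -> LogisticFit:
    """IRLS logistic fit (statsmodels GLM), capped iterations, honest flags.

    Complete separation is expected in overtrained behavior; it is reported
    via ``converged=False`` plus a diagnostic, never raised.
    """
    Xd = sm.add_constant(X, has_constant="add")
    n = len(y)
    try:
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            res = sm.GLM(y, Xd, family=sm.families.Binomial()).fit(
                maxiter=MAX_IRLS_ITER
            )
        converged = bool(res.converged)
        beta = np.asarray(res.params, float)
        se = np.asarray(res.bse, float)
        diagnostic = "" if converged else "IRLS did not converge in 25 iterations"
        # huge |beta| or exploding SEs signal (quasi-)separation
        if converged and (np.any(np.abs(beta) > 50) or np.any(~np.isfinite(se))):
            converged = False
            diagnostic = "possible complete separation (unbounded estimates)"
    except Exception as exc:  # e.g. PerfectSeparationError
        k = Xd.shape[1]
        return LogisticFit(
            beta=np.full(k, np.nan),
            se=np.full(k, np.nan),
            converged=False,
            n=n,
            diagnostic=f"separation: {exc}",
        )
    return LogisticFit(beta=beta, se=se, converged=converged, n=n, diagnostic=diagnostic)


class ChoiceLogistic(BaseEstimator):
    """Psychometric logistic of first-object choice on first-object value.

    Fitted attributes: ``coef_`` (intercept, slope), ``se_``, ``converged_``,
    ``n_``. ``indifference_value()`` returns -b0/b1.
    """

    def fit(self, trials) -> "ChoiceLogistic":
        df = as_trial_frame(trials)
        df = df[df["task"] == "decision"]
        v = df["value1"].to_numpy(float)
        y = df["chosen"].to_numpy(float)
        if np.unique(v).size < 2 or np.unique(y).size < 2:
            # degenerate design: report, do not raise
            fit = LogisticFit(
                beta=np.full(2, np.nan),
                se=np.full(2, np.nan),
                converged=False,
                n=len(y),
                diagnostic="degenerate input: constant value or single outcome",
            )
        else:
            fit = _fit_logistic(y, v)
        self.fit_ = fit
        self.coef_ = fit.beta
        self.se_ = fit.se
        self.converged_ = fit.converged
        self.n_ = fit.n
        return self

    def indifference_value(self) -> float:
        b0, b1 = self.coef_[0], self.coef_[1]
        if not np.isfinite(b1) or b1 == 0:
            raise UndefinedIndifferenceError("value slope is zero or undefined")
        return -b0 / b1


class PreviousValueLogistic(BaseEstimator):
    """Logistic of current choice on previous second-object value and current value.

    Coefficient order: (intercept, previous second-object value V2[t-1],
    current first-object value V1[t]). The first trial of every session is
    dropped (no predecessor), so n = total trials - number of sessions.
    """

    def fit(self, trials) -> "PreviousValueLogistic":
        df = as_trial_frame(trials)
        df = df[df["task"] == "decision"].sort_values(["session_id", "trial_index"])
        rows = []
        for _, g in df.groupby("session_id", sort=False):
            v2_prev = g["value2"].shift(1)
            sub = g.iloc[1:]
            keep = ~v2_prev.iloc[1:].isna()
            rows.append(
                pd.DataFrame(
                    {
                        "chosen": sub["chosen"].to_numpy(float)[keep.to_numpy()],
                        "v2_prev": v2_prev.iloc[1:].to_numpy(float)[keep.to_numpy()],
                        "v1": sub["value1"].to_numpy(float)[keep.to_numpy()],
                    }
                )
            )
        d = pd.concat(rows, ignore_index=True) if rows else pd.DataFrame()
        if len(d) < 3:
            raise InsufficientDataError("need >= 2 trials per session")
        X = d[["v2_prev", "v1"]].to_numpy(float)
        if np.unique(X[:, 0]).size < 2:
            fit = LogisticFit(
                beta=np.full(3, np.nan),
                se=np.full(3, np.nan),
                converged=False,
                n=len(d),
                diagnostic="rank deficiency: previous second-object value constant",
            )
        else:
            fit = _fit_logistic(d["chosen"].to_numpy(float), X)
        self.fit_ = fit
        self.coef_ = fit.beta
        self.se_ = fit.se
        self.converged_ = fit.converged
        self.n_ = fit.n
        return self


class LatencyRegression(BaseEstimator):
    """OLS of button-release latency on object value.

    ``which='first'`` regresses on value1 over trials carrying a latency;
    ``which='second'`` regresses on value2 (second-object responses) over
    records where both latency and value2 are present.
    """

    def __init__(self, which: str = "first"):
        self.which = which

    def fit(self, trials) -> "LatencyRegression":
        if self.which not in ("first", "second"):
            raise ParameterError(f"which must be 'first' or 'second', got {self.which}")
        df = as_trial_frame(trials)
        df = df[~df["latency_ms"].isna()]
        col = "value1" if self.which == "first" else "value2"
        df = df[~df[col].isna()]
        if len(df) < 3:
            raise InsufficientDataError("need >= 3 trials with latency")
        x = df[col].to_numpy(float)
        y = df["latency_ms"].to_numpy(float)
        if np.ptp(x) == 0:
            raise InsufficientDataError("object value constant; slope undefined")
        if np.ptp(y) == 0:  # constant latency: flat line, no explained variance
            self.fit_ = LinearFit(
                slope=0.0, intercept=float(y[0]), se_slope=0.0, r2=0.0, n=len(x)
            )
        else:
            res = stats.linregress(x, y)
            self.fit_ = LinearFit(
                slope=float(res.slope),
                intercept=float(res.intercept),
                se_slope=float(res.stderr),
                r2=float(res.rvalue**2),
                n=len(x),
            )
        self.slope_ = self.fit_.slope
        self.intercept_ = self.fit_.intercept
        self.r2_ = self.fit_.r2
        return self


# ---------------------------------------------------------------------------
# thin functional wrappers


def fit_choice_logistic(trials) -> LogisticFit:
    return ChoiceLogistic().fit(trials).fit_


def risk_attitude(fit: LogisticFit) -> float:
    """Indifference value -b0/b1 of a fitted psychometric logistic."""
    if not fit.converged:
        raise UndefinedIndifferenceError(f"fit not converged: {fit.diagnostic}")
    b0, b1 = fit.beta[0], fit.beta[1]
    if b1 == 0 or not np.isfinite(b1):
        raise UndefinedIndifferenceError("value slope is zero")
    return float(-b0 / b1)


def fit_previous_value_logistic(trials) -> LogisticFit:
    return PreviousValueLogistic().fit(trials).fit_


def fit_latency_regression(trials, which: str = "first") -> LinearFit:
    return LatencyRegression(which=which).fit(trials).fit_


def session_slope_summary(trials, model: str = "choice") -> dict:
    """Per-session fits with across-session summary statistics.

    Fits the requested model (``choice``, ``previous_value`` or
    ``latency_first``/``latency_second``) separately per session and reports
    the mean +/- SEM of the slope of interest plus a two-sided Wilcoxon
    signed-rank test of the per-session slopes against zero.
    """
    df = as_trial_frame(trials)
    slopes, sessions = [], []
    for sid, g in df.groupby("session_id"):
        try:
            if model == "choice":
                f = fit_choice_logistic(g)
                if not f.converged:
                    continue
                slopes.append(f.beta[1])
            elif model == "previous_value":
                f = fit_previous_value_logistic(g)
                if not f.converged:
                    continue
                slopes.append(f.beta[1])
            elif model in ("latency_first", "latency_second"):
                which = "first" if model.endswith("first") else "second"
                slopes.append(fit_latency_regression(g, which).slope)
            else:
                raise ParameterError(f"unknown model {model!r}")
        except InsufficientDataError:
            continue
        sessions.append(sid)
    slopes_arr = np.asarray(slopes, float)
    out = {
        "model": model,
        "n_sessions": len(slopes_arr),
        "mean_slope": float(np.mean(slopes_arr)) if len(slopes_arr) else np.nan,
        "sem_slope": float(stats.sem(slopes_arr)) if len(slopes_arr) > 1 else np.nan,
    }
    if len(slopes_arr) > 1 and np.any(slopes_arr != 0):
        w = stats.wilcoxon(slopes_arr, alternative="two-sided")
        out["wilcoxon_p"] = float(w.pvalue)
    else:
        out["wilcoxon_p"] = np.nan
    out["sessions"] = sessions
    out["slopes"] = slopes_arr
    return out
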