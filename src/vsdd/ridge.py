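"""Ridge regression with permutation significance and max-statistic FWER.

Three window-wise ridge models probe what drives trial-by-trial firing
rates F when predictors are correlated:

* value + choice: ``F = b0 + b1*V + b2*C``;
* value + reaction time (chosen trials only, where a release latency
  exists): ``F = b0 + b1*V + b2*RT``;
* previous second-object value + current value + choice (first trial of
  each session dropped): ``F = b0 + b1*V2[t-1] + b2*V1[t] + b3*C[t]``.

Predictors are standardized (zero mean, unit variance) before
penalization; the intercept is unpenalized, so it equals the mean response
and the penalized solution is closed-form,
``beta = (Xs'Xs + lambda*I)^-1 Xs' (F - mean(F))``.

Per-coefficient significance is assessed by permuting the response across
trials and refitting: ``p = (1 + #{|beta_perm| >= |beta_obs|}) / (1 + n_perm)``.
The population question — in which windows is the proportion of neurons
with a significant coefficient above chance? — is answered with a
max-statistic permutation procedure: for each permutation the proportion
is recomputed on every neuron's shuffled data and its maximum across all
windows collected; a window is significant iff its observed proportion
strictly exceeds the (1 - alpha) quantile of that null max distribution,
which controls the family-wise error rate across windows.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass
from typing import Optional, Sequence

import numpy as np
import pandas as pd
from scipy.stats import rankdata
from sklearn.base import BaseEstimator

from .config import AnalysisConfig, substream
from .exceptions import InsufficientDataError, ParameterError
from .io import SpikeTrain, TrialRecord
from .classify import ANALYSIS_END_MS, _window_rates

__all__ = [
    "RidgeFit",
    "ProportionSeries",
    "MODELS",
    "fit_ridge",
    "ridge_coef_significance",
    "population_proportion_fwer",
    "run_ridge_analysis",
    "WindowedRidgeAnalysis",
]

MODELS = {
    "value_choice": ("value", "choice"),
    "value_rt": ("value", "rt"),
    "prev_value": ("prev_value", "value", "choice"),
}


@dataclass
class RidgeFit:
    """Penalized fit on the standardized design (intercept unpenalized)."""

    beta0: float
    beta: np.ndarray  # one entry per predictor, standardized scale
    lam: float
    coef_p: Optional[np.ndarray] = None


def _standardize(X: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    """Column-standardize; constant columns become all-zero (flagged)."""
    X = np.asarray(X, float)
    mu = X.mean(axis=0)
    sd = X.std(axis=0)
    const = sd == 0
    if np.any(const):
        warnings.warn(
            "constant predictor column(s): coefficient defined as 0",
            RuntimeWarning,
            stacklevel=3,
        )
    sd_safe = np.where(const, 1.0, sd)
    Xs = (X - mu) / sd_safe
    Xs[:, const] = 0.0
    return Xs, const


def _ridge_solver(Xs: np.ndarray, lam: float) -> np.ndarray:
    """Matrix A with beta = A @ (F - mean F); shape (n_coef, n)."""
    k = Xs.shape[1]
    return np.linalg.solve(Xs.T @ Xs + lam * np.eye(k), Xs.T)


def fit_ridge(F, X, lam: float) -> RidgeFit:
    """Closed-form ridge of response F on predictors X (columns).

    Minimizes ``||F - b0 - Xs b||^2 + lam * ||b||^2`` with Xs the
    standardized design. ``lam = 0`` reproduces OLS on the same design;
    as ``lam -> inf`` penalized coefficients vanish.
    """
    F = np.asarray(F, float)
    X = np.atleast_2d(np.asarray(X, float))
    if X.shape[0] != len(F):
        X = X.T
    if lam < 0:
        raise ParameterError("lambda must be >= 0")
    Xs, const = _standardize(X)
    Fc = F - F.mean()
    beta = _ridge_solver(Xs, lam) @ Fc
    beta[const] = 0.0
    return RidgeFit(beta0=float(F.mean()), beta=beta, lam=lam)


def ridge_coef_significance(
    F,
    X,
    lam: float,
    n_perm: int = 1000,
    seed: int = 0,
    rng: Optional[np.random.Generator] = None,
) -> np.ndarray:
    """Permutation p-value per penalized coefficient.

    The response is permuted across trials and the ridge refit; ties
    (|beta_perm| == |beta_obs|) count toward the p-value, so a constant
    response yields p = 1 for every coefficient.
    """
    if n_perm < 100:
        raise ParameterError("n_perm must be >= 100")
    if rng is None:
        rng = substream(seed, "ridge-perm")
    F = np.asarray(F, float)
    X = np.atleast_2d(np.asarray(X, float))
    if X.shape[0] != len(F):
        X = X.T
    Xs, const = _standardize(X)
    A = _ridge_solver(Xs, lam)
    Fc = F - F.mean()
    beta_obs = A @ Fc
    beta_obs[const] = 0.0
    P = rng.permuted(np.tile(Fc, (n_perm, 1)), axis=1)
    beta_perm = P @ A.T  # (n_perm, n_coef)
    beta_perm[:, const] = 0.0
    geq = np.sum(np.abs(beta_perm) >= np.abs(beta_obs)[None, :], axis=0)
    return (1.0 + geq) / (1.0 + n_perm)


def gcv_lambda(F, X, grid=None) -> float:
    """Generalized cross-validation over a lambda grid.

    Optional alternative to the fixed default penalty: minimizes
    ``n * RSS(lam) / (n - tr(H(lam)))^2`` with H the hat matrix of the
    standardized design (intercept unpenalized).
    """
    F = np.asarray(F, float)
    X = np.atleast_2d(np.asarray(X, float))
    if X.shape[0] != len(F):
        X = X.T
    if grid is None:
        grid = np.logspace(-3, 3, 25)
    Xs, _ = _standardize(X)
    n = len(F)
    Fc = F - F.mean()
    best_lam, best_score = float(grid[0]), np.inf
    for lam in grid:
        A = _ridge_solver(Xs, float(lam))
        H = Xs @ A
        resid = Fc - H @ Fc
        edf = 1.0 + np.trace(H)  # +1 for the unpenalized intercept
        score = n * float(resid @ resid) / (n - edf) ** 2
        if score < best_score:
            best_lam, best_score = float(lam), score
    return best_lam


def neuron_perm_pvalues(
    F: np.ndarray,
    X: np.ndarray,
    lam: float,
    n_perm: int,
    rng: np.random.Generator,
) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    """Window-wise ridge coefficients with observed and null permutation p-values.

    ``F`` is the (n_trials, n_windows) rate matrix of one neuron, ``X`` its
    (n_trials, k) design. One trial permutation per repetition is applied
    to every window (a dataset-level shuffle). Returns ``(beta, obs_p,
    null_p)`` with shapes (n_windows, k), (n_windows, k) and (n_perm,
    n_windows, k); ``null_p[k']`` is the p-value the k'-th shuffled dataset
    attains against the remaining shuffles.
    """
    F = np.asarray(F, float)
    Xs, const = _standardize(np.asarray(X, float))
    A = _ridge_solver(Xs, lam)
    Fc = F - F.mean(axis=0, keepdims=True)
    beta = A @ Fc  # (k, n_windows)
    beta[const] = 0.0
    n, n_windows = F.shape
    k = Xs.shape[1]
    perm_idx = rng.permuted(np.tile(np.arange(n), (n_perm, 1)), axis=1)
    obs_p = np.empty((n_windows, k))
    null_p = np.empty((n_perm, n_windows, k))
    for w in range(n_windows):
        bp = Fc[:, w][perm_idx] @ A.T  # (n_perm, k)
        bp[:, const] = 0.0
        geq = np.sum(np.abs(bp) >= np.abs(beta[:, w])[None, :], axis=0)
        obs_p[w] = (1.0 + geq) / (1.0 + n_perm)
        # rank-based count of strictly smaller |beta| among the shuffles
        rmin = rankdata(np.abs(bp), method="min", axis=0)
        null_p[:, w] = (n_perm - (rmin - 1.0)) / n_perm
    return beta.T, obs_p, null_p


@dataclass
class ProportionSeries:
    """Per-window significant-neuron proportions for one predictor."""

    predictor: str
    window_starts: np.ndarray
    prop_significant: np.ndarray
    null_max_quantile: float
    significant_windows: np.ndarray  # bool per window


def population_proportion_fwer(
    obs_p: np.ndarray,
    null_p: np.ndarray,
    alpha: float = 0.05,
    window_starts: Optional[np.ndarray] = None,
    predictor: str = "",
) -> ProportionSeries:
    """Max-statistic FWER control on significant-neuron proportions.

    Parameters
    ----------
    obs_p : (n_neurons, n_windows) observed per-neuron p-values.
    null_p : (n_perm, n_neurons, n_windows) p-values on shuffled data.
    """
    obs_p = np.asarray(obs_p, float)
    null_p = np.asarray(null_p, float)
    n_neurons, n_windows = obs_p.shape
    if n_windows < 2:
        warnings.warn(
            "fewer than 2 windows: degenerates to a single-window permutation test",
            RuntimeWarning,
            stacklevel=2,
        )
    if window_starts is None:
        window_starts = np.arange(n_windows)
    prop_obs = np.mean(obs_p < alpha, axis=0)
    prop_null = np.mean(null_p < alpha, axis=1)  # (n_perm, n_windows)
    null_max = prop_null.max(axis=1)
    q = float(np.quantile(null_max, 1.0 - alpha, method="higher"))
    return ProportionSeries(
        predictor=predictor,
        window_starts=np.asarray(window_starts),
        prop_significant=prop_obs,
        null_max_quantile=q,
        significant_windows=prop_obs > q,  # strict: a tie is not significant
    )


def _design_for_model(trials: Sequence[TrialRecord], model: str):
    """(row mask over trials, design matrix) for the requested model."""
    if model not in MODELS:
        raise ParameterError(f"unknown model {model!r}; choose from {sorted(MODELS)}")
    V = np.array([t.value1 for t in trials], float)
    C = np.array([t.chosen for t in trials], float)
    if model == "value_choice":
        return np.ones(len(trials), bool), np.column_stack([V, C])
    if model == "value_rt":
        mask = np.array([t.chosen == 1 and t.latency_ms is not None for t in trials])
        if not np.any(mask):
            raise InsufficientDataError("no chosen trials: RT model undefined")
        RT = np.array([t.latency_ms for t in trials if t.chosen == 1], float)
        return mask, np.column_stack([V[mask], RT])
    # prev_value: V2 of the previous trial within the session
    mask = np.zeros(len(trials), bool)
    v2prev = np.full(len(trials), np.nan)
    for i in range(1, len(trials)):
        prev, cur = trials[i - 1], trials[i]
        if prev.session_id == cur.session_id and prev.value2 is not None:
            mask[i] = True
            v2prev[i] = prev.value2
    if not np.any(mask):
        raise InsufficientDataError("no trials with a previous second-object value")
    return mask, np.column_stack([v2prev[mask], V[mask], C[mask]])


def run_ridge_analysis(
    trains_by_neuron: dict[str, Sequence[SpikeTrain]],
    trials_by_neuron: dict[str, Sequence[TrialRecord]],
    model: str = "value_choice",
    cfg: AnalysisConfig = AnalysisConfig(),
    n_perm: int = 200,
) -> tuple[pd.DataFrame, dict[str, ProportionSeries]]:
    """Window-wise ridge fits for a population plus FWER proportion series.

    Each permutation reshuffles every neuron's firing rates across trials
    (one trial permutation per neuron per permutation, applied to all
    windows); the permutation ensemble provides both the per-neuron
    coefficient p-values and the shuffled-data replicates feeding the
    max-statistic null.
    """
    if n_perm < 100:
        raise ParameterError("n_perm must be >= 100")
    names = MODELS[model]
    starts = np.arange(0, ANALYSIS_END_MS - cfg.window_len_ms + 1, cfg.step_ms)
    neuron_ids = sorted(trains_by_neuron)
    n_neurons = len(neuron_ids)
    k = len(names)
    obs_beta = np.full((n_neurons, len(starts), k), np.nan)
    obs_p = np.full((n_neurons, len(starts), k), np.nan)
    null_p = np.full((n_perm, n_neurons, len(starts), k), np.nan)

    for i, nid in enumerate(neuron_ids):
        trials = list(trials_by_neuron[nid])
        trains = sorted(trains_by_neuron[nid], key=lambda t: t.trial_index)
        if len(trains) != len(trials):
            raise ParameterError(f"neuron {nid}: trains and trials must align")
        mask, X = _design_for_model(trials, model)
        sub = [t for t, m in zip(trains, mask) if m]
        if len(sub) < max(10, k + 2):
            raise InsufficientDataError(f"neuron {nid}: too few usable trials")
        F = _window_rates(sub, starts, cfg.window_len_ms)  # (n_used, n_windows)
        rng = substream(cfg.seed, "ridge-perm", nid)
        obs_beta[i], obs_p[i], null_p[:, i] = neuron_perm_pvalues(
            F, X, cfg.ridge_lambda, n_perm, rng
        )
    coef_rows = []
    for i, nid in enumerate(neuron_ids):
        for w, s in enumerate(starts):
            row = {"neuron_id": nid, "window_start_ms": int(s)}
            for j, name in enumerate(names):
                row[f"beta_{name}"] = obs_beta[i, w, j]
                row[f"p_{name}"] = obs_p[i, w, j]
            coef_rows.append(row)
    coefs = pd.DataFrame(coef_rows)
    series = {
        name: population_proportion_fwer(
            obs_p[:, :, j],
            null_p[:, :, :, j],
            alpha=cfg.alpha,
            window_starts=starts,
            predictor=name,
        )
        for j, name in enumerate(names)
    }
    return coefs, series


class WindowedRidgeAnalysis(BaseEstimator):
    """Population window-wise ridge analysis with FWER-corrected proportions.

    Fitted attributes: ``coefs_`` (per neuron per window coefficients and
    permutation p-values) and ``proportions_`` (dict predictor ->
    :class:`ProportionSeries`).
    """

    def __init__(
        self,
        model: str = "value_choice",
        ridge_lambda: float = 1.0,
        n_perm: int = 200,
        alpha: float = 0.05,
        window_len_ms: int = 150,
        step_ms: int = 50,
        seed: int = 0,
    ):
        self.model = model
        self.ridge_lambda = ridge_lambda
        self.n_perm = n_perm
        self.alpha = alpha
        self.window_len_ms = window_len_ms
        self.step_ms = step_ms
        self.seed = seed

    def fit(self, trains: Sequence[SpikeTrain], trials: Sequence[TrialRecord]):
        cfg = AnalysisConfig(
            window_len_ms=self.window_len_ms,
            step_ms=self.step_ms,
            alpha=self.alpha,
            ridge_lambda=self.ridge_lambda,
            seed=self.seed,
        )
        trial_map: dict[tuple[str, int], TrialRecord] = {
            (t.session_id, t.trial_index): t for t in trials
        }
        by_neuron: dict[str, list[SpikeTrain]] = {}
        for tr in trains:
            by_neuron.setdefault(tr.neuron_id, []).append(tr)
        trials_by_neuron = {
            nid: [
                trial_map[t.trial_id]
                for t in sorted(ts, key=lambda t: (t.session_id, t.trial_index))
            ]
            for nid, ts in by_neuron.items()
        }
        self.coefs_, self.proportions_ = run_ridge_analysis(
            by_neuron, trials_by_neuron, self.model, cfg, n_perm=self.n_perm
        )
        return self
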