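"""Sliding-window value/choice model comparison with a Monte Carlo null.

The central question for each neuron and each 150-ms window is whether its
trial-by-trial firing rate F is better explained by the option value
(value model, ``F = b0 + b1*V``) or by the animal's action selection
(choice model, ``F = b0 + b1*C``, C in {0,1}). Because V and C are highly
correlated in behavior, the two single-predictor models are compared by
their coefficients of determination instead of entering one multiple
regression.

The observed statistic is ``dR2 = R2_value - R2_choice`` in the analysis
window. Its null distribution is built by shuffling: the *baseline* firing
rate (the pre-onset window, where no signal can exist) is randomly
reassigned across trials, both models are fit to the shuffled baseline
rates, and their R2 difference recorded; this is repeated ``n_shuffle``
times. If the observed dR2 exceeds the null in more than
``(1 - alpha/2) * n_shuffle`` repetitions (975/1000 at alpha = 0.05) and
the value model itself fits significantly (F-test), the window carries a
value-modulated signal; the mirror-image tail with a significant choice
fit gives a choice-modulated signal; no significant difference but both
fits significant gives an intermediate signal; anything else is unlabeled.

A signal is called only when the same label holds for a run of consecutive
windows whose duration matches 40 windows at the 1-ms reference step; the
signal latency is the start time of the first window of the run.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass
from typing import Optional, Sequence

import numpy as np
import pandas as pd
from scipy import stats
from sklearn.base import BaseEstimator

from .config import AnalysisConfig, substream
from .exceptions import InsufficientDataError, ParameterError
from .io import SpikeTrain, TrialRecord
from .spikes import window_counts

__all__ = [
    "KINDS",
    "MCComparison",
    "WindowLabelSeries",
    "SignalSegment",
    "fit_single_predictor",
    "mc_model_comparison",
    "classify_neuron",
    "extract_segments",
    "signal_latencies",
    "transition_probabilities",
    "SlidingWindowSignalClassifier",
]

KINDS = ("value", "intermediate", "choice")
ANALYSIS_END_MS = 1000  # first-object presentation length

MIN_TRIALS = 10


@dataclass
class MCComparison:
    dr2_obs: float
    exceed_count: int
    n_shuffle: int
    fit_p_value: float
    fit_p_choice: float
    label: str


@dataclass
class WindowLabelSeries:
    """Per-window classification outcome for one neuron."""

    neuron_id: str
    window_starts: np.ndarray
    labels: np.ndarray  # array of {'value','intermediate','choice','none'}
    dr2_obs: np.ndarray
    exceed_count: np.ndarray
    fit_p_value: np.ndarray
    fit_p_choice: np.ndarray
    n_shuffle: int

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {
                "neuron_id": self.neuron_id,
                "window_start_ms": self.window_starts,
                "label": self.labels,
                "dr2_obs": self.dr2_obs,
                "exceed_count": self.exceed_count,
                "fit_p_value": self.fit_p_value,
                "fit_p_choice": self.fit_p_choice,
            }
        )


@dataclass(frozen=True)
class SignalSegment:
    """A contiguous qualifying run of one signal kind."""

    neuron_id: str
    kind: str
    latency_ms: float  # start of the first window of the run
    end_ms: float  # start of the last window of the run


def _simple_r2_p(F: np.ndarray, x: np.ndarray) -> tuple[float, float, float, float]:
    """Closed-form simple OLS: (beta0, beta1, r2, F-test p)."""
    F = np.asarray(F, float)
    x = np.asarray(x, float)
    n = len(F)
    xc = x - x.mean()
    Fc = F - F.mean()
    sxx = float(xc @ xc)
    if sxx == 0.0:
        raise ParameterError("degenerate design: predictor is constant")
    sxy = float(xc @ Fc)
    syy = float(Fc @ Fc)
    beta1 = sxy / sxx
    beta0 = float(F.mean() - beta1 * x.mean())
    if syy == 0.0:
        return beta0, beta1, 0.0, 1.0
    r2 = sxy * sxy / (sxx * syy)
    r2 = min(r2, 1.0)
    if n <= 2:
        return beta0, beta1, r2, 1.0
    if r2 >= 1.0:
        return beta0, beta1, 1.0, 0.0
    fstat = r2 * (n - 2) / (1.0 - r2)
    p = float(stats.f.sf(fstat, 1, n - 2))
    return beta0, beta1, r2, p


def fit_single_predictor(F, X) -> tuple[float, float, float, float]:
    """Simple linear regression of rate on one predictor.

    Returns (beta0, beta1, r2, f_test_p). A constant predictor raises; a
    constant response yields r2 = 0 with p = 1.
    """
    F = np.asarray(F, float)
    if len(F) < 3:
        raise InsufficientDataError("need >= 3 observations")
    return _simple_r2_p(F, X)


def _null_dr2(
    baseline_F: np.ndarray,
    V: np.ndarray,
    C: np.ndarray,
    n_shuffle: int,
    rng: np.random.Generator,
) -> np.ndarray:
    """Null dR2 draws: shuffle baseline rates across trials, fit both models.

    R2 of a simple regression is the squared correlation, so each shuffle
    reduces to two inner products with the centered predictors.
    """
    b = np.asarray(baseline_F, float)
    bc = b - b.mean()
    sbb = float(bc @ bc)
    if sbb == 0.0:
        warnings.warn(
            "constant baseline rates: null dR2 undefined, treated as 0",
            RuntimeWarning,
            stacklevel=2,
        )
        return np.zeros(n_shuffle)
    vc = V - V.mean()
    cc = C - C.mean()
    svv = float(vc @ vc)
    scc = float(cc @ cc)
    P = rng.permuted(np.tile(bc, (n_shuffle, 1)), axis=1)
    rv2 = (P @ vc) ** 2 / (svv * sbb) if svv > 0 else np.zeros(n_shuffle)
    rc2 = (P @ cc) ** 2 / (scc * sbb) if scc > 0 else np.zeros(n_shuffle)
    return rv2 - rc2


def _label_window(
    dr2_obs: float,
    exceed: int,
    n_shuffle: int,
    p_value_fit: float,
    p_choice_fit: float,
    alpha: float,
) -> str:
    hi = (1.0 - alpha / 2.0) * n_shuffle
    lo = (alpha / 2.0) * n_shuffle
    if exceed > hi and p_value_fit < alpha:
        return "value"
    if exceed < lo and p_choice_fit < alpha:
        return "choice"
    if lo <= exceed <= hi and p_value_fit < alpha and p_choice_fit < alpha:
        return "intermediate"
    return "none"


def mc_model_comparison(
    F,
    V,
    C,
    baseline_F,
    cfg: AnalysisConfig = AnalysisConfig(),
    rng: Optional[np.random.Generator] = None,
) -> MCComparison:
    """Monte Carlo comparison of the value and choice models in one window.

    ``F`` are analysis-window firing rates, ``baseline_F`` pre-onset
    baseline rates over the same trials; ties between observed and null
    dR2 count as non-exceeding (conservative).
    """
    F = np.asarray(F, float)
    V = np.asarray(V, float)
    C = np.asarray(C, float)
    baseline_F = np.asarray(baseline_F, float)
    if not (len(F) == len(V) == len(C) == len(baseline_F)):
        raise ParameterError("F, V, C and baseline_F must have equal length")
    if len(F) < MIN_TRIALS:
        raise InsufficientDataError(f"need >= {MIN_TRIALS} trials")
    if rng is None:
        rng = substream(cfg.seed, "mc-null")
    _, _, r2v, pv = _simple_r2_p(F, V)
    _, _, r2c, pc = _simple_r2_p(F, C)
    dr2_obs = r2v - r2c
    null = _null_dr2(baseline_F, V, C, cfg.n_shuffle, rng)
    exceed = int(np.sum(dr2_obs > null))
    label = _label_window(dr2_obs, exceed, cfg.n_shuffle, pv, pc, cfg.alpha)
    return MCComparison(
        dr2_obs=float(dr2_obs),
        exceed_count=exceed,
        n_shuffle=cfg.n_shuffle,
        fit_p_value=pv,
        fit_p_choice=pc,
        label=label,
    )


def _window_rates(
    trains: Sequence[SpikeTrain], starts: np.ndarray, length_ms: float
) -> np.ndarray:
    """(n_trials, n_windows) firing-rate matrix."""
    rates = np.empty((len(trains), len(starts)))
    for i, tr in enumerate(trains):
        rates[i] = window_counts(tr.spikes_ms, starts, length_ms)
    return rates / (length_ms / 1000.0)


def classify_neuron(
    trains: Sequence[SpikeTrain],
    trials: Sequence[TrialRecord],
    cfg: AnalysisConfig = AnalysisConfig(),
    neuron_id: Optional[str] = None,
) -> WindowLabelSeries:
    """Run the model comparison at every sliding-window start.

    ``trains`` must align with ``trials`` (same order, one train per
    trial). Window starts cover [0, 1000 - window_len] at ``cfg.step_ms``;
    each window draws a fresh permutation substream keyed by (neuron,
    window start).
    """
    if len(trains) != len(trials):
        raise ParameterError("trains and trials must align one-to-one")
    if len(trials) < MIN_TRIALS:
        raise InsufficientDataError(f"need >= {MIN_TRIALS} trials")
    nid = neuron_id or trains[0].neuron_id
    V = np.array([t.value1 for t in trials], float)
    C = np.array([t.chosen for t in trials], float)

    starts = np.arange(0, ANALYSIS_END_MS - cfg.window_len_ms + 1, cfg.step_ms)
    F = _window_rates(trains, starts, cfg.window_len_ms)
    a, b = cfg.baseline_window_ms
    baseline = _window_rates(trains, np.array([a]), b - a)[:, 0]

    vc = V - V.mean()
    cc = C - C.mean()
    svv = float(vc @ vc)
    scc = float(cc @ cc)
    n = len(trials)

    # observed dR2 and fit p-values, vectorized over windows
    Fc = F - F.mean(axis=0, keepdims=True)
    syy = np.einsum("ij,ij->j", Fc, Fc)
    with np.errstate(divide="ignore", invalid="ignore"):
        r2v = np.where(syy > 0, (vc @ Fc) ** 2 / (svv * syy), 0.0) if svv > 0 else np.zeros(len(starts))
        r2c = np.where(syy > 0, (cc @ Fc) ** 2 / (scc * syy), 0.0) if scc > 0 else np.zeros(len(starts))
    r2v = np.clip(r2v, 0.0, 1.0)
    r2c = np.clip(r2c, 0.0, 1.0)

    def _fp(r2: np.ndarray) -> np.ndarray:
        with np.errstate(divide="ignore"):
            fstat = r2 * (n - 2) / np.clip(1.0 - r2, 1e-300, None)
        p = stats.f.sf(fstat, 1, n - 2)
        return np.where(syy > 0, p, 1.0)

    pv = _fp(r2v)
    pc = _fp(r2c)
    dr2 = r2v - r2c

    exceed = np.empty(len(starts), dtype=int)
    with warnings.catch_warnings():
        warnings.simplefilter("once", RuntimeWarning)
        for w, s in enumerate(starts):
            rng = substream(cfg.seed, "mc-null", nid, int(s))
            null = _null_dr2(baseline, V, C, cfg.n_shuffle, rng)
            exceed[w] = int(np.sum(dr2[w] > null))

    labels = np.array(
        [
            _label_window(dr2[w], exceed[w], cfg.n_shuffle, pv[w], pc[w], cfg.alpha)
            for w in range(len(starts))
        ]
    )
    return WindowLabelSeries(
        neuron_id=nid,
        window_starts=starts,
        labels=labels,
        dr2_obs=dr2,
        exceed_count=exceed,
        fit_p_value=pv,
        fit_p_choice=pc,
        n_shuffle=cfg.n_shuffle,
    )


def extract_segments(series: WindowLabelSeries, run_len_windows: int) -> list[SignalSegment]:
    """Maximal same-label runs of length >= run_len_windows become segments."""
    segments: list[SignalSegment] = []
    labels = series.labels
    starts = series.window_starts
    i = 0
    while i < len(labels):
        j = i
        while j + 1 < len(labels) and labels[j + 1] == labels[i]:
            j += 1
        if labels[i] in KINDS and (j - i + 1) >= run_len_windows:
            segments.append(
                SignalSegment(
                    neuron_id=series.neuron_id,
                    kind=str(labels[i]),
                    latency_ms=float(starts[i]),
                    end_ms=float(starts[j]),
                )
            )
        i = j + 1
    return segments


def signal_latencies(
    segments: Sequence[SignalSegment],
    align: str = "object_onset",
    release_times: Optional[dict[str, float]] = None,
) -> tuple[dict[str, np.ndarray], dict[str, float]]:
    """First-segment latency per neuron per kind, plus across-kind rank-sum tests.

    With ``align='button_release'`` each neuron's latency is re-referenced
    to its mean release time (``release_times[neuron_id]``).
    """
    if align not in ("object_onset", "button_release"):
        raise ParameterError(f"unknown alignment {align!r}")
    first: dict[str, dict[str, float]] = {k: {} for k in KINDS}
    for seg in segments:
        d = first[seg.kind]
        if seg.neuron_id not in d or seg.latency_ms < d[seg.neuron_id]:
            d[seg.neuron_id] = seg.latency_ms
    lat: dict[str, np.ndarray] = {}
    for kind in KINDS:
        vals = []
        for nid, t in first[kind].items():
            if align == "button_release":
                if release_times is None or nid not in release_times:
                    raise ParameterError("release_times required for release alignment")
                t = t - release_times[nid]
            vals.append(t)
        lat[kind] = np.sort(np.asarray(vals, float))
    tests: dict[str, float] = {}
    for a, b in (("value", "intermediate"), ("intermediate", "choice"), ("value", "choice")):
        if len(lat[a]) and len(lat[b]):
            tests[f"{a}_vs_{b}_p"] = float(stats.ranksums(lat[a], lat[b]).pvalue)
        else:
            tests[f"{a}_vs_{b}_p"] = np.nan
    return lat, tests


def transition_probabilities(
    segments: Sequence[SignalSegment],
) -> pd.DataFrame:
    """Order statistics of signal kinds within neurons showing >= 2 kinds.

    For each unordered kind pair (A, B), among neurons exhibiting both,
    P(A->B) is the fraction whose first A-segment precedes their first
    B-segment; latency ties contribute half to each direction (flagged in
    the ``ties`` column). The transition time is the later signal's latency.
    """
    first: dict[str, dict[str, float]] = {k: {} for k in KINDS}
    for seg in segments:
        d = first[seg.kind]
        if seg.neuron_id not in d or seg.latency_ms < d[seg.neuron_id]:
            d[seg.neuron_id] = seg.latency_ms
    rows = []
    pairs = (("value", "intermediate"), ("intermediate", "choice"), ("value", "choice"))
    for a, b in pairs:
        both = sorted(set(first[a]) & set(first[b]))
        n = len(both)
        if n == 0:
            continue
        a_first = ties = 0.0
        times_ab, times_ba = [], []
        for nid in both:
            ta, tb = first[a][nid], first[b][nid]
            if ta < tb:
                a_first += 1
                times_ab.append(tb)
            elif tb < ta:
                times_ba.append(ta)
            else:
                a_first += 0.5
                ties += 1
        rows.append(
            {
                "from": a,
                "to": b,
                "n_both": n,
                "p_forward": a_first / n,
                "p_backward": 1.0 - a_first / n,
                "ties": int(ties),
                "mean_transition_ms": float(np.mean(times_ab)) if times_ab else np.nan,
                "mean_reverse_transition_ms": float(np.mean(times_ba)) if times_ba else np.nan,
            }
        )
    return pd.DataFrame(
        rows,
        columns=[
            "from",
            "to",
            "n_both",
            "p_forward",
            "p_backward",
            "ties",
            "mean_transition_ms",
            "mean_reverse_transition_ms",
        ],
    )


class SlidingWindowSignalClassifier(BaseEstimator):
    """Population-level sliding-window signal classification.

    Fit on a spike-train list and the matching trial table; one series of
    window labels per neuron is produced, runs of qualifying windows become
    signal segments, and population latency and transition statistics are
    derived from the segments.

    Fitted attributes
    -----------------
    series_ : dict neuron_id -> WindowLabelSeries
    segments_ : list[SignalSegment]
    latencies_ : dict kind -> sorted latency array (one per neuron per kind)
    latency_tests_ : dict of pairwise rank-sum p-values
    transitions_ : DataFrame of transition probabilities
    counts_ : dict kind -> number of neurons exhibiting that signal
    """

    def __init__(
        self,
        window_len_ms: int = 150,
        step_ms: int = 1,
        run_len: int = 40,
        n_shuffle: int = 1000,
        alpha: float = 0.05,
        baseline_window_ms: tuple[float, float] = (-200.0, 0.0),
        seed: int = 0,
    ):
        self.window_len_ms = window_len_ms
        self.step_ms = step_ms
        self.run_len = run_len
        self.n_shuffle = n_shuffle
        self.alpha = alpha
        self.baseline_window_ms = baseline_window_ms
        self.seed = seed

    def _config(self) -> AnalysisConfig:
        return AnalysisConfig(
            window_len_ms=self.window_len_ms,
            step_ms=self.step_ms,
            run_len=self.run_len,
            n_shuffle=self.n_shuffle,
            alpha=self.alpha,
            baseline_window_ms=tuple(self.baseline_window_ms),
            seed=self.seed,
        )

    def fit(self, trains: Sequence[SpikeTrain], trials: Sequence[TrialRecord]):
        cfg = self._config()
        trial_map = {(t.session_id, t.trial_index): t for t in trials}
        by_neuron: dict[str, list[SpikeTrain]] = {}
        for tr in trains:
            by_neuron.setdefault(tr.neuron_id, []).append(tr)
        self.series_ = {}
        self.segments_ = []
        for nid in sorted(by_neuron):
            ntr = sorted(by_neuron[nid], key=lambda t: (t.session_id, t.trial_index))
            ntrials = [trial_map[t.trial_id] for t in ntr]
            series = classify_neuron(ntr, ntrials, cfg, neuron_id=nid)
            self.series_[nid] = series
            self.segments_.extend(extract_segments(series, cfg.run_len_windows))
        self.latencies_, self.latency_tests_ = signal_latencies(self.segments_)
        self.transitions_ = transition_probabilities(self.segments_)
        self.counts_ = {
            kind: len({s.neuron_id for s in self.segments_ if s.kind == kind})
            for kind in KINDS
        }
        return self

    def labels_frame(self) -> pd.DataFrame:
        return pd.concat(
            [s.to_frame() for s in self.series_.values()], ignore_index=True
        )

    def segments_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            [
                {
                    "neuron_id": s.neuron_id,
                    "kind": s.kind,
                    "latency_ms": s.latency_ms,
                    "end_ms": s.end_ms,
                }
                for s in self.segments_
            ],
            columns=["neuron_id", "kind", "latency_ms", "end_ms"],
        )
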