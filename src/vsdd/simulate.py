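"""Synthetic behavioral sessions, spiking neurons, and stimulation sessions.

The generator mirrors the statistical structure the analyses assume:

* six option values drawn uniformly and independently for first and second
  object;
* choice of the first object follows a logistic law in its value, with a
  weak negative carry-over from the previous trial's second-object value;
* button-release latency (present only on chosen trials) decreases linearly
  with value plus Gaussian noise, truncated positive;
* neurons are inhomogeneous Poisson processes whose rate tracks the
  (centered) option value during an early epoch and the realized choice
  during a late epoch, with a hard switch at ``t_switch_ms`` that provides
  an unambiguous ground-truth signal latency;
* stimulation sessions add a per-site logit shift on a random half of the
  trials, which moves choice mainly near the indifference value.

Defaults put the indifference point at value 4 (logit 1.2*(V-4)), latencies
around 400 - 20*V ms, ~300 trials per recording session and ~900 trials per
stimulation site, matching the scale of the behavioral sessions the analyses
are built for.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

import numpy as np
from scipy.special import expit
from scipy.stats import truncnorm

from .config import substream
from .exceptions import ParameterError
from .io import SpikeTrain, TrialRecord

__all__ = [
    "BehaviorParams",
    "NeuronParams",
    "StimParams",
    "simulate_behavior",
    "simulate_neuron",
    "simulate_stim_session",
    "simulate_population",
]

T_MIN_MS = -400.0
T_MAX_MS = 1000.0


@dataclass(frozen=True)
class BehaviorParams:
    """Generative parameters of one behavioral session."""

    beta0: float = -4.8
    beta1: float = 1.2
    beta_prev: float = -0.3
    lat_intercept_ms: float = 400.0
    lat_slope_ms: float = -20.0
    lat_sd_ms: float = 30.0
    n_trials: int = 300

    def __post_init__(self) -> None:
        if self.n_trials < 1:
            raise ParameterError("n_trials must be >= 1")
        if not self.lat_sd_ms > 0:
            raise ParameterError("lat_sd_ms must be > 0")


@dataclass(frozen=True)
class NeuronParams:
    """Rate profile of one simulated neuron.

    Rate (Hz, clipped at 0) over a trial:
    ``baseline + value_gain*(V1-3.5)*[t in value epoch] + choice_gain*C*[t in choice epoch]``
    with the value epoch ``[t_value_on_ms, t_switch_ms)`` and the choice
    epoch ``[t_switch_ms, 1000)``. Value coding is centered at 3.5 (the mean
    of a uniform draw over the six values) so the baseline equals the
    grand-mean rate.
    """

    baseline_hz: float = 10.0
    value_gain_hz: float = 4.0
    choice_gain_hz: float = 8.0
    t_value_on_ms: float = 150.0
    t_switch_ms: float = 500.0

    def __post_init__(self) -> None:
        if self.baseline_hz < 0:
            raise ParameterError("baseline_hz must be >= 0")
        if not (T_MIN_MS <= 0 <= self.t_value_on_ms < self.t_switch_ms <= T_MAX_MS):
            raise ParameterError(
                "epochs must satisfy 0 <= t_value_on_ms < t_switch_ms <= 1000"
            )


@dataclass(frozen=True)
class StimParams:
    """One stimulation site: additive logit shift on half of the trials.

    The default psychometric is steep (logit ``4*(V-4)``), reflecting the
    overtrained animals' near-deterministic choices away from the medium
    value; a fixed logit shift then moves choice almost exclusively at the
    indifference value, which is the mechanism under study.
    """

    delta_logit: float = 1.5
    n_trials: int = 900
    behavior: BehaviorParams = field(
        default_factory=lambda: BehaviorParams(
            beta0=-16.0, beta1=4.0, beta_prev=0.0, n_trials=900
        )
    )

    def __post_init__(self) -> None:
        if self.n_trials % 2 != 0:
            raise ParameterError("n_trials must be even (half of trials stimulated)")


def _draw_latencies(params: BehaviorParams, values: np.ndarray, rng) -> np.ndarray:
    mu = params.lat_intercept_ms + params.lat_slope_ms * values
    a = (0.0 - mu) / params.lat_sd_ms  # truncate at 0 from below
    return truncnorm.rvs(a, np.inf, loc=mu, scale=params.lat_sd_ms, random_state=rng)


def simulate_behavior(
    params: BehaviorParams = BehaviorParams(),
    seed: int = 0,
    session_id: str = "s1",
    *,
    stim_mask: np.ndarray | None = None,
    delta_logit: float = 0.0,
) -> list[TrialRecord]:
    """Simulate one behavioral session of the decision task.

    ``stim_mask``/``delta_logit`` support stimulation sessions: trials where
    the mask is set receive the logit shift and carry stim=1.
    """
    rng = substream(seed, "behavior", session_id)
    n = params.n_trials
    v1 = rng.integers(1, 7, size=n)
    v2 = rng.integers(1, 7, size=n)
    logit = params.beta0 + params.beta1 * v1.astype(float)
    # previous-trial second-object value; no term on trial 1
    logit[1:] += params.beta_prev * v2[:-1].astype(float)
    if stim_mask is not None:
        logit = logit + delta_logit * stim_mask.astype(float)
    chosen = (rng.random(n) < expit(logit)).astype(int)
    lats = _draw_latencies(params, v1.astype(float), rng)
    records = []
    for i in range(n):
        records.append(
            TrialRecord(
                session_id=session_id,
                trial_index=i + 1,
                value1=int(v1[i]),
                value2=int(v2[i]),
                chosen=int(chosen[i]),
                latency_ms=float(lats[i]) if chosen[i] else None,
                stim=int(stim_mask[i]) if stim_mask is not None else 0,
            )
        )
    return records


def _piecewise_rate(params: NeuronParams, value1: int, chosen: int):
    """Breakpoints and rates (Hz) of the piecewise-constant intensity."""
    edges = np.array(
        [T_MIN_MS, params.t_value_on_ms, params.t_switch_ms, T_MAX_MS]
    )
    rates = np.full(3, params.baseline_hz)
    rates[1] += params.value_gain_hz * (value1 - 3.5)
    rates[2] += params.choice_gain_hz * chosen
    return edges, np.clip(rates, 0.0, None)


def simulate_neuron(
    params: NeuronParams,
    trials: list[TrialRecord],
    seed: int = 0,
    neuron_id: str = "n1",
) -> list[SpikeTrain]:
    """Simulate inhomogeneous-Poisson spike trains over [-400, 1000) ms.

    The piecewise-constant intensity makes exact sampling trivial: a Poisson
    count per constant segment, spike times uniform within it.
    """
    rng = substream(seed, "neuron", neuron_id)
    trains = []
    for t in trials:
        edges, rates = _piecewise_rate(params, t.value1, t.chosen)
        spikes = []
        for k in range(3):
            dur_s = (edges[k + 1] - edges[k]) / 1000.0
            count = rng.poisson(rates[k] * dur_s)
            if count:
                spikes.append(rng.uniform(edges[k], edges[k + 1], size=count))
        sp = np.sort(np.concatenate(spikes)) if spikes else np.empty(0)
        trains.append(SpikeTrain(neuron_id, t.session_id, t.trial_index, sp))
    return trains


def simulate_stim_session(
    params: StimParams = StimParams(),
    seed: int = 0,
    session_id: str = "site1",
) -> list[TrialRecord]:
    """Simulate one stimulation site: logit shift on a random half of trials."""
    behavior = replace(params.behavior, n_trials=params.n_trials)
    rng = substream(seed, "stim-assignment", session_id)
    mask = np.zeros(params.n_trials, dtype=bool)
    mask[rng.permutation(params.n_trials)[: params.n_trials // 2]] = True
    return simulate_behavior(
        behavior,
        seed,
        session_id,
        stim_mask=mask,
        delta_logit=params.delta_logit,
    )


def simulate_population(
    neuron_params: list[NeuronParams],
    behavior: BehaviorParams = BehaviorParams(),
    seed: int = 0,
):
    """Simulate one session per neuron; returns (trials, trains, truth).

    Each neuron gets its own behavioral session (sessions never share
    history), mirroring single-electrode recordings where one neuron is one
    session. ``truth`` maps neuron id to its generating parameters.
    """
    all_trials: list[TrialRecord] = []
    all_trains: list[SpikeTrain] = []
    truth: dict[str, NeuronParams] = {}
    for j, np_ in enumerate(neuron_params):
        sid = f"s{j + 1}"
        nid = f"n{j + 1}"
        trials = simulate_behavior(behavior, seed, session_id=sid)
        all_trials.extend(trials)
        all_trains.extend(simulate_neuron(np_, trials, seed, neuron_id=nid))
        truth[nid] = np_
    return all_trials, all_trains, truth
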