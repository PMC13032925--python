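"""Firing-rate primitives and the motor-control comparison.

Spike density functions replace each spike with a Gaussian kernel
(sigma = 30 ms by default), normalized so that each spike contributes unit
area in seconds: a single spike peaks at 1000/(sigma*sqrt(2*pi)) spikes/s.
Windowed rates count spikes in half-open [a, b) windows.

The motor-control comparison asks whether neurons that carry a
choice-modulated signal in the decision task merely reflect the button
release: peri-release modulation (peri-release rate minus pre-onset
baseline rate) is measured in both the decision task and a simple
button-release task and compared across neurons with a paired Wilcoxon
signed-rank test, separately for positively and negatively modulated
neurons (sign taken from the decision task).
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Sequence

import numpy as np
from scipy import stats

from .config import substream
from .exceptions import ParameterError
from .io import SpikeTrain

__all__ = [
    "SDF",
    "ModulationResult",
    "compute_sdf",
    "window_rate",
    "window_counts",
    "surrogate_release_times",
    "motor_modulation_compare",
]


@dataclass
class SDF:
    """Trial-averaged spike density function on a uniform grid."""

    times_ms: np.ndarray
    rate_hz: np.ndarray
    sigma_ms: float
    n_trials: int

    def integral_spikes(self) -> float:
        """Trapezoidal integral in units of spikes per trial."""
        return float(np.trapezoid(self.rate_hz, self.times_ms / 1000.0))


@dataclass
class ModulationResult:
    neuron_id: str
    mod_decision_hz: float
    mod_motor_hz: float
    p_decision: float
    p_motor: float
    sign: str  # 'positive' | 'negative'


def compute_sdf(
    trains: Sequence[SpikeTrain] | Sequence[np.ndarray],
    grid: np.ndarray,
    sigma_ms: float = 30.0,
) -> SDF:
    """Average Gaussian-kernel SDF over trials, in spikes/s."""
    grid = np.asarray(grid, float)
    if grid.size == 0:
        raise ParameterError("empty grid")
    if len(trains) < 1:
        raise ParameterError("need at least one trial")
    spikes = [t.spikes_ms if isinstance(t, SpikeTrain) else np.asarray(t, float) for t in trains]
    all_sp = np.concatenate(spikes) if any(s.size for s in spikes) else np.empty(0)
    rate = np.zeros_like(grid)
    if all_sp.size:
        # chunk the outer difference to bound memory on long recordings
        step = max(1, int(5e6 // max(all_sp.size, 1)))
        norm = 1000.0 / (sigma_ms * np.sqrt(2.0 * np.pi))
        for i in range(0, grid.size, step):
            d = (grid[i : i + step, None] - all_sp[None, :]) / sigma_ms
            rate[i : i + step] = norm * np.exp(-0.5 * d * d).sum(axis=1)
    return SDF(times_ms=grid, rate_hz=rate / len(trains), sigma_ms=sigma_ms, n_trials=len(trains))


def window_counts(spikes_ms: np.ndarray, starts: np.ndarray, length_ms: float) -> np.ndarray:
    """Spike counts in half-open windows [s, s+length) for each start s."""
    sp = np.asarray(spikes_ms, float)
    starts = np.asarray(starts, float)
    return np.searchsorted(sp, starts + length_ms, side="left") - np.searchsorted(
        sp, starts, side="left"
    )


def window_rate(train: SpikeTrain | np.ndarray, window: tuple[float, float]) -> float:
    """Firing rate (Hz) in the half-open window [a, b)."""
    a, b = window
    if not a < b:
        raise ParameterError(f"window must satisfy a < b, got {window}")
    sp = train.spikes_ms if isinstance(train, SpikeTrain) else np.asarray(train, float)
    sp = np.sort(sp)
    count = np.searchsorted(sp, b, side="left") - np.searchsorted(sp, a, side="left")
    return float(count) / ((b - a) / 1000.0)


def surrogate_release_times(
    release_times: np.ndarray, n_unchosen: int, seed: int = 0, unit: str = ""
) -> np.ndarray:
    """Resample chosen-trial release times with replacement for unchosen trials."""
    rng = substream(seed, "surrogate-release", unit)
    release_times = np.asarray(release_times, float)
    if release_times.size == 0:
        raise ParameterError("no chosen-trial release times to resample")
    return rng.choice(release_times, size=n_unchosen, replace=True)


def _per_trial_modulation(
    trains: Sequence[SpikeTrain],
    release_times: np.ndarray,
    peri_window: tuple[float, float],
    baseline_window: tuple[float, float],
) -> np.ndarray:
    """Per-trial (peri-release rate - baseline rate), Hz.

    Peri window is release-aligned, baseline window is onset-aligned.
    """
    out = np.empty(len(trains))
    for i, tr in enumerate(trains):
        r = release_times[i]
        peri = window_rate(tr, (r + peri_window[0], r + peri_window[1]))
        base = window_rate(tr, baseline_window)
        out[i] = peri - base
    return out


def motor_modulation_compare(
    decision_trains: dict[str, Sequence[SpikeTrain]],
    motor_trains: dict[str, Sequence[SpikeTrain]],
    decision_release: dict[str, np.ndarray],
    motor_release: dict[str, np.ndarray],
    peri_window: tuple[float, float] = (-200.0, 200.0),
    baseline_window: tuple[float, float] = (-200.0, 0.0),
) -> tuple[list[ModulationResult], dict]:
    """Compare peri-release modulation between decision and motor tasks.

    Inputs map neuron id -> per-trial spike trains and per-trial release
    times (already including surrogate releases for unchosen trials).
    Neurons missing either task are excluded with a warning entry in the
    summary. Population comparison: paired two-sided Wilcoxon signed-rank
    across neurons, run separately for neurons whose decision-task
    modulation is positive and negative.
    """
    results: list[ModulationResult] = []
    skipped: list[str] = []
    for nid in sorted(decision_trains):
        if nid not in motor_trains:
            skipped.append(nid)
            continue
        mod_d = _per_trial_modulation(
            decision_trains[nid], decision_release[nid], peri_window, baseline_window
        )
        mod_m = _per_trial_modulation(
            motor_trains[nid], motor_release[nid], peri_window, baseline_window
        )

        def _p(mod: np.ndarray) -> float:
            if np.allclose(mod, 0.0) or len(mod) < 2:
                return 1.0
            return float(stats.wilcoxon(mod, alternative="two-sided").pvalue)

        md, mm = float(np.mean(mod_d)), float(np.mean(mod_m))
        results.append(
            ModulationResult(
                neuron_id=nid,
                mod_decision_hz=md,
                mod_motor_hz=mm,
                p_decision=_p(mod_d),
                p_motor=_p(mod_m),
                sign="positive" if md >= 0 else "negative",
            )
        )

    summary: dict = {"skipped_neurons": skipped}
    for sign in ("positive", "negative"):
        sub = [r for r in results if r.sign == sign]
        key = f"{sign}_p"
        if len(sub) >= 2:
            d = np.array([r.mod_decision_hz for r in sub])
            m = np.array([r.mod_motor_hz for r in sub])
            if np.allclose(d, m):
                summary[key] = 1.0
                summary[f"{sign}_stat"] = 0.0
            else:
                w = stats.wilcoxon(d, m, alternative="two-sided")
                summary[key] = float(w.pvalue)
                summary[f"{sign}_stat"] = float(w.statistic)
            summary[f"{sign}_n"] = len(sub)
        else:
            summary[key] = np.nan
            summary[f"{sign}_n"] = len(sub)
    return results, summary
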