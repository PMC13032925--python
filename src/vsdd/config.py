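"""Analysis configuration and seeded random-number substreams.

One seed in the configuration governs every stochastic stage. Each stage
derives an independent substream keyed by (stage name, unit id), so adding or
removing one neuron never perturbs another neuron's permutations.
"""

from __future__ import annotations

import zlib
from dataclasses import dataclass, field, asdict
from typing import Sequence

import numpy as np
import yaml

from .exceptions import ParameterError

__all__ = ["AnalysisConfig", "substream"]


@dataclass
class AnalysisConfig:
    """Parameters shared across the pipeline stages.

    window_len_ms / step_ms
        Sliding analysis window length and step. Windows are half-open
        ``[t, t + window_len_ms)`` labeled by their start ``t``, with 0 at
        first-object onset. The reference step is 1 ms; coarser steps trade
        temporal resolution for speed.
    run_len
        Number of consecutive qualifying windows, counted at the 1-ms
        reference step, required to call a signal (default 40, i.e. a 40-ms
        run of window starts). At a coarser step the run *duration* is
        preserved: ``ceil(run_len / step_ms)`` consecutive windows.
    n_shuffle
        Monte Carlo repetitions for shuffle/permutation nulls.
    alpha
        Two-sided significance level used throughout.
    baseline_window_ms
        Half-open pre-onset window providing baseline firing rates.
    sigma_ms
        Gaussian kernel width for spike density functions.
    ridge_lambda
        Ridge penalty applied to standardized (non-intercept) coefficients.
    """

    window_len_ms: int = 150
    step_ms: int = 1
    run_len: int = 40
    n_shuffle: int = 1000
    alpha: float = 0.05
    baseline_window_ms: tuple[float, float] = (-200.0, 0.0)
    sigma_ms: float = 30.0
    ridge_lambda: float = 1.0
    seed: int = 0

    def __post_init__(self) -> None:
        if self.window_len_ms <= 0:
            raise ParameterError("window_len_ms must be > 0")
        if self.step_ms <= 0:
            raise ParameterError("step_ms must be > 0")
        if self.run_len < 1:
            raise ParameterError("run_len must be >= 1")
        if self.n_shuffle < 100:
            raise ParameterError("n_shuffle must be >= 100")
        if not 0.0 < self.alpha < 1.0:
            raise ParameterError("alpha must lie in (0, 1)")
        a, b = self.baseline_window_ms
        if not a < b:
            raise ParameterError("baseline_window_ms must satisfy a < b")
        if self.ridge_lambda < 0:
            raise ParameterError("ridge_lambda must be >= 0")

    @property
    def run_len_windows(self) -> int:
        """Consecutive windows required at the configured step."""
        return max(1, int(np.ceil(self.run_len / self.step_ms)))

    @classmethod
    def from_yaml(cls, path) -> "AnalysisConfig":
        with open(path, "r", encoding="utf-8") as fh:
            raw = yaml.safe_load(fh) or {}
        if "baseline_window_ms" in raw:
            raw["baseline_window_ms"] = tuple(raw["baseline_window_ms"])
        return cls(**raw)

    def to_yaml(self, path) -> None:
        d = asdict(self)
        d["baseline_window_ms"] = list(d["baseline_window_ms"])
        with open(path, "w", encoding="utf-8") as fh:
            yaml.safe_dump(d, fh, sort_keys=False)


def _key_int(key) -> int:
    return zlib.crc32(str(key).encode("utf-8"))


def substream(seed: int, *keys) -> np.random.Generator:
    """Return an RNG independent across distinct ``(seed, *keys)`` tuples.

    Keys may be strings or integers (stage names, neuron ids, window starts).
    """
    entropy: Sequence[int] = [int(seed) & 0x7FFFFFFF] + [_key_int(k) for k in keys]
    return np.random.default_rng(entropy)
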