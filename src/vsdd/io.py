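"""Domain records and delimited-text readers/writers.

Trial tables and spike tables travel as plain CSV (comma, UTF-8, ``.``
decimal, mandatory header, absent values as empty fields). Times are
real-valued milliseconds with 0 at first-object onset; negative spike times
are pre-onset baseline activity.

trials.csv columns: session_id,trial_index,value1,value2,chosen,latency_ms,stim,task
spikes.csv columns: neuron_id,session_id,trial_index,spike_ms
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Iterable, Optional, Sequence

import numpy as np
import pandas as pd

from .exceptions import (
    EmptyInputError,
    InvariantError,
    ParseError,
    ReferentialError,
    SchemaError,
)

__all__ = [
    "TrialRecord",
    "SpikeTrain",
    "read_trials",
    "read_spikes",
    "write_results",
    "trials_to_frame",
    "as_trial_frame",
]

TRIAL_COLUMNS = [
    "session_id",
    "trial_index",
    "value1",
    "value2",
    "chosen",
    "latency_ms",
    "stim",
    "task",
]
SPIKE_COLUMNS = ["neuron_id", "session_id", "trial_index", "spike_ms"]

VALUES = (1, 2, 3, 4, 5, 6)


@dataclass(frozen=True)
class TrialRecord:
    """One behavioral trial.

    ``value1`` is the first-object value (1-6, six reward magnitudes),
    ``value2`` the second-object value when recorded. ``chosen`` is 1 when
    the button was released for the first object, in which case
    ``latency_ms`` holds the release latency. ``stim`` flags
    stimulation trials in causal sessions.
    """

    session_id: str
    trial_index: int
    value1: int
    value2: Optional[int] = None
    chosen: int = 0
    latency_ms: Optional[float] = None
    stim: int = 0
    task: str = "decision"

    def __post_init__(self) -> None:
        if self.value1 not in VALUES:
            raise InvariantError(f"value1 must be in 1..6, got {self.value1}")
        if self.value2 is not None and self.value2 not in VALUES:
            raise InvariantError(f"value2 must be in 1..6 or absent, got {self.value2}")
        if self.chosen not in (0, 1):
            raise InvariantError(f"chosen must be 0/1, got {self.chosen}")
        if self.stim not in (0, 1):
            raise InvariantError(f"stim must be 0/1, got {self.stim}")
        if self.task not in ("decision", "button_release"):
            raise InvariantError(f"unknown task {self.task!r}")
        if self.task == "decision":
            if self.chosen == 1 and self.latency_ms is None:
                raise InvariantError("chosen trial lacks latency_ms")
            if self.chosen == 0 and self.latency_ms is not None:
                raise InvariantError("unchosen trial carries latency_ms")
        if self.latency_ms is not None and not self.latency_ms > 0:
            raise InvariantError(f"latency_ms must be > 0, got {self.latency_ms}")


@dataclass
class SpikeTrain:
    """Spike times (ms, onset-aligned, sorted ascending) for one neuron on one trial."""

    neuron_id: str
    session_id: str
    trial_index: int
    spikes_ms: np.ndarray = field(default_factory=lambda: np.empty(0))

    def __post_init__(self) -> None:
        sp = np.asarray(self.spikes_ms, dtype=float)
        if sp.size and not np.all(np.isfinite(sp)):
            raise InvariantError(f"non-finite spike time for neuron {self.neuron_id}")
        self.spikes_ms = np.sort(sp)

    @property
    def trial_id(self) -> tuple[str, int]:
        return (self.session_id, self.trial_index)


def _opt_int(x, row: int, col: str) -> Optional[int]:
    if pd.isna(x) or x == "":
        return None
    f = float(x)
    if f != int(f):
        raise ParseError(f"row {row}: non-integer {col} value {x!r}")
    return int(f)


def read_trials(path) -> list[TrialRecord]:
    """Read and validate a trial table.

    Rows violating record invariants are rejected with their (1-based data)
    row number. Records are returned grouped by session and ordered by
    trial_index; trial_index must be strictly increasing within a session.
    """
    df = pd.read_csv(path, dtype={"session_id": str, "task": str})
    missing = [c for c in ("session_id", "trial_index", "value1", "chosen") if c not in df.columns]
    if missing:
        raise SchemaError(f"trial table missing column(s): {', '.join(missing)}")
    for c in TRIAL_COLUMNS:
        if c not in df.columns:
            df[c] = np.nan
    if len(df) == 0:
        raise EmptyInputError(f"no data rows in {path}")

    records: list[TrialRecord] = []
    for i, row in enumerate(df.itertuples(index=False), start=1):
        try:
            v2 = _opt_int(row.value2, i, "value2")
            lat = None if pd.isna(row.latency_ms) else float(row.latency_ms)
            stim = _opt_int(row.stim, i, "stim")
            task = row.task if isinstance(row.task, str) else "decision"
            rec = TrialRecord(
                session_id=str(row.session_id),
                trial_index=int(_opt_int(row.trial_index, i, "trial_index")),
                value1=int(_opt_int(row.value1, i, "value1")),
                value2=v2,
                chosen=int(_opt_int(row.chosen, i, "chosen")),
                latency_ms=lat,
                stim=0 if stim is None else stim,
                task=task,
            )
        except ParseError:
            raise
        except InvariantError as exc:
            raise InvariantError(f"row {i}: {exc}") from exc
        except (TypeError, ValueError) as exc:
            raise ParseError(f"row {i}: {exc}") from exc
        records.append(rec)

    records.sort(key=lambda r: (r.session_id, r.trial_index))
    by_session: dict[str, int] = {}
    for r in records:
        prev = by_session.get(r.session_id)
        if prev is not None and r.trial_index <= prev:
            raise InvariantError(
                f"trial_index not strictly increasing in session {r.session_id}"
            )
        by_session[r.session_id] = r.trial_index
    return records


def read_spikes(path, trials: Sequence[TrialRecord]) -> list[SpikeTrain]:
    """Read a long-format spike table into per-(neuron, trial) trains.

    Every spike must reference a trial present in ``trials``. For each
    neuron, trials of the sessions in which it fired at all are materialized
    as (possibly empty) trains, so zero-spike trials are represented.
    Unsorted input is silently sorted; output trains are sorted.
    """
    df = pd.read_csv(path, dtype={"neuron_id": str, "session_id": str})
    missing = [c for c in SPIKE_COLUMNS if c not in df.columns]
    if missing:
        raise SchemaError(f"spike table missing column(s): {', '.join(missing)}")

    trial_keys = {(t.session_id, t.trial_index) for t in trials}
    trains: list[SpikeTrain] = []
    if len(df):
        bad = [
            (s, int(i))
            for s, i in zip(df["session_id"], df["trial_index"])
            if (s, int(i)) not in trial_keys
        ]
        if bad:
            raise ReferentialError(f"spike(s) reference unknown trial(s), e.g. {bad[0]}")
        grouped = {
            (str(n), str(s)): g
            for (n, s), g in df.groupby(["neuron_id", "session_id"], sort=True)
        }
    else:
        grouped = {}
    # materialize empty trains for every trial of each neuron's session(s)
    session_trials: dict[str, list[int]] = {}
    for t in trials:
        session_trials.setdefault(t.session_id, []).append(t.trial_index)
    for (neuron, session), g in grouped.items():
        by_trial = {int(k): v["spike_ms"].to_numpy(float) for k, v in g.groupby("trial_index")}
        for idx in session_trials[session]:
            trains.append(
                SpikeTrain(neuron, session, idx, by_trial.get(idx, np.empty(0)))
            )
    return trains


def trials_to_frame(trials: Iterable[TrialRecord]) -> pd.DataFrame:
    rows = [
        dict(
            session_id=t.session_id,
            trial_index=t.trial_index,
            value1=t.value1,
            value2=np.nan if t.value2 is None else t.value2,
            chosen=t.chosen,
            latency_ms=np.nan if t.latency_ms is None else t.latency_ms,
            stim=t.stim,
            task=t.task,
        )
        for t in trials
    ]
    return pd.DataFrame(rows, columns=TRIAL_COLUMNS)


def as_trial_frame(trials) -> pd.DataFrame:
    """Coerce a sequence of TrialRecord or a DataFrame to the canonical frame."""
    if isinstance(trials, pd.DataFrame):
        return trials
    return trials_to_frame(trials)


def write_results(records, path, allow_empty: bool = False) -> None:
    """Write a result table (DataFrame or records) as CSV.

    Numeric precision is at least 6 significant digits so that read-back
    reproduces written values within formatting precision.
    """
    df = records if isinstance(records, pd.DataFrame) else pd.DataFrame(records)
    if len(df) == 0 and not allow_empty:
        raise EmptyInputError("refusing to write empty result (pass allow_empty=True)")
    df.to_csv(path, index=False, float_format="%.8g")
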