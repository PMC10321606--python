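"""Trial exclusion, event time-locking, and per-participant condition averages.

Traces of variable length are interpolated onto a lock-relative uniform grid
(one sample per nominal frame period, always containing time 0) so that
trials, participants, and conditions can be averaged and compared
timepoint-wise.  Three lock points are supported: TL1 = question offset,
TL2 = critical-word onset (or its control-word equivalent), TL3 = response
onset.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass
from typing import Iterable, Sequence

import numpy as np
import pandas as pd

from .delta_extraction import DeltaTrace
from .synthetic_data import ADMISSIBLE_PHONEMES, EXCLUDED_PHONEMES

LOCKS = ("TL1", "TL2", "TL3")

_LOCK_COLUMN = {
    "TL1": "question_offset",
    "TL2": "critical_word_onset",
    "TL3": "response_onset",
}

__all__ = [
    "LOCKS",
    "ExclusionConfig",
    "ExclusionReport",
    "Epoch",
    "ConditionAverage",
    "WindowPolicy",
    "filter_trials",
    "epoch_trace",
    "average_condition",
    "build_analysis_matrix",
]


class LockError(ValueError):
    """Raised when a lock point lies too far outside a trace's span."""


class GridMismatchError(ValueError):
    """Raised when epochs/averages do not share a common grid convention."""


class EmptyWindowError(ValueError):
    """Raised when no timepoint satisfies the analysis-window policy."""


@dataclass
class ExclusionConfig:
    """Sequential trial-exclusion rules.

    Stage 1 removes incorrect responses (including responses slower than
    ``max_rt``); stage 2 removes hesitations among the correct responses;
    stage 3 removes trials whose response starts with a phoneme that
    ultrasound picks up poorly.
    """

    max_rt: float = 5.0
    excluded_phonemes: frozenset = frozenset(EXCLUDED_PHONEMES)
    drop_incorrect: bool = True
    drop_hesitation: bool = True
    participant_subset: Sequence[int] | None = None

    def __post_init__(self) -> None:
        if self.max_rt <= 0:
            raise ValueError("max_rt must be positive")
        self.excluded_phonemes = frozenset(self.excluded_phonemes)


@dataclass
class ExclusionReport:
    """Per-stage removal counts with their stage-specific denominators."""

    n_input: int
    stages: list  # dicts: name, removed, denominator, percent
    n_kept: int

    def to_dict(self) -> dict:
        return {
            "n_input": self.n_input,
            "stages": self.stages,
            "n_kept": self.n_kept,
        }


def filter_trials(
    events: pd.DataFrame, config: ExclusionConfig | None = None
) -> tuple[pd.DataFrame, ExclusionReport]:
    """Apply the sequential exclusion rules to an events table.

    Returns the kept rows and a report whose stage percentages use the
    stage's own denominator: all trials, correct answers, and correct
    answers without hesitations, respectively.
    """
    config = config or ExclusionConfig()
    df = events
    if config.participant_subset is not None:
        df = df[df["participant_id"].isin(set(config.participant_subset))]
    n_input = len(df)

    known = set(EXCLUDED_PHONEMES) | set(ADMISSIBLE_PHONEMES) | config.excluded_phonemes
    unknown = sorted(set(df["onset_phoneme"]) - known)
    if unknown:
        warnings.warn(
            f"unknown onset phoneme labels retained: {unknown}", stacklevel=2
        )

    stages = []
    rt = df["response_onset"] - df["question_offset"]
    if config.drop_incorrect:
        bad = (~df["correct"].astype(bool)) | (rt > config.max_rt)
    else:
        bad = pd.Series(False, index=df.index)
    stages.append(_stage("incorrect_or_slow", bad, len(df)))
    df = df[~bad]

    if config.drop_hesitation:
        bad = df["hesitation"].astype(bool)
    else:
        bad = pd.Series(False, index=df.index)
    stages.append(_stage("hesitation", bad, len(df)))
    df = df[~bad]

    bad = df["onset_phoneme"].isin(config.excluded_phonemes)
    stages.append(_stage("excluded_phoneme", bad, len(df)))
    df = df[~bad]

    return df.copy(), ExclusionReport(n_input=n_input, stages=stages, n_kept=len(df))


def _stage(name: str, mask: pd.Series, denominator: int) -> dict:
    removed = int(mask.sum())
    return {
        "name": name,
        "removed": removed,
        "denominator": denominator,
        "percent": 100.0 * removed / denominator if denominator else 0.0,
    }


@dataclass
class Epoch:
    """One trial's trace interpolated onto a lock-relative uniform grid.

    The grid is ``k / frame_rate_hz`` for consecutive integers k and always
    contains k = 0 (the lock point).  ``valid`` marks grid points inside the
    trial's recorded span; ``values`` are NaN elsewhere.
    """

    lock: str
    grid_times: np.ndarray
    values: np.ndarray
    valid: np.ndarray
    k_start: int  # grid index of grid_times[0] (time = k_start / fps)
    frame_rate_hz: float
    participant_id: int
    item_id: int
    condition: str


def epoch_trace(trace: DeltaTrace, events, lock: str) -> Epoch:
    """Time-lock a trace: interpolate it onto the lock-relative grid."""
    if lock not in LOCKS:
        raise ValueError(f"unknown lock {lock!r}; expected one of {LOCKS}")
    t0 = events.lock_time(lock) if hasattr(events, "lock_time") else float(
        events[_LOCK_COLUMN[lock]]
    )
    dt = 1.0 / trace.frame_rate_hz
    rel = trace.timestamps - t0
    if rel[-1] < -dt - 1e-9 or rel[0] > dt + 1e-9:
        raise LockError(
            f"lock {lock} at {t0:.3f}s lies beyond trace span "
            f"[{trace.timestamps[0]:.3f}, {trace.timestamps[-1]:.3f}]s "
            "by more than one frame"
        )
    eps = 1e-9
    k_start = min(int(np.ceil(rel[0] / dt - eps)), 0)
    k_stop = max(int(np.floor(rel[-1] / dt + eps)), 0)
    grid = np.arange(k_start, k_stop + 1) * dt
    values = np.interp(grid, rel, trace.values)
    valid = (grid >= rel[0] - eps) & (grid <= rel[-1] + eps)
    values = np.where(valid, values, np.nan)
    return Epoch(
        lock=lock,
        grid_times=grid,
        values=values,
        valid=valid,
        k_start=k_start,
        frame_rate_hz=trace.frame_rate_hz,
        participant_id=trace.participant_id,
        item_id=trace.item_id,
        condition=trace.condition,
    )


@dataclass
class ConditionAverage:
    """Per-participant mean trace for one condition and lock, on the union
    grid of the contributing epochs, with per-timepoint trial counts."""

    participant_id: int
    condition: str
    lock: str
    grid_times: np.ndarray
    mean_values: np.ndarray  # NaN where n_trials == 0
    n_trials: np.ndarray
    k_start: int
    frame_rate_hz: float


def average_condition(epochs: Sequence[Epoch]) -> ConditionAverage:
    """Average same-participant/condition/lock epochs timepoint-wise."""
    if not epochs:
        raise ValueError("need at least one epoch")
    first = epochs[0]
    for e in epochs[1:]:
        if (
            e.lock != first.lock
            or e.participant_id != first.participant_id
            or e.condition != first.condition
        ):
            raise GridMismatchError("epochs mix locks, participants, or conditions")
        if not np.isclose(e.frame_rate_hz, first.frame_rate_hz):
            raise GridMismatchError("epochs sampled at different frame rates")
    dt = 1.0 / first.frame_rate_hz
    k_start = min(e.k_start for e in epochs)
    k_stop = max(e.k_start + len(e.grid_times) - 1 for e in epochs)
    width = k_stop - k_start + 1
    total = np.zeros(width)
    count = np.zeros(width, dtype=int)
    for e in epochs:
        lo = e.k_start - k_start
        sl = slice(lo, lo + len(e.grid_times))
        total[sl] += np.where(e.valid, e.values, 0.0)
        count[sl] += e.valid.astype(int)
    with np.errstate(invalid="ignore"):
        mean = np.where(count > 0, total / np.maximum(count, 1), np.nan)
    return ConditionAverage(
        participant_id=first.participant_id,
        condition=first.condition,
        lock=first.lock,
        grid_times=np.arange(k_start, k_stop + 1) * dt,
        mean_values=mean,
        n_trials=count,
        k_start=k_start,
        frame_rate_hz=first.frame_rate_hz,
    )


@dataclass
class WindowPolicy:
    """How the common analysis window is chosen across participants."""

    min_trials: int = 1
    clip: tuple[float, float] | None = None  # lock-relative seconds


def build_analysis_matrix(
    averages: Iterable[ConditionAverage],
    lock: str,
    policy: WindowPolicy | None = None,
) -> tuple[dict, np.ndarray]:
    """Stack per-participant averages into per-condition P x T matrices.

    The analysis window is the largest contiguous run of grid points where
    every participant x condition average has at least ``min_trials``
    contributing trials (optionally clipped to ``policy.clip``); the run
    containing time 0 is preferred.
    """
    policy = policy or WindowPolicy()
    avs = [a for a in averages if a.lock == lock]
    if not avs:
        raise EmptyWindowError(f"no averages for lock {lock}")
    participants = sorted({a.participant_id for a in avs})
    conditions = sorted({a.condition for a in avs})
    by_key = {(a.participant_id, a.condition): a for a in avs}
    for p in participants:
        for c in conditions:
            if (p, c) not in by_key:
                raise ValueError(f"participant {p} lacks a {c} average for {lock}")

    fps = avs[0].frame_rate_hz
    dt = 1.0 / fps
    k_lo = max(a.k_start for a in avs)
    k_hi = min(a.k_start + len(a.grid_times) - 1 for a in avs)
    if k_lo > k_hi:
        raise EmptyWindowError("participant windows do not overlap")
    ks = np.arange(k_lo, k_hi + 1)
    ok = np.ones(len(ks), dtype=bool)
    for a in avs:
        lo = k_lo - a.k_start
        ok &= a.n_trials[lo : lo + len(ks)] >= policy.min_trials
    if policy.clip is not None:
        times = ks * dt
        ok &= (times >= policy.clip[0] - 1e-9) & (times <= policy.clip[1] + 1e-9)
    if not ok.any():
        raise EmptyWindowError("no timepoint satisfies the window policy")

    run = _best_run(ok, zero_pos=int(np.searchsorted(ks, 0)))
    ks = ks[run]
    times = ks * dt
    matrices = {}
    for c in conditions:
        rows = []
        for p in participants:
            a = by_key[(p, c)]
            lo = ks[0] - a.k_start
            rows.append(a.mean_values[lo : lo + len(ks)])
        matrices[c] = np.vstack(rows)
    return matrices, times


def _best_run(ok: np.ndarray, zero_pos: int) -> slice:
    """Largest contiguous True run, preferring one that contains zero_pos."""
    edges = np.flatnonzero(np.diff(np.concatenate(([0], ok.view(np.int8), [0]))))
    starts, stops = edges[::2], edges[1::2]
    containing = [
        (sta, sto) for sta, sto in zip(starts, stops) if sta <= zero_pos < sto
    ]
    if containing:
        sta, sto = containing[0]
    else:
        i = int(np.argmax(stops - starts))
        sta, sto = starts[i], stops[i]
    return slice(sta, sto)
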