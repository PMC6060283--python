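"""Firing-power alarm generation from window-wise classifier labels.

The classifier emits one binary label per 5-s window.  Raising an alarm
on every preictal label would be hopelessly noisy, so labels are
regularised by counting:

* **two-step** — labels are summed over non-overlapping 2-min *short
  windows* (24 labels each); a short window whose count reaches the
  threshold ``p`` is itself called preictal; three consecutive short
  windows form a 6-min *long window*, and a long window containing at
  least ``k`` preictal shorts raises one alarm, timestamped at the long
  window's start;
* **one-step** — labels are summed directly over non-overlapping 6-min
  blocks (72 labels) against a single count threshold.

Long windows are a fixed partition into consecutive triples, not a
sliding triple, and the decision is evaluated at window end.  An
optional refractory period suppresses alarms that follow a kept alarm
too closely — without it, one sustained preictal-like stretch would be
counted as many false predictions.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import List, Optional, Sequence

import numpy as np

from .errors import ConfigurationError, ValidationError

__all__ = [
    "FPConfig",
    "AlarmSequence",
    "short_window_counts",
    "classify_short_windows",
    "two_step_alarms",
    "one_step_alarms",
    "alarms_from_labels",
]

PREICTAL_STATE, INTERICTAL_STATE = "preictal", "interictal"


@dataclass(frozen=True)
class FPConfig:
    """Firing-power configuration.

    mode : 'two_step' or 'one_step'.
    short_window_labels : labels per short window (24 = 2 min of 5-s
        windows).
    long_window_shorts : short windows per long window (3 = 6 min).
    p : count threshold per short window, 1..short_window_labels/2
        (the studied range is {1..12}).
    k : preictal short windows required per long window, two_step only.
    one_step_threshold : count threshold per 6-min block, one_step only.
    refractory_min : minutes after a kept alarm during which further
        alarms are suppressed; ``None`` disables suppression.
    """

    mode: str = "two_step"
    short_window_labels: int = 24
    long_window_shorts: int = 3
    p: int = 7
    k: int = 2
    one_step_threshold: int = 21
    refractory_min: Optional[float] = 50.0
    label_period_s: float = 5.0

    def __post_init__(self) -> None:
        if self.mode not in ("two_step", "one_step"):
            raise ConfigurationError(f"unknown FP mode {self.mode!r}")
        if not 1 <= self.p <= self.short_window_labels // 2:
            raise ConfigurationError(
                f"p={self.p} outside 1..{self.short_window_labels // 2}"
            )
        if not 1 <= self.k <= self.long_window_shorts:
            raise ConfigurationError(f"k={self.k} outside 1..{self.long_window_shorts}")
        if self.one_step_threshold < 1:
            raise ConfigurationError("one_step_threshold must be >= 1")


@dataclass
class AlarmSequence:
    """Alarm timestamps (seconds, start of the triggering window)."""

    alarm_times: np.ndarray
    config: FPConfig

    def __post_init__(self) -> None:
        self.alarm_times = np.asarray(self.alarm_times, dtype=float)
        if self.alarm_times.size and np.any(np.diff(self.alarm_times) <= 0):
            raise ValidationError("alarm times must be strictly increasing")


def _check_binary(tg: np.ndarray) -> np.ndarray:
    tg = np.asarray(tg)
    if tg.size and not np.isin(tg, (0, 1)).all():
        raise ValidationError("label stream must be binary (0/1)")
    return tg.astype(int)


def short_window_counts(tg: Sequence[int], m: int = 24) -> np.ndarray:
    """Sum labels over non-overlapping blocks of ``m``; drop the partial tail."""
    tg = _check_binary(np.asarray(tg))
    n_short = tg.size // m
    return tg[: n_short * m].reshape(n_short, m).sum(axis=1)


def classify_short_windows(num_pre: Sequence[int], p: int) -> List[str]:
    """Threshold short-window counts: count >= p means preictal."""
    if p < 1:
        raise ValidationError("p must be >= 1")
    return [PREICTAL_STATE if c >= p else INTERICTAL_STATE for c in np.asarray(num_pre)]


def _suppress_refractory(times: np.ndarray, refractory_s: Optional[float]) -> np.ndarray:
    if refractory_s is None or times.size == 0:
        return times
    kept = [times[0]]
    for t in times[1:]:
        if t - kept[-1] >= refractory_s:
            kept.append(t)
    return np.asarray(kept)


def two_step_alarms(
    states: Sequence[str],
    k: int,
    refractory_min: Optional[float] = 50.0,
    short_window_s: float = 120.0,
    long_window_shorts: int = 3,
    stream_start_s: float = 0.0,
) -> AlarmSequence:
    """k-of-3 rule over consecutive long windows of short-window states.

    States are partitioned into consecutive non-overlapping groups of
    ``long_window_shorts``; a group with >= k preictal members raises
    one alarm at the group's start time.  A trailing partial group is
    not evaluated.
    """
    if not 1 <= k <= long_window_shorts:
        raise ValidationError(f"k={k} outside 1..{long_window_shorts}")
    flags = np.asarray([s == PREICTAL_STATE for s in states], dtype=int)
    n_long = flags.size // long_window_shorts
    groups = flags[: n_long * long_window_shorts].reshape(n_long, long_window_shorts)
    fire = np.flatnonzero(groups.sum(axis=1) >= k)
    times = stream_start_s + fire * long_window_shorts * short_window_s
    times = _suppress_refractory(times, None if refractory_min is None else refractory_min * 60.0)
    cfg = FPConfig(mode="two_step", k=k, refractory_min=refractory_min)
    return AlarmSequence(times, cfg)


def one_step_alarms(
    tg: Sequence[int],
    window_labels: int = 72,
    threshold: int = 21,
    refractory_min: Optional[float] = 50.0,
    label_period_s: float = 5.0,
    stream_start_s: float = 0.0,
) -> AlarmSequence:
    """Single-window variant: one count threshold per 6-min block."""
    if threshold < 1:
        raise ValidationError("threshold must be >= 1")
    counts = short_window_counts(tg, m=window_labels)
    fire = np.flatnonzero(counts >= threshold)
    times = stream_start_s + fire * window_labels * label_period_s
    times = _suppress_refractory(times, None if refractory_min is None else refractory_min * 60.0)
    cfg = FPConfig(mode="one_step", one_step_threshold=threshold, refractory_min=refractory_min)
    return AlarmSequence(times, cfg)


def alarms_from_labels(tg: Sequence[int], cfg: FPConfig, stream_start_s: float = 0.0) -> AlarmSequence:
    """Dispatch a label stream through the configured firing-power mode."""
    if cfg.mode == "one_step":
        return one_step_alarms(
            tg,
            window_labels=cfg.short_window_labels * cfg.long_window_shorts,
            threshold=cfg.one_step_threshold,
            refractory_min=cfg.refractory_min,
            label_period_s=cfg.label_period_s,
            stream_start_s=stream_start_s,
        )
    counts = short_window_counts(tg, m=cfg.short_window_labels)
    states = classify_short_windows(counts, cfg.p)
    seq = two_step_alarms(
        states,
        k=cfg.k,
        refractory_min=cfg.refractory_min,
        short_window_s=cfg.short_window_labels * cfg.label_period_s,
        long_window_shorts=cfg.long_window_shorts,
        stream_start_s=stream_start_s,
    )
    return AlarmSequence(seq.alarm_times, cfg)
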