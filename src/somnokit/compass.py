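"""PIR-actigraphy sleep scoring (COMPASS-style).

Passive-infrared cage-top sensors summarize mouse movement as a 0-100
activity score per 10-s bin (percent of the bin spent moving).  Extended
behavioral quiescence — a run of zero-score bins lasting at least 40 s —
is scored as sleep.  Contiguous scored-sleep runs form *sleep bouts*,
summarized by count, mean, and maximum duration.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy import stats as _sstats

__all__ = [
    "ActivityTrace",
    "SleepBout",
    "BoutStats",
    "score_sleep",
    "detect_bouts",
    "bout_statistics",
    "validate_against_truth",
    "SLEEP_RUN_S",
]

#: Minimum duration of a zero-activity run that converts to sleep (seconds).
SLEEP_RUN_S = 40.0


@dataclass
class ActivityTrace:
    """Sequence of PIR activity scores on a fixed bin grid.

    Parameters
    ----------
    scores
        Activity per bin, each in [0, 100] (percent of bin spent moving).
    bin_s
        Bin width in seconds (10 s for the standard hardware).
    start_hour
        Clock hour of the first bin's left edge (fractional hours, 0-24).
    """

    scores: np.ndarray
    bin_s: float = 10.0
    start_hour: float = 7.0

    def __post_init__(self) -> None:
        self.scores = np.asarray(self.scores, dtype=float)
        if self.bin_s <= 0:
            raise ValueError("bin_s must be positive")
        if self.scores.ndim != 1:
            raise ValueError("scores must be one-dimensional")
        if self.scores.size and (
            self.scores.min() < 0 or self.scores.max() > 100
        ):
            raise ValueError("activity scores must lie in [0, 100]")

    def __len__(self) -> int:
        return self.scores.size


@dataclass(frozen=True)
class SleepBout:
    """A maximal contiguous run of scored sleep."""

    start_bin: int
    n_bins: int
    bin_s: float = 10.0

    @property
    def duration_s(self) -> float:
        return self.n_bins * self.bin_s


@dataclass(frozen=True)
class BoutStats:
    """Summary of a collection of sleep bouts."""

    bout_count: int
    mean_bout_s: float
    max_bout_s: float
    total_sleep_min: float


def _zero_runs(mask: np.ndarray) -> list[tuple[int, int]]:
    """Maximal runs of True in a boolean vector as (start, length) pairs."""
    if mask.size == 0:
        return []
    padded = np.concatenate(([False], mask, [False]))
    edges = np.flatnonzero(np.diff(padded.astype(np.int8)))
    starts, stops = edges[0::2], edges[1::2]
    return [(int(a), int(b - a)) for a, b in zip(starts, stops)]


def score_sleep(trace: ActivityTrace, strict: bool = False) -> np.ndarray:
    """Score each bin as sleep (True) or wake (False).

    A bin is sleep iff it belongs to a maximal run of consecutive
    *exactly-zero* scores whose total duration reaches 40 s — four 10-s
    bins.  Any nonzero score, however small, interrupts a run.

    Parameters
    ----------
    trace
        The activity trace.  Scores outside [0, 100] are rejected by the
        trace constructor.
    strict
        If True, require the run to *exceed* 40 s (five 10-s bins)
        instead of reaching it.

    Returns
    -------
    numpy.ndarray of bool, same length as the trace.
    """
    zero = trace.scores == 0
    sleep = np.zeros(len(trace), dtype=bool)
    for start, length in _zero_runs(zero):
        duration = length * trace.bin_s
        if (duration > SLEEP_RUN_S) if strict else (duration >= SLEEP_RUN_S):
            sleep[start : start + length] = True
    return sleep


def detect_bouts(sleep: np.ndarray, bin_s: float = 10.0) -> list[SleepBout]:
    """Identify maximal contiguous sleep runs as bouts.

    Runs are never merged across intervening wake bins.
    """
    sleep = np.asarray(sleep, dtype=bool)
    return [
        SleepBout(start_bin=s, n_bins=n, bin_s=bin_s)
        for s, n in _zero_runs(sleep)
    ]


def bout_statistics(bouts: list[SleepBout]) -> BoutStats:
    """Count, mean duration, max duration, and total sleep minutes.

    An empty bout list yields all-zero statistics.
    """
    if not bouts:
        return BoutStats(0, 0.0, 0.0, 0.0)
    durations = np.array([b.duration_s for b in bouts], dtype=float)
    return BoutStats(
        bout_count=len(bouts),
        mean_bout_s=float(durations.mean()),
        max_bout_s=float(durations.max()),
        total_sleep_min=float(durations.sum() / 60.0),
    )


def validate_against_truth(
    sleep: np.ndarray, truth: np.ndarray
) -> float:
    """Pearson correlation between scored and ground-truth sleep vectors.

    Both vectors are per-bin 0/1 indicators of equal length.  The
    correlation is undefined when either vector is constant; that case
    raises rather than returning NaN silently.
    """
    sleep = np.asarray(sleep, dtype=float)
    truth = np.asarray(truth, dtype=float)
    if sleep.shape != truth.shape:
        raise ValueError("scored and truth vectors must have equal length")
    if sleep.size < 2:
        raise ValueError("need at least two bins")
    if np.ptp(sleep) == 0 or np.ptp(truth) == 0:
        raise ValueError("Pearson r undefined for a constant vector")
    r, _ = _sstats.pearsonr(sleep, truth)
    return float(r)
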