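"""Core vigilance-state containers shared across the package.

A hypnogram is a sequence of stage labels (WAKE / NREM / REM) on a fixed
epoch grid anchored to clock time.  The standard epoch is 4 s; clock time
matters because mouse sleep is organized by the 12:12 light/dark cycle.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

__all__ = ["WAKE", "NREM", "REM", "STAGES", "LightCycle", "Hypnogram"]

WAKE, NREM, REM = 0, 1, 2
STAGES: tuple[str, ...] = ("WAKE", "NREM", "REM")
_STAGE_TO_CODE = {s: i for i, s in enumerate(STAGES)}


def stage_code(label: str) -> int:
    """Map a stage label to its integer code."""
    try:
        return _STAGE_TO_CODE[label]
    except KeyError:
        raise ValueError(f"unknown stage label {label!r}") from None


@dataclass(frozen=True)
class LightCycle:
    """Laboratory lighting schedule (clock hours).

    The default 7/19 encodes the standard 12:12 cycle with lights on
    0700-1900 h.  Zeitgeber time zero (ZT0) is lights-on.
    """

    lights_on_hour: float = 7.0
    lights_off_hour: float = 19.0

    def __post_init__(self) -> None:
        for h in (self.lights_on_hour, self.lights_off_hour):
            if not 0 <= h < 24:
                raise ValueError("clock hours must lie in [0, 24)")
        if self.lights_on_hour == self.lights_off_hour:
            raise ValueError("lights-on and lights-off hours must differ")

    def is_light(self, clock_hour):
        """True where the clock hour falls in the lights-on phase.

        Handles schedules that wrap midnight.  Accepts scalars or arrays.
        """
        h = np.asarray(clock_hour) % 24.0
        on, off = self.lights_on_hour, self.lights_off_hour
        if on < off:
            return (h >= on) & (h < off)
        return (h >= on) | (h < off)

    def zt(self, clock_hour):
        """Zeitgeber time: hours since lights-on, in [0, 24)."""
        return (np.asarray(clock_hour) - self.lights_on_hour) % 24.0


@dataclass
class Hypnogram:
    """Stage labels on a fixed epoch grid, anchored to clock time.

    Parameters
    ----------
    stages
        Integer stage codes (0 = WAKE, 1 = NREM, 2 = REM), one per epoch.
    epoch_s
        Epoch length in seconds (4 s is the scoring standard used here).
    start_hour
        Clock hour of the first epoch's left edge (fractional hours).
    """

    stages: np.ndarray
    epoch_s: float = 4.0
    start_hour: float = 7.0

    def __post_init__(self) -> None:
        stages = np.asarray(self.stages)
        if stages.dtype.kind in "US":
            stages = np.array([stage_code(s) for s in stages], dtype=np.int8)
        else:
            stages = stages.astype(np.int8)
        if stages.ndim != 1:
            raise ValueError("stages must be one-dimensional")
        if stages.size and (stages.min() < 0 or stages.max() > 2):
            raise ValueError("stage codes must be 0 (WAKE), 1 (NREM) or 2 (REM)")
        if self.epoch_s <= 0:
            raise ValueError("epoch_s must be positive")
        self.stages = stages

    def __len__(self) -> int:
        return self.stages.size

    @property
    def n_epochs(self) -> int:
        return self.stages.size

    @property
    def duration_h(self) -> float:
        return self.n_epochs * self.epoch_s / 3600.0

    @property
    def labels(self) -> np.ndarray:
        """Stage labels as strings."""
        return np.array(STAGES, dtype=object)[self.stages]

    def epoch_clock_hours(self) -> np.ndarray:
        """Clock hour (mod 24) of each epoch's left edge."""
        idx = np.arange(self.n_epochs)
        return (self.start_hour + idx * self.epoch_s / 3600.0) % 24.0

    def sleep_indicator(self) -> np.ndarray:
        """Boolean per-epoch sleep vector (NREM or REM)."""
        return self.stages != WAKE

    def stage_minutes(self) -> dict[str, float]:
        """Total minutes spent in each stage."""
        out = {}
        for code, name in enumerate(STAGES):
            out[name] = float(
                np.count_nonzero(self.stages == code) * self.epoch_s / 60.0
            )
        return out
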