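"""Circadian summaries of hypnograms and PIR sleep vectors.

The study's descriptive readouts: minutes per stage per clock hour,
12-h light/dark totals, and the drinking-water dose arithmetic
(mL/day x mg/mL scaled by body weight).
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .hypnogram import STAGES, Hypnogram, LightCycle

__all__ = [
    "HourlySummary",
    "LightDarkSummary",
    "IntakeRecord",
    "minutes_per_hour",
    "sleep_minutes_per_hour",
    "aggregate_light_dark",
    "dose_from_intake",
]


@dataclass
class HourlySummary:
    """Per-clock-hour stage minutes.

    ``table`` has one row per occupied clock hour, in recording order,
    with columns: ``hour`` (clock hour, int), ``zt`` (hours since
    lights-on when a light cycle is supplied, else NaN), one minutes
    column per stage, ``coverage_min`` (minutes of recording inside the
    hour) and ``complete`` (coverage == 60).  Partial first/last hours
    are reported, flagged incomplete.
    """

    table: pd.DataFrame
    epoch_s: float

    @property
    def minute_columns(self) -> list[str]:
        return [c for c in self.table.columns if c.endswith("_min") and c != "coverage_min"]


@dataclass
class LightDarkSummary:
    """Stage minutes per 12-h light phase and dark phase.

    ``table`` is indexed by phase ('light', 'dark') with the same minutes
    columns as the hourly summary.  Per stage, light + dark equals the
    24-h total by construction.
    """

    table: pd.DataFrame


@dataclass(frozen=True)
class IntakeRecord:
    """Daily drinking-water drug intake for one animal."""

    volume_ml_per_day: float
    concentration_mg_per_ml: float
    body_weight_g: float

    def __post_init__(self) -> None:
        if self.volume_ml_per_day < 0 or self.concentration_mg_per_ml < 0:
            raise ValueError("volume and concentration must be non-negative")
        if self.body_weight_g < 0:
            raise ValueError("body weight must be non-negative")


def _hourly_frame(
    hour_of_slot: np.ndarray,
    slot_s: float,
    minute_counts: dict[str, np.ndarray],
    light_cycle: LightCycle | None,
) -> pd.DataFrame:
    # slots (epochs or bins) are assigned to the clock hour containing
    # their left edge; the caller guarantees no slot straddles an hour.
    order = []
    seen = set()
    for h in hour_of_slot:
        if h not in seen:
            seen.add(h)
            order.append(h)
    rows = []
    for h in order:
        mask = hour_of_slot == h
        coverage = mask.sum() * slot_s / 60.0
        row = {"hour": int(h)}
        row["zt"] = float(light_cycle.zt(h)) if light_cycle else np.nan
        for name, slots in minute_counts.items():
            row[name] = float(slots[mask].sum() * slot_s / 60.0)
        row["coverage_min"] = float(coverage)
        row["complete"] = bool(abs(coverage - 60.0) < 1e-9)
        rows.append(row)
    return pd.DataFrame(rows)


def minutes_per_hour(
    hypnogram: Hypnogram, light_cycle: LightCycle | None = None
) -> HourlySummary:
    """Minutes of WAKE/NREM/REM per clock hour.

    Epochs may not straddle hour boundaries: the epoch length must divide
    3600 s and the recording must start on the epoch grid.
    """
    if 3600.0 % hypnogram.epoch_s != 0:
        raise ValueError("epoch length must divide one hour")
    offset = (hypnogram.start_hour * 3600.0) % hypnogram.epoch_s
    if offset > 1e-9 and abs(offset - hypnogram.epoch_s) > 1e-9:
        raise ValueError("recording start must align with the epoch grid")

    hours = np.floor(hypnogram.epoch_clock_hours()).astype(int)
    # distinguish repeated clock hours on recordings > 24 h by absolute hour
    abs_hours = np.floor(
        hypnogram.start_hour + np.arange(len(hypnogram)) * hypnogram.epoch_s / 3600.0
    ).astype(int)
    counts = {
        f"{name.lower()}_min": (hypnogram.stages == code).astype(float)
        for code, name in enumerate(STAGES)
    }
    frame = _hourly_frame(abs_hours, hypnogram.epoch_s, counts, light_cycle)
    frame["hour"] = frame["hour"] % 24
    if light_cycle:
        frame["zt"] = light_cycle.zt(frame["hour"].to_numpy()).astype(float)
    return HourlySummary(table=frame, epoch_s=hypnogram.epoch_s)


def sleep_minutes_per_hour(
    sleep: np.ndarray,
    bin_s: float = 10.0,
    start_hour: float = 7.0,
    light_cycle: LightCycle | None = None,
) -> HourlySummary:
    """Minutes asleep/awake per clock hour from a per-bin sleep vector."""
    sleep = np.asarray(sleep, dtype=bool)
    if 3600.0 % bin_s != 0:
        raise ValueError("bin length must divide one hour")
    abs_hours = np.floor(start_hour + np.arange(sleep.size) * bin_s / 3600.0).astype(
        int
    )
    counts = {
        "sleep_min": sleep.astype(float),
        "wake_min": (~sleep).astype(float),
    }
    frame = _hourly_frame(abs_hours, bin_s, counts, light_cycle)
    frame["hour"] = frame["hour"] % 24
    if light_cycle:
        frame["zt"] = light_cycle.zt(frame["hour"].to_numpy()).astype(float)
    return HourlySummary(table=frame, epoch_s=bin_s)


def aggregate_light_dark(
    hourly: HourlySummary, light_cycle: LightCycle | None = None
) -> LightDarkSummary:
    """Sum hourly stage minutes into 12-h light and dark totals.

    An hour belongs to the light phase when its midpoint falls within
    [lights_on, lights_off).  Partial coverage is carried through and
    flagged, never rescaled.
    """
    lc = light_cycle or LightCycle()
    t = hourly.table
    is_light = lc.is_light(t["hour"].to_numpy() + 0.5)
    cols = hourly.minute_columns + ["coverage_min"]
    phase_hours = lc.is_light(np.arange(24) + 0.5)
    expected = {"light": 60.0 * phase_hours.sum(), "dark": 60.0 * (~phase_hours).sum()}
    rows = {}
    for phase, mask in (("light", is_light), ("dark", ~is_light)):
        sub = t.loc[mask, cols].sum()
        rows[phase] = {c: float(sub[c]) for c in cols}
        rows[phase]["complete"] = bool(
            abs(sub["coverage_min"] - expected[phase]) < 1e-9
        )
    return LightDarkSummary(table=pd.DataFrame(rows).T.loc[["light", "dark"]])


def dose_from_intake(record: IntakeRecord) -> float:
    """Daily drug dose in mg per kg body weight.

    dose = volume (mL/day) x concentration (mg/mL) / weight (kg).
    E.g. 5 mL/day of 0.5 mg/mL in a 25 g mouse is 100 mg/kg/day.
    """
    if record.body_weight_g <= 0:
        raise ValueError("body weight must be positive to compute a dose")
    mg_per_day = record.volume_ml_per_day * record.concentration_mg_per_ml
    return mg_per_day / (record.body_weight_g / 1000.0)
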