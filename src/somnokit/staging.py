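"""Rule-based EEG/EMG sleep staging at 4-s epochs.

Each epoch is labeled WAKE, NREM, or REM from two kinds of evidence:

* how much of the epoch is *dominated* by each EEG frequency band —
  operationalized as the fraction of short sub-windows (0.5 s by default)
  whose spectral peak falls in the band; and
* whether the epoch's EMG amplitude is high (muscle tone, wake) or low
  (atonia, sleep), relative to a threshold calibrated per recording.

The rules, applied in fixed order:

1. WAKE  — fast (>12 Hz) dominance more than 10% of the time AND high EMG;
2. NREM  — delta (0.5-4 Hz) dominance more than 30% of the time AND fast
   dominance less than 10% AND low EMG;
3. REM   — 5-10 Hz dominance more than 20% of the time AND low EMG;
4. otherwise the fallback stage (WAKE by default).
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np

from .hypnogram import Hypnogram, stage_code

__all__ = [
    "StagingRules",
    "EpochFeatures",
    "compute_epoch_features",
    "calibrate_emg_threshold",
    "stage_epoch",
    "stage_recording",
]


@dataclass(frozen=True)
class StagingRules:
    """Band definitions and dominance thresholds for the staging rules.

    Bands are (low, high) in Hz; the fast band is open-ended
    (high = inf, membership is strictly above the low edge, matching
    "greater than 12 Hz").  Delta and theta membership is inclusive of
    both edges.  ``subwindow_s`` sets the dominance resolution;
    sub-window spectra are zero-padded to ``pad_s`` so the peak can be
    located on a finer frequency grid than a raw 0.5-s window allows.
    """

    epoch_s: float = 4.0
    fast_band: tuple[float, float] = (12.0, math.inf)
    delta_band: tuple[float, float] = (0.5, 4.0)
    theta_band: tuple[float, float] = (5.0, 10.0)
    wake_fast_frac: float = 0.10
    nrem_delta_frac: float = 0.30
    nrem_fast_frac_max: float = 0.10
    rem_theta_frac: float = 0.20
    subwindow_s: float = 0.5
    pad_s: float = 2.0
    fallback: str = "WAKE"

    def __post_init__(self) -> None:
        for frac in (
            self.wake_fast_frac,
            self.nrem_delta_frac,
            self.nrem_fast_frac_max,
            self.rem_theta_frac,
        ):
            if not 0.0 < frac < 1.0:
                raise ValueError("dominance fractions must lie in (0, 1)")
        n_sub = self.epoch_s / self.subwindow_s
        if abs(n_sub - round(n_sub)) > 1e-9:
            raise ValueError("subwindow_s must divide epoch_s")
        if self.pad_s < self.subwindow_s:
            raise ValueError("pad_s must be at least subwindow_s")
        for lo, hi in (self.fast_band, self.delta_band, self.theta_band):
            if lo < 0 or hi <= lo:
                raise ValueError("bands must satisfy 0 <= low < high")
        stage_code(self.fallback)  # validates the label

    @property
    def n_subwindows(self) -> int:
        return round(self.epoch_s / self.subwindow_s)


@dataclass(frozen=True)
class EpochFeatures:
    """Per-epoch staging evidence.

    frac_* are the fractions of sub-windows whose dominant frequency
    falls in the corresponding band; they sum to at most 1 (a sub-window
    can dominate in at most one band, or in none — e.g. silence or a
    peak in the 4-5 Hz or 10-12 Hz gaps).
    """

    frac_fast: float
    frac_delta: float
    frac_theta: float
    emg_rms: float
    emg_high: bool

    def __post_init__(self) -> None:
        for f in (self.frac_fast, self.frac_delta, self.frac_theta):
            if not 0.0 <= f <= 1.0:
                raise ValueError("band fractions must lie in [0, 1]")
        if self.frac_fast + self.frac_delta + self.frac_theta > 1.0 + 1e-9:
            raise ValueError("band fractions must sum to at most 1")
        if self.emg_rms < 0:
            raise ValueError("emg_rms must be non-negative")


def _in_band(freq: np.ndarray, band: tuple[float, float]) -> np.ndarray:
    lo, hi = band
    if math.isinf(hi):
        return freq > lo
    return (freq >= lo) & (freq <= hi)


def dominant_frequencies(
    eeg: np.ndarray, fs: float, rules: StagingRules
) -> np.ndarray:
    """Dominant frequency of each sub-window of one epoch.

    Each sub-window is mean-removed, Hann-tapered, zero-padded to
    ``pad_s``, and the peak of the magnitude spectrum (DC excluded) is
    reported.  A silent (all-zero) sub-window has no dominant frequency
    and yields NaN.
    """
    spw = round(fs * rules.subwindow_s)
    windows = np.asarray(eeg, dtype=float).reshape(rules.n_subwindows, spw)
    windows = windows - windows.mean(axis=1, keepdims=True)
    windows = windows * np.hanning(spw)
    n_fft = round(fs * rules.pad_s)
    mag = np.abs(np.fft.rfft(windows, n=n_fft, axis=1))
    mag[:, 0] = 0.0  # DC never dominates
    freqs = np.fft.rfftfreq(n_fft, d=1.0 / fs)
    peak = freqs[mag.argmax(axis=1)]
    peak[mag.max(axis=1) == 0.0] = np.nan
    return peak


def compute_epoch_features(
    eeg: np.ndarray,
    emg: np.ndarray,
    fs: float,
    rules: StagingRules | None = None,
    emg_threshold: float = math.inf,
) -> EpochFeatures:
    """Band-dominance fractions and EMG amplitude for one epoch.

    Parameters
    ----------
    eeg, emg
        Sample arrays of length ``fs * epoch_s``.
    fs
        Sampling rate in Hz.
    rules
        Band definitions; defaults apply.
    emg_threshold
        Calibrated RMS threshold; ``emg_high`` is True strictly above it.
        The default (+inf) classifies every epoch as low-EMG.
    """
    rules = rules or StagingRules()
    n_expected = fs * rules.epoch_s
    if abs(n_expected - round(n_expected)) > 1e-9:
        raise ValueError("fs * epoch_s must be an integer number of samples")
    n_expected = round(n_expected)
    eeg = np.asarray(eeg, dtype=float)
    emg = np.asarray(emg, dtype=float)
    if eeg.size != n_expected or emg.size != n_expected:
        raise ValueError(
            f"expected {n_expected} samples per channel, "
            f"got EEG {eeg.size}, EMG {emg.size}"
        )
    if fs / 2.0 <= rules.fast_band[0]:
        raise ValueError("sampling rate cannot resolve the fast band")

    peaks = dominant_frequencies(eeg, fs, rules)
    valid = ~np.isnan(peaks)
    n = rules.n_subwindows
    frac_fast = float(np.count_nonzero(_in_band(peaks[valid], rules.fast_band)) / n)
    frac_delta = float(np.count_nonzero(_in_band(peaks[valid], rules.delta_band)) / n)
    frac_theta = float(np.count_nonzero(_in_band(peaks[valid], rules.theta_band)) / n)
    emg_rms = float(np.sqrt(np.mean(emg**2)))
    return EpochFeatures(
        frac_fast=frac_fast,
        frac_delta=frac_delta,
        frac_theta=frac_theta,
        emg_rms=emg_rms,
        emg_high=bool(emg_rms > emg_threshold),
    )


def calibrate_emg_threshold(emg_rms_per_epoch: np.ndarray) -> float:
    """High/low EMG threshold from a 2-means split of log RMS values.

    The optimal two-cluster partition of 1-D data is a split of the
    sorted values; it is found exactly by scanning all split points for
    the minimum within-cluster sum of squares.  The threshold is the
    midpoint of the two cluster centers, mapped back from log space.
    Degenerate input (all values within 1% relative range) returns +inf,
    classifying every epoch as low-EMG.
    """
    rms = np.asarray(emg_rms_per_epoch, dtype=float)
    if rms.size == 0:
        raise ValueError("need at least one RMS value")
    if (rms < 0).any():
        raise ValueError("RMS values must be non-negative")
    if rms.size < 2 or np.ptp(rms) <= 0.01 * rms.max():
        return math.inf

    floor = rms.max() * 1e-12
    logv = np.sort(np.log(np.maximum(rms, floor)))
    n = logv.size
    csum = np.cumsum(logv)
    csq = np.cumsum(logv**2)
    k = np.arange(1, n)  # left cluster sizes
    left_ss = csq[:-1] - csum[:-1] ** 2 / k
    right_sum = csum[-1] - csum[:-1]
    right_ss = (csq[-1] - csq[:-1]) - right_sum**2 / (n - k)
    best = int(np.argmin(left_ss + right_ss))
    lo_center = csum[best] / (best + 1)
    hi_center = (csum[-1] - csum[best]) / (n - best - 1)
    return float(np.exp(0.5 * (lo_center + hi_center)))


def stage_epoch(f: EpochFeatures, rules: StagingRules | None = None) -> str:
    """Apply the staging rules to one epoch's features.

    Precedence is fixed (WAKE, then NREM, then REM, then fallback), so
    every epoch receives exactly one label.
    """
    rules = rules or StagingRules()
    if f.frac_fast > rules.wake_fast_frac and f.emg_high:
        return "WAKE"
    if (
        f.frac_delta > rules.nrem_delta_frac
        and f.frac_fast < rules.nrem_fast_frac_max
        and not f.emg_high
    ):
        return "NREM"
    if f.frac_theta > rules.rem_theta_frac and not f.emg_high:
        return "REM"
    return rules.fallback


def _majority_smooth(codes: np.ndarray) -> np.ndarray:
    """3-epoch majority filter; endpoints kept as-is."""
    out = codes.copy()
    for i in range(1, codes.size - 1):
        window = codes[i - 1 : i + 2]
        vals, counts = np.unique(window, return_counts=True)
        if counts.max() >= 2:
            out[i] = vals[counts.argmax()]
    return out


def stage_recording(
    eeg_epochs: np.ndarray,
    emg_epochs: np.ndarray,
    fs: float,
    rules: StagingRules | None = None,
    start_hour: float = 7.0,
    smooth: bool = False,
) -> Hypnogram:
    """Stage a whole recording of per-epoch EEG/EMG arrays.

    The EMG threshold is calibrated on the full recording (2-means on
    log RMS), then every epoch is featurized and staged.  Requires at
    least 10 epochs so the calibration sees both EMG regimes.

    Parameters
    ----------
    eeg_epochs, emg_epochs
        Arrays of shape (n_epochs, fs * epoch_s).
    smooth
        Apply an optional 3-epoch majority filter (off by default).
    """
    rules = rules or StagingRules()
    eeg_epochs = np.atleast_2d(np.asarray(eeg_epochs, dtype=float))
    emg_epochs = np.atleast_2d(np.asarray(emg_epochs, dtype=float))
    if eeg_epochs.shape != emg_epochs.shape:
        raise ValueError("EEG and EMG epoch arrays must have the same shape")
    if eeg_epochs.shape[0] < 10:
        raise ValueError("need at least 10 epochs to calibrate the EMG threshold")

    rms = np.sqrt(np.mean(emg_epochs**2, axis=1))
    threshold = calibrate_emg_threshold(rms)
    labels = [
        stage_epoch(
            compute_epoch_features(e, m, fs, rules, emg_threshold=threshold),
            rules,
        )
        for e, m in zip(eeg_epochs, emg_epochs)
    ]
    codes = np.array([stage_code(s) for s in labels], dtype=np.int8)
    if smooth:
        codes = _majority_smooth(codes)
    return Hypnogram(codes, epoch_s=rules.epoch_s, start_hour=start_hour)
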