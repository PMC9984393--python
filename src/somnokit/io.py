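"""File formats: hypnogram TSV, activity CSV, and two-channel EDF.

EDF *reading* goes through mne.  No EDF-writing backend is bundled with
mne, so a minimal single-record-duration writer for the classic 16-bit
EDF layout lives here; round trips against mne's reader are covered by
the test suite.
"""

from __future__ import annotations

import datetime as _dt
from pathlib import Path

import numpy as np
import pandas as pd

from .compass import ActivityTrace
from .hypnogram import Hypnogram, stage_code

__all__ = [
    "write_hypnogram_tsv",
    "read_hypnogram_tsv",
    "write_activity_csv",
    "read_activity_csv",
    "write_edf",
    "read_edf",
]


def _clock_strings(start_hour: float, step_s: float, n: int) -> list[str]:
    start = round(start_hour * 3600.0)
    out = []
    for i in range(n):
        s = (start + round(i * step_s)) % 86400
        out.append(f"{s // 3600:02d}:{s % 3600 // 60:02d}:{s % 60:02d}")
    return out


def write_hypnogram_tsv(hypnogram: Hypnogram, path: str | Path) -> None:
    """Write a hypnogram as TSV: epoch_index, clock_time, stage."""
    df = pd.DataFrame(
        {
            "epoch_index": np.arange(hypnogram.n_epochs),
            "clock_time": _clock_strings(
                hypnogram.start_hour, hypnogram.epoch_s, hypnogram.n_epochs
            ),
            "stage": hypnogram.labels,
        }
    )
    df.to_csv(path, sep="\t", index=False)


def read_hypnogram_tsv(path: str | Path, epoch_s: float | None = None) -> Hypnogram:
    """Read a hypnogram TSV written by :func:`write_hypnogram_tsv`.

    The epoch length is inferred from the first two clock times unless
    given explicitly (required for single-epoch files).
    """
    df = pd.read_csv(path, sep="\t", dtype={"clock_time": str})
    times = [
        _dt.datetime.strptime(t, "%H:%M:%S").time() for t in df["clock_time"]
    ]
    start_hour = times[0].hour + times[0].minute / 60.0 + times[0].second / 3600.0
    if epoch_s is None:
        if len(times) < 2:
            raise ValueError("cannot infer epoch_s from a single epoch")
        t0 = times[0].hour * 3600 + times[0].minute * 60 + times[0].second
        t1 = times[1].hour * 3600 + times[1].minute * 60 + times[1].second
        epoch_s = float((t1 - t0) % 86400)
    codes = np.array([stage_code(s) for s in df["stage"]], dtype=np.int8)
    return Hypnogram(codes, epoch_s=epoch_s, start_hour=start_hour)


def write_activity_csv(trace: ActivityTrace, path: str | Path) -> None:
    """Write an activity trace as CSV: bin_index, clock_time, score.

    Scores are rounded to integers (the hardware reports integer percent
    of bin spent moving) except that small nonzero scores never round to
    zero — a zero in the file must mean true immobility.
    """
    scores = np.rint(trace.scores).astype(int)
    scores[(trace.scores > 0) & (scores == 0)] = 1
    df = pd.DataFrame(
        {
            "bin_index": np.arange(len(trace)),
            "clock_time": _clock_strings(trace.start_hour, trace.bin_s, len(trace)),
            "score": scores,
        }
    )
    df.to_csv(path, index=False)


def read_activity_csv(path: str | Path, bin_s: float | None = None) -> ActivityTrace:
    """Read an activity-trace CSV written by :func:`write_activity_csv`."""
    df = pd.read_csv(path, dtype={"clock_time": str})
    times = [
        _dt.datetime.strptime(t, "%H:%M:%S").time() for t in df["clock_time"]
    ]
    start_hour = times[0].hour + times[0].minute / 60.0 + times[0].second / 3600.0
    if bin_s is None:
        if len(times) < 2:
            raise ValueError("cannot infer bin_s from a single bin")
        t0 = times[0].hour * 3600 + times[0].minute * 60 + times[0].second
        t1 = times[1].hour * 3600 + times[1].minute * 60 + times[1].second
        bin_s = float((t1 - t0) % 86400)
    return ActivityTrace(
        scores=df["score"].to_numpy(dtype=float),
        bin_s=bin_s,
        start_hour=start_hour,
    )


def _ascii_field(value, width: int) -> bytes:
    s = str(value)[:width]
    return s.ljust(width).encode("ascii")


def write_edf(
    path: str | Path,
    eeg: np.ndarray,
    emg: np.ndarray,
    fs: float,
    start_hour: float = 7.0,
) -> None:
    """Write EEG and EMG as a two-channel 16-bit EDF file.

    Per-epoch arrays are flattened; the record duration is 1 s, so the
    sampling rate must be an integer and the total length a whole number
    of seconds.  Physical units are microvolts (uV); each channel is
    scaled to the full 16-bit digital range.
    """
    eeg = np.asarray(eeg, dtype=float).ravel()
    emg = np.asarray(emg, dtype=float).ravel()
    if eeg.size != emg.size:
        raise ValueError("EEG and EMG must have the same number of samples")
    if fs != round(fs):
        raise ValueError("sampling rate must be an integer for 1-s EDF records")
    fs = int(fs)
    if eeg.size % fs != 0:
        raise ValueError("signal length must be a whole number of seconds")
    n_records = eeg.size // fs

    channels = [("EEG", eeg), ("EMG", emg)]
    ns = len(channels)
    start = round(start_hour * 3600.0) % 86400
    header = b"".join(
        [
            _ascii_field("0", 8),
            _ascii_field("X X X X", 80),
            _ascii_field("Startdate 01-JAN-2000 X X X", 80),
            _ascii_field("01.01.00", 8),
            _ascii_field(
                f"{start // 3600:02d}.{start % 3600 // 60:02d}.{start % 60:02d}", 8
            ),
            _ascii_field(256 * (ns + 1), 8),
            _ascii_field("", 44),
            _ascii_field(n_records, 8),
            _ascii_field(1, 8),
            _ascii_field(ns, 4),
        ]
    )

    dmin, dmax = -32768, 32767
    pmins, pmaxs, digital = [], [], []
    for _, sig in channels:
        span = float(np.max(np.abs(sig))) or 1.0
        pmin, pmax = -span, span
        scale = (dmax - dmin) / (pmax - pmin)
        dig = np.clip(np.rint((sig - pmin) * scale + dmin), dmin, dmax)
        pmins.append(pmin)
        pmaxs.append(pmax)
        digital.append(dig.astype("<i2"))

    def _per_signal(values, width):
        return b"".join(_ascii_field(v, width) for v in values)

    header += _per_signal([name for name, _ in channels], 16)
    header += _per_signal([""] * ns, 80)  # transducer
    header += _per_signal(["uV"] * ns, 8)
    header += _per_signal([f"{p:.6g}" for p in pmins], 8)
    header += _per_signal([f"{p:.6g}" for p in pmaxs], 8)
    header += _per_signal([dmin] * ns, 8)
    header += _per_signal([dmax] * ns, 8)
    header += _per_signal([""] * ns, 80)  # prefiltering
    header += _per_signal([fs] * ns, 8)
    header += _per_signal([""] * ns, 32)  # reserved

    records = np.empty((n_records, ns, fs), dtype="<i2")
    for j, dig in enumerate(digital):
        records[:, j, :] = dig.reshape(n_records, fs)
    with open(path, "wb") as fh:
        fh.write(header)
        fh.write(records.tobytes())


def read_edf(path: str | Path) -> tuple[np.ndarray, np.ndarray, float]:
    """Read a two-channel (EEG, EMG) EDF file via mne.

    Returns flat sample arrays in microvolts and the sampling rate.
    """
    import mne

    raw = mne.io.read_raw_edf(str(path), preload=True, verbose="error")
    fs = float(raw.info["sfreq"])
    picks = {name.upper(): i for i, name in enumerate(raw.ch_names)}
    data = raw.get_data() * 1e6  # mne stores EEG-like channels in volts
    try:
        eeg = data[picks["EEG"]]
        emg = data[picks["EMG"]]
    except KeyError:
        raise ValueError("EDF file must contain channels named EEG and EMG")
    return eeg, emg, fs


def epochs_from_flat(
    signal: np.ndarray, fs: float, epoch_s: float = 4.0
) -> np.ndarray:
    """Reshape a flat signal into (n_epochs, fs * epoch_s), dropping a
    trailing partial epoch."""
    spe = round(fs * epoch_s)
    n = signal.size // spe
    return np.asarray(signal, dtype=float)[: n * spe].reshape(n, spe)
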