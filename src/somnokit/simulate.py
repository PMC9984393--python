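"""Synthetic hypnograms, EEG/EMG signals, and PIR activity traces.

The generator mirrors the structure of a chronic oral-morphine mouse
study: vigilance states evolve as a first-order Markov chain over
{WAKE, NREM, REM} at 4-s resolution, with a different transition matrix
per light phase and experimental condition.  Chronic morphine raises
dark-phase wake persistence; an optional intervention window (emulating
chemogenetic inhibition by a CNO injection early in the dark phase)
temporarily swaps in a replacement matrix.

Signals are tonal-plus-noise: each stage contributes a dominant sinusoid
in its characteristic EEG band (delta 0.5-4 Hz in NREM, theta 5-10 Hz in
REM, >12 Hz in wake) and EMG is Gaussian with stage-dependent RMS (atonia
in sleep).  PIR traces give zero activity in sleep bins apart from a
small false-movement probability.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np

from .compass import ActivityTrace
from .hypnogram import NREM, REM, STAGES, WAKE, Hypnogram, LightCycle

__all__ = [
    "CONTROL",
    "MORPHINE",
    "HypnogramParams",
    "SignalParams",
    "PirParams",
    "default_transition_matrices",
    "default_intervention_window",
    "stationary_distribution",
    "simulate_hypnogram",
    "synthesize_signals",
    "simulate_activity_trace",
    "bin_states",
    "true_sleep_bins",
]

CONTROL = "control"
MORPHINE = "morphine"


def _check_stochastic(m: np.ndarray, allow_wake_rem: bool) -> np.ndarray:
    m = np.asarray(m, dtype=float)
    if m.shape != (3, 3):
        raise ValueError("transition matrix must be 3x3 over (WAKE, NREM, REM)")
    if (m < 0).any():
        raise ValueError("transition probabilities must be non-negative")
    if not np.allclose(m.sum(axis=1), 1.0, atol=1e-12):
        raise ValueError("each transition-matrix row must sum to 1")
    if not allow_wake_rem and m[WAKE, REM] > 0:
        raise ValueError(
            "direct WAKE->REM transitions are disabled by default "
            "(REM is entered from NREM); pass allow_wake_rem=True to permit"
        )
    return m


def default_transition_matrices() -> dict[tuple[str, str], np.ndarray]:
    """Per-(light phase, condition) transition matrices at 4-s epochs.

    Rows/columns are ordered (WAKE, NREM, REM).  Values encode standard
    mouse sleep architecture: the light phase is sleep-dominant with NREM
    bouts of a couple of minutes and shorter REM bouts entered only from
    NREM; the dark phase is wake-dominant.  The chronic-morphine dark
    matrix raises wake persistence (longer wake runs, faster sleep exit),
    producing elevated dark-cycle wake; its light matrix equals the
    control's, since the morphine wake phenotype is dark-phase specific.
    """
    light = np.array(
        [
            [0.950, 0.050, 0.000],
            [0.015, 0.973, 0.012],
            [0.050, 0.010, 0.940],
        ]
    )
    dark_control = np.array(
        [
            [0.985, 0.015, 0.000],
            [0.030, 0.958, 0.012],
            [0.060, 0.010, 0.930],
        ]
    )
    dark_morphine = np.array(
        [
            [0.993, 0.007, 0.000],
            [0.045, 0.943, 0.012],
            [0.070, 0.010, 0.920],
        ]
    )
    return {
        ("light", CONTROL): light,
        ("dark", CONTROL): dark_control,
        ("light", MORPHINE): light.copy(),
        ("dark", MORPHINE): dark_morphine,
    }


def default_intervention_window() -> tuple[float, float, np.ndarray]:
    """Default chemogenetic-inhibition window.

    The injection is given 1 h into the dark phase (clock hour 20 under
    the 7/19 cycle) and the agonist is effective for roughly 4 h; during
    the window the chain runs under the control dark matrix, i.e. the
    inhibition cancels the morphine-specific wake elevation without
    abolishing normal dark-phase wake.
    """
    return (20.0, 4.0, default_transition_matrices()[("dark", CONTROL)])


@dataclass
class HypnogramParams:
    """Configuration for the Markov hypnogram generator.

    Parameters
    ----------
    epoch_s
        Epoch length in seconds; must divide the duration.
    duration_h
        Recording length in hours.
    transition_matrices
        Map from (light phase, condition) to a 3x3 row-stochastic matrix
        over (WAKE, NREM, REM).  Defaults to
        :func:`default_transition_matrices`.
    intervention_window
        Optional (start clock hour, duration h, replacement matrix): while
        the clock is inside the window the replacement matrix drives the
        chain regardless of phase.
    start_hour
        Clock hour at which the recording starts (default lights-on, 7).
    allow_wake_rem
        Permit direct WAKE->REM transitions (off by default; rodent REM
        is entered from NREM).
    seed
        Seed for the generator; identical seeds give identical hypnograms.
    """

    epoch_s: float = 4.0
    duration_h: float = 24.0
    transition_matrices: dict[tuple[str, str], np.ndarray] = field(
        default_factory=default_transition_matrices
    )
    intervention_window: tuple[float, float, np.ndarray] | None = None
    start_hour: float = 7.0
    allow_wake_rem: bool = False
    seed: int = 0

    def __post_init__(self) -> None:
        if self.epoch_s <= 0:
            raise ValueError("epoch_s must be positive")
        n = self.duration_h * 3600.0 / self.epoch_s
        if abs(n - round(n)) > 1e-9:
            raise ValueError("duration must be divisible by the epoch length")
        self.transition_matrices = {
            k: _check_stochastic(v, self.allow_wake_rem)
            for k, v in self.transition_matrices.items()
        }
        if self.intervention_window is not None:
            start, dur, m = self.intervention_window
            if dur <= 0:
                raise ValueError("intervention window duration must be positive")
            self.intervention_window = (
                float(start) % 24.0,
                float(dur),
                _check_stochastic(m, self.allow_wake_rem),
            )


def stationary_distribution(m: np.ndarray) -> np.ndarray:
    """Stationary distribution of a row-stochastic matrix.

    Solved as the null space of (P^T - I) with the normalization
    constraint appended; assumes a single recurrent class.
    """
    m = np.asarray(m, dtype=float)
    k = m.shape[0]
    a = np.vstack([m.T - np.eye(k), np.ones(k)])
    b = np.concatenate([np.zeros(k), [1.0]])
    pi, *_ = np.linalg.lstsq(a, b, rcond=None)
    pi = np.clip(pi, 0.0, None)
    return pi / pi.sum()


def _in_window(hour: float, start: float, dur: float) -> bool:
    return (hour - start) % 24.0 < dur


def _active_matrix(
    params: HypnogramParams,
    light_cycle: LightCycle,
    condition: str,
    clock_hour: float,
) -> np.ndarray:
    if params.intervention_window is not None:
        start, dur, m = params.intervention_window
        if _in_window(clock_hour, start, dur):
            return m
    phase = "light" if bool(light_cycle.is_light(clock_hour)) else "dark"
    try:
        return params.transition_matrices[(phase, condition)]
    except KeyError:
        raise KeyError(
            f"no transition matrix configured for phase {phase!r}, "
            f"condition {condition!r}"
        ) from None


def simulate_hypnogram(
    params: HypnogramParams,
    light_cycle: LightCycle | None = None,
    condition: str = CONTROL,
) -> Hypnogram:
    """Simulate a hypnogram from phase-switched Markov dynamics.

    At every epoch the active matrix is selected by clock time (light
    phase, condition, and intervention window if configured); the first
    state is drawn from the stationary distribution of the matrix active
    at the start.  Fully reproducible from ``params.seed``.
    """
    if light_cycle is None:
        light_cycle = LightCycle()
    n_epochs = round(params.duration_h * 3600.0 / params.epoch_s)
    rng = np.random.default_rng(params.seed)
    u = rng.random(n_epochs)

    stages = np.empty(n_epochs, dtype=np.int8)
    m0 = _active_matrix(params, light_cycle, condition, params.start_hour % 24.0)
    pi0 = stationary_distribution(m0)
    state = int(np.searchsorted(np.cumsum(pi0), u[0], side="right"))
    state = min(state, 2)
    stages[0] = state
    for i in range(1, n_epochs):
        hour = (params.start_hour + i * params.epoch_s / 3600.0) % 24.0
        m = _active_matrix(params, light_cycle, condition, hour)
        row = np.cumsum(m[state])
        state = min(int(np.searchsorted(row, u[i], side="right")), 2)
        stages[i] = state
    return Hypnogram(stages, epoch_s=params.epoch_s, start_hour=params.start_hour)


@dataclass
class SignalParams:
    """Tonal-plus-noise EEG/EMG synthesis parameters.

    Each stage's EEG is a sinusoid whose frequency is jittered uniformly
    within ``tone_hz[stage] ± tone_jitter_hz[stage]``, plus white noise.
    EMG is zero-mean Gaussian at the stage's RMS; wake EMG must exceed
    both sleep stages' (atonia).
    """

    fs: float = 256.0
    tone_hz: dict[str, float] = field(
        default_factory=lambda: {"WAKE": 18.0, "NREM": 2.25, "REM": 7.5}
    )
    tone_jitter_hz: dict[str, float] = field(
        default_factory=lambda: {"WAKE": 3.0, "NREM": 1.0, "REM": 1.5}
    )
    tone_amp: dict[str, float] = field(
        default_factory=lambda: {"WAKE": 1.0, "NREM": 1.5, "REM": 1.0}
    )
    noise_amp: float = 0.1
    emg_rms: dict[str, float] = field(
        default_factory=lambda: {"WAKE": 3.0, "NREM": 0.3, "REM": 0.2}
    )
    seed: int = 0

    def __post_init__(self) -> None:
        if self.fs < 64:
            raise ValueError("fs must be at least 64 Hz to resolve >12 Hz content")
        if self.noise_amp < 0 or any(a < 0 for a in self.tone_amp.values()):
            raise ValueError("amplitudes must be non-negative")
        if not (
            self.emg_rms["WAKE"] > self.emg_rms["NREM"]
            and self.emg_rms["WAKE"] > self.emg_rms["REM"]
        ):
            raise ValueError("wake EMG RMS must exceed both sleep stages'")


def synthesize_signals(
    hypnogram: Hypnogram, params: SignalParams
) -> tuple[np.ndarray, np.ndarray]:
    """Render per-epoch EEG and EMG sample arrays for a hypnogram.

    Returns
    -------
    (eeg, emg)
        Arrays of shape (n_epochs, fs * epoch_s).
    """
    if hypnogram.n_epochs == 0:
        raise ValueError("hypnogram must be nonempty")
    spe = params.fs * hypnogram.epoch_s
    if abs(spe - round(spe)) > 1e-9:
        raise ValueError("fs * epoch_s must be an integer number of samples")
    spe = round(spe)

    rng = np.random.default_rng(params.seed)
    t = np.arange(spe) / params.fs
    eeg = np.empty((hypnogram.n_epochs, spe))
    emg = np.empty((hypnogram.n_epochs, spe))
    for i, code in enumerate(hypnogram.stages):
        name = STAGES[code]
        f0 = params.tone_hz[name]
        jit = params.tone_jitter_hz[name]
        freq = rng.uniform(f0 - jit, f0 + jit)
        phase = rng.uniform(0.0, 2.0 * np.pi)
        eeg[i] = params.tone_amp[name] * np.sin(2.0 * np.pi * freq * t + phase)
        if params.noise_amp > 0:
            eeg[i] += params.noise_amp * rng.standard_normal(spe)
        emg[i] = params.emg_rms[name] * rng.standard_normal(spe)
    return eeg, emg


@dataclass
class PirParams:
    """PIR activity-trace synthesis parameters.

    Sleep-state bins score 0 with probability ``1 - false_movement_prob``
    and otherwise a small positive score uniform on
    [false_move_low, false_move_high].  Wake bins score uniform on
    [wake_low, wake_high] (percent of bin spent moving).
    """

    bin_s: float = 10.0
    false_movement_prob: float = 0.005
    wake_low: float = 20.0
    wake_high: float = 100.0
    false_move_low: float = 1.0
    false_move_high: float = 10.0
    seed: int = 0

    def __post_init__(self) -> None:
        if not 0.0 <= self.false_movement_prob <= 1.0:
            raise ValueError("false_movement_prob must lie in [0, 1]")
        if not (0 <= self.wake_low <= self.wake_high <= 100):
            raise ValueError("wake score range must lie within [0, 100]")
        if not (0 < self.false_move_low <= self.false_move_high <= 100):
            raise ValueError("false-movement scores must be positive and <= 100")


def bin_states(hypnogram: Hypnogram, bin_s: float = 10.0) -> np.ndarray:
    """Per-bin stage codes from an epoch-resolution hypnogram.

    Each bin takes the majority stage among overlapping epochs, weighted
    by overlap duration; any tie for the maximum goes to WAKE (the
    conservative choice — binning never invents sleep).  The epoch and
    bin grids must be commensurate.
    """
    epoch_ms = round(hypnogram.epoch_s * 1000)
    bin_ms = round(bin_s * 1000)
    tick = math.gcd(epoch_ms, bin_ms)
    per_epoch = epoch_ms // tick
    per_bin = bin_ms // tick
    ticks = np.repeat(hypnogram.stages, per_epoch)
    n_bins = ticks.size // per_bin
    ticks = ticks[: n_bins * per_bin].reshape(n_bins, per_bin)
    counts = np.stack([(ticks == c).sum(axis=1) for c in (WAKE, NREM, REM)], axis=1)
    best = counts.argmax(axis=1)
    top = counts.max(axis=1)
    tied = (counts == top[:, None]).sum(axis=1) > 1
    best[tied] = WAKE
    return best.astype(np.int8)


def true_sleep_bins(hypnogram: Hypnogram, bin_s: float = 10.0) -> np.ndarray:
    """Ground-truth per-bin sleep indicator (NREM or REM majority)."""
    return bin_states(hypnogram, bin_s) != WAKE


def simulate_activity_trace(
    hypnogram: Hypnogram, params: PirParams
) -> ActivityTrace:
    """Derive a PIR activity trace from a hypnogram.

    Reproducible from ``params.seed``.
    """
    states = bin_states(hypnogram, params.bin_s)
    n = states.size
    rng = np.random.default_rng(params.seed)
    scores = rng.uniform(params.wake_low, params.wake_high, size=n)
    asleep = states != WAKE
    false_move = rng.random(n) < params.false_movement_prob
    small = rng.uniform(params.false_move_low, params.false_move_high, size=n)
    scores[asleep] = np.where(false_move[asleep], small[asleep], 0.0)
    return ActivityTrace(
        scores=scores, bin_s=params.bin_s, start_hour=hypnogram.start_hour
    )
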