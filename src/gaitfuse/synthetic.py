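"""Synthetic multimodal gait-signal generator.

Produces labeled trials with the statistical structure the recognition
pipeline assumes: eight channels of surface EMG (envelope-modulated
broadband noise), eight tri-axial accelerometers (cadence-locked periodic
waveforms), and a vertical ground reaction force (GRF) whose upward
crossings of 15 N mark the start of each gait cycle.

Six conditions are simulated: level treadmill walking/running at 0.75,
1.25, 2.0 and 2.75 m/s, walking on a 15 % incline at 1.25 m/s, and
walking with a 10 kg load at 1.25 m/s.  Class identity is encoded in the
per-muscle activation envelopes (amplitude and timing) and in the
accelerometer harmonics; by construction acceleration amplitude tracks
speed strongly but carries only a weak load signature, so an ACC-only
feature set is informative for speed and much less so for load.

Everything is deterministic given (config, class, seed): one
``numpy.random.SeedSequence`` is spawned into independent per-channel
streams, so adding channels never perturbs existing ones.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy import signal as sps

GRF_THRESHOLD_N = 15.0

#: Canonical electrode montage: right-leg muscles, proximal to distal.
CHANNELS = ("GM", "RF", "VL", "VM", "BF", "TA", "GAS", "SOL")


@dataclass(frozen=True)
class LocomotionClass:
    """One of the six locomotion mode/task conditions.

    ``speed`` is treadmill belt speed in m/s, ``incline`` the grade in
    percent, ``load`` the carried mass in kg.  The triple uniquely
    identifies the class.
    """

    id: int
    name: str
    speed: float
    incline: float
    load: float


CLASSES: tuple[LocomotionClass, ...] = (
    LocomotionClass(0, "level-0.75", 0.75, 0.0, 0.0),
    LocomotionClass(1, "level-1.25", 1.25, 0.0, 0.0),
    LocomotionClass(2, "level-2.00", 2.00, 0.0, 0.0),
    LocomotionClass(3, "level-2.75", 2.75, 0.0, 0.0),
    LocomotionClass(4, "incline15-1.25", 1.25, 15.0, 0.0),
    LocomotionClass(5, "load10-1.25", 1.25, 0.0, 10.0),
)

CLASS_BY_NAME = {c.name: c for c in CLASSES}

#: Default cycle duration per class in ms.  Cadence rises with speed;
#: the 2.75 m/s default (660 ms -> 1320 samples at 2000 Hz) sits inside
#: the 1220-1600 sample range spanned by the reference participants.
DEFAULT_CYCLE_MS = {
    "level-0.75": 1400.0,
    "level-1.25": 1150.0,
    "level-2.00": 870.0,
    "level-2.75": 660.0,
    "incline15-1.25": 1180.0,
    "load10-1.25": 1160.0,
}

# Activation timing per muscle: envelope peak location and width as a
# fraction of the gait cycle (heel strike = phase 0).  Extensors fire in
# early stance, plantarflexors in late stance, TA around swing, BF in
# terminal swing.
_MUSCLE_PHASE = {
    "GM": 0.05, "RF": 0.12, "VL": 0.10, "VM": 0.11,
    "BF": 0.90, "TA": 0.70, "GAS": 0.45, "SOL": 0.48,
}
_MUSCLE_WIDTH = {
    "GM": 0.12, "RF": 0.10, "VL": 0.11, "VM": 0.11,
    "BF": 0.10, "TA": 0.15, "GAS": 0.09, "SOL": 0.10,
}
#: Relative size of the secondary (antiphase) activation burst; real
#: lower-limb EMG shows biphasic activity over the cycle, and the second
#: burst keeps every gait phase informative about the condition.
_SECONDARY_BURST = 0.35

# Class-conditional envelope modifiers relative to level walking at the
# same speed.  Incline preferentially recruits hip extensors and
# plantarflexors and shifts bursts slightly later in the cycle; load
# carriage raises extensor (GM, VL, VM, SOL) drive with sharper bursts.
# The per-muscle factors are deliberately non-uniform so each condition
# moves the 8-muscle activation vector in its own direction, keeping
# all six classes pairwise distinguishable in expectation.
_INCLINE_FACTOR = {"GM": 1.55, "RF": 1.05, "VL": 1.15, "VM": 1.15,
                   "BF": 1.30, "TA": 1.20, "GAS": 1.60, "SOL": 1.55}
_INCLINE_SHIFT = 0.06
_LOAD_FACTOR = {"GM": 1.35, "RF": 1.25, "VL": 1.50, "VM": 1.50,
                "BF": 1.05, "TA": 1.04, "GAS": 1.10, "SOL": 1.30}
_LOAD_WIDTH, _LOAD_SHIFT = 1.0, 0.0


class ConfigError(ValueError):
    """Invalid simulation configuration."""


@dataclass(frozen=True)
class SimulationConfig:
    """Knobs of the synthetic recording generator.

    snr_db applies per channel to EMG and ACC (signal RMS over additive
    Gaussian noise RMS, in dB).  GRF noise is additive in newtons and
    kept small so swing never jitters across the 15 N event threshold,
    matching force-plate noise floors rather than EMG-style SNR.
    """

    n_cycles: int = 5
    cycle_ms: dict = field(default_factory=lambda: dict(DEFAULT_CYCLE_MS))
    stance_fraction: float = 0.6
    snr_db: float = 30.0
    emg_rate: float = 2000.0
    grf_rate: float = 1000.0
    channels: tuple = CHANNELS
    peak_grf: float = 700.0
    grf_noise_std: float = 1.0

    def __post_init__(self):
        if self.n_cycles < 1:
            raise ConfigError("n_cycles must be >= 1")
        if self.emg_rate != 2 * self.grf_rate:
            raise ConfigError("emg_rate must be exactly twice grf_rate")
        if not 0 < self.stance_fraction < 1:
            raise ConfigError("stance_fraction must lie in (0, 1)")
        if len(self.channels) != 8:
            raise ConfigError("exactly 8 EMG/ACC channels are required")
        if any(d <= 0 for d in self.cycle_ms.values()):
            raise ConfigError("cycle durations must be positive")


@dataclass
class MultimodalRecording:
    """Synchronized sEMG/ACC (emg_rate) and GRF (grf_rate) streams.

    ``emg``: (8, T_emg) in mV; ``acc``: (8, 3, T_emg) in g;
    ``grf``: (T_grf,) vertical force in N with T_emg = 2 * T_grf.
    ``cycle_starts_truth`` holds ground-truth cycle-start indices on the
    GRF timeline.
    """

    emg: np.ndarray
    acc: np.ndarray
    grf: np.ndarray
    label: LocomotionClass
    cycle_starts_truth: np.ndarray
    emg_rate: float
    grf_rate: float
    channels: tuple = CHANNELS
    seed: int | None = None

    @property
    def n_emg_samples(self) -> int:
        return self.emg.shape[1]

    @property
    def n_grf_samples(self) -> int:
        return self.grf.shape[0]


def grf_profile(cycle_ms: float, stance_fraction: float, peak_force: float,
                rate: float = 1000.0) -> np.ndarray:
    """One gait cycle of vertical GRF starting at the upward 15 N crossing.

    The stance phase is the classic double-hump (loading response and
    push-off) shape; the swing phase is identically zero, so each cycle
    contains exactly one upward crossing of the 15 N event threshold, at
    sample 0.
    """
    if cycle_ms <= 0:
        raise ConfigError("cycle duration must be positive")
    if not 0 < stance_fraction < 1:
        raise ConfigError("stance_fraction must lie in (0, 1)")
    if peak_force <= GRF_THRESHOLD_N:
        raise ConfigError(
            f"peak_force must exceed the {GRF_THRESHOLD_N:g} N event "
            "threshold, otherwise cycle starts are undetectable")
    n = int(round(cycle_ms * rate / 1000.0))
    if n < 4:
        raise ConfigError("cycle too short for the sampling rate")
    n_stance = max(2, int(round(stance_fraction * n)))
    p = np.linspace(0.0, 1.0, n_stance)
    # sin hump with a mid-stance valley carved out -> two maxima
    shape = np.sin(np.pi * p) * (1.0 - 0.35 * np.exp(-((p - 0.5) / 0.18) ** 2))
    shape /= shape.max()
    # keep the whole stance strictly above threshold so that threshold
    # crossings happen only at stance onset/offset
    base = GRF_THRESHOLD_N + 0.05 * (peak_force - GRF_THRESHOLD_N)
    stance = base + (peak_force - base) * shape
    out = np.zeros(n)
    out[:n_stance] = stance
    return out


def emg_envelope(muscle: str, cls: LocomotionClass,
                 phase: float | np.ndarray) -> np.ndarray:
    """Activation-envelope amplitude for ``muscle`` at gait ``phase``.

    Periodic in phase with period 1; non-negative; amplitude grows
    monotonically with walking speed, and the incline and load classes
    are scaled/shifted variants of level walking at 1.25 m/s so all six
    classes have distinct mean envelopes.
    """
    if muscle not in _MUSCLE_PHASE:
        raise ConfigError(f"unknown muscle {muscle!r}; expected one of {CHANNELS}")
    phase = np.asarray(phase, dtype=float)
    if np.any(phase < 0) or np.any(phase > 1):
        raise ValueError("phase must lie in [0, 1]")
    center = _MUSCLE_PHASE[muscle]
    width = _MUSCLE_WIDTH[muscle]
    amp = 0.25 + 0.65 * cls.speed
    if cls.incline > 0:
        amp *= _INCLINE_FACTOR[muscle]
        center = (center + _INCLINE_SHIFT) % 1.0
    if cls.load > 0:
        amp *= _LOAD_FACTOR[muscle]
        width *= _LOAD_WIDTH
        center = (center + _LOAD_SHIFT) % 1.0
    def bump(c):
        d = np.abs(phase - c)
        d = np.minimum(d, 1.0 - d)  # wrapped distance keeps periodicity
        return np.exp(-0.5 * (d / width) ** 2)

    return amp * (0.15 + bump(center)
                  + _SECONDARY_BURST * bump((center + 0.5) % 1.0))


def _bandlimited_noise(rng: np.random.Generator, n: int, rate: float,
                       low: float = 15.0, high: float = 500.0) -> np.ndarray:
    """Unit-variance Gaussian noise bandlimited to the EMG passband."""
    x = rng.standard_normal(n)
    sos = sps.butter(4, [low, high], btype="bandpass", fs=rate, output="sos")
    y = sps.sosfiltfilt(sos, x)
    return y / y.std()


def _acc_waveform(sensor_idx: int, axis: int, phase: np.ndarray,
                  cls: LocomotionClass) -> np.ndarray:
    """Deterministic cadence-locked acceleration for one sensor axis (g)."""
    amp = 0.5 + 1.0 * cls.speed
    if cls.incline > 0:
        amp *= 1.06
    if cls.load > 0:
        amp *= 1.03  # deliberately faint load signature
    # fixed per-sensor/axis harmonic mix so sensors are distinguishable
    y = np.zeros_like(phase)
    for h in (1, 2, 3):
        a_h = 1.0 / h * (1.0 + 0.15 * np.sin(1.7 * sensor_idx + 2.3 * axis + h))
        shift = 0.35 * h if cls.incline > 0 else 0.0
        y += a_h * np.cos(2 * np.pi * h * phase
                          + 0.9 * sensor_idx + 1.3 * axis + shift)
    return amp * 0.3 * y


def generate_recording(config: SimulationConfig, cls: LocomotionClass,
                       seed: int) -> MultimodalRecording:
    """Generate one labeled trial of ``config.n_cycles`` gait cycles.

    sEMG = per-muscle activation envelope x bandlimited Gaussian carrier
    plus sensor noise at ``config.snr_db``; ACC = cadence-locked harmonic
    waveforms plus noise at the same SNR; GRF = concatenated stance/swing
    profiles plus a small force-plate noise floor (clipped at 0 N).
    Bit-identical output for identical (config, class, seed).
    """
    if cls.name not in config.cycle_ms:
        raise ConfigError(f"no cycle duration configured for class {cls.name!r}")
    dur_ms = config.cycle_ms[cls.name]
    n_grf_cycle = int(round(dur_ms * config.grf_rate / 1000.0))
    n_emg_cycle = 2 * n_grf_cycle
    n_cycles = config.n_cycles

    ss = np.random.SeedSequence([int(seed) & 0x7FFFFFFF, cls.id])
    emg_ss, acc_ss, grf_ss = ss.spawn(3)
    emg_streams = [np.random.default_rng(s) for s in emg_ss.spawn(8)]
    acc_streams = [np.random.default_rng(s) for s in acc_ss.spawn(8)]
    grf_rng = np.random.default_rng(grf_ss)

    phase_cycle = np.arange(n_emg_cycle) / n_emg_cycle
    phase = np.tile(phase_cycle, n_cycles)
    n_emg = n_emg_cycle * n_cycles
    noise_lin = 10.0 ** (-config.snr_db / 20.0)

    emg = np.empty((8, n_emg))
    for i, muscle in enumerate(config.channels):
        env = emg_envelope(muscle, cls, phase)
        carrier = _bandlimited_noise(emg_streams[i], n_emg, config.emg_rate)
        clean = 0.05 * env * carrier  # mV scale
        noise = emg_streams[i].standard_normal(n_emg)
        emg[i] = clean + _rms(clean) * noise_lin * noise

    acc = np.empty((8, 3, n_emg))
    for i in range(8):
        for ax in range(3):
            clean = _acc_waveform(i, ax, phase, cls)
            noise = acc_streams[i].standard_normal(n_emg)
            acc[i, ax] = clean + _rms(clean) * noise_lin * noise

    cycle = grf_profile(dur_ms, config.stance_fraction, config.peak_grf,
                        rate=config.grf_rate)
    grf = np.tile(cycle, n_cycles)
    if config.grf_noise_std > 0:
        grf = np.clip(grf + config.grf_noise_std
                      * grf_rng.standard_normal(grf.size), 0.0, None)
    starts = np.arange(n_cycles) * n_grf_cycle

    return MultimodalRecording(
        emg=emg, acc=acc, grf=grf, label=cls,
        cycle_starts_truth=starts,
        emg_rate=config.emg_rate, grf_rate=config.grf_rate,
        channels=tuple(config.channels), seed=int(seed))


def _rms(x: np.ndarray) -> float:
    return float(np.sqrt(np.mean(np.square(x))))


def make_dataset(config: SimulationConfig, seed: int,
                 classes: tuple[LocomotionClass, ...] = CLASSES
                 ) -> list[MultimodalRecording]:
    """One trial per locomotion class, each sub-seeded from ``seed``."""
    return [generate_recording(config, cls, seed) for cls in classes]
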