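"""Windowed time-domain feature extraction and feature-matrix assembly.

The myoelectric features are the standard time-domain set: root mean
square (RMS), mean absolute value (MAV), waveform length (WL), slope
sign changes (SSC) and zero crossings (ZC); accelerometers contribute
the per-axis window mean (ACC, 3 values per sensor).  Fifteen named
feature sets combine them; per-channel dimensionality ranges from 1
(single EMG feature) to 8 (all five EMG features plus ACC).

Column layout is channels-major, components-minor: for each of the 8
channels, that channel's components in the set's declared order, with
ACC expanding to (x, y, z).  The layout is fixed so saved matrices are
portable.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np

from .segmentation import GaitCycle, WindowScheme, enumerate_windows
from .synthetic import MultimodalRecording

_AXES = ("x", "y", "z")


def rms(window: np.ndarray) -> float:
    """Root mean square, sqrt(mean(x^2))."""
    x = _as_window(window, 1)
    return float(np.sqrt(np.mean(np.square(x))))


def mav(window: np.ndarray) -> float:
    """Mean absolute value."""
    x = _as_window(window, 1)
    return float(np.mean(np.abs(x)))


def wl(window: np.ndarray) -> float:
    """Waveform length: total variation sum |x[i+1] - x[i]|."""
    x = _as_window(window, 2)
    return float(np.sum(np.abs(np.diff(x))))


def zc(window: np.ndarray, eps: float = 0.0) -> int:
    """Zero crossings: sign changes between consecutive samples whose
    amplitude step is at least ``eps`` (deadband, default none)."""
    x = _as_window(window, 2)
    sign_change = np.sign(x[:-1]) != np.sign(x[1:])
    big_enough = np.abs(np.diff(x)) >= eps
    return int(np.count_nonzero(sign_change & big_enough))


def ssc(window: np.ndarray, eps: float = 0.0) -> int:
    """Slope sign changes: interior samples i where the product
    (x[i] - x[i-1]) * (x[i] - x[i+1]) is at least ``eps``."""
    x = _as_window(window, 3)
    prod = (x[1:-1] - x[:-2]) * (x[1:-1] - x[2:])
    return int(np.count_nonzero(prod >= eps))


def acc_mean(window: np.ndarray) -> np.ndarray:
    """Per-axis arithmetic mean of a (3, W) centered-ACC window."""
    x = np.asarray(window, dtype=float)
    if x.ndim != 2 or x.shape[0] != 3 or x.shape[1] == 0:
        raise ValueError("expected a non-empty (3, W) accelerometer window")
    return x.mean(axis=1)


def _as_window(window, min_len: int) -> np.ndarray:
    x = np.asarray(window, dtype=float)
    if x.ndim != 1:
        raise ValueError("expected a 1-D window")
    if x.size < min_len:
        raise ValueError(f"window needs at least {min_len} samples")
    return x


@dataclass(frozen=True)
class FeatureSetSpec:
    """A named combination of per-channel features.

    ``components`` are drawn from {RMS, MAV, WL, SSC, ZC, ACC}; ACC
    contributes 3 dimensions per channel, each EMG feature 1.
    """

    name: str
    components: tuple

    @property
    def dim_per_channel(self) -> int:
        return sum(3 if c == "ACC" else 1 for c in self.components)

    def column_names(self, channels) -> list[str]:
        names = []
        for ch in channels:
            for comp in self.components:
                if comp == "ACC":
                    names.extend(f"acc_{ch}_{ax}" for ax in _AXES)
                else:
                    names.append(f"{comp.lower()}_{ch}")
        return names


def _spec(name, *components):
    return FeatureSetSpec(name, tuple(components))


#: The fifteen evaluated feature sets.  "EMG" is all five time-domain
#: EMG features; "ALL" (a.k.a. E/A) adds the accelerometer means.
FEATURE_SETS: dict[str, FeatureSetSpec] = {s.name: s for s in (
    _spec("ACC", "ACC"),
    _spec("RMS", "RMS"),
    _spec("MAV", "MAV"),
    _spec("WL", "WL"),
    _spec("SSC", "SSC"),
    _spec("ZC", "ZC"),
    _spec("R/M", "RMS", "MAV"),
    _spec("R/W", "RMS", "WL"),
    _spec("M/W", "MAV", "WL"),
    _spec("R/M/W", "RMS", "MAV", "WL"),
    _spec("R/W/A", "RMS", "WL", "ACC"),
    _spec("R/M/W/S", "RMS", "MAV", "WL", "SSC"),
    _spec("R/M/W/A", "RMS", "MAV", "WL", "ACC"),
    _spec("EMG", "RMS", "MAV", "WL", "SSC", "ZC"),
    _spec("ALL", "RMS", "MAV", "WL", "SSC", "ZC", "ACC"),
)}

#: Alternate name used for the all-features set in accuracy tables.
FEATURE_SET_ALIASES = {"E/A": "ALL"}


def get_feature_set(name: str) -> FeatureSetSpec:
    key = FEATURE_SET_ALIASES.get(name, name)
    try:
        return FEATURE_SETS[key]
    except KeyError:
        raise KeyError(
            f"unknown feature set {name!r}; choose from "
            f"{sorted(FEATURE_SETS)}") from None


def feature_dimension(spec: FeatureSetSpec | str, n_channels: int) -> int:
    """Total feature-vector dimensionality for ``n_channels`` channels."""
    if isinstance(spec, str):
        spec = get_feature_set(spec)
    if n_channels < 1:
        raise ValueError("need at least one channel")
    return spec.dim_per_channel * n_channels


@dataclass
class FeatureMatrix:
    """Windows x features table with per-window bookkeeping.

    Rows are ordered by window start; ``labels`` carry the trial's class
    id, ``cycle_ids`` index the gait cycle each window came from and
    ``trial_ids`` distinguish concatenated trials.
    """

    values: np.ndarray
    labels: np.ndarray
    window_starts: np.ndarray
    cycle_ids: np.ndarray
    spec: FeatureSetSpec
    channels: tuple
    trial_ids: np.ndarray = None
    column_names: list = field(default_factory=list)

    def __post_init__(self):
        if self.trial_ids is None:
            self.trial_ids = np.zeros(len(self.labels), dtype=int)
        if not self.column_names:
            self.column_names = self.spec.column_names(self.channels)
        if not np.all(np.isfinite(self.values)):
            raise ValueError("feature matrix contains non-finite entries")

    @property
    def n_windows(self) -> int:
        return self.values.shape[0]

    def select_rows(self, idx) -> "FeatureMatrix":
        return FeatureMatrix(
            values=self.values[idx], labels=self.labels[idx],
            window_starts=self.window_starts[idx],
            cycle_ids=self.cycle_ids[idx], spec=self.spec,
            channels=self.channels, trial_ids=self.trial_ids[idx],
            column_names=list(self.column_names))


def extract_features(rec: MultimodalRecording, cycles: list[GaitCycle],
                     scheme: WindowScheme,
                     spec: FeatureSetSpec | str = "R/W/A",
                     eps_zc: float = 0.0, eps_ssc: float = 0.0
                     ) -> FeatureMatrix:
    """One feature row per analysis window of a preprocessed trial.

    ``rec`` must already be filtered/centered; EMG features see the
    bandpassed EMG and ACC means see the centered accelerations.  Raises
    if no cycle is long enough for a single window.
    """
    if isinstance(spec, str):
        spec = get_feature_set(spec)
    rows, starts, cyc_ids = [], [], []
    for ci, cycle in enumerate(cycles):
        for s in enumerate_windows(cycle, scheme):
            rows.append(_window_row(rec, int(s), scheme.length, spec,
                                    eps_zc, eps_ssc))
            starts.append(int(s))
            cyc_ids.append(ci)
    if not rows:
        raise ValueError(
            "no valid analysis windows: every cycle is shorter than the "
            f"window length {scheme.length}")
    values = np.vstack(rows)
    n = values.shape[0]
    return FeatureMatrix(
        values=values,
        labels=np.full(n, rec.label.id, dtype=int),
        window_starts=np.asarray(starts, dtype=int),
        cycle_ids=np.asarray(cyc_ids, dtype=int),
        spec=spec, channels=rec.channels)


def _window_row(rec, start, length, spec, eps_zc, eps_ssc) -> np.ndarray:
    stop = start + length
    out = []
    for i in range(len(rec.channels)):
        for comp in spec.components:
            if comp == "ACC":
                out.extend(acc_mean(rec.acc[i, :, start:stop]))
            elif comp == "RMS":
                out.append(rms(rec.emg[i, start:stop]))
            elif comp == "MAV":
                out.append(mav(rec.emg[i, start:stop]))
            elif comp == "WL":
                out.append(wl(rec.emg[i, start:stop]))
            elif comp == "SSC":
                out.append(ssc(rec.emg[i, start:stop], eps_ssc))
            elif comp == "ZC":
                out.append(zc(rec.emg[i, start:stop], eps_zc))
            else:  # pragma: no cover - specs are validated at build time
                raise ValueError(f"unknown component {comp!r}")
    return np.asarray(out, dtype=float)


def downsample_by_two(matrix: FeatureMatrix) -> FeatureMatrix:
    """Keep every second row (0, 2, 4, ...), aligning the decision rate
    with the half-rate GRF timeline.  Pure decimation, no averaging."""
    if matrix.n_windows == 0:
        return matrix
    return matrix.select_rows(np.arange(0, matrix.n_windows, 2))


def normalize01(matrix: FeatureMatrix, fit_rows: np.ndarray | None = None,
                clip: bool = False):
    """Min-max scale each column to [0, 1].

    Column minima/maxima are estimated on ``fit_rows`` (default: all
    rows) and applied everywhere, so when fit on training rows only the
    transform is leakage-safe; held-out rows may then fall outside
    [0, 1] and are clipped only if ``clip`` is set.  Constant columns
    map to 0 with a warning.

    Returns (normalized matrix, mins, maxs).
    """
    if fit_rows is None:
        fit_rows = np.arange(matrix.n_windows)
    fit_rows = np.asarray(fit_rows)
    if fit_rows.size == 0:
        raise ValueError("fit_rows must be non-empty")
    sub = matrix.values[fit_rows]
    mins = sub.min(axis=0)
    maxs = sub.max(axis=0)
    out = apply_normalization(matrix, mins, maxs, clip=clip, warn=True)
    return out, mins, maxs


def apply_normalization(matrix: FeatureMatrix, mins: np.ndarray,
                        maxs: np.ndarray, clip: bool = False,
                        warn: bool = False) -> FeatureMatrix:
    """Apply previously fitted per-column (min, max) bounds."""
    span = maxs - mins
    constant = span == 0
    if warn and np.any(constant):
        warnings.warn(
            f"{int(constant.sum())} constant feature column(s) mapped to 0",
            stacklevel=2)
    safe = np.where(constant, 1.0, span)
    values = (matrix.values - mins) / safe
    values[:, constant] = 0.0
    if clip:
        values = np.clip(values, 0.0, 1.0)
    out = matrix.select_rows(np.arange(matrix.n_windows))
    out.values = values
    return out


def concat_feature_matrices(mats: list[FeatureMatrix]) -> FeatureMatrix:
    """Stack per-trial matrices, tagging rows with their trial index."""
    if not mats:
        raise ValueError("nothing to concatenate")
    first = mats[0]
    for m in mats[1:]:
        if m.spec.name != first.spec.name or m.channels != first.channels:
            raise ValueError("matrices use different specs or channels")
    return FeatureMatrix(
        values=np.vstack([m.values for m in mats]),
        labels=np.concatenate([m.labels for m in mats]),
        window_starts=np.concatenate([m.window_starts for m in mats]),
        cycle_ids=np.concatenate([m.cycle_ids for m in mats]),
        spec=first.spec, channels=first.channels,
        trial_ids=np.concatenate(
            [np.full(m.n_windows, t, dtype=int) for t, m in enumerate(mats)]),
        column_names=list(first.column_names))
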