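"""Gait-cycle detection from GRF and overlapping analysis-window layout.

A gait cycle runs from one heel strike to the next; a heel strike is the
first sample at which the (filtered) vertical GRF rises above 15 N.
Analysis windows of length W advanced by increment I are laid out on the
2000 Hz EMG timeline and confined within a single cycle, so a cycle of L
EMG samples yields floor((L - W) / I) + 1 classification decisions.

Conventions: 0-based indices, half-open windows [start, start + W).
The GRF timeline runs at half the EMG rate; ``grf_index_for_window``
maps EMG indices down with a floor.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np

from .synthetic import GRF_THRESHOLD_N

WINDOW_LENGTH_RANGE = (30, 200)   # samples at 2000 Hz (15-100 ms)
WINDOW_INCREMENT_RANGE = (10, 60)  # samples at 2000 Hz (5-30 ms)


@dataclass(frozen=True)
class GaitCycle:
    """One heel-strike-to-heel-strike interval on both timelines."""

    start_grf: int
    end_grf: int

    def __post_init__(self):
        if self.end_grf <= self.start_grf:
            raise ValueError("cycle end must come after its start")

    @property
    def start_emg(self) -> int:
        return 2 * self.start_grf

    @property
    def end_emg(self) -> int:
        return 2 * self.end_grf

    @property
    def duration_grf(self) -> int:
        return self.end_grf - self.start_grf

    @property
    def duration_emg(self) -> int:
        return self.end_emg - self.start_emg


@dataclass(frozen=True)
class WindowScheme:
    """Sliding-window layout: length W and increment I in EMG samples.

    Defaults to the validated grids W in [30, 200], I in [10, 60]; pass
    ``validate=False`` to explore outside them.
    """

    length: int = 170
    increment: int = 20
    validate: bool = True

    def __post_init__(self):
        if self.increment <= 0 or self.length <= 0:
            raise ValueError("window length and increment must be positive")
        if self.length < self.increment:
            raise ValueError("window length must be >= increment")
        if self.validate:
            lo, hi = WINDOW_LENGTH_RANGE
            if not lo <= self.length <= hi:
                raise ValueError(
                    f"window length {self.length} outside [{lo}, {hi}]")
            lo, hi = WINDOW_INCREMENT_RANGE
            if not lo <= self.increment <= hi:
                raise ValueError(
                    f"window increment {self.increment} outside [{lo}, {hi}]")

    @property
    def length_ms(self) -> float:
        return self.length / 2.0  # 2000 Hz EMG timeline

    @property
    def increment_ms(self) -> float:
        return self.increment / 2.0


def detect_cycle_starts(grf: np.ndarray,
                        threshold: float = GRF_THRESHOLD_N,
                        hysteresis: bool = True) -> np.ndarray:
    """Indices of upward threshold crossings of the vertical GRF.

    A start is a sample i with grf[i] > threshold and grf[i-1] <=
    threshold (i = 0 counts if grf[0] > threshold).  With ``hysteresis``
    (default) the detector re-arms only after the force has dropped back
    below the threshold, which is implicit in the crossing definition but
    made explicit as a state machine so a re-arm margin could be added.
    """
    grf = np.asarray(grf, dtype=float)
    if threshold <= 0:
        raise ValueError("threshold must be positive")
    if grf.size == 0:
        return np.empty(0, dtype=int)
    above = grf > threshold
    if hysteresis:
        starts = []
        armed = True
        for i, a in enumerate(above):
            if a and armed:
                starts.append(i)
                armed = False
            elif not a:
                armed = True
        return np.asarray(starts, dtype=int)
    crossings = np.flatnonzero(above[1:] & ~above[:-1]) + 1
    if above[0]:
        crossings = np.concatenate(([0], crossings))
    return crossings


def cycles_from_starts(starts: np.ndarray, n_grf: int | None = None,
                       include_final: bool = True) -> list[GaitCycle]:
    """Build GaitCycle objects from consecutive detected starts.

    With n consecutive starts this yields n - 1 complete cycles; if
    ``include_final`` and the total GRF length is given, the tail from
    the last start to the end of the recording is kept as a final cycle
    (the synthetic generator ends trials exactly on a cycle boundary).
    """
    starts = np.asarray(starts, dtype=int)
    cycles = [GaitCycle(int(a), int(b)) for a, b in zip(starts, starts[1:])]
    if include_final and n_grf is not None and starts.size:
        last = int(starts[-1])
        if n_grf > last:
            cycles.append(GaitCycle(last, int(n_grf)))
    return cycles


def count_windows(cycle_len: int, length: int, increment: int) -> int:
    """Number of whole analysis windows that fit in a cycle of ``cycle_len``
    EMG samples: floor((L - W) / I) + 1, or 0 (with a warning) if L < W."""
    if length <= 0 or increment <= 0:
        raise ValueError("window length and increment must be positive")
    if cycle_len < length:
        warnings.warn(
            f"cycle of {cycle_len} samples shorter than window {length}; "
            "no decisions in this cycle", stacklevel=2)
        return 0
    return (cycle_len - length) // increment + 1


def enumerate_windows(cycle: GaitCycle, scheme: WindowScheme) -> np.ndarray:
    """EMG-timeline start indices of every window fully inside ``cycle``."""
    n = count_windows(cycle.duration_emg, scheme.length, scheme.increment)
    return cycle.start_emg + scheme.increment * np.arange(n, dtype=int)


def grf_index_for_window(start_emg: int) -> int:
    """Map an EMG-timeline index to the GRF timeline (rate ratio 2, floor)."""
    if start_emg < 0:
        raise ValueError("sample index must be non-negative")
    return int(start_emg) // 2


def segment_recording(rec, threshold: float = GRF_THRESHOLD_N,
                      prefiltered: bool = False) -> list[GaitCycle]:
    """Detect cycles on a trial's (lowpassed) GRF stream.

    Set ``prefiltered`` when ``rec.grf`` has already been through the
    12 Hz lowpass to avoid filtering twice.
    """
    from .preprocess import filter_grf

    grf = rec.grf if prefiltered else filter_grf(rec.grf, rec.grf_rate)
    starts = detect_cycle_starts(grf, threshold=threshold)
    return cycles_from_starts(starts, n_grf=rec.n_grf_samples)
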