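"""Continuous decision streams, latency accounting, and assistive torque.

Every analysis window yields one class decision; within a gait cycle of
L EMG samples a window of length W stepped by I produces
floor((L - W) / I) + 1 decisions, so the mean interval between
decisions — the decision delay an exoskeleton controller experiences —
is the cycle duration divided by the decision count.  The latency
budget for the controller is 15 ms between decisions, which constrains
the usable window increment: at the reference per-cycle decision counts
only increments of 10 and 20 samples stay under budget.

A decision also selects an assistive ankle-torque profile: a sum of
Gaussian bumps over the gait cycle, scaled to 0.2 times the biological
ankle torque so the device assists rather than replaces the muscle.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np

from .segmentation import count_windows

#: Controller latency budget between consecutive decisions (ms),
#: leaving headroom for hardware/data-transfer delays.
DELAY_BUDGET_MS = 15.0

#: Scale of assistive torque relative to biological ankle torque.
TORQUE_SCALE = 0.2

#: Reference per-participant decision counts per gait cycle at the
#: fastest condition with window 140 / increment 10.  Used for latency
#: budgeting: the minimum across participants gives the worst-case
#: (largest) decision delay a deployed system must tolerate.
REFERENCE_COUNTS_I10 = {
    "P1": 119, "P2": 139, "P3": 109, "P4": 125,
    "P5": 147, "P6": 143, "P7": 133,
}


def cycle_length_from_count(n_decisions: int, length: int = 140,
                            increment: int = 10) -> int:
    """Invert the decision-count formula: the (minimal) cycle length in
    EMG samples that yields ``n_decisions`` windows,
    L = (N - 1) * I + W."""
    if n_decisions < 1:
        raise ValueError("need at least one decision")
    return (n_decisions - 1) * increment + length


@dataclass
class DecisionStream:
    """Time-ordered per-window class decisions over one trial.

    ``timestamps_emg`` are the EMG-timeline indices of each window's END
    sample — a decision cannot precede the data it is computed from —
    strictly increasing in steps of the window increment within a cycle.
    """

    timestamps_emg: np.ndarray
    predictions: np.ndarray
    cycle_ids: np.ndarray
    emg_rate: float = 2000.0

    @property
    def n_decisions(self) -> int:
        return self.predictions.size

    @property
    def times_ms(self) -> np.ndarray:
        return 1000.0 * self.timestamps_emg / self.emg_rate

    def per_cycle_counts(self) -> dict[int, int]:
        ids, counts = np.unique(self.cycle_ids, return_counts=True)
        return dict(zip(ids.tolist(), counts.tolist()))

    def majority_class(self) -> dict[int, int]:
        """Per-cycle majority vote (ties broken by lowest class id)."""
        out = {}
        for ci in np.unique(self.cycle_ids):
            preds = self.predictions[self.cycle_ids == ci]
            vals, counts = np.unique(preds, return_counts=True)
            out[int(ci)] = int(vals[np.argmax(counts)])
        return out


def stream_decisions(matrix, model, window_length: int) -> DecisionStream:
    """Predict every window of a normalized FeatureMatrix in time order.

    ``model`` is a fitted classifier (as returned by
    ``recognition.train_and_classify``).  The decision timestamp is the
    window's end index, ``start + window_length`` (causality: a decision
    cannot precede its data).  An empty matrix yields an empty stream
    with a warning.
    """
    if matrix.n_windows == 0:
        warnings.warn("no analysis windows; empty decision stream",
                      stacklevel=2)
        return DecisionStream(np.empty(0, int), np.empty(0, int),
                              np.empty(0, int))
    order = np.argsort(matrix.window_starts, kind="stable")
    m = matrix.select_rows(order)
    pred = model.predict(m.values)
    return DecisionStream(
        timestamps_emg=m.window_starts + int(window_length),
        predictions=np.asarray(pred, dtype=int),
        cycle_ids=m.cycle_ids)


def decision_delay(cycle_duration_ms: float, n_decisions: int) -> float:
    """Mean time between decisions: cycle duration / decision count (ms)."""
    if n_decisions < 1:
        raise ValueError("decision delay undefined for zero decisions")
    if cycle_duration_ms <= 0:
        raise ValueError("cycle duration must be positive")
    return cycle_duration_ms / n_decisions


def min_decisions_across_subjects(counts) -> int:
    """Worst case (minimum) per-cycle decision count across subjects."""
    counts = list(counts)
    if not counts:
        raise ValueError("no counts supplied")
    return int(min(counts))


def delay_table(cycle_duration_ms: float = 641.0,
                counts_i10: dict[str, int] | None = None,
                length: int = 140,
                increments=(10, 20, 30, 40, 50, 60)) -> dict[int, dict]:
    """Worst-case decision delay per window increment.

    From each subject's decision count at increment 10, reconstruct the
    cycle length L = (N - 1) * 10 + W, recount the windows at every
    increment, take the across-subject minimum and convert to a delay
    using ``cycle_duration_ms``.  The cycle duration is an explicit
    argument: it is a property of the gait being budgeted for, not of
    the windowing arithmetic.
    """
    if counts_i10 is None:
        counts_i10 = REFERENCE_COUNTS_I10
    lengths = {s: cycle_length_from_count(n, length, 10)
               for s, n in counts_i10.items()}
    out = {}
    for inc in increments:
        per_subject = {s: count_windows(L, length, inc)
                       for s, L in lengths.items()}
        n_min = min_decisions_across_subjects(per_subject.values())
        out[inc] = {
            "counts": per_subject,
            "min_count": n_min,
            "delay_ms": decision_delay(cycle_duration_ms, n_min),
            "within_budget": decision_delay(cycle_duration_ms, n_min)
            <= DELAY_BUDGET_MS,
        }
    return out


@dataclass(frozen=True)
class GaussianComponent:
    """One torque bump: amplitude (N*m), center and width (% gait cycle)."""

    amplitude: float
    center: float
    width: float

    def __post_init__(self):
        if self.width <= 0:
            raise ValueError("width must be positive")
        if self.amplitude < 0:
            raise ValueError("amplitude must be non-negative")


@dataclass(frozen=True)
class TorqueProfile:
    """Assistive ankle-torque curve for one class: 0.2 x a Gaussian fit
    of the biological torque over the gait cycle (phase in %)."""

    class_id: int
    components: tuple
    scale: float = TORQUE_SCALE

    def torque(self, phase) -> np.ndarray:
        phase = np.asarray(phase, dtype=float)
        if np.any(phase < 0) or np.any(phase > 100):
            raise ValueError("phase must lie in [0, 100] % of the cycle")
        y = np.zeros_like(phase, dtype=float)
        for c in self.components:
            y += c.amplitude * np.exp(-0.5 * ((phase - c.center) / c.width) ** 2)
        return self.scale * y


def default_torque_profiles() -> dict[int, TorqueProfile]:
    """Synthetic per-class profiles: a dominant push-off peak near 50 %
    of the cycle whose biological amplitude grows with speed, incline
    and load, plus a small early-stance dorsiflexion bump."""
    biological_peak = {0: 55.0, 1: 75.0, 2: 100.0, 3: 130.0, 4: 95.0, 5: 90.0}
    profiles = {}
    for cid, amp in biological_peak.items():
        profiles[cid] = TorqueProfile(cid, (
            GaussianComponent(amp, 48.0, 9.0),
            GaussianComponent(0.08 * amp, 8.0, 5.0),
        ))
    return profiles


def torque_for_decision(class_id: int, phase: float,
                        profiles: dict[int, TorqueProfile] | None = None
                        ) -> float:
    """Assistive torque (N*m) commanded for a decision at ``phase`` %."""
    if profiles is None:
        profiles = default_torque_profiles()
    if class_id not in profiles:
        raise KeyError(f"no torque profile registered for class {class_id}")
    return float(profiles[class_id].torque(phase))
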