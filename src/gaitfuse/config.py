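"""Pipeline configuration and end-to-end orchestration.

``PipelineConfig`` gathers every tunable of the pipeline — simulation,
filters, windowing, feature set, classifier, muscle group, seed — into
one YAML-serializable object validated against the supported grids.
``run_pipeline`` executes the whole chain (simulate -> preprocess ->
segment -> featurize -> downsample -> normalize -> classify -> decision
stream) and writes its result tables under ``output_dir``.

The default operating point is the selected configuration of the study
design: SVM, the RMS/WL/ACC feature set, window length 170 and
increment 20.
"""

from __future__ import annotations

import logging
import time
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import yaml

from . import io as gio
from .features import FEATURE_SET_ALIASES, FEATURE_SETS, normalize01
from .preprocess import EMG_FILTER, GRF_FILTER, FilterSpec
from .recognition import (ClassifierSpec, MUSCLE_GROUPS, build_feature_dataset,
                          muscle_group_subset, split_train_test,
                          train_and_classify)
from .segmentation import WindowScheme
from .stream import default_torque_profiles, stream_decisions
from .synthetic import CLASSES, SimulationConfig, make_dataset

log = logging.getLogger("gaitfuse")

_KNOWN_KEYS = {"simulation", "filters", "window", "feature_set",
               "classifier", "muscle_group", "normalization", "seed",
               "output_dir"}


class ConfigValidationError(ValueError):
    pass


@dataclass
class PipelineConfig:
    simulation: SimulationConfig = field(default_factory=SimulationConfig)
    emg_filter: FilterSpec = EMG_FILTER
    grf_filter: FilterSpec = GRF_FILTER
    scheme: WindowScheme = field(default_factory=WindowScheme)  # 170 / 20
    feature_set: str = "R/W/A"
    classifier: ClassifierSpec = field(default_factory=ClassifierSpec)
    muscle_group: str = "All"
    normalization: str = "train"
    seed: int = 0
    output_dir: str = "gaitfuse_out"

    def __post_init__(self):
        name = FEATURE_SET_ALIASES.get(self.feature_set, self.feature_set)
        if name not in FEATURE_SETS:
            raise ConfigValidationError(
                f"feature_set {self.feature_set!r} not one of "
                f"{sorted(FEATURE_SETS)}")
        self.feature_set = name
        if self.muscle_group not in MUSCLE_GROUPS:
            raise ConfigValidationError(
                f"muscle_group {self.muscle_group!r} not one of "
                f"{sorted(MUSCLE_GROUPS)}")
        if self.normalization not in ("train", "all"):
            raise ConfigValidationError(
                "normalization must be 'train' or 'all'")

    def to_dict(self) -> dict:
        sim = self.simulation
        return {
            "simulation": {
                "n_cycles": sim.n_cycles,
                "cycle_ms": {k: float(v) for k, v in sim.cycle_ms.items()},
                "stance_fraction": sim.stance_fraction,
                "snr_db": sim.snr_db,
                "emg_rate": sim.emg_rate,
                "grf_rate": sim.grf_rate,
                "peak_grf": sim.peak_grf,
                "grf_noise_std": sim.grf_noise_std,
            },
            "filters": {"emg": self.emg_filter.to_dict(),
                        "grf": self.grf_filter.to_dict()},
            "window": {"length": self.scheme.length,
                       "increment": self.scheme.increment},
            "feature_set": self.feature_set,
            "classifier": {"algo": self.classifier.algo,
                           "hyperparameters": dict(
                               self.classifier.hyperparameters),
                           "cv_folds": self.classifier.cv_folds},
            "muscle_group": self.muscle_group,
            "normalization": self.normalization,
            "seed": self.seed,
            "output_dir": self.output_dir,
        }

    @classmethod
    def from_dict(cls, d: dict) -> "PipelineConfig":
        unknown = set(d) - _KNOWN_KEYS
        if unknown:
            raise ConfigValidationError(
                f"unknown config keys {sorted(unknown)}; "
                f"valid keys are {sorted(_KNOWN_KEYS)}")
        kwargs = {}
        if "simulation" in d:
            kwargs["simulation"] = SimulationConfig(**d["simulation"])
        filt = d.get("filters", {})
        if "emg" in filt:
            kwargs["emg_filter"] = FilterSpec.from_dict(filt["emg"])
        if "grf" in filt:
            kwargs["grf_filter"] = FilterSpec.from_dict(filt["grf"])
        if "window" in d:
            try:
                kwargs["scheme"] = WindowScheme(
                    int(d["window"]["length"]),
                    int(d["window"]["increment"]))
            except ValueError as e:
                raise ConfigValidationError(f"window: {e}") from e
        for key in ("feature_set", "muscle_group", "normalization",
                    "seed", "output_dir"):
            if key in d:
                kwargs[key] = d[key]
        if "classifier" in d:
            kwargs["classifier"] = ClassifierSpec(**d["classifier"])
        return cls(**kwargs)


def save_config(config: PipelineConfig, path) -> None:
    Path(path).write_text(yaml.safe_dump(config.to_dict(), sort_keys=False))


def load_config(path) -> PipelineConfig:
    """Load and validate a YAML pipeline configuration."""
    d = yaml.safe_load(Path(path).read_text())
    if not isinstance(d, dict):
        raise ConfigValidationError("config file must contain a mapping")
    return PipelineConfig.from_dict(d)


def run_pipeline(config: PipelineConfig,
                 recordings=None) -> dict:
    """Execute the full recognition chain and write the report bundle.

    If ``recordings`` is None a synthetic dataset (one trial per class)
    is generated from ``config.simulation`` and ``config.seed``.  Writes
    the normalized feature matrix, confusion matrix, per-class accuracy
    table, the test-trial decision streams with assistive torques, and
    a run log into ``config.output_dir``.  Returns a report dict.
    """
    out = Path(config.output_dir)
    out.mkdir(parents=True, exist_ok=True)
    t0 = time.time()
    timings = {}

    if recordings is None:
        log.info("simulating %d trials (seed=%d)", len(CLASSES), config.seed)
        recordings = make_dataset(config.simulation, config.seed)
    timings["simulate_s"] = time.time() - t0

    t1 = time.time()
    matrix = build_feature_dataset(recordings, config.scheme,
                                   config.feature_set)
    if config.muscle_group != "All":
        matrix = muscle_group_subset(matrix, config.muscle_group)
    train_rows, test_rows = split_train_test(matrix)
    fit_rows = train_rows if config.normalization == "train" else None
    matrix, mins, maxs = normalize01(matrix, fit_rows=fit_rows)
    timings["features_s"] = time.time() - t1

    t2 = time.time()
    train = matrix.select_rows(train_rows)
    test = matrix.select_rows(test_rows)
    cm, model = train_and_classify(train, test, config.classifier,
                                   seed=config.seed)
    timings["train_s"] = time.time() - t2

    class_names = {c.id: c.name for c in CLASSES}
    gio.save_feature_matrix(matrix, out / "features.tsv")
    gio.save_confusion(cm, class_names, out / "confusion.tsv")
    gio.save_table(
        [{"class": class_names[c], "accuracy_pct": a}
         for c, a in zip(cm.class_ids, cm.per_class_accuracy)],
        out / "per_class_accuracy.tsv")

    profiles = default_torque_profiles()
    stream = stream_decisions(test, model, config.scheme.length)
    phases = _stream_phases(test)
    torques = [profiles[int(p)].torque(ph)
               for p, ph in zip(stream.predictions, phases)]
    gio.save_decision_stream(stream, out / "decision_stream.tsv",
                             class_names=class_names, torques=torques)

    report = {
        "accuracy_pct": cm.accuracy,
        "n_train_windows": int(train_rows.size),
        "n_test_windows": int(test_rows.size),
        "n_decisions": stream.n_decisions,
        "seed": config.seed,
        "timings": timings,
    }
    (out / "run_log.txt").write_text(
        "\n".join(f"{k}: {v}" for k, v in report.items()) + "\n")
    save_config(config, out / "config.yaml")
    log.info("pipeline finished: accuracy %.2f%%", cm.accuracy)
    return report


def _stream_phases(matrix) -> np.ndarray:
    """Approximate each window's phase (%) within its gait cycle."""
    phases = np.zeros(matrix.n_windows)
    key = matrix.trial_ids * 10_000 + matrix.cycle_ids
    for k in np.unique(key):
        rows = np.flatnonzero(key == k)
        starts = matrix.window_starts[rows].astype(float)
        span = starts.max() - starts.min()
        if span > 0:
            phases[rows] = 100.0 * (starts - starts.min()) / span
    return phases
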