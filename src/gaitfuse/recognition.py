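"""Train/test protocol, classifiers, and the four parameter studies.

The protocol is within-subject: for each trial the final gait cycle is
held out for testing and the preceding four cycles train the model.
Four classifiers are supported — SVM (RBF, with a small inner
cross-validated grid over C), KNN, QDA and decision tree — through
scikit-learn.  Parameter studies sweep the classifier, the 15 feature
sets, window length (30-200 samples) and increment (10-60 samples), and
the muscle-group robustness subsets; Kruskal-Wallis rank ANOVA compares
accuracy distributions across settings, appropriate because the EMG
feature values are not normally distributed.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy import stats
from sklearn.discriminant_analysis import QuadraticDiscriminantAnalysis
from sklearn.model_selection import GridSearchCV, StratifiedKFold
from sklearn.neighbors import KNeighborsClassifier
from sklearn.svm import SVC
from sklearn.tree import DecisionTreeClassifier

from .features import (FEATURE_SETS, FeatureMatrix, FeatureSetSpec,
                       concat_feature_matrices, downsample_by_two,
                       extract_features, normalize01)
from .preprocess import preprocess_recording
from .segmentation import WindowScheme, segment_recording
from .synthetic import CHANNELS, MultimodalRecording

ALGORITHMS = ("SVM", "KNN", "QDA", "DT")

#: Functional muscle groupings for the robustness study.
MUSCLE_GROUPS: dict[str, tuple] = {
    "Gluteus": ("GM",),
    "Thigh": ("RF", "VL", "VM", "BF"),
    "Calf": ("TA", "GAS", "SOL"),
    "Anterior Thigh": ("RF", "VL", "VM"),
    "Posterior Calf": ("GAS", "SOL"),
    "All": CHANNELS,
}

WINDOW_LENGTH_GRID = (30, 50, 70, 90, 110, 130, 150, 170, 200)
WINDOW_INCREMENT_GRID = (10, 20, 30, 40, 50, 60)


@dataclass(frozen=True)
class SplitSpec:
    """Per-trial cycle split: held-out test cycles vs training cycles."""

    train_cycles: tuple
    test_cycles: tuple

    def __post_init__(self):
        if set(self.train_cycles) & set(self.test_cycles):
            raise ValueError("train and test cycles overlap")


@dataclass(frozen=True)
class ClassifierSpec:
    """Which algorithm to fit and with what hyperparameters.

    Unspecified hyperparameters fall back to documented defaults:
    RBF-SVM with an inner CV grid over C; KNN k=5; QDA with a small
    covariance regularizer; unrestricted decision tree.
    """

    algo: str = "SVM"
    hyperparameters: dict = field(default_factory=dict)
    cv_folds: int = 5

    def __post_init__(self):
        if self.algo not in ALGORITHMS:
            raise ValueError(f"algo must be one of {ALGORITHMS}")
        if self.cv_folds < 2:
            raise ValueError("cv_folds must be >= 2")


@dataclass
class ConfusionMatrix:
    """6x6 confusion counts (rows true, columns predicted) plus accuracy."""

    counts: np.ndarray
    class_ids: np.ndarray

    @property
    def total(self) -> int:
        return int(self.counts.sum())

    @property
    def accuracy(self) -> float:
        """Overall accuracy in percent (100 - classification error)."""
        return 100.0 * np.trace(self.counts) / self.total

    @property
    def per_class_accuracy(self) -> np.ndarray:
        row = self.counts.sum(axis=1)
        with np.errstate(invalid="ignore", divide="ignore"):
            acc = 100.0 * np.diag(self.counts) / row
        return np.where(row > 0, acc, np.nan)


@dataclass
class SweepResult:
    """Accuracies across one swept axis, with optional rank-ANOVA stat."""

    axis: str
    settings: list
    accuracies: dict            # setting -> accuracy (%) or list of %
    group_stat: tuple | None = None   # (H, p) across settings
    extras: dict = field(default_factory=dict)


def split_train_test(matrix: FeatureMatrix,
                     n_train_cycles: int = 4) -> tuple[np.ndarray, np.ndarray]:
    """Row indices for the 4-train / final-test cycle protocol.

    For every trial in the matrix the last cycle's windows become test
    rows and the preceding ``n_train_cycles`` cycles train the model.
    Trials with fewer than n_train_cycles + 1 cycles are rejected.
    """
    train_idx, test_idx = [], []
    for t in np.unique(matrix.trial_ids):
        rows = np.flatnonzero(matrix.trial_ids == t)
        cycles = np.unique(matrix.cycle_ids[rows])
        if cycles.size < n_train_cycles + 1:
            raise ValueError(
                f"trial {t} has only {cycles.size} cycles; need "
                f"{n_train_cycles + 1} for the split")
        test_cycle = cycles[-1]
        train_cycles = cycles[-1 - n_train_cycles:-1]
        test_idx.append(rows[np.isin(matrix.cycle_ids[rows], [test_cycle])])
        train_idx.append(rows[np.isin(matrix.cycle_ids[rows], train_cycles)])
    return np.concatenate(train_idx), np.concatenate(test_idx)


def make_classifier(spec: ClassifierSpec, seed: int = 0):
    """Instantiate the scikit-learn estimator behind a ClassifierSpec."""
    hp = dict(spec.hyperparameters)
    if spec.algo == "SVM":
        grid = hp.pop("C_grid", (1.0, 10.0, 100.0))
        gamma = hp.pop("gamma", "scale")
        base = SVC(kernel=hp.pop("kernel", "rbf"), gamma=gamma,
                   random_state=seed, **hp)
        cv = StratifiedKFold(n_splits=spec.cv_folds, shuffle=True,
                             random_state=seed)
        return GridSearchCV(base, {"C": list(grid)}, cv=cv, n_jobs=1)
    if spec.algo == "KNN":
        return KNeighborsClassifier(n_neighbors=hp.pop("k", 5), **hp)
    if spec.algo == "QDA":
        # smallest ridge that keeps class covariances full rank on
        # min-max-scaled feature matrices
        return QuadraticDiscriminantAnalysis(
            reg_param=hp.pop("reg_param", 1e-4), **hp)
    return DecisionTreeClassifier(random_state=seed, **hp)


def train_and_classify(train: FeatureMatrix, test: FeatureMatrix,
                       spec: ClassifierSpec = ClassifierSpec(),
                       seed: int = 0) -> tuple[ConfusionMatrix, object]:
    """Fit on ``train`` and score ``test``; returns (confusion, model).

    Features are assumed normalized.  The confusion matrix is indexed by
    the union of class ids present; training must cover every class that
    appears in the test set.
    """
    class_ids = np.unique(np.concatenate([train.labels, test.labels]))
    missing = np.setdiff1d(class_ids, np.unique(train.labels))
    if missing.size:
        raise ValueError(f"classes {missing.tolist()} absent from training set")
    clf = make_classifier(spec, seed=seed)
    clf.fit(train.values, train.labels)
    pred = clf.predict(test.values)
    k = class_ids.size
    pos = {c: i for i, c in enumerate(class_ids)}
    counts = np.zeros((k, k), dtype=int)
    for t, p in zip(test.labels, pred):
        counts[pos[t], pos[p]] += 1
    return ConfusionMatrix(counts=counts, class_ids=class_ids), clf


def build_feature_dataset(recordings: list[MultimodalRecording],
                          scheme: WindowScheme,
                          spec: FeatureSetSpec | str = "R/W/A",
                          preprocessed: bool = False,
                          downsample: bool = True) -> FeatureMatrix:
    """Preprocess, segment, window and featurize a list of trials."""
    mats = []
    for rec in recordings:
        prep = rec if preprocessed else preprocess_recording(rec)
        cycles = segment_recording(prep, prefiltered=True)
        m = extract_features(prep, cycles, scheme, spec)
        if downsample:
            m = downsample_by_two(m)
        mats.append(m)
    return concat_feature_matrices(mats)


def run_experiment(recordings: list[MultimodalRecording],
                   scheme: WindowScheme = WindowScheme(),
                   feature_set: FeatureSetSpec | str = "R/W/A",
                   classifier: ClassifierSpec = ClassifierSpec(),
                   seed: int = 0,
                   normalization: str = "train",
                   muscle_group: str = "All",
                   permute_train_labels: bool = False,
                   preprocessed: bool = False) -> ConfusionMatrix:
    """Full pipeline on a set of trials, one confusion matrix out.

    ``normalization``: "train" fits the 0-1 scaling on training rows
    only (leakage-safe default); "all" fits it on the whole matrix
    before the split.  ``permute_train_labels`` shuffles the training
    labels (chance-floor control).
    """
    matrix = build_feature_dataset(recordings, scheme, feature_set,
                                   preprocessed=preprocessed)
    if muscle_group != "All":
        matrix = muscle_group_subset(matrix, muscle_group)
    train_rows, test_rows = split_train_test(matrix)
    if normalization == "train":
        matrix, mins, maxs = normalize01(matrix, fit_rows=train_rows)
    elif normalization == "all":
        matrix, mins, maxs = normalize01(matrix)
    else:
        raise ValueError("normalization must be 'train' or 'all'")
    train = matrix.select_rows(train_rows)
    test = matrix.select_rows(test_rows)
    if permute_train_labels:
        rng = np.random.default_rng(seed)
        train.labels = rng.permutation(train.labels)
    cm, _ = train_and_classify(train, test, classifier, seed=seed)
    return cm


def muscle_group_subset(matrix: FeatureMatrix, group: str) -> FeatureMatrix:
    """Restrict a feature matrix to the channels of one muscle group."""
    if group not in MUSCLE_GROUPS:
        raise KeyError(
            f"unknown muscle group {group!r}; choose from "
            f"{sorted(MUSCLE_GROUPS)}")
    keep_channels = MUSCLE_GROUPS[group]
    if tuple(keep_channels) == tuple(matrix.channels):
        return matrix
    dpc = matrix.spec.dim_per_channel
    cols = []
    for i, ch in enumerate(matrix.channels):
        if ch in keep_channels:
            cols.extend(range(i * dpc, (i + 1) * dpc))
    out = FeatureMatrix(
        values=matrix.values[:, cols], labels=matrix.labels,
        window_starts=matrix.window_starts, cycle_ids=matrix.cycle_ids,
        spec=matrix.spec,
        channels=tuple(ch for ch in matrix.channels if ch in keep_channels),
        trial_ids=matrix.trial_ids)
    return out


def kruskal_wallis_compare(*groups) -> tuple[float, float]:
    """Kruskal-Wallis H and p across >= 2 groups of accuracy samples.

    Identical constant groups (zero rank variance) return H = 0, p = 1.
    """
    if len(groups) < 2 or any(len(g) < 2 for g in groups):
        raise ValueError("need >= 2 groups with >= 2 samples each")
    flat = np.concatenate([np.asarray(g, dtype=float) for g in groups])
    if np.all(flat == flat[0]):
        return 0.0, 1.0
    h, p = stats.kruskal(*groups)
    return float(h), float(p)


def sweep_classifiers(recordings, scheme=WindowScheme(140, 10),
                      feature_set="R/W/A", seed: int = 0) -> SweepResult:
    """Accuracy of each of the four algorithms at fixed windowing."""
    acc = {}
    for algo in ALGORITHMS:
        cm = run_experiment(recordings, scheme, feature_set,
                            ClassifierSpec(algo=algo), seed=seed)
        acc[algo] = cm.accuracy
    return SweepResult(axis="classifier", settings=list(ALGORITHMS),
                       accuracies=acc)


def sweep_feature_sets(recordings, scheme=WindowScheme(140, 10),
                       classifier=ClassifierSpec(), seed: int = 0
                       ) -> SweepResult:
    """Accuracy of all 15 feature sets at fixed windowing (SVM default).

    ``extras['acc_gain']`` pairs each EMG-only set with its +ACC
    counterpart so the contribution of the accelerometers can be read
    off directly.
    """
    acc = {}
    for name in sorted(FEATURE_SETS):
        cm = run_experiment(recordings, scheme, name, classifier, seed=seed)
        acc[name] = cm.accuracy
    pairs = {"R/W": "R/W/A", "R/M/W": "R/M/W/A", "EMG": "ALL"}
    gain = {f"{a}->{b}": acc[b] - acc[a] for a, b in pairs.items()}
    return SweepResult(axis="feature_set", settings=sorted(acc),
                       accuracies=acc, extras={"acc_gain": gain})


def sweep_window_params(recordings,
                        lengths=WINDOW_LENGTH_GRID,
                        increments=WINDOW_INCREMENT_GRID,
                        feature_set="R/W/A",
                        classifier=ClassifierSpec(), seed: int = 0
                        ) -> SweepResult:
    """Accuracy over the window-length grid (at I=20) and the increment
    grid (at W=140), plus per-increment decision counts per trial."""
    from .segmentation import count_windows

    acc_len = {}
    for w in lengths:
        cm = run_experiment(recordings, WindowScheme(w, 20), feature_set,
                            classifier, seed=seed)
        acc_len[w] = cm.accuracy
    acc_inc, counts = {}, {}
    cycle_lengths = _fastest_cycle_lengths(recordings)
    for inc in increments:
        cm = run_experiment(recordings, WindowScheme(140, inc), feature_set,
                            classifier, seed=seed)
        acc_inc[inc] = cm.accuracy
        counts[inc] = [count_windows(L, 140, inc) for L in cycle_lengths]
    return SweepResult(
        axis="window", settings=list(lengths),
        accuracies={"length": acc_len, "increment": acc_inc},
        extras={"decision_counts": counts,
                "cycle_lengths_emg": cycle_lengths})


def _fastest_cycle_lengths(recordings) -> list[int]:
    """EMG-timeline cycle length at each trial's cadence (per-trial)."""
    out = []
    for rec in recordings:
        starts = rec.cycle_starts_truth
        if starts.size >= 2:
            out.append(int(2 * (starts[1] - starts[0])))
        else:
            out.append(int(rec.n_emg_samples))
    return out


def sweep_muscle_groups(recordings, scheme=WindowScheme(140, 10),
                        feature_set="R/W/A",
                        classifier=ClassifierSpec(), seed: int = 0
                        ) -> SweepResult:
    """Robustness study: accuracy per functional muscle group."""
    acc = {}
    for group in MUSCLE_GROUPS:
        cm = run_experiment(recordings, scheme, feature_set, classifier,
                            seed=seed, muscle_group=group)
        acc[group] = cm.accuracy
    return SweepResult(axis="muscle_group", settings=list(MUSCLE_GROUPS),
                       accuracies=acc)
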