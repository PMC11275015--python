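"""Patient-grouped resampling evaluation of a random-forest classifier.

Every measurement of a patient stays on the same side of a split, so
performance reflects generalisation to unseen patients rather than
memorised within-patient structure.  Across 200 randomized stratified
60/40 splits, a 100-tree depth-10 random forest scores each test frame by
the fraction of trees voting "cancer"; the ROC operating point is the
threshold closest to the ideal classifier's corner (0, 1), where
sensitivity and specificity are read off.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from sklearn.ensemble import RandomForestClassifier
from sklearn.metrics import auc as _trapezoid_auc
from sklearn.metrics import roc_curve as _roc_curve

from .exceptions import SingleClassTest, SingleClassTrain, TooFewPatients
from .harmonize import HarmonizedMatrix, standardize

POSITIVE = "cancer"
NEGATIVE = "non-cancer"


@dataclass(frozen=True)
class SplitRealization:
    index: int
    seed: int
    train_patients: frozenset
    test_patients: frozenset


@dataclass(frozen=True)
class ClassifierConfig:
    n_trees: int = 100
    max_depth: int = 10

    def __post_init__(self):
        if self.n_trees < 1 or self.max_depth < 1:
            raise ValueError("n_trees and max_depth must be ≥ 1")


@dataclass
class RocResult:
    realization: int
    fpr: np.ndarray
    tpr: np.ndarray
    thresholds: np.ndarray
    auc: float
    threshold: float
    sensitivity: float
    specificity: float


@dataclass
class MetricsSummary:
    """Min/max/mean of each metric over realizations, Table-2 style."""

    metrics: dict               # metric name -> {"min": .., "max": .., "mean": ..}
    best_realization: int       # highest AUC
    worst_realization: int      # lowest AUC
    n_realizations: int


def make_patient_splits(
    patient_ids: list[str],
    labels: list[str],
    n_realizations: int = 200,
    train_fraction: float = 0.6,
    seed: int = 0,
) -> list[SplitRealization]:
    """Stratified patient-level train/test splits, deterministic given seed.

    Patients are shuffled within class and the first round(f·n) of each
    class go to training, so each class's train fraction matches
    ``train_fraction`` to the nearest patient.
    """
    pat_label: dict[str, str] = {}
    for p, l in zip(patient_ids, labels):
        if pat_label.setdefault(p, l) != l:
            raise ValueError(f"patient {p} carries conflicting labels")
    by_class: dict[str, list[str]] = {}
    for p, l in sorted(pat_label.items()):
        by_class.setdefault(l, []).append(p)
    if len(by_class) < 2:
        raise TooFewPatients("need patients from both diagnosis classes")
    for l, pats in by_class.items():
        if len(pats) < 2:
            raise TooFewPatients(f"class {l!r} has {len(pats)} patient(s)")
    splits = []
    for r in range(n_realizations):
        rng = np.random.default_rng(np.random.SeedSequence((int(seed), r)))
        train: set[str] = set()
        test: set[str] = set()
        for l in sorted(by_class):
            pats = np.array(by_class[l])
            rng.shuffle(pats)
            n_train = int(round(train_fraction * len(pats)))
            n_train = min(max(n_train, 1), len(pats) - 1)
            train.update(pats[:n_train])
            test.update(pats[n_train:])
        splits.append(SplitRealization(r, int(seed), frozenset(train), frozenset(test)))
    return splits


def train_and_score(
    X_train: np.ndarray,
    y_train: np.ndarray,
    X_test: np.ndarray,
    config: ClassifierConfig = ClassifierConfig(),
    seed: int = 0,
) -> np.ndarray:
    """Random-forest cancer scores: fraction of trees voting the positive class.

    Bootstrap per tree and √(n_features) feature subsampling at each split;
    deterministic given the seed.  ``y_train`` is binary (1 = cancer).
    """
    y_train = np.asarray(y_train)
    if len(np.unique(y_train)) < 2:
        raise SingleClassTrain("training labels contain a single class")
    clf = RandomForestClassifier(
        n_estimators=config.n_trees,
        max_depth=config.max_depth,
        max_features="sqrt",
        bootstrap=True,
        random_state=int(seed) % (2**31),
        n_jobs=1,
    )
    clf.fit(X_train, y_train)
    pos_idx = int(np.nonzero(clf.classes_ == 1)[0][0])
    votes = np.zeros(len(X_test))
    for tree in clf.estimators_:
        proba = tree.predict_proba(X_test)
        votes += (np.argmax(proba, axis=1) == pos_idx)
    return votes / config.n_trees


def roc_and_threshold(scores: np.ndarray, y: np.ndarray,
                      realization: int = 0) -> RocResult:
    """ROC over all distinct score thresholds; operating point nearest (0, 1).

    AUC by the trapezoidal rule.  The chosen threshold minimises the
    Euclidean distance from (fpr, tpr) to the ideal corner; ties resolve to
    the higher threshold.  Sensitivity and specificity are recomputed from
    the confusion matrix at the chosen threshold (rule: score ≥ threshold
    ⇒ cancer), which reproduces the ROC coordinates exactly.
    """
    y = np.asarray(y)
    scores = np.asarray(scores, dtype=float)
    if len(np.unique(y)) < 2:
        raise SingleClassTest("test labels contain a single class")
    fpr, tpr, thr = _roc_curve(y, scores, pos_label=1, drop_intermediate=False)
    area = float(_trapezoid_auc(fpr, tpr))
    dist2 = fpr**2 + (1.0 - tpr) ** 2
    i = int(np.argmin(dist2))  # first minimum = highest threshold on ties
    chosen = float(thr[i])
    pred = scores >= chosen
    tp = int(np.sum(pred & (y == 1)))
    fn = int(np.sum(~pred & (y == 1)))
    tn = int(np.sum(~pred & (y == 0)))
    fp = int(np.sum(pred & (y == 0)))
    sens = tp / (tp + fn)
    spec = tn / (tn + fp)
    return RocResult(realization, fpr, tpr, thr, area, chosen, sens, spec)


def aggregate(results: list[RocResult],
              fpr_grid: np.ndarray | None = None
              ) -> tuple[MetricsSummary, np.ndarray, np.ndarray]:
    """Min/max/mean metrics plus the vertically averaged ROC curve.

    Returns (summary, fpr_grid, mean_tpr).  The averaged curve is the mean
    of tpr linearly interpolated onto a fixed 101-point fpr grid.
    """
    if not results:
        raise ValueError("need at least one realization")
    if fpr_grid is None:
        fpr_grid = np.linspace(0.0, 1.0, 101)
    metrics = {}
    for name in ("auc", "sensitivity", "specificity"):
        vals = np.array([getattr(r, name) for r in results])
        metrics[name] = {"min": float(vals.min()), "max": float(vals.max()),
                         "mean": float(vals.mean())}
    aucs = np.array([r.auc for r in results])
    tprs = np.stack([np.interp(fpr_grid, r.fpr, r.tpr) for r in results])
    summary = MetricsSummary(
        metrics=metrics,
        best_realization=int(np.argmax(aucs)),
        worst_realization=int(np.argmin(aucs)),
        n_realizations=len(results),
    )
    return summary, fpr_grid, tprs.mean(axis=0)


def patient_level_scores(scores: np.ndarray, patient_ids: list[str],
                         y: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    """Optional aggregation: mean frame score (and label) per patient."""
    order = sorted(set(patient_ids))
    s_out, y_out = [], []
    pid_arr = np.asarray(patient_ids)
    for p in order:
        sel = pid_arr == p
        s_out.append(float(np.mean(scores[sel])))
        y_out.append(int(np.asarray(y)[sel][0]))
    return np.array(s_out), np.array(y_out)


def _binary_labels(labels: list[str]) -> np.ndarray:
    return np.array([1 if l == POSITIVE else 0 for l in labels])


def evaluate_cluster(
    matrix: HarmonizedMatrix,
    n_realizations: int = 200,
    train_fraction: float = 0.6,
    config: ClassifierConfig = ClassifierConfig(),
    seed: int = 0,
    scaler_mode: str = "train_only",
    permute_labels: bool = False,
) -> tuple[list[RocResult], MetricsSummary, np.ndarray, np.ndarray]:
    """Full patient-grouped resampling evaluation of one cluster.

    ``scaler_mode``: "train_only" fits the per-column scaler on training
    rows of each realization (leakage-free, default); "cluster_wide" fits
    once on the whole cluster before splitting, mirroring a pre-split
    normalisation.  ``permute_labels`` permutes the patient→label mapping
    per realization to produce a chance-level reference.
    """
    if scaler_mode not in ("train_only", "cluster_wide"):
        raise ValueError("scaler_mode must be 'train_only' or 'cluster_wide'")
    patients = np.asarray(matrix.patient_ids)
    labels = list(matrix.labels)
    splits = make_patient_splits(matrix.patient_ids, labels,
                                 n_realizations, train_fraction, seed)
    base = standardize(matrix) if scaler_mode == "cluster_wide" else matrix

    pat_label = {p: l for p, l in zip(matrix.patient_ids, labels)}
    uniq_patients = sorted(pat_label)
    results = []
    for split in splits:
        assert not (split.train_patients & split.test_patients)
        if permute_labels:
            rng = np.random.default_rng(
                np.random.SeedSequence((int(seed), split.index, 0x9E3779)))
            shuffled = rng.permutation([pat_label[p] for p in uniq_patients])
            eff = dict(zip(uniq_patients, shuffled))
            row_labels = [eff[p] for p in patients]
        else:
            row_labels = labels
        y = _binary_labels(row_labels)
        in_train = np.isin(patients, list(split.train_patients))
        in_test = ~in_train
        if scaler_mode == "train_only":
            scaled = standardize(matrix, fit_on=np.nonzero(in_train)[0])
        else:
            scaled = base
        rf_seed = int(np.random.SeedSequence((int(seed), split.index, 1)).generate_state(1)[0] % (2**31))
        try:
            scores = train_and_score(scaled.X[in_train], y[in_train],
                                     scaled.X[in_test], config, rf_seed)
            results.append(roc_and_threshold(scores, y[in_test], split.index))
        except (SingleClassTrain, SingleClassTest):
            # degenerate permutation draw; skip this realization
            continue
    summary, grid, mean_tpr = aggregate(results)
    return results, summary, grid, mean_tpr
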