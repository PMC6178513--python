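"""False-positive reduction: classifiers, cross-validation and metrics.

Candidate ROIs described by the 986-dimensional sparse-curvelet-LBP
vector are classified as true mass (positive) or false positive by one
of three classifiers: a feed-forward neural network (986 inputs, one
hidden layer, logistic units, single probability output), an RBF-kernel
SVM scored by its decision function, or a k-nearest-neighbor voter
(k = 5, score = fraction of positive neighbors).

Evaluation uses 3-fold cross-validation.  Folds are split by *group* —
all augmented copies of a patch carry its group id — so no source patch
can appear in both a training and a test fold.  Reported metrics are
sensitivity, specificity, accuracy, ROC AUC (trapezoidal), and the
detection-level rates TPR = TP / #lesions and FPPI = FP / #images.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from sklearn.metrics import roc_curve
from sklearn.neighbors import KNeighborsClassifier
from sklearn.neural_network import MLPClassifier
from sklearn.svm import SVC

from .roi import SparseROI
from .sparselbp import N_FEATURES, describe_roi

__all__ = [
    "LabeledDataset",
    "build_dataset",
    "augment",
    "EvalReport",
    "CVReport",
    "compute_metrics",
    "train_ann",
    "train_svm",
    "train_knn",
    "three_fold_cv",
]


@dataclass
class LabeledDataset:
    """Feature matrix with binary labels and per-source group ids."""

    features: np.ndarray   # (N, d)
    labels: np.ndarray     # (N,) in {0, 1}
    groups: np.ndarray     # (N,) int

    def __post_init__(self) -> None:
        self.features = np.asarray(self.features, dtype=float)
        self.labels = np.asarray(self.labels, dtype=int)
        self.groups = np.asarray(self.groups, dtype=int)
        n = self.features.shape[0]
        if self.labels.shape != (n,) or self.groups.shape != (n,):
            raise ValueError("features, labels and groups must align")
        if not np.all(np.isfinite(self.features)):
            raise ValueError("features contain non-finite values")
        if not set(np.unique(self.labels)) <= {0, 1}:
            raise ValueError("labels must be binary")

    def __len__(self) -> int:
        return self.features.shape[0]


def build_dataset(rois: list[SparseROI], labels: list[int] | np.ndarray,
                  tol_rel: float = 1e-6) -> LabeledDataset:
    """Describe every ROI and assemble a dataset.

    ROIs without a group id get a fresh one each (treated as independent
    sources).
    """
    feats = np.empty((len(rois), N_FEATURES))
    groups = np.empty(len(rois), dtype=int)
    for i, roi in enumerate(rois):
        feats[i] = describe_roi(roi, tol_rel=tol_rel)
        groups[i] = roi.group if roi.group is not None else i
    return LabeledDataset(features=feats, labels=np.asarray(labels, dtype=int),
                          groups=groups)


def augment(rois: list[SparseROI], factor: int, seed: int = 0) -> list[SparseROI]:
    """Flip/rotation augmentation preserving the sparse support.

    ``factor=2`` keeps the originals and adds horizontal flips;
    ``factor=4`` adds horizontal flip, vertical flip and 180-degree
    rotation.  Augmented patches inherit the source group id so they stay
    in the same cross-validation fold.
    """
    if factor not in (2, 4):
        raise ValueError("factor must be 2 or 4")
    transforms = [lambda p: p[:, ::-1]]
    if factor == 4:
        transforms += [lambda p: p[::-1, :], lambda p: p[::-1, ::-1]]
    out = list(rois)
    for roi in rois:
        for tf in transforms:
            out.append(SparseROI(pixels=tf(roi.pixels).copy(),
                                 bbox=roi.bbox, group=roi.group))
    return out


@dataclass
class EvalReport:
    """Threshold metrics plus ROC AUC for one evaluation set."""

    sensitivity: float
    specificity: float
    accuracy: float
    auc: float
    tp: int
    fn: int
    tn: int
    fp: int
    tpr: float | None = None
    fppi: float | None = None

    def as_dict(self) -> dict:
        return {k: v for k, v in self.__dict__.items()}


@dataclass
class CVReport:
    """Per-fold reports and their means."""

    folds: list[EvalReport]

    @property
    def sensitivity(self) -> float:
        return float(np.mean([f.sensitivity for f in self.folds]))

    @property
    def specificity(self) -> float:
        return float(np.mean([f.specificity for f in self.folds]))

    @property
    def accuracy(self) -> float:
        return float(np.mean([f.accuracy for f in self.folds]))

    @property
    def auc(self) -> float:
        return float(np.mean([f.auc for f in self.folds]))

    def as_dict(self) -> dict:
        return {"folds": [f.as_dict() for f in self.folds],
                "mean": {"sensitivity": self.sensitivity,
                         "specificity": self.specificity,
                         "accuracy": self.accuracy,
                         "auc": self.auc}}


def _auc_trapezoid(scores: np.ndarray, labels: np.ndarray) -> float:
    if len(np.unique(labels)) < 2:
        return float("nan")
    fpr, tpr, _ = roc_curve(labels, scores)
    return float(np.trapezoid(tpr, fpr))


def compute_metrics(scores: np.ndarray, labels: np.ndarray,
                    threshold: float = 0.5, *,
                    n_lesions: int | None = None,
                    n_images: int | None = None) -> EvalReport:
    """Confusion metrics at a threshold plus trapezoidal ROC AUC.

    Predictions are positive when ``score >= threshold``.  When lesion /
    image counts are supplied, the detection-level rates TPR = TP /
    #lesions and FPPI = FP / #images are filled in as well.
    """
    scores = np.asarray(scores, dtype=float)
    labels = np.asarray(labels, dtype=int)
    if scores.shape != labels.shape or scores.size < 1:
        raise ValueError("scores and labels must be equal-length, non-empty")
    pred = scores >= threshold
    tp = int(np.sum(pred & (labels == 1)))
    fn = int(np.sum(~pred & (labels == 1)))
    tn = int(np.sum(~pred & (labels == 0)))
    fp = int(np.sum(pred & (labels == 0)))
    sens = tp / (tp + fn) if tp + fn else float("nan")
    spec = tn / (tn + fp) if tn + fp else float("nan")
    acc = (tp + tn) / scores.size
    report = EvalReport(sensitivity=sens, specificity=spec, accuracy=acc,
                        auc=_auc_trapezoid(scores, labels),
                        tp=tp, fn=fn, tn=tn, fp=fp)
    if n_lesions is not None:
        report.tpr = tp / n_lesions
    if n_images is not None:
        report.fppi = fp / n_images
    return report


def detection_tpr(n_detected: int, n_lesions: int) -> float:
    """Lesion-level true-positive rate: detected lesions / total lesions."""
    return n_detected / n_lesions


def detection_fppi(n_fp: int, n_images: int) -> float:
    """False positives per image: FP count / number of images."""
    return n_fp / n_images


def train_ann(features: np.ndarray, labels: np.ndarray, hidden: int = 20,
              seed: int = 0, max_iter: int = 800):
    """Feed-forward network scorer (one logistic hidden layer).

    A third of the training material is held out internally for early
    stopping, mirroring an equal train/validation/test economy; with fewer
    than 60 training samples the validation third is too small to be
    informative and the network simply trains to convergence.  Returns a
    ``scorer(X) -> probability of the positive class``.
    """
    early = len(labels) >= 60
    clf = MLPClassifier(hidden_layer_sizes=(hidden,), activation="logistic",
                        solver="adam", max_iter=max_iter, random_state=seed,
                        learning_rate_init=0.01,
                        early_stopping=early, validation_fraction=1 / 3,
                        n_iter_no_change=50)
    import warnings
    from sklearn.exceptions import ConvergenceWarning
    with warnings.catch_warnings():
        warnings.simplefilter("ignore", ConvergenceWarning)
        clf.fit(features, labels)
    return lambda X: clf.predict_proba(np.asarray(X, dtype=float))[:, 1]


def train_svm(features: np.ndarray, labels: np.ndarray, c: float = 1.0,
              gamma: str | float = "scale", seed: int = 0):
    """RBF-kernel SVM; scores are signed decision-function values."""
    clf = SVC(C=c, kernel="rbf", gamma=gamma, random_state=seed)
    clf.fit(features, labels)
    return lambda X: clf.decision_function(np.asarray(X, dtype=float))


def train_knn(features: np.ndarray, labels: np.ndarray, k: int = 5):
    """k-NN scorer: fraction of positive labels among the k neighbors."""
    clf = KNeighborsClassifier(n_neighbors=min(k, len(labels)))
    clf.fit(features, labels)
    return lambda X: clf.predict_proba(np.asarray(X, dtype=float))[:, 1]


_DEFAULT_THRESHOLDS = {"ann": 0.5, "knn": 0.5, "svm": 0.0}


def _fit_scorer(name: str, X: np.ndarray, y: np.ndarray, seed: int,
                params: dict):
    if name == "ann":
        return train_ann(X, y, seed=seed, **params)
    if name == "svm":
        return train_svm(X, y, seed=seed, **params)
    if name == "knn":
        return train_knn(X, y, **params)
    raise ValueError(f"unknown classifier {name!r}")


def three_fold_cv(ds: LabeledDataset, clf: str = "ann", seed: int = 0,
                  threshold: float | None = None,
                  **clf_params) -> CVReport:
    """Group-aware 3-fold cross-validation.

    Groups are shuffled deterministically by ``seed`` and split into three
    nearly equal folds (sizes differing by at most one group); each fold
    is held out once.  Raises if a training fold is missing a class.
    """
    if threshold is None:
        threshold = _DEFAULT_THRESHOLDS[clf]
    rng = np.random.default_rng(seed)
    uniq = np.unique(ds.groups)
    if min(len(np.unique(ds.groups[ds.labels == c])) for c in (0, 1)) < 3:
        raise ValueError("need at least 3 groups per class for 3-fold CV")
    order = rng.permutation(len(uniq))
    fold_groups = np.array_split(uniq[order], 3)

    seen: set[int] = set()
    reports: list[EvalReport] = []
    for k, test_groups in enumerate(fold_groups):
        assert seen.isdisjoint(test_groups), "group leaked across folds"
        seen.update(int(g) for g in test_groups)
        test = np.isin(ds.groups, test_groups)
        train = ~test
        y_train = ds.labels[train]
        if len(np.unique(y_train)) < 2:
            raise ValueError(f"training fold {k} lost a class")
        scorer = _fit_scorer(clf, ds.features[train], y_train,
                             seed + k, clf_params)
        scores = scorer(ds.features[test])
        reports.append(compute_metrics(scores, ds.labels[test], threshold))
    return CVReport(folds=reports)
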