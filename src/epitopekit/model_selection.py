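"""Classifier training, cross-validation, metrics and greedy selection.

Binary epitope/non-epitope classification on a
:class:`~epitopekit.io_formats.FeatureMatrix`.  The metric set is chosen
for 1:6-imbalanced data: Matthews correlation coefficient (MCC) as the
primary score, plus ROC AUC, F1 and balanced accuracy.  MCC and AUC are
computed directly from their definitions (confusion-matrix formula with
the zero-denominator convention; tie-aware rank statistic) so the
conventions are explicit and testable against independent oracles.

Feature selection is forward stepwise greedy on cross-validated MCC:
start from the empty set and repeatedly add the single feature whose
addition improves CV MCC the most, stopping once no candidate improves by
more than a tolerance for ``patience`` consecutive rounds.
"""

from __future__ import annotations

import hashlib
from dataclasses import dataclass, field
from pathlib import Path
from typing import Callable, Dict, List, Sequence

import joblib
import numpy as np
from scipy.stats import rankdata
from sklearn.ensemble import (
    AdaBoostClassifier,
    ExtraTreesClassifier,
    GradientBoostingClassifier,
    RandomForestClassifier,
)
from sklearn.model_selection import StratifiedKFold
from sklearn.neighbors import KNeighborsClassifier
from sklearn.calibration import CalibratedClassifierCV
from sklearn.neural_network import MLPClassifier
from sklearn.svm import SVC

from .descriptors import FeaturizeOptions, fit_aat_scale, featurize
from .io_formats import FeatureMatrix, PeptideRecord, labels_to_binary
from .signatures import SignatureConfig

BUNDLE_FORMAT = "epitopekit.model_bundle/1"


# ---------------------------------------------------------------------------
# Metrics
# ---------------------------------------------------------------------------

@dataclass
class MetricsReport:
    """Thresholded and ranking metrics of one evaluation.

    ``roc_auc`` is ``None`` (undefined) when only one class is present.
    """

    mcc: float
    roc_auc: float | None
    f1: float
    balanced_accuracy: float
    tp: int
    fp: int
    tn: int
    fn: int
    threshold: float = 0.5

    @property
    def n(self) -> int:
        return self.tp + self.fp + self.tn + self.fn

    def to_dict(self) -> dict:
        return {
            "mcc": self.mcc,
            "roc_auc": self.roc_auc,
            "f1": self.f1,
            "balanced_accuracy": self.balanced_accuracy,
            "confusion": {"tp": self.tp, "fp": self.fp, "tn": self.tn, "fn": self.fn},
            "threshold": self.threshold,
        }


def mcc_from_confusion(tp: int, fp: int, tn: int, fn: int) -> float:
    """MCC from confusion counts; 0 when any denominator factor is 0."""
    denom_sq = float(tp + fp) * (tp + fn) * (tn + fp) * (tn + fn)
    if denom_sq == 0:
        return 0.0
    return (tp * tn - fp * fn) / denom_sq ** 0.5


def auc_score(labels: np.ndarray, scores: np.ndarray) -> float | None:
    """ROC AUC by the rank (Mann-Whitney) statistic; ties get half credit.

    Equivalent to counting concordant score pairs between classes plus
    half the tied pairs.  Returns ``None`` when only one class is present
    (the AUC is undefined, not 0.5).
    """
    labels = np.asarray(labels)
    scores = np.asarray(scores, dtype=float)
    n_pos = int(labels.sum())
    n_neg = len(labels) - n_pos
    if n_pos == 0 or n_neg == 0:
        return None
    ranks = rankdata(scores)  # average ranks: tie-aware
    rank_sum_pos = ranks[labels == 1].sum()
    return float((rank_sum_pos - n_pos * (n_pos + 1) / 2) / (n_pos * n_neg))


def compute_metrics(labels: Sequence[int], scores: Sequence[float],
                    threshold: float = 0.5) -> MetricsReport:
    """Evaluate binary predictions at a decision threshold.

    Predicted positive iff score >= threshold.  MCC uses the
    zero-denominator convention (0 when a full row/column of the confusion
    matrix is empty); F1 is 0 when precision+recall is 0.
    """
    labels = np.asarray(labels, dtype=int)
    scores = np.asarray(scores, dtype=float)
    if labels.shape != scores.shape:
        raise ValueError("labels and scores must have equal length")
    if np.any((scores < 0) | (scores > 1)):
        raise ValueError("scores must lie in [0, 1]")
    pred = (scores >= threshold).astype(int)
    tp = int(np.sum((pred == 1) & (labels == 1)))
    fp = int(np.sum((pred == 1) & (labels == 0)))
    tn = int(np.sum((pred == 0) & (labels == 0)))
    fn = int(np.sum((pred == 0) & (labels == 1)))

    mcc = mcc_from_confusion(tp, fp, tn, fn)
    denom = 2 * tp + fp + fn
    f1 = 2 * tp / denom if denom else 0.0
    tpr = tp / (tp + fn) if (tp + fn) else 0.0
    tnr = tn / (tn + fp) if (tn + fp) else 0.0
    bal_acc = (tpr + tnr) / 2
    return MetricsReport(
        mcc=mcc, roc_auc=auc_score(labels, scores), f1=f1,
        balanced_accuracy=bal_acc, tp=tp, fp=fp, tn=tn, fn=fn,
        threshold=threshold,
    )


# ---------------------------------------------------------------------------
# Algorithms
# ---------------------------------------------------------------------------

def _make_additive_boosting(seed: int, params: dict):
    try:
        from interpret.glassbox import ExplainableBoostingClassifier

        return ExplainableBoostingClassifier(random_state=seed, **params)
    except ImportError:
        # additive interpretable model unavailable: gradient boosting with
        # per-feature partial dependence (explain.response_curve) stands in
        return GradientBoostingClassifier(random_state=seed, **params)


ALGORITHMS: Dict[str, Callable[[int, dict], object]] = {
    "random_forest": lambda seed, p: RandomForestClassifier(random_state=seed, **p),
    "extra_trees": lambda seed, p: ExtraTreesClassifier(random_state=seed, **p),
    "gradient_boosting": lambda seed, p: GradientBoostingClassifier(random_state=seed, **p),
    "adaptive_boosting": lambda seed, p: AdaBoostClassifier(random_state=seed, **p),
    "additive_boosting": _make_additive_boosting,
    # probability estimates via Platt scaling on the fitted margin
    "svm": lambda seed, p: CalibratedClassifierCV(
        SVC(random_state=seed, **p), cv=3, ensemble=False),
    "knn": lambda seed, p: KNeighborsClassifier(**p),
    "mlp": lambda seed, p: MLPClassifier(random_state=seed, max_iter=500, **p),
}


def make_classifier(algorithm: str, seed: int, hyperparameters: dict | None = None):
    if algorithm not in ALGORITHMS:
        raise KeyError(
            f"unknown algorithm {algorithm!r}; available: {sorted(ALGORITHMS)}"
        )
    return ALGORITHMS[algorithm](seed, dict(hyperparameters or {}))


# ---------------------------------------------------------------------------
# Model bundle
# ---------------------------------------------------------------------------

@dataclass
class ModelBundle:
    """A trained classifier plus everything needed to apply it honestly:
    the selected feature names (order matters), algorithm id, seed,
    hyperparameters and a fingerprint of the training matrix."""

    algorithm: str
    feature_names: List[str]
    model: object
    seed: int
    training_fingerprint: str = ""
    hyperparameters: dict = field(default_factory=dict)
    threshold: float = 0.5
    format: str = BUNDLE_FORMAT

    def save(self, path) -> None:
        joblib.dump(self, path)

    @classmethod
    def load(cls, path) -> "ModelBundle":
        obj = joblib.load(path)
        if not isinstance(obj, cls) or obj.format != BUNDLE_FORMAT:
            raise ValueError(f"{path}: not an epitopekit model bundle")
        return obj


def _matrix_fingerprint(X: np.ndarray, y: np.ndarray) -> str:
    h = hashlib.sha256()
    h.update(np.ascontiguousarray(X).tobytes())
    h.update(np.ascontiguousarray(y).tobytes())
    return h.hexdigest()


def _select_columns(matrix: FeatureMatrix, names: Sequence[str]) -> np.ndarray:
    missing = [n for n in names if n not in matrix.data.columns]
    if missing:
        raise KeyError(f"feature matrix is missing selected feature(s): {missing}")
    return matrix.data.loc[:, list(names)].to_numpy(dtype=float)


def train(matrix: FeatureMatrix, labels: Sequence[int], algorithm: str = "random_forest",
          hyperparameters: dict | None = None, seed: int = 0,
          feature_names: Sequence[str] | None = None) -> ModelBundle:
    """Fit a classifier; returns a serializable :class:`ModelBundle`.

    ``feature_names`` restricts training to a selected subset (defaults to
    all columns).
    """
    y = np.asarray(labels, dtype=int)
    names = list(feature_names) if feature_names is not None else matrix.feature_names
    if not names:
        raise ValueError("cannot train on an empty feature set")
    X = _select_columns(matrix, names)
    clf = make_classifier(algorithm, seed, hyperparameters)
    clf.fit(X, y)
    return ModelBundle(
        algorithm=algorithm, feature_names=names, model=clf, seed=seed,
        training_fingerprint=_matrix_fingerprint(X, y),
        hyperparameters=dict(hyperparameters or {}),
    )


def predict(bundle: ModelBundle, matrix: FeatureMatrix) -> np.ndarray:
    """Epitope-class probability per peptide, in matrix row order.

    Fails loudly (KeyError naming the columns) if the matrix lacks any
    feature the bundle was trained on.
    """
    X = _select_columns(matrix, bundle.feature_names)
    proba = bundle.model.predict_proba(X)
    classes = list(getattr(bundle.model, "classes_", [0, 1]))
    return np.asarray(proba[:, classes.index(1)], dtype=float)


def evaluate(bundle: ModelBundle, matrix: FeatureMatrix,
             labels: Sequence[int], threshold: float | None = None) -> MetricsReport:
    """Score a bundle on labeled data (the blind-test entry point)."""
    scores = predict(bundle, matrix)
    return compute_metrics(labels, scores,
                           threshold if threshold is not None else bundle.threshold)


# ---------------------------------------------------------------------------
# Cross-validation
# ---------------------------------------------------------------------------

def _summary(reports: Sequence[MetricsReport]) -> dict:
    out = {}
    for metric in ("mcc", "roc_auc", "f1", "balanced_accuracy"):
        vals = [getattr(r, metric) for r in reports]
        if any(v is None for v in vals):
            out[metric] = {"mean": None, "sd": None}
        else:
            arr = np.asarray(vals, dtype=float)
            out[metric] = {"mean": float(arr.mean()),
                           "sd": float(arr.std(ddof=1)) if len(arr) > 1 else 0.0}
    return out


def cross_validate(matrix: FeatureMatrix, labels: Sequence[int],
                   algorithm: str = "random_forest", k: int = 10, seed: int = 0,
                   hyperparameters: dict | None = None,
                   threshold: float = 0.5):
    """Stratified k-fold CV on a fixed feature matrix.

    Returns ``(per-fold MetricsReports, summary dict of mean±sd)``.  The
    matrix must already be leakage-free (features fitted on external data
    or purely per-peptide); for pipelines with training-data-fitted
    components use :func:`cross_validate_records`, which refits them
    inside each fold.
    """
    y = np.asarray(labels, dtype=int)
    counts = np.bincount(y, minlength=2)
    if counts.min() < k:
        raise ValueError(
            f"smallest class has {counts.min()} members < k={k}; use a smaller k"
        )
    skf = StratifiedKFold(n_splits=k, shuffle=True, random_state=seed)
    X_all = matrix.data.to_numpy(dtype=float)
    reports = []
    for train_idx, test_idx in skf.split(X_all, y):
        sub_train = FeatureMatrix(matrix.data.iloc[train_idx],
                                  provenance=matrix.provenance)
        sub_test = FeatureMatrix(matrix.data.iloc[test_idx],
                                 provenance=matrix.provenance)
        bundle = train(sub_train, y[train_idx], algorithm,
                       hyperparameters, seed=seed)
        reports.append(evaluate(bundle, sub_test, y[test_idx], threshold))
    return reports, _summary(reports)


def cross_validate_records(records: Sequence[PeptideRecord],
                           algorithm: str = "random_forest", k: int = 10,
                           seed: int = 0,
                           signature_config: SignatureConfig | None = None,
                           options: FeaturizeOptions = FeaturizeOptions(),
                           pseudocount: float = 1.0,
                           hyperparameters: dict | None = None,
                           threshold: float = 0.5):
    """Leakage-free stratified k-fold CV starting from raw peptide records.

    The AAT scale is refitted on each fold's training split only, and both
    splits are featurized with that fold-local scale, so no statistic
    fitted on data ever sees its own test fold.
    """
    records = list(records)
    y = labels_to_binary(records)
    counts = np.bincount(y, minlength=2)
    if counts.min() < k:
        raise ValueError(
            f"smallest class has {counts.min()} members < k={k}; use a smaller k"
        )
    skf = StratifiedKFold(n_splits=k, shuffle=True, random_state=seed)
    reports = []
    for train_idx, test_idx in skf.split(np.zeros(len(records)), y):
        fold_train = [records[i] for i in train_idx]
        fold_test = [records[i] for i in test_idx]
        scale = None
        if options.aat:
            scale = fit_aat_scale(
                [r.sequence for r in fold_train if r.label == "epitope"],
                [r.sequence for r in fold_train if r.label == "non_epitope"],
                pseudocount=pseudocount,
            )
        m_train = featurize(fold_train, scale, signature_config, options)
        m_test = featurize(fold_test, scale, signature_config, options)
        bundle = train(m_train, y[train_idx], algorithm, hyperparameters, seed=seed)
        reports.append(evaluate(bundle, m_test, y[test_idx], threshold))
    return reports, _summary(reports)


# ---------------------------------------------------------------------------
# Greedy forward feature selection
# ---------------------------------------------------------------------------

def greedy_forward_select(matrix: FeatureMatrix, labels: Sequence[int],
                          algorithm: str = "random_forest", k: int = 5,
                          seed: int = 0, tolerance: float = 1e-4,
                          patience: int = 1,
                          max_features: int | None = None,
                          hyperparameters: dict | None = None) -> list:
    """Forward stepwise greedy feature selection on cross-validated MCC.

    Starting from the empty set (baseline score 0), each round evaluates
    every remaining candidate by the mean CV MCC of the model trained on
    selected + candidate, and adds the best one if its gain exceeds
    ``tolerance``; otherwise a gainless round is counted and selection
    stops after ``patience`` of them.  Ties break toward the earlier
    column.  Deterministic under ``seed``.
    """
    if len(matrix.feature_names) < 1:
        raise ValueError("need at least one feature to select from")
    y = np.asarray(labels, dtype=int)
    selected: list = []
    remaining = list(matrix.feature_names)
    best_score = 0.0
    gainless = 0
    while remaining and gainless < patience:
        if max_features is not None and len(selected) >= max_features:
            break
        round_best_name = None
        round_best_score = -np.inf
        for name in remaining:
            sub = FeatureMatrix(matrix.data.loc[:, selected + [name]])
            _, summary = cross_validate(sub, y, algorithm, k=k, seed=seed,
                                        hyperparameters=hyperparameters)
            score = summary["mcc"]["mean"]
            if score > round_best_score:  # strict: ties keep earlier column
                round_best_score = score
                round_best_name = name
        if round_best_score - best_score > tolerance:
            selected.append(round_best_name)
            remaining.remove(round_best_name)
            best_score = round_best_score
            gainless = 0
        else:
            gainless += 1
    return selected
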