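"""Feature-importance reporting and single-feature response curves.

Mirrors the interpretability analysis practitioners run on epitope
classifiers: impurity-based (Gini) importance from tree ensembles, model
-agnostic permutation importance (degradation of MCC when one feature is
shuffled), optionally SHAP when that library is installed, and partial-
dependence-style response curves (mean predicted epitope probability as
one feature is clamped over a grid).
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Dict, Sequence

import numpy as np

from .io_formats import FeatureMatrix
from .model_selection import ModelBundle, compute_metrics, predict


@dataclass
class ImportanceReport:
    """Ranked per-feature importance values under one method."""

    values: Dict[str, float]
    method: str
    normalized: bool = False

    def ranked(self) -> list:
        """Feature names by decreasing importance (ties by name order)."""
        return sorted(self.values, key=lambda n: (-self.values[n], n))

    def to_dict(self) -> dict:
        return {"method": self.method, "normalized": self.normalized,
                "values": self.values}


def importance(bundle: ModelBundle, matrix: FeatureMatrix,
               labels: Sequence[int], method: str = "gini",
               n_repeats: int = 10, seed: int = 0) -> ImportanceReport:
    """Per-feature importance of a trained bundle.

    ``gini``: the tree ensemble's impurity-based importances (non-negative,
    sum to 1).  ``permutation``: mean drop in MCC over ``n_repeats``
    seeded shuffles of each feature column; matrix columns outside the
    bundle's selected feature set get importance 0.  ``shap``: mean |SHAP
    value| per feature, if the optional dependency is installed.
    """
    y = np.asarray(labels, dtype=int)
    if method == "gini":
        imps = getattr(bundle.model, "feature_importances_", None)
        if imps is None:
            raise ValueError(
                f"algorithm {bundle.algorithm!r} has no impurity-based "
                "importances; use method='permutation'"
            )
        values = {n: float(v) for n, v in zip(bundle.feature_names, imps)}
        return ImportanceReport(values=values, method="gini", normalized=True)

    if method == "permutation":
        rng = np.random.default_rng(seed)
        baseline = compute_metrics(y, predict(bundle, matrix)).mcc
        values = {n: 0.0 for n in matrix.feature_names}
        for name in bundle.feature_names:
            if name not in values:
                continue
            drops = []
            for _ in range(n_repeats):
                shuffled = matrix.data.copy()
                shuffled[name] = rng.permutation(shuffled[name].to_numpy())
                perm_mcc = compute_metrics(
                    y, predict(bundle, FeatureMatrix(shuffled))
                ).mcc
                drops.append(baseline - perm_mcc)
            values[name] = float(np.mean(drops))
        return ImportanceReport(values=values, method="permutation")

    if method == "shap":
        try:
            import shap
        except ImportError:
            raise ImportError(
                "method='shap' requires the optional 'shap' package, which "
                "is not installed; use method='gini' or 'permutation'"
            ) from None
        X = matrix.data.loc[:, bundle.feature_names].to_numpy(dtype=float)
        explainer = shap.TreeExplainer(bundle.model)
        sv = explainer.shap_values(X)
        if isinstance(sv, list):  # one array per class
            sv = sv[1]
        if sv.ndim == 3:
            sv = sv[:, :, 1]
        mean_abs = np.abs(sv).mean(axis=0)
        values = {n: float(v) for n, v in zip(bundle.feature_names, mean_abs)}
        return ImportanceReport(values=values, method="shap")

    raise ValueError(f"unknown importance method {method!r}")


def response_curve(bundle: ModelBundle, matrix: FeatureMatrix,
                   feature: str, grid: Sequence[float]):
    """Partial-dependence-style response of the model to one feature.

    For each grid value the feature column is clamped to it across the
    whole matrix and the mean predicted epitope probability is recorded.
    Returns ``(grid array, mean-score array)``.
    """
    if feature not in bundle.feature_names:
        raise KeyError(f"feature {feature!r} not in the bundle's selected set")
    grid = np.asarray(list(grid), dtype=float)
    if grid.size == 0:
        raise ValueError("grid must be non-empty")
    means = np.empty(grid.shape)
    for i, v in enumerate(grid):
        clamped = matrix.data.copy()
        clamped[feature] = v
        means[i] = float(predict(bundle, FeatureMatrix(clamped)).mean())
    return grid, means
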