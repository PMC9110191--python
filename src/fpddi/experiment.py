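"""Cross-validation experiments over the interaction classifier.

Each experiment trains one classifier per fold and scores held-out
predictions.  By default predictions are pooled across folds — all test-set
probabilities concatenated, then one confusion matrix and one curve pair —
which matches plotting a single ROC/PR curve per classifier.  Per-fold scalar
measures (and their mean) are also available for comparison, since fold
averaging and pooling can differ slightly.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .dataset import InteractionDataset
from .fusion import encode_pairs, models_code, ALL_COMBINATIONS
from .metrics import MetricsReport, confusion, evaluate_predictions, scalar_metrics
from .model import ClassifierConfig, InteractionModel, DEFAULT_THRESHOLD
from .splits import composition_cv_split, entire_cv_split


@dataclass
class CVResult:
    """Pooled predictions of one cross-validated stratum plus per-fold rows."""

    name: str
    labels: np.ndarray
    scores: np.ndarray
    fold_index: np.ndarray
    report: MetricsReport = field(repr=False, default=None)

    def per_fold_frame(self, threshold: float = DEFAULT_THRESHOLD) -> pd.DataFrame:
        """Scalar measures computed within each fold separately."""
        rows = []
        for k in sorted(set(self.fold_index)):
            mask = self.fold_index == k
            y = self.labels[mask]
            preds = (self.scores[mask] >= threshold).astype(np.int8)
            row = {"fold": int(k), "n": int(mask.sum())}
            row.update(scalar_metrics(confusion(y, preds)).__dict__)
            rows.append(row)
        return pd.DataFrame(rows)


def _pooled_result(name, labels, scores, folds, threshold, metadata) -> CVResult:
    labels = np.concatenate(labels) if labels else np.empty(0, dtype=np.int8)
    scores = np.concatenate(scores) if scores else np.empty(0)
    fold_index = np.concatenate(folds) if folds else np.empty(0, dtype=int)
    report = evaluate_predictions(labels, scores, threshold=threshold, metadata=metadata)
    return CVResult(name=name, labels=labels, scores=scores,
                    fold_index=fold_index, report=report)


def run_entire_cv(
    dataset: InteractionDataset,
    feature_models: str = "AS",
    config: ClassifierConfig | None = None,
    K: int = 10,
    split_seed: int = 0,
    threshold: float = DEFAULT_THRESHOLD,
) -> CVResult:
    """Entire K-fold CV: every sample tested exactly once; pooled report."""
    config = config or ClassifierConfig()
    plan = entire_cv_split(dataset, K=K, seed=split_seed)
    X = encode_pairs(dataset.drugs, dataset.pairs, feature_models)
    y = dataset.labels
    labels, scores, folds = [], [], []
    for k, (train_idx, test_idx) in enumerate(plan.iter_folds()):
        results = InteractionModel(
            X[train_idx], y[train_idx], feature_models=feature_models, config=config
        ).fit()
        labels.append(y[test_idx])
        scores.append(results.predict_proba(X[test_idx]))
        folds.append(np.full(len(test_idx), k))
    meta = {
        "protocol": "entire_cv", "K": K, "split_seed": split_seed,
        "feature_models": models_code(feature_models), "backend": config.backend,
        "model_seed": config.seed,
    }
    return _pooled_result("entire", labels, scores, folds, threshold, meta)


def run_composition_cv(
    dataset: InteractionDataset,
    feature_models: str = "AH",
    config: ClassifierConfig | None = None,
    K: int = 10,
    split_seed: int = 0,
    threshold: float = DEFAULT_THRESHOLD,
) -> tuple[CVResult, CVResult]:
    """Composition K-fold CV: drug-partitioned; returns (ODIT, NDIT) results.

    Folds whose ODIT or NDIT stratum is empty contribute nothing to that
    stratum's pool.
    """
    config = config or ClassifierConfig()
    split = composition_cv_split(dataset, K=K, seed=split_seed)
    X = encode_pairs(dataset.drugs, dataset.pairs, feature_models)
    y = dataset.labels
    pools = {"odit": ([], [], []), "ndit": ([], [], [])}
    for k, fold in enumerate(split.folds):
        results = InteractionModel(
            X[fold.train], y[fold.train], feature_models=feature_models, config=config
        ).fit()
        for stratum, idx in (("odit", fold.odit), ("ndit", fold.ndit)):
            if len(idx) == 0:
                continue
            labels, scores, folds = pools[stratum]
            labels.append(y[idx])
            scores.append(results.predict_proba(X[idx]))
            folds.append(np.full(len(idx), k))
    meta = {
        "protocol": "composition_cv", "K": K, "split_seed": split_seed,
        "feature_models": models_code(feature_models), "backend": config.backend,
        "model_seed": config.seed,
    }
    odit = _pooled_result("odit", *pools["odit"], threshold, {**meta, "stratum": "ODIT"})
    ndit = _pooled_result("ndit", *pools["ndit"], threshold, {**meta, "stratum": "NDIT"})
    return odit, ndit


def run_model_grid(
    dataset: InteractionDataset,
    cv: str = "entire",
    config: ClassifierConfig | None = None,
    K: int = 10,
    split_seed: int = 0,
    combinations: tuple[str, ...] = ALL_COMBINATIONS,
) -> pd.DataFrame:
    """Evaluate every fusion-model combination under one protocol.

    Returns one summary row per combination (two per combination — ODIT and
    NDIT — for composition CV), mirroring the per-combination comparison
    tables this kind of study reports.
    """
    rows = []
    for code in combinations:
        if cv == "entire":
            res = run_entire_cv(dataset, code, config=config, K=K, split_seed=split_seed)
            rows.append({"model": code, **res.report.scalar_row()})
        elif cv == "composition":
            odit, ndit = run_composition_cv(
                dataset, code, config=config, K=K, split_seed=split_seed
            )
            rows.append({"model": code, "test_set": "ODIT", **odit.report.scalar_row()})
            rows.append({"model": code, "test_set": "NDIT", **ndit.report.scalar_row()})
        else:
            raise ValueError(f"unknown cv protocol {cv!r}")
    return pd.DataFrame(rows)
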