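"""Random-forest multimodal classification harness.

Assembles named feature combinations from per-subject multimodal records
(image morphometry x 6 structures, CSF biochemistry, MMSE), trains a
random forest with fixed design (150 trees, max depth 8, min split 2,
Gini criterion, bootstrap, sqrt features per split), and reports
stratified 10-fold cross-validation accuracy, holdout confusion matrices
and Gini-importance rankings. CDR never enters the feature vector: it
defines the diagnostic gold standard.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from sklearn.ensemble import RandomForestClassifier
from sklearn.model_selection import StratifiedKFold

from .morphometrics import IMAGE_METRICS, STRUCTURES
from .stats import CLASS_ORDER, FeatureMatrix

__all__ = [
    "RF_PARAMS",
    "BLOCK_COLUMNS",
    "STANDARD_COMBINATIONS",
    "ClassifierReport",
    "image_feature_names",
    "combination_columns",
    "assemble_features",
    "gini_impurity",
    "train_rf",
    "cross_validate",
    "evaluate_holdout",
    "run_combination_suite",
]

RF_PARAMS = {
    "n_estimators": 150,
    "max_depth": 8,
    "min_samples_split": 2,
    "criterion": "gini",
    "max_features": "sqrt",
    "bootstrap": True,
}


def image_feature_names(metrics=IMAGE_METRICS) -> list[str]:
    """Metric-major image column names, structure order GM..LPL (30 total)."""
    return [f"{m}_{s}" for m in metrics for s in STRUCTURES]


# Feature blocks a combination may draw on. Image blocks contribute one
# column per structure; CSF is the post-screening biochemical pair; MMSE
# is the single cognitive surrogate.
BLOCK_COLUMNS: dict[str, list[str]] = {
    **{m: [f"{m}_{s}" for s in STRUCTURES] for m in IMAGE_METRICS},
    "CSF": ["tau_csf", "abeta42_csf"],
    "MMSE": ["MMSE"],
}

# The six standard combinations, in table order; the with/without-TR pairs
# are (base, base+TR), (base+CSF, base+CSF+TR), (base+CSF+MMSE, all).
STANDARD_COMBINATIONS: dict[str, tuple[str, ...]] = {
    "base": ("V", "NV", "DC", "CT"),
    "base+TR": ("V", "NV", "DC", "CT", "TR"),
    "base+CSF": ("V", "NV", "DC", "CT", "CSF"),
    "base+CSF+TR": ("V", "NV", "DC", "CT", "TR", "CSF"),
    "base+CSF+MMSE": ("V", "NV", "DC", "CT", "CSF", "MMSE"),
    "all": ("V", "NV", "DC", "CT", "TR", "CSF", "MMSE"),
}

TR_PAIRS = (
    ("base", "base+TR"),
    ("base+CSF", "base+CSF+TR"),
    ("base+CSF+MMSE", "all"),
)


def combination_columns(combination) -> list[str]:
    """Deterministic column list for a combination of block names.

    Block order follows the canonical sequence V, NV, DC, CT, TR, CSF,
    MMSE regardless of the order blocks are given in.
    """
    blocks = set(combination)
    if "CDR" in blocks:
        raise ValueError("CDR is the gold standard, never a classifier feature")
    unknown = blocks - set(BLOCK_COLUMNS)
    if unknown:
        raise ValueError(f"unknown feature blocks: {sorted(unknown)}")
    if not blocks:
        raise ValueError("combination must name at least one feature block")
    ordered = [b for b in ("V", "NV", "DC", "CT", "TR", "CSF", "MMSE") if b in blocks]
    cols: list[str] = []
    for b in ordered:
        cols.extend(BLOCK_COLUMNS[b])
    return cols


def assemble_features(records: pd.DataFrame, combination) -> FeatureMatrix:
    """Build a FeatureMatrix for one combination from a subject table.

    ``records`` has one row per subject with named feature columns and a
    ``label`` column in {HC, MCI, AD}. Missing values are an error naming
    the subject and column — incomplete records are excluded upstream.
    """
    cols = combination_columns(combination)
    absent = [c for c in cols if c not in records.columns]
    if absent:
        raise ValueError(f"record table lacks columns: {absent}")
    sub = records[cols]
    if sub.isna().any().any():
        for col in cols:
            bad = records.index[sub[col].isna()]
            if len(bad):
                sid = (
                    records.loc[bad[0], "subject_id"]
                    if "subject_id" in records.columns
                    else bad[0]
                )
                raise ValueError(f"missing value for subject {sid!r}, column {col!r}")
    return FeatureMatrix(
        names=cols,
        X=sub.to_numpy(dtype=float),
        labels=records["label"].to_numpy(),
    )


def gini_impurity(class_proportions) -> float:
    """Gini impurity 1 - sum(p_j^2) of a class-proportion vector.

    Zero at a pure node, maximal at the uniform distribution.
    """
    p = np.asarray(class_proportions, dtype=float)
    if np.any(p < 0) or abs(p.sum() - 1.0) > 1e-9:
        raise ValueError(f"proportions must be >= 0 and sum to 1, got {p}")
    return float(1.0 - np.sum(p**2))


def train_rf(features: FeatureMatrix, seed: int) -> RandomForestClassifier:
    """Fit the fixed-design random forest; reproducible for a fixed seed."""
    if len(np.unique(features.labels)) < 2:
        raise ValueError("training data must contain at least 2 classes")
    clf = RandomForestClassifier(random_state=seed, **RF_PARAMS)
    clf.fit(features.X, features.labels)
    return clf


def cross_validate(
    features: FeatureMatrix, folds: int = 10, seed: int = 0
) -> tuple[np.ndarray, float, float]:
    """Stratified k-fold CV accuracy: per-fold values, mean and std."""
    _, counts = np.unique(features.labels, return_counts=True)
    if counts.min() < folds:
        raise ValueError(
            f"smallest class has {counts.min()} subjects, fewer than {folds} folds"
        )
    skf = StratifiedKFold(n_splits=folds, shuffle=True, random_state=seed)
    accs = []
    for tr_idx, te_idx in skf.split(features.X, features.labels):
        clf = RandomForestClassifier(random_state=seed, **RF_PARAMS)
        clf.fit(features.X[tr_idx], features.labels[tr_idx])
        accs.append(float(np.mean(clf.predict(features.X[te_idx]) == features.labels[te_idx])))
    accs = np.asarray(accs)
    return accs, float(accs.mean()), float(accs.std())


def evaluate_holdout(
    model: RandomForestClassifier, holdout: FeatureMatrix
) -> tuple[float, np.ndarray]:
    """Accuracy and 3x3 confusion matrix (rows true, cols predicted, HC/MCI/AD)."""
    if model.n_features_in_ != len(holdout.names):
        raise ValueError(
            f"model expects {model.n_features_in_} features, holdout has "
            f"{len(holdout.names)}"
        )
    pred = model.predict(holdout.X)
    order = {c: i for i, c in enumerate(CLASS_ORDER)}
    confusion = np.zeros((3, 3), dtype=int)
    for t, p in zip(holdout.labels, pred):
        confusion[order[t], order[p]] += 1
    accuracy = float(np.trace(confusion)) / len(holdout.labels)
    return accuracy, confusion


@dataclass
class ClassifierReport:
    """One combination's complete evaluation record."""

    combination: str
    feature_names: list[str]
    fold_accuracies: list[float]
    cv_mean: float
    cv_std: float
    holdout_accuracy: float
    confusion: np.ndarray  # rows true, cols predicted, order HC/MCI/AD
    importances: list[tuple[str, float]]  # descending Gini importance
    seed: int
    rf_params: dict = field(default_factory=lambda: dict(RF_PARAMS))

    def to_dict(self) -> dict:
        return {
            "combination": self.combination,
            "n_features": len(self.feature_names),
            "feature_names": self.feature_names,
            "fold_accuracies": self.fold_accuracies,
            "cv_mean": self.cv_mean,
            "cv_std": self.cv_std,
            "holdout_accuracy": self.holdout_accuracy,
            "confusion": self.confusion.tolist(),
            "class_order": list(CLASS_ORDER),
            "importances": [[f, v] for f, v in self.importances],
            "seed": self.seed,
            "rf_params": self.rf_params,
        }

    def to_json(self, **kwargs) -> str:
        return json.dumps(self.to_dict(), indent=2, **kwargs)


def evaluate_combination(
    train: pd.DataFrame, holdout: pd.DataFrame, name: str, blocks, seed: int,
    folds: int = 10,
) -> ClassifierReport:
    """CV on the training table, fit on all of it, evaluate on the holdout."""
    fm_train = assemble_features(train, blocks)
    fm_hold = assemble_features(holdout, blocks)
    fold_accs, mean, std = cross_validate(fm_train, folds=folds, seed=seed)
    model = train_rf(fm_train, seed=seed)
    acc, confusion = evaluate_holdout(model, fm_hold)
    ranked = sorted(
        zip(fm_train.names, model.feature_importances_),
        key=lambda t: -t[1],
    )
    return ClassifierReport(
        combination=name,
        feature_names=fm_train.names,
        fold_accuracies=[float(a) for a in fold_accs],
        cv_mean=mean,
        cv_std=std,
        holdout_accuracy=acc,
        confusion=confusion,
        importances=[(f, float(v)) for f, v in ranked],
        seed=seed,
    )


def run_combination_suite(
    train: pd.DataFrame,
    holdout: pd.DataFrame,
    combinations: dict[str, tuple[str, ...]] | None = None,
    seed: int = 0,
    folds: int = 10,
) -> tuple[list[ClassifierReport], pd.DataFrame]:
    """Evaluate every combination and emit the with/without-TR delta table.

    Returns the reports plus a DataFrame pairing each TR-free combination
    with its TR-bearing counterpart (delta = with TR minus without, for CV
    mean and holdout accuracy) — the headline comparison of the design.
    """
    if combinations is None:
        combinations = STANDARD_COMBINATIONS
    reports = [
        evaluate_combination(train, holdout, name, blocks, seed=seed, folds=folds)
        for name, blocks in combinations.items()
    ]
    by_name = {r.combination: r for r in reports}
    rows = []
    for without, with_tr in TR_PAIRS:
        if without in by_name and with_tr in by_name:
            a, b = by_name[without], by_name[with_tr]
            rows.append(
                {
                    "without_TR": without,
                    "with_TR": with_tr,
                    "cv_delta": b.cv_mean - a.cv_mean,
                    "holdout_delta": b.holdout_accuracy - a.holdout_accuracy,
                }
            )
    return reports, pd.DataFrame(rows)
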