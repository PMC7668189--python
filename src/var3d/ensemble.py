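"""Bagged decision-tree ensemble over predictor scores and P3DFi.

A random forest (2,000 Gini trees of depth ≤ 10 by default, bootstrap
resampling on) is trained on per-variant predictor scores (SIFT-like,
PolyPhen2-like, CADD-like) with or without the P3DFi index as an extra
column, and evaluated with the full confusion-matrix panel (sensitivity,
specificity, balanced accuracy, MCC, F1, precision, FPR, FNR) plus a
rank-based AUC. The decision rule is strict: score > 0.5 calls a variant
pathogenic, score ≤ 0.5 benign/neutral.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
from scipy import stats
from sklearn.ensemble import RandomForestClassifier

SCORE_COLUMNS = ["sift", "polyphen2", "cadd"]
POSITIVE_LABELS = frozenset({"pathogenic"})
NEGATIVE_LABELS = frozenset({"benign", "population"})


@dataclass
class EnsembleSpec:
    n_trees: int = 2000
    criterion: str = "gini"
    max_depth: int = 10
    bootstrap: bool = True
    threshold: float = 0.5
    seed: int = 0
    score_rule: str = "probability"  # 'probability' (mean leaf prob.) or 'vote'

    def __post_init__(self) -> None:
        if self.n_trees < 1:
            raise ValueError("n_trees must be >= 1")
        if self.max_depth < 1:
            raise ValueError("max_depth must be >= 1")
        if self.score_rule not in ("probability", "vote"):
            raise ValueError("score_rule must be 'probability' or 'vote'")


@dataclass
class EnsembleModel:
    forest: RandomForestClassifier
    features: tuple[str, ...]
    spec: EnsembleSpec


@dataclass(frozen=True)
class MetricsReport:
    sensitivity: float
    specificity: float
    balanced_accuracy: float
    mcc: float
    f1: float
    precision: float
    fpr: float
    fnr: float
    auc: float

    def to_dict(self) -> dict[str, float]:
        return {
            "sensitivity": self.sensitivity,
            "specificity": self.specificity,
            "balanced_accuracy": self.balanced_accuracy,
            "mcc": self.mcc,
            "f1": self.f1,
            "precision": self.precision,
            "fpr": self.fpr,
            "fnr": self.fnr,
            "auc": self.auc,
        }


def binarise_labels(labels: Sequence[str]) -> np.ndarray:
    """pathogenic -> 1; benign/population -> 0; anything else errors."""
    out = np.empty(len(labels), dtype=int)
    for i, lab in enumerate(labels):
        if lab in POSITIVE_LABELS:
            out[i] = 1
        elif lab in NEGATIVE_LABELS:
            out[i] = 0
        else:
            raise ValueError(f"unexpected label {lab!r}")
    return out


def drop_missing(df: pd.DataFrame, columns: Sequence[str]) -> tuple[pd.DataFrame, int]:
    """Drop rows with any missing score; returns (kept, n_dropped)."""
    mask = df[list(columns)].notna().all(axis=1)
    return df[mask].reset_index(drop=True), int((~mask).sum())


def train(
    samples: pd.DataFrame,
    features: Sequence[str],
    spec: EnsembleSpec | None = None,
) -> EnsembleModel:
    """Fit the forest on ``samples`` using the given feature columns.

    ``samples`` must have a ``label`` column with both classes present;
    rows with missing feature values must be dropped beforehand (see
    :func:`drop_missing`).
    """
    spec = spec or EnsembleSpec()
    y = binarise_labels(samples["label"].tolist())
    if len(set(y)) < 2:
        raise ValueError("training set must contain both classes")
    X = samples[list(features)].to_numpy(dtype=float)
    if np.isnan(X).any():
        raise ValueError("missing feature values in training set")
    forest = RandomForestClassifier(
        n_estimators=spec.n_trees,
        criterion=spec.criterion,
        max_depth=spec.max_depth,
        bootstrap=spec.bootstrap,
        random_state=spec.seed,
        n_jobs=1,
    )
    forest.fit(X, y)
    return EnsembleModel(forest, tuple(features), spec)


def predict_score(model: EnsembleModel, samples: pd.DataFrame) -> np.ndarray:
    """Pathogenicity score in [0, 1] per sample.

    'probability' averages per-tree class probabilities (the default);
    'vote' reports the fraction of trees voting pathogenic.
    """
    missing = set(model.features) - set(samples.columns)
    if missing:
        raise ValueError(f"samples lack feature columns {sorted(missing)}")
    X = samples[list(model.features)].to_numpy(dtype=float)
    pos = list(model.forest.classes_).index(1)
    if model.spec.score_rule == "probability":
        return model.forest.predict_proba(X)[:, pos]
    votes = np.stack([t.predict(X) for t in model.forest.estimators_])
    return (votes == model.forest.classes_[pos]).mean(axis=0)


def predict_label(scores: np.ndarray, threshold: float = 0.5) -> np.ndarray:
    """Strict rule: score > threshold is pathogenic (1), else benign (0)."""
    return (np.asarray(scores) > threshold).astype(int)


def rank_auc(y_true: np.ndarray, scores: np.ndarray) -> float:
    """AUC as P(random positive outranks random negative), midranks for ties."""
    y_true = np.asarray(y_true)
    scores = np.asarray(scores, dtype=float)
    n_pos = int(y_true.sum())
    n_neg = len(y_true) - n_pos
    if n_pos == 0 or n_neg == 0:
        return math.nan
    ranks = stats.rankdata(scores)
    r_pos = ranks[y_true == 1].sum()
    return float((r_pos - n_pos * (n_pos + 1) / 2) / (n_pos * n_neg))


def compute_metrics(
    y_true: Sequence[int],
    y_pred: Sequence[int],
    scores: Sequence[float] | None = None,
) -> MetricsReport:
    """Confusion-matrix panel; one-class truth yields nan sentinels and
    a zero MCC denominator yields MCC = 0 (documented convention)."""
    y_true = np.asarray(y_true, dtype=int)
    y_pred = np.asarray(y_pred, dtype=int)
    tp = int(((y_true == 1) & (y_pred == 1)).sum())
    fn = int(((y_true == 1) & (y_pred == 0)).sum())
    tn = int(((y_true == 0) & (y_pred == 0)).sum())
    fp = int(((y_true == 0) & (y_pred == 1)).sum())

    sens = tp / (tp + fn) if tp + fn else math.nan
    spec = tn / (tn + fp) if tn + fp else math.nan
    prec = tp / (tp + fp) if tp + fp else math.nan
    f1 = 2 * tp / (2 * tp + fp + fn) if 2 * tp + fp + fn else math.nan
    denom = math.sqrt(
        float(tp + fp) * float(tp + fn) * float(tn + fp) * float(tn + fn)
    )
    mcc = (tp * tn - fp * fn) / denom if denom else 0.0
    auc = rank_auc(y_true, scores) if scores is not None else math.nan
    return MetricsReport(
        sensitivity=sens,
        specificity=spec,
        balanced_accuracy=(sens + spec) / 2,
        mcc=mcc,
        f1=f1,
        precision=prec,
        fpr=1 - spec if not math.isnan(spec) else math.nan,
        fnr=1 - sens if not math.isnan(sens) else math.nan,
        auc=auc,
    )


def evaluate(
    model: EnsembleModel, test: pd.DataFrame
) -> tuple[MetricsReport, np.ndarray]:
    """Score a held-out set and compute the metric panel."""
    if len(test) == 0:
        raise ValueError("empty test set")
    scores = predict_score(model, test)
    y_true = binarise_labels(test["label"].tolist())
    y_pred = predict_label(scores, model.spec.threshold)
    return compute_metrics(y_true, y_pred, scores), scores


def compare_models(
    train_df: pd.DataFrame,
    test_df: pd.DataFrame,
    feature_sets: Mapping[str, Sequence[str]],
    spec: EnsembleSpec | None = None,
) -> dict[str, MetricsReport]:
    """Train one model per feature set on a common split and evaluate all
    on the identical test set (the with/without-P3DFi comparison)."""
    spec = spec or EnsembleSpec()
    out: dict[str, MetricsReport] = {}
    for name, feats in feature_sets.items():
        model = train(train_df, feats, spec)
        out[name], _ = evaluate(model, test_df)
    return out


def roc_table(y_true: Sequence[int], scores: Sequence[float]) -> pd.DataFrame:
    """threshold/FPR/TPR rows sufficient to replot the ROC curve."""
    from sklearn.metrics import roc_curve

    fpr, tpr, thr = roc_curve(np.asarray(y_true), np.asarray(scores, dtype=float))
    return pd.DataFrame({"threshold": thr, "fpr": fpr, "tpr": tpr})
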