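"""Classifiers separating antibody aggregates (label 0) from EV particles (label 1).

Training data come from the two unambiguous populations: double-positive
clusters (true vesicles) and antibody-only control clusters (aggregates).
Each double positive is split into two single-positive-like rows — one per
channel view, the other channel's binned count zeroed — because the deployed
model scores single-positive rows, which carry signal in one channel only.
Class weights are balanced since aggregates usually outnumber vesicles.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from sklearn.ensemble import RandomForestClassifier
from sklearn.inspection import permutation_importance
from sklearn.linear_model import LogisticRegression
from sklearn.metrics import (
    accuracy_score,
    precision_recall_curve,
    precision_score,
    recall_score,
    roc_auc_score,
    roc_curve,
)
from sklearn.pipeline import make_pipeline
from sklearn.preprocessing import StandardScaler
from sklearn.svm import SVC

from evpipe.cluster_features import FEATURE_NAMES
from evpipe.phenotyping import PhenotypeSummary, PHENOTYPES
from evpipe.size_correction import CorrectedSummary

MODEL_NAMES = ("random_forest", "logistic_regression", "svm")

#: model input columns: the 12 descriptors plus a degeneracy indicator
TRAINING_COLUMNS = FEATURE_NAMES + ["degenerate"]


@dataclass
class TrainingSet:
    X: pd.DataFrame
    y: np.ndarray
    provenance: np.ndarray = field(default=None)

    def __post_init__(self) -> None:
        if list(self.X.columns) != TRAINING_COLUMNS:
            raise ValueError("feature matrix must have the canonical columns")
        if len(self.X) != len(self.y):
            raise ValueError("X/y length mismatch")


@dataclass
class EvaluationMetrics:
    accuracy: float
    precision: float
    recall: float
    auc_roc: float
    roc_points: pd.DataFrame = field(repr=False, default=None)
    pr_points: pd.DataFrame = field(repr=False, default=None)


def _prepare(features: pd.DataFrame) -> pd.DataFrame:
    """Canonical model matrix: impute NaN/degenerate values to 0, add indicator."""
    out = features.reindex(columns=FEATURE_NAMES).astype(float)
    if "degenerate" in features.columns:
        degen = features["degenerate"].astype(bool).to_numpy()
    else:
        degen = np.zeros(len(features), dtype=bool)
    degen = degen | out.isna().any(axis=1).to_numpy()
    out = out.fillna(0.0)
    out["degenerate"] = degen.astype(float)
    return out.reset_index(drop=True)


def split_double_positive(dp_features: pd.DataFrame) -> pd.DataFrame:
    """Two rows per double positive, emulating single-positive signatures.

    Each channel view zeroes the cross-channel binned count and rescales the
    count-coupled features (num_localisations, density) to the kept channel,
    so a view is commensurate with a genuine single positive; the geometry
    features (hull, radius of gyration, ...) are shared.
    """
    views = []
    for own, other in (("ch1_binned_counts", "ch2_binned_counts"),
                       ("ch2_binned_counts", "ch1_binned_counts")):
        v = dp_features.copy()
        own_counts = v[own].to_numpy(float)
        v[other] = 0
        v["num_localisations"] = own_counts
        hull = v["convex_hull_area"].to_numpy(float)
        with np.errstate(divide="ignore", invalid="ignore"):
            dens = np.where(hull > 0, own_counts / hull, 0.0)
        v["density"] = dens
        views.append(v)
    return pd.concat(views, ignore_index=True)


def build_training_set(
    dp_features: pd.DataFrame,
    ab_features: pd.DataFrame,
    dp_views: pd.DataFrame | None = None,
) -> TrainingSet:
    """Label double positives 1 (two channel views each) and controls 0.

    ``dp_views`` may supply exact per-channel feature rows recomputed from
    the raw localizations (two per double positive); otherwise the views are
    derived from the pooled feature rows by :func:`split_double_positive`.
    """
    if len(dp_features) == 0 or len(ab_features) == 0:
        raise ValueError("both classes must be non-empty")
    if dp_views is not None:
        if len(dp_views) != 2 * len(dp_features):
            raise ValueError("dp_views must hold exactly two rows per double positive")
        pos = _prepare(dp_views)
    else:
        pos = _prepare(split_double_positive(dp_features))
    neg = _prepare(ab_features)
    X = pd.concat([pos, neg], ignore_index=True)
    y = np.concatenate([np.ones(len(pos), dtype=int), np.zeros(len(neg), dtype=int)])
    provenance = np.array(
        ["double_positive"] * len(pos) + ["antibody_control"] * len(neg)
    )
    return TrainingSet(X=X, y=y, provenance=provenance)


def train_model(ts: TrainingSet, model: str = "random_forest", seed: int = 0):
    """Fit one of the three balanced-weight classifiers; deterministic per seed."""
    if len(np.unique(ts.y)) < 2:
        raise ValueError("training set must contain both classes")
    if model == "random_forest":
        clf = RandomForestClassifier(
            n_estimators=200, class_weight="balanced", random_state=seed, n_jobs=1
        )
    elif model == "logistic_regression":
        clf = make_pipeline(
            StandardScaler(),
            LogisticRegression(class_weight="balanced", max_iter=5000, random_state=seed),
        )
    elif model == "svm":
        clf = make_pipeline(
            StandardScaler(), SVC(class_weight="balanced", random_state=seed)
        )
    else:
        raise ValueError(f"unknown model {model!r}; choose from {MODEL_NAMES}")
    clf.fit(ts.X, ts.y)
    return clf


def decision_scores(model, X: pd.DataFrame) -> np.ndarray:
    """Continuous score for the positive (EV) class."""
    if hasattr(model, "predict_proba"):
        return model.predict_proba(X)[:, 1]
    return model.decision_function(X)


def evaluate(model, test: TrainingSet) -> EvaluationMetrics:
    """Held-out metrics; ROC/PR by threshold sweep of the model scores."""
    if len(test.X) == 0:
        raise ValueError("empty test set")
    if len(np.unique(test.y)) < 2:
        raise ValueError("test set must contain both classes for AUC")
    y_pred = model.predict(test.X)
    scores = decision_scores(model, test.X)
    fpr, tpr, roc_thr = roc_curve(test.y, scores)
    prec, rec, pr_thr = precision_recall_curve(test.y, scores)
    return EvaluationMetrics(
        accuracy=float(accuracy_score(test.y, y_pred)),
        precision=float(precision_score(test.y, y_pred)),
        recall=float(recall_score(test.y, y_pred)),
        auc_roc=float(roc_auc_score(test.y, scores)),
        roc_points=pd.DataFrame({"fpr": fpr, "tpr": tpr}),
        pr_points=pd.DataFrame({"precision": prec, "recall": rec}),
    )


def ml_correct(
    raw: PhenotypeSummary, sp_features: pd.DataFrame, model
) -> CorrectedSummary:
    """Remove single positives the classifier calls aggregates; renormalize.

    ``sp_features`` must carry the feature columns plus a ``phenotype``
    column restricted to the two single-positive classes.
    """
    sp = sp_features[sp_features["phenotype"].isin(["CD81_only", "CD9_only"])]
    counts = {
        "CD81_only": 0.0,
        "CD9_only": 0.0,
        "double_positive": float(raw.counts["double_positive"]),
    }
    if len(sp):
        pred = model.predict(_prepare(sp))
        for p in ("CD81_only", "CD9_only"):
            kept = int(((sp["phenotype"] == p).to_numpy() & (pred == 1)).sum())
            counts[p] = float(kept)
    total = sum(counts.values())
    if total == 0:
        raise ValueError("no particles left after ML correction")
    fractions = {p: counts[p] / total for p in PHENOTYPES}
    return CorrectedSummary(counts=counts, fractions=fractions, correction_method="ml")


def feature_importance(
    model, ts: TrainingSet, seed: int = 0, n_repeats: int = 10
) -> pd.DataFrame:
    """Permutation importance (model-agnostic), ranked by mean decrease."""
    res = permutation_importance(
        model, ts.X, ts.y, n_repeats=n_repeats, random_state=seed, n_jobs=1
    )
    report = pd.DataFrame(
        {
            "feature": ts.X.columns,
            "importance_mean": res.importances_mean,
            "importance_sd": res.importances_std,
        }
    ).sort_values("importance_mean", ascending=False, kind="mergesort")
    report["rank"] = np.arange(1, len(report) + 1)
    return report.reset_index(drop=True)
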