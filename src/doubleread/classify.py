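"""Discordance prediction from baseline features.

Repeated stratified 80:20 cross-validation of two tabular classifiers (a
random forest, optionally after recursive feature elimination, and a small
feed-forward network standing in for a generic deep tabular model), with
pooled-test-set metrics (AUC, accuracy, sensitivity, specificity, PPV,
NPV) reported as percentages with percentile-bootstrap confidence
intervals.  Accuracy is only marked reportable when McNemar's test finds
no significant imbalance bias between the classifier's errors.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from sklearn.ensemble import RandomForestClassifier
from sklearn.metrics import roc_auc_score
from sklearn.model_selection import train_test_split
from sklearn.neural_network import MLPClassifier

from .risk_factors import BINARY_FEATURES, CONTINUOUS_FEATURES
from .stats import bootstrap_ci, mcnemar

__all__ = [
    "MODEL_NAMES",
    "ClassificationReport",
    "build_feature_matrix",
    "crossval_classify",
    "recursive_feature_elimination",
]

MODEL_NAMES = ("forest", "feedforward")
METRIC_NAMES = ("auc", "acc", "se", "sp", "ppv", "npv")


@dataclass
class ClassificationReport:
    kod_name: str
    model: str
    n_train: int
    n_test: int
    n_repeats: int
    metrics: dict[str, float] = field(default_factory=dict)  # percentages
    ci: dict[str, tuple[float, float]] = field(default_factory=dict)
    mcnemar_p: float = math.nan
    acc_reportable: bool = True

    def to_frame(self) -> pd.DataFrame:
        rows = [
            {
                "kod": self.kod_name,
                "model": self.model,
                "metric": m,
                "value_pct": self.metrics[m],
                "ci_low_pct": self.ci[m][0],
                "ci_high_pct": self.ci[m][1],
            }
            for m in METRIC_NAMES
        ]
        return pd.DataFrame(rows)


def build_feature_matrix(
    features: pd.DataFrame,
    kods: pd.DataFrame,
    kod_name: str,
    feature_names: list[str] | None = None,
) -> tuple[pd.DataFrame, np.ndarray, list[str]]:
    """Labeled per-patient matrix for one KoD.

    Inner-joins the feature and KoD tables on patient id, casts binary
    features to 0/1 and median-imputes missing continuous ones.  Returns
    ``(X, y, imputed_columns)``.
    """
    feature_names = feature_names or (BINARY_FEATURES + CONTINUOUS_FEATURES)
    labels = kods.loc[kods["included"], ["patient_id", kod_name]]
    merged = features.merge(labels, on="patient_id", how="inner")
    if merged.empty:
        raise ValueError("no overlapping patients between tables")
    if len(merged) < 10:
        raise ValueError(f"too few patients ({len(merged)}) to classify")
    y = merged[kod_name].astype(bool).to_numpy()
    if len(np.unique(y)) < 2:
        raise ValueError("labels are single-class")
    X = merged[feature_names].copy()
    imputed: list[str] = []
    for col in feature_names:
        if X[col].dtype == bool:
            X[col] = X[col].astype(int)
        elif X[col].isna().any():
            X[col] = X[col].fillna(X[col].median())
            imputed.append(col)
    X.index = merged["patient_id"]
    return X, y, imputed


def _make_model(model: str, seed: int):
    if model == "forest":
        return RandomForestClassifier(
            n_estimators=200, min_samples_leaf=2, random_state=seed
        )
    if model == "feedforward":
        return MLPClassifier(
            hidden_layer_sizes=(16, 8),
            alpha=1e-3,
            max_iter=600,
            random_state=seed,
        )
    raise ValueError(f"unknown model {model!r}; choose from {MODEL_NAMES}")


def _confusion_metrics(y_true: np.ndarray, y_pred: np.ndarray) -> dict[str, float]:
    tp = float(np.sum(y_pred & y_true))
    tn = float(np.sum(~y_pred & ~y_true))
    fp = float(np.sum(y_pred & ~y_true))
    fn = float(np.sum(~y_pred & y_true))
    div = lambda a, b: a / b if b > 0 else math.nan  # noqa: E731
    return {
        "acc": div(tp + tn, tp + tn + fp + fn),
        "se": div(tp, tp + fn),
        "sp": div(tn, tn + fp),
        "ppv": div(tp, tp + fp),
        "npv": div(tn, tn + fn),
    }


def crossval_classify(
    X: pd.DataFrame,
    y: np.ndarray,
    kod_name: str = "kod",
    model: str = "forest",
    test_size: float = 0.2,
    n_repeats: int = 50,
    n_boot: int = 1000,
    threshold: float = 0.5,
    seed: int = 0,
    max_resplits: int = 20,
) -> ClassificationReport:
    """Repeated stratified 80:20 evaluation of one classifier.

    Test-fold predictions are pooled over repeats; all metrics and their
    percentile-bootstrap CIs come from the pooled predictions.  Degenerate
    splits (single-class training fold) are redrawn with a shifted seed, up
    to ``max_resplits`` times.
    """
    y = np.asarray(y, dtype=bool)
    truths, preds, probs = [], [], []
    for rep in range(n_repeats):
        for attempt in range(max_resplits):
            split_seed = seed + 1000 * rep + attempt
            X_tr, X_te, y_tr, y_te = train_test_split(
                X.to_numpy(dtype=float),
                y,
                test_size=test_size,
                random_state=split_seed,
                stratify=y,
            )
            if len(np.unique(y_tr)) == 2 and len(np.unique(y_te)) == 2:
                break
        else:
            raise RuntimeError("could not obtain a two-class split")
        clf = _make_model(model, seed=split_seed)
        clf.fit(X_tr, y_tr)
        p = clf.predict_proba(X_te)[:, list(clf.classes_).index(True)]
        truths.append(y_te)
        preds.append(p >= threshold)
        probs.append(p)
    y_true = np.concatenate(truths)
    y_pred = np.concatenate(preds)
    y_prob = np.concatenate(probs)

    metrics = _confusion_metrics(y_true, y_pred)
    metrics["auc"] = roc_auc_score(y_true, y_prob)
    rng = np.random.default_rng(seed)
    idx = np.arange(y_true.size, dtype=float)

    def metric_stat(name):
        def stat(sample_idx):
            ii = sample_idx.astype(int)
            if name == "auc":
                if len(np.unique(y_true[ii])) < 2:
                    return math.nan
                return roc_auc_score(y_true[ii], y_prob[ii])
            return _confusion_metrics(y_true[ii], y_pred[ii])[name]

        return stat

    ci = {}
    for name in METRIC_NAMES:
        lo, hi = bootstrap_ci(
            idx, statistic=metric_stat(name), n_boot=n_boot, seed=rng
        )
        ci[name] = (round(100 * lo, 1), round(100 * hi, 1))
    b = int(np.sum(y_pred & ~y_true))
    c = int(np.sum(~y_pred & y_true))
    _, mcnemar_p = mcnemar(b, c)
    return ClassificationReport(
        kod_name=kod_name,
        model=model,
        n_train=int(round((1 - test_size) * len(y))),
        n_test=int(round(test_size * len(y))),
        n_repeats=n_repeats,
        metrics={m: round(100 * v, 1) for m, v in metrics.items()},
        ci=ci,
        mcnemar_p=mcnemar_p,
        acc_reportable=mcnemar_p > 0.05,
    )


def recursive_feature_elimination(
    X: pd.DataFrame,
    y: np.ndarray,
    seed: int = 0,
    n_repeats: int = 5,
    test_size: float = 0.2,
) -> tuple[list[str], pd.DataFrame]:
    """Backward feature elimination driven by forest importances.

    Iteratively drops the least-important feature, scoring each subset by
    repeated-split AUC, and returns ``(best_subset, path)`` where the path
    records subset size, features and AUC at each step.
    """
    if X.shape[1] < 1:
        raise ValueError("need at least one feature")
    current = list(X.columns)
    rows = []
    best_subset, best_auc = list(current), -math.inf
    while current:
        rep = crossval_classify(
            X[current],
            y,
            model="forest",
            n_repeats=n_repeats,
            n_boot=50,
            test_size=test_size,
            seed=seed,
        )
        auc = rep.metrics["auc"]
        rows.append(
            {"n_features": len(current), "features": tuple(current), "auc": auc}
        )
        if auc > best_auc:
            best_subset, best_auc = list(current), auc
        if len(current) == 1:
            break
        forest = _make_model("forest", seed)
        forest.fit(X[current].to_numpy(dtype=float), y)
        drop = current[int(np.argmin(forest.feature_importances_))]
        current = [c for c in current if c != drop]
    return best_subset, pd.DataFrame(rows)
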