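"""Classifier training, repeated stratified k-fold CV, ROC/AUC, transfer.

Random forest (500 trees) is the primary model; an RBF-kernel SVM with cost 1
and a median-heuristic sigma grid is available as an alternative. Evaluation
is repeated stratified 3-fold cross-validation with a per-repeat AUC and a
normal-approximation confidence interval over repeats. A tissue-trained model
can be transferred unchanged to plasma score matrices on the same markers.
"""
from __future__ import annotations

from dataclasses import dataclass
from typing import Sequence

import numpy as np
import pandas as pd
from scipy.cluster.hierarchy import leaves_list, linkage
from scipy.spatial.distance import pdist
from sklearn.decomposition import PCA
from sklearn.ensemble import RandomForestClassifier
from sklearn.metrics import roc_auc_score, roc_curve as _sk_roc_curve
from sklearn.svm import SVC

from .errors import EmptyCohortError, SchemaError, StratificationError
from sklearn.model_selection import StratifiedKFold


@dataclass
class ModelConfig:
    model: str = "random_forest"   # or "svm_rbf"
    n_trees: int = 500
    svm_cost: float = 1.0
    k_folds: int = 3
    n_repeats: int = 10
    seed: int = 0

    def __post_init__(self):
        if self.model not in ("random_forest", "svm_rbf"):
            raise SchemaError("model must be random_forest or svm_rbf")
        if self.n_trees < 1 or self.k_folds < 2 or self.n_repeats < 1:
            raise SchemaError("invalid model configuration")


@dataclass
class CVResult:
    """Out-of-fold scores and per-repeat AUCs of a repeated CV run."""

    oof_scores: pd.DataFrame       # samples x repeats
    fold_assignments: pd.DataFrame  # samples x repeats
    repeat_aucs: np.ndarray
    mean_auc: float
    ci_lower: float
    ci_upper: float
    seed: int

    def mean_scores(self) -> pd.Series:
        return self.oof_scores.mean(axis=1)


def _derived_seed(*parts: int) -> int:
    return int(np.random.SeedSequence(list(parts)).generate_state(1)[0] % (2**31))


def _labels_to_binary(labels: pd.Series, positive_label=None) -> tuple[np.ndarray, object]:
    classes = sorted(pd.unique(labels.dropna()))
    if len(classes) != 2:
        raise SchemaError(f"need exactly two classes, got {classes}")
    if positive_label is None:
        positive_label = classes[1]
    elif positive_label not in classes:
        raise SchemaError(f"positive label {positive_label!r} not in {classes}")
    return (labels == positive_label).to_numpy(), positive_label


def _impute_medians(train: np.ndarray, y: np.ndarray | None = None) -> np.ndarray:
    """Per-feature imputation reference from the training data.

    An undetected block carries no evidence of the case-specific signal, so
    missing cells are imputed with the *control-class* (background) median
    when labels are available; the pooled training median is class-informative
    and would inject case signal into controls. Features never observed in the
    reference fall back to the pooled median, then to 0.5 (the midpoint of the
    score scale).
    """
    with np.errstate(all="ignore"):
        pooled = np.nanmedian(train, axis=0)
        med = np.nanmedian(train[~y], axis=0) if y is not None else pooled
    med = np.where(np.isfinite(med), med, pooled)
    return np.where(np.isfinite(med), med, 0.5)


def _fill(X: np.ndarray, medians: np.ndarray) -> np.ndarray:
    X = X.copy()
    idx = np.where(np.isnan(X))
    X[idx] = medians[idx[1]]
    return X


def _median_heuristic_gamma(X: np.ndarray) -> float:
    d2 = pdist(X, metric="sqeuclidean")
    d2 = d2[d2 > 0]
    return 1.0 / float(np.median(d2)) if d2.size else 1.0


def _make_estimator(config: ModelConfig, seed: int, X: np.ndarray, y: np.ndarray):
    if config.model == "random_forest":
        return RandomForestClassifier(n_estimators=config.n_trees, random_state=seed)
    g0 = _median_heuristic_gamma(X)
    grid = g0 * 2.0 ** np.arange(-4, 5)
    best_g, best_auc = grid[0], -np.inf
    inner_k = min(3, int(np.bincount(y.astype(int)).min()))
    if inner_k >= 2:
        skf = StratifiedKFold(inner_k, shuffle=True, random_state=seed)
        for g in grid:
            aucs = []
            for tr, te in skf.split(X, y):
                if len(np.unique(y[te])) < 2:
                    continue
                m = SVC(C=config.svm_cost, kernel="rbf", gamma=g).fit(X[tr], y[tr])
                aucs.append(roc_auc_score(y[te], m.decision_function(X[te])))
            score = np.mean(aucs) if aucs else -np.inf
            if score > best_auc:
                best_auc, best_g = score, g
    return SVC(C=config.svm_cost, kernel="rbf", gamma=best_g)


def _score_samples(est, X: np.ndarray) -> np.ndarray:
    if hasattr(est, "predict_proba"):
        return est.predict_proba(X)[:, list(est.classes_).index(True)]
    from scipy.special import expit

    return expit(est.decision_function(X))


def cross_validate(
    features: pd.DataFrame,
    labels: pd.Series,
    config: ModelConfig | None = None,
    positive_label=None,
) -> CVResult:
    """Repeated stratified k-fold CV; every sample scored once per repeat.

    Missing feature values are imputed with the training fold's control-class
    per-feature median (leak-free; see :func:`_impute_medians`). Deterministic
    given ``config.seed``.
    """
    config = config or ModelConfig()
    labels = labels.loc[features.index]
    y, positive_label = _labels_to_binary(labels, positive_label)
    counts = np.bincount(y.astype(int))
    if counts.min() < config.k_folds:
        raise StratificationError(
            f"each class needs >= k_folds={config.k_folds} samples, got {counts.tolist()}"
        )
    X = features.to_numpy(dtype=float)
    n = X.shape[0]
    oof = np.full((n, config.n_repeats), np.nan)
    folds = np.full((n, config.n_repeats), -1, dtype=int)
    aucs = np.empty(config.n_repeats)
    for r in range(config.n_repeats):
        skf = StratifiedKFold(
            config.k_folds, shuffle=True, random_state=_derived_seed(config.seed, r)
        )
        for f, (tr, te) in enumerate(skf.split(X, y)):
            med = _impute_medians(X[tr], y[tr])
            est = _make_estimator(
                config, _derived_seed(config.seed, r, f), _fill(X[tr], med), y[tr]
            )
            est.fit(_fill(X[tr], med), y[tr])
            oof[te, r] = _score_samples(est, _fill(X[te], med))
            folds[te, r] = f
        aucs[r] = roc_auc_score(y, oof[:, r])
    mean, lo, hi = auc_confidence_interval(aucs) if config.n_repeats > 1 else (
        float(aucs[0]), float(aucs[0]), float(aucs[0])
    )
    return CVResult(
        pd.DataFrame(oof, index=features.index,
                     columns=[f"repeat_{r}" for r in range(config.n_repeats)]),
        pd.DataFrame(folds, index=features.index,
                     columns=[f"repeat_{r}" for r in range(config.n_repeats)]),
        aucs, mean, lo, hi, config.seed,
    )


def roc_points(scores: Sequence[float], labels: Sequence[bool]) -> pd.DataFrame:
    """ROC curve points (FPR, TPR) ordered by threshold."""
    y = np.asarray(labels, dtype=bool)
    if y.all() or not y.any():
        raise EmptyCohortError("ROC needs both classes")
    fpr, tpr, thr = _sk_roc_curve(y, np.asarray(scores, dtype=float))
    return pd.DataFrame({"fpr": fpr, "tpr": tpr, "threshold": thr})


def auc(scores: Sequence[float], labels: Sequence[bool]) -> float:
    """Probability that a random positive outranks a random negative (ties 1/2)."""
    y = np.asarray(labels, dtype=bool)
    if y.all() or not y.any():
        raise EmptyCohortError("AUC needs both classes")
    return float(roc_auc_score(y, np.asarray(scores, dtype=float)))


def auc_confidence_interval(repeat_aucs: Sequence[float]) -> tuple[float, float, float]:
    """Normal-approximation 95% CI over per-repeat AUCs, truncated to [0, 1]."""
    a = np.asarray(repeat_aucs, dtype=float)
    if a.size < 2:
        raise SchemaError("confidence interval needs >= 2 repeats")
    mean = float(a.mean())
    half = 1.96 * float(a.std(ddof=1)) / np.sqrt(a.size)
    return mean, max(0.0, mean - half), min(1.0, mean + half)


@dataclass
class FittedModel:
    """A trained classifier plus everything needed to apply it elsewhere."""

    estimator: object
    columns: list[str]
    medians: np.ndarray
    positive_label: object


def fit_model(
    features: pd.DataFrame,
    labels: pd.Series,
    config: ModelConfig | None = None,
    positive_label=None,
) -> FittedModel:
    """Fit one model on the full feature matrix (e.g. all tissue samples)."""
    config = config or ModelConfig()
    labels = labels.loc[features.index]
    y, positive_label = _labels_to_binary(labels, positive_label)
    X = features.to_numpy(dtype=float)
    med = _impute_medians(X, y)
    est = _make_estimator(config, _derived_seed(config.seed, 9999), _fill(X, med), y)
    est.fit(_fill(X, med), y)
    return FittedModel(est, list(features.columns), med, positive_label)


def transfer_predict(model: FittedModel, features: pd.DataFrame) -> pd.Series:
    """Apply a tissue-trained model to new samples on the same marker columns.

    Missing cells are imputed with the training medians; a marker column
    absent from the new matrix is a schema error.
    """
    missing = [c for c in model.columns if c not in features.columns]
    if missing:
        raise SchemaError(f"marker columns absent from matrix: {missing[:5]}")
    X = features[model.columns].to_numpy(dtype=float)
    return pd.Series(
        _score_samples(model.estimator, _fill(X, model.medians)),
        index=features.index,
        name="score",
    )


def predict_mvi(
    features: pd.DataFrame,
    labels: pd.Series,
    config: ModelConfig | None = None,
    threshold: float = 0.5,
) -> tuple[CVResult, pd.Series]:
    """Cross-validated MVI classification plus hard calls.

    Hard calls threshold the across-repeat mean out-of-fold score at 0.5;
    they feed the survival comparison of predicted MVI groups.
    """
    cv = cross_validate(features, labels, config, positive_label="positive")
    calls = cv.mean_scores().ge(threshold).map({True: "positive", False: "negative"})
    calls.name = "predicted_mvi"
    return cv, calls


@dataclass
class UnsupervisedViews:
    """Hierarchical clustering and PCA of the most variable blocks."""

    block_ids: list[str]
    linkage_matrix: np.ndarray
    leaf_order: list[str]
    pc_scores: pd.DataFrame
    explained_variance_ratio: np.ndarray


def unsupervised_views(matrix: pd.DataFrame, top_k: int = 100) -> UnsupervisedViews:
    """Average-linkage correlation-distance clustering + PC scores.

    Blocks are ranked by cross-sample SD; missing cells are filled with the
    block median before distance computation. Deterministic.
    """
    if matrix.shape[0] < 2:
        raise EmptyCohortError("need at least two samples")
    data = matrix.dropna(axis=1, how="all")
    sd = data.std(axis=0, ddof=1).fillna(0.0)
    top = sd.sort_values(ascending=False, kind="stable").index[:top_k]
    sub = data[top].apply(lambda col: col.fillna(col.median()), axis=0)
    X = sub.to_numpy(dtype=float)
    dist = pdist(X, metric="correlation")
    dist = np.nan_to_num(dist, nan=0.0)  # constant samples -> zero distance
    Z = linkage(dist, method="average")
    order = [matrix.index[i] for i in leaves_list(Z)]
    n_comp = max(1, min(X.shape[0] - 1, X.shape[1]))
    pca = PCA(n_components=n_comp, svd_solver="full")
    scores = pca.fit_transform(X - X.mean(axis=0))
    pc = pd.DataFrame(
        scores, index=matrix.index, columns=[f"PC{i + 1}" for i in range(n_comp)]
    )
    return UnsupervisedViews(list(top), Z, order, pc, pca.explained_variance_ratio_)
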