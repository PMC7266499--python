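"""Tree-based participant classification from CSF protein panels.

The feature-selection stage fits a single decision tree (axis-aligned,
Gini impurity) whose maximum depth is increased until the training
accuracy reaches 1.0; the features the tree uses, in traversal order
(root first, then by level), are the candidate panel. Rank stability is
assessed by refitting the tree many times with shuffled sample order and
random split tie-breaking, recording how often each protein occupies the
root (rank 1) and the second level (ranks 2-3). Features are then added
iteratively in tree order until the cross-validated AUC plateaus.

Evaluation uses stratified k-fold cross-validation (k = 6): per fold a
gradient-boosted tree ensemble is trained with early stopping (10 rounds,
log-loss on a held-out slice of the training fold) and scored on the test
fold. Because the test folds partition the samples, pooling them yields a
combined confusion matrix in which each participant is predicted exactly
once ("net reclassification"); sensitivity, specificity and accuracy
derive from it at a probability cutoff of 0.5.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Literal, Sequence

import numpy as np
import pandas as pd
from sklearn.ensemble import GradientBoostingClassifier
from sklearn.metrics import roc_curve
from sklearn.model_selection import StratifiedKFold
from sklearn.tree import DecisionTreeClassifier

from .datatypes import IntensityMatrix

__all__ = [
    "MLConfig",
    "MLReport",
    "prepare_feature_table",
    "fit_decision_tree",
    "tree_feature_order",
    "min_depth_for_full_training_accuracy",
    "feature_rank_stability",
    "iterative_feature_addition",
    "kfold_evaluate",
    "roc_auc",
    "confusion_metrics",
]


@dataclass
class MLConfig:
    k_folds: int = 6
    n_stability_repeats: int = 10_000
    early_stopping_rounds: int = 10
    eval_metric: str = "logloss"
    plateau_epsilon: float = 0.01  # AUC units
    backend: Literal["gradient_boosting", "xgboost"] = "gradient_boosting"
    validation_fraction: float = 0.2  # early-stopping slice of the training fold
    stratified: bool = True
    seed: int = 0

    def __post_init__(self) -> None:
        if self.k_folds < 2:
            raise ValueError("k_folds must be >= 2")
        if self.n_stability_repeats < 1:
            raise ValueError("n_stability_repeats must be >= 1")


@dataclass
class MLReport:
    fold_curves: list[tuple[np.ndarray, np.ndarray]]  # (fpr, tpr) per fold
    fold_aucs: list[float]
    mean_auc: float
    tp: int
    fn: int
    tn: int
    fp: int
    sensitivity: float
    specificity: float
    accuracy: float
    feature_names: list[str] = field(default_factory=list)


def prepare_feature_table(
    zmatrix: IntensityMatrix,
    protein_ids: Sequence[str],
    labels: pd.Series,
    impute_zero: bool = True,
) -> tuple[pd.DataFrame, pd.Series]:
    """samples x features table from a within-cohort Z-scored matrix.

    Missing Z-scores are replaced with 0 (the stratum mean) unless the
    downstream learner handles missing values natively. Labels are aligned
    to the matrix samples; samples without a label are dropped.
    """
    protein_ids = list(protein_ids)
    if not protein_ids:
        raise ValueError("protein subset must be non-empty")
    unknown = [p for p in protein_ids if p not in zmatrix.values.index]
    if unknown:
        raise KeyError(f"unknown proteins: {unknown}")
    cols = [s for s in zmatrix.samples if s in labels.index]
    X = zmatrix.values.loc[protein_ids, cols].T
    if impute_zero:
        X = X.fillna(0.0)
    return X, labels.loc[cols]


def fit_decision_tree(
    X: pd.DataFrame,
    y: Sequence,
    max_depth: int | None = None,
    seed: int = 0,
) -> DecisionTreeClassifier:
    """Axis-aligned Gini decision tree; deterministic given data and seed.

    The random state breaks ties between equally good splits, which is the
    randomness the stability resampling exploits.
    """
    if len(X) == 0:
        raise ValueError("empty training data")
    tree = DecisionTreeClassifier(
        criterion="gini", max_depth=max_depth, random_state=seed
    )
    tree.fit(X, y)
    return tree


def tree_feature_order(tree: DecisionTreeClassifier, feature_names: Sequence[str]) -> list[str]:
    """Features in traversal order: root first, then level by level.

    Within a level, nodes are ordered by their weighted impurity decrease
    (largest first); each feature is listed once, at its first appearance.
    """
    t = tree.tree_
    order: list[str] = []
    level = [0]
    while level:
        entries = []
        for node in level:
            if t.children_left[node] == -1:
                continue
            left, right = t.children_left[node], t.children_right[node]
            decrease = t.weighted_n_node_samples[node] * t.impurity[node] - (
                t.weighted_n_node_samples[left] * t.impurity[left]
                + t.weighted_n_node_samples[right] * t.impurity[right]
            )
            entries.append((decrease, node))
        entries.sort(key=lambda e: -e[0])
        next_level = []
        for _, node in entries:
            name = feature_names[t.feature[node]]
            if name not in order:
                order.append(name)
            next_level.extend([t.children_left[node], t.children_right[node]])
        level = next_level
    return order


def min_depth_for_full_training_accuracy(
    X: pd.DataFrame,
    y: Sequence,
    depth_max_cap: int = 20,
    seed: int = 0,
) -> tuple[int, list[str], dict[int, float]]:
    """Smallest tree depth reaching training accuracy 1.0.

    Returns (depth, features in tree order, per-depth training accuracy).
    Raises if the cap is reached (e.g. duplicate feature vectors with
    conflicting labels), carrying the best accuracy achieved.
    """
    y = np.asarray(y)
    accuracies: dict[int, float] = {}
    for depth in range(1, depth_max_cap + 1):
        tree = fit_decision_tree(X, y, max_depth=depth, seed=seed)
        acc = float(tree.score(X, y))
        accuracies[depth] = acc
        if acc == 1.0:
            return depth, tree_feature_order(tree, list(X.columns)), accuracies
    raise ValueError(
        f"training accuracy 1.0 not reached by depth {depth_max_cap} "
        f"(best {max(accuracies.values()):.4f})"
    )


def feature_rank_stability(
    X: pd.DataFrame,
    y: Sequence,
    n_repeats: int = 1000,
    seed: int = 0,
    max_depth: int | None = None,
) -> pd.DataFrame:
    """Frequency of each feature at rank 1 (root) and ranks 2-3 over refits.

    Each repeat shuffles the sample order and refits the tree with a fresh
    random state (randomized split tie-breaking), emulating repeated
    training from random initial states.
    """
    y = np.asarray(y)
    rng = np.random.default_rng(seed)
    features = list(X.columns)
    rank1 = pd.Series(0, index=features, dtype=float)
    rank23 = pd.Series(0, index=features, dtype=float)
    Xv = X.to_numpy()
    for _ in range(n_repeats):
        perm = rng.permutation(len(X))
        tree = DecisionTreeClassifier(
            criterion="gini", max_depth=max_depth,
            random_state=int(rng.integers(2**31 - 1)),
        )
        tree.fit(Xv[perm], y[perm])
        t = tree.tree_
        if t.children_left[0] == -1:
            continue  # pure root: no split recorded
        rank1[features[t.feature[0]]] += 1
        for child in (t.children_left[0], t.children_right[0]):
            if t.children_left[child] != -1:
                rank23[features[t.feature[child]]] += 1
    out = pd.DataFrame(
        {"rank1_freq": rank1 / n_repeats, "rank23_freq": rank23 / n_repeats}
    )
    out.index.name = "feature"
    return out.sort_values("rank1_freq", ascending=False)


def _fit_backend(config: MLConfig, seed: int):
    if config.backend == "gradient_boosting":
        return GradientBoostingClassifier(
            loss="log_loss",
            n_estimators=500,
            validation_fraction=config.validation_fraction,
            n_iter_no_change=config.early_stopping_rounds,
            random_state=seed,
        )
    if config.backend == "xgboost":
        from xgboost import XGBClassifier

        return XGBClassifier(
            n_estimators=500,
            eval_metric=config.eval_metric,
            early_stopping_rounds=config.early_stopping_rounds,
            random_state=seed,
            verbosity=0,
        )
    raise ValueError(f"unknown backend {config.backend!r}")


def _fit_and_score(model, config: MLConfig, X_tr, y_tr, X_te, seed: int) -> np.ndarray:
    if config.backend == "xgboost":
        from sklearn.model_selection import train_test_split

        X_fit, X_val, y_fit, y_val = train_test_split(
            X_tr, y_tr, test_size=config.validation_fraction,
            stratify=y_tr, random_state=seed,
        )
        model.fit(X_fit, y_fit, eval_set=[(X_val, y_val)], verbose=False)
    else:
        model.fit(X_tr, y_tr)
    return model.predict_proba(X_te)[:, 1]


def _folds(y: np.ndarray, config: MLConfig):
    if config.stratified:
        splitter = StratifiedKFold(
            n_splits=config.k_folds, shuffle=True, random_state=config.seed
        )
        return list(splitter.split(np.zeros_like(y), y))
    from sklearn.model_selection import KFold

    splitter = KFold(n_splits=config.k_folds, shuffle=True, random_state=config.seed)
    return list(splitter.split(np.zeros_like(y)))


def kfold_evaluate(
    X: pd.DataFrame,
    y: Sequence,
    features: Sequence[str] | None = None,
    config: MLConfig | None = None,
) -> MLReport:
    """Cross-validated boosted-ensemble evaluation with pooled confusion matrix.

    ``y`` is binary (bool/0-1 or a two-class label series; the
    lexicographically larger class is the positive one). The test folds
    partition the samples, so each participant appears in the pooled
    confusion matrix exactly once.
    """
    config = config or MLConfig()
    feats = list(features) if features is not None else list(X.columns)
    Xs = X[feats].to_numpy(dtype=float)
    y_arr = np.asarray(y)
    if y_arr.dtype.kind not in "bif":
        classes = list(np.unique(y_arr))
        if len(classes) != 2:
            raise ValueError(f"need exactly two classes, got {classes}")
        positive = "AD" if "AD" in classes else classes[-1]
        y_arr = (y_arr == positive).astype(int)
    else:
        y_arr = y_arr.astype(int)
    if len(np.unique(y_arr)) != 2:
        raise ValueError("need both classes present")

    curves, aucs = [], []
    pooled_pred = np.full(len(y_arr), -1.0)
    for i, (train, test) in enumerate(_folds(y_arr, config)):
        if len(np.unique(y_arr[train])) < 2 or len(np.unique(y_arr[test])) < 2:
            raise ValueError(
                "a fold lacks one class; use stratified folds or another seed"
            )
        model = _fit_backend(config, config.seed + i)
        scores = _fit_and_score(
            model, config, Xs[train], y_arr[train], Xs[test], config.seed + i
        )
        fpr, tpr = roc_auc(scores, y_arr[test])[0]
        curves.append((fpr, tpr))
        aucs.append(roc_auc(scores, y_arr[test])[1])
        pooled_pred[test] = scores
    assert np.all(pooled_pred >= 0), "test folds must cover every sample"

    hard = pooled_pred >= 0.5
    tp = int(np.sum(hard & (y_arr == 1)))
    fn = int(np.sum(~hard & (y_arr == 1)))
    tn = int(np.sum(~hard & (y_arr == 0)))
    fp = int(np.sum(hard & (y_arr == 0)))
    sens, spec, acc = confusion_metrics(tp, fn, tn, fp)
    return MLReport(
        fold_curves=curves,
        fold_aucs=[float(a) for a in aucs],
        mean_auc=float(np.mean(aucs)),
        tp=tp, fn=fn, tn=tn, fp=fp,
        sensitivity=sens, specificity=spec, accuracy=acc,
        feature_names=feats,
    )


def iterative_feature_addition(
    X: pd.DataFrame,
    y: Sequence,
    ordered_features: Sequence[str],
    config: MLConfig | None = None,
) -> tuple[pd.Series, int]:
    """Cross-validated AUC as features are added in importance order.

    Returns (auc per feature count, selected count), the selected count
    being the smallest m whose mean AUC is within plateau_epsilon of the
    maximum over all counts.
    """
    config = config or MLConfig()
    ordered_features = list(ordered_features)
    if not ordered_features:
        raise ValueError("ordered feature list must be non-empty")
    aucs = {}
    for m in range(1, len(ordered_features) + 1):
        report = kfold_evaluate(X, y, ordered_features[:m], config)
        aucs[m] = report.mean_auc
    series = pd.Series(aucs, name="mean_auc")
    best = series.max()
    selected = int(min(m for m, a in aucs.items() if a >= best - config.plateau_epsilon))
    return series, selected


def roc_auc(scores: Sequence[float], labels: Sequence) -> tuple[tuple[np.ndarray, np.ndarray], float]:
    """ROC curve points and AUC (pairwise concordance with tie credit 0.5)."""
    scores = np.asarray(scores, dtype=float)
    labels = np.asarray(labels).astype(int)
    if len(np.unique(labels)) != 2:
        raise ValueError("roc_auc needs both classes present")
    fpr, tpr, _ = roc_curve(labels, scores)
    # Mann-Whitney identity: concordant pairs + half the tied pairs
    pos = scores[labels == 1]
    neg = scores[labels == 0]
    greater = (pos[:, None] > neg[None, :]).sum()
    ties = (pos[:, None] == neg[None, :]).sum()
    auc = (greater + 0.5 * ties) / (len(pos) * len(neg))
    return (fpr, tpr), float(auc)


def confusion_metrics(tp: int, fn: int, tn: int, fp: int) -> tuple[float, float, float]:
    """(sensitivity, specificity, accuracy) from pooled confusion counts."""
    if min(tp, fn, tn, fp) < 0:
        raise ValueError("counts must be >= 0")
    if tp + fn < 1 or tn + fp < 1:
        raise ValueError("both classes must be represented")
    sensitivity = tp / (tp + fn)
    specificity = tn / (tn + fp)
    accuracy = (tp + tn) / (tp + fn + tn + fp)
    return float(sensitivity), float(specificity), float(accuracy)
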