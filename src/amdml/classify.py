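"""Classification in the learned metric space and the evaluation harness.

Ships a deterministic K-nearest-neighbour vote over the fused features plus
stratified cross-validation and the two sensitivity sweeps (neighbour
counts k1=k2 of the graphs; K of the KNN classifier).  Any external margin
classifier with a ``fit(X, y)`` / ``predict(X)`` surface (samples in rows)
can be plugged in instead of KNN.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy.spatial.distance import cdist
from sklearn.model_selection import LeaveOneOut, StratifiedKFold

from .data import EEGSegment, MultiViewDataset
from .model import AMDML, FitConfig


def knn_predict(
    train_X: np.ndarray,
    train_labels: np.ndarray,
    test_X: np.ndarray,
    K: int = 7,
) -> np.ndarray:
    """Majority vote of the K Euclidean-nearest training samples.

    Matrices are features x samples.  K must be odd so the binary vote can
    never tie.  Distance ties are broken by lower training-sample index.
    """
    if K % 2 == 0:
        raise ValueError("K must be odd to keep the binary vote well-defined")
    train_labels = np.asarray(train_labels)
    if K > train_labels.size:
        raise ValueError(f"K={K} exceeds {train_labels.size} training samples")
    D = cdist(test_X.T, train_X.T)
    n_train = train_labels.size
    preds = np.empty(D.shape[0], dtype=train_labels.dtype)
    for i in range(D.shape[0]):
        order = np.lexsort((np.arange(n_train), D[i]))
        votes = train_labels[order[:K]]
        preds[i] = 1 if np.sum(votes == 1) > K / 2 else -1
    return preds


@dataclass
class EvalResult:
    """Accuracy, per-class accuracies and the balanced loss l_bal.

    l_bal = 1 - (ACC_positive + ACC_negative) / 2: zero for a perfect
    classifier, 0.5 for a trivial one on balanced data.
    """

    accuracy: float
    acc_positive: float
    acc_negative: float
    l_bal: float
    n: int
    per_fold: list = field(default_factory=list)
    config: dict = field(default_factory=dict)


def evaluate(true_labels: np.ndarray, predicted_labels: np.ndarray) -> EvalResult:
    """Score +1/-1 predictions against +1/-1 truth."""
    y, p = np.asarray(true_labels), np.asarray(predicted_labels)
    if y.size != p.size or y.size == 0:
        raise ValueError("label vectors must be non-empty and equal-length")
    pos, neg = y == 1, y == -1
    acc = float(np.mean(y == p))
    acc_pos = float(np.mean(p[pos] == 1)) if pos.any() else float("nan")
    acc_neg = float(np.mean(p[neg] == -1)) if neg.any() else float("nan")
    l_bal = 1.0 - (acc_pos + acc_neg) / 2.0
    return EvalResult(
        accuracy=acc, acc_positive=acc_pos, acc_negative=acc_neg,
        l_bal=l_bal, n=int(y.size),
    )


def _aggregate(folds: list[tuple[np.ndarray, np.ndarray]], config: dict) -> EvalResult:
    y = np.concatenate([t for t, _ in folds])
    p = np.concatenate([q for _, q in folds])
    out = evaluate(y, p)
    out.per_fold = [evaluate(t, q) for t, q in folds]
    out.config = config
    return out


def _classify(train_F, train_y, test_F, classifier):
    if isinstance(classifier, int):
        return knn_predict(train_F, train_y, test_F, K=classifier)
    clf = classifier()
    clf.fit(train_F.T, train_y)
    return np.asarray(clf.predict(test_F.T))


def _splits(labels: np.ndarray, n_folds: int, seed: int):
    """Stratified K-fold splits; n_folds == N degrades to leave-one-out."""
    if n_folds == labels.size:
        yield from LeaveOneOut().split(labels.reshape(-1, 1))
        return
    skf = StratifiedKFold(n_splits=n_folds, shuffle=True, random_state=seed)
    yield from skf.split(labels.reshape(-1, 1), labels)


def cross_validate(
    dataset: MultiViewDataset,
    fit_config: FitConfig | None = None,
    classifier: int | type = 7,
    n_folds: int = 10,
    seed: int = 0,
    fusion: str = "weighted-concat",
) -> EvalResult:
    """Stratified K-fold CV over precomputed views.

    Per fold the metric is fitted on the training columns only, both
    portions are projected with it, and the classifier votes in the fused
    space.  ``classifier`` is either an odd integer K (built-in KNN) or a
    zero-argument factory returning a fit/predict estimator.
    """
    fit_config = fit_config or FitConfig()
    labels = dataset.labels
    folds = []
    for train_idx, test_idx in _splits(labels, n_folds, seed):
        if len(np.unique(labels[train_idx])) < 2:
            raise ValueError("a training fold lost one of the classes")
        train = dataset.subset(train_idx)
        test = dataset.subset(test_idx)
        res = AMDML(train, fit_config).fit()
        train_F = res.transform(train, mode=fusion)
        test_F = res.transform(test, mode=fusion)
        preds = _classify(train_F, labels[train_idx], test_F, classifier)
        folds.append((labels[test_idx], preds))
    return _aggregate(
        folds,
        {"n_folds": n_folds, "seed": seed, "fusion": fusion,
         "classifier": repr(classifier), "fit_config": fit_config},
    )


def cross_validate_segments(
    segments: list[EEGSegment],
    labels: np.ndarray,
    pipeline_factory,
    fit_config: FitConfig | None = None,
    classifier: int | type = 7,
    n_folds: int = 10,
    seed: int = 0,
    fusion: str = "weighted-concat",
) -> EvalResult:
    """Full-pipeline CV: feature extraction refitted per training fold.

    ``pipeline_factory`` is a zero-argument callable returning a fresh
    :class:`~amdml.features.FeaturePipeline`; the KPCA map and
    standardisation statistics therefore never see the test fold.
    """
    fit_config = fit_config or FitConfig()
    labels = np.asarray(labels)
    folds = []
    for train_idx, test_idx in _splits(labels, n_folds, seed):
        train_seg = [segments[i] for i in train_idx]
        test_seg = [segments[i] for i in test_idx]
        pipe = pipeline_factory().fit(train_seg)
        train = pipe.transform(train_seg, labels[train_idx])
        test = pipe.transform(test_seg, labels[test_idx])
        res = AMDML(train, fit_config).fit()
        train_F = res.transform(train, mode=fusion)
        test_F = res.transform(test, mode=fusion)
        preds = _classify(train_F, labels[train_idx], test_F, classifier)
        folds.append((labels[test_idx], preds))
    return _aggregate(
        folds,
        {"n_folds": n_folds, "seed": seed, "fusion": fusion,
         "classifier": repr(classifier), "fit_config": fit_config},
    )


def sensitivity_sweep(
    dataset: MultiViewDataset,
    k_grid: list[int] | None = None,
    K_grid: list[int] | None = None,
    fixed_K: int = 7,
    fixed_k: int = 5,
    base_config: FitConfig | None = None,
    n_folds: int = 10,
    seed: int = 0,
) -> pd.DataFrame:
    """The two standard sensitivity sweeps as one tidy table.

    Sweep 1 varies the graph neighbour counts k1=k2 over ``k_grid``
    (default 2..10) with the KNN classifier's K fixed at 7; sweep 2 varies
    K over ``K_grid`` (default 1,3,5,7,9) with k1=k2 fixed at 5.  Each row
    reports CV accuracy and l_bal for one grid point.
    """
    if k_grid is None:
        k_grid = list(range(2, 11))
    if K_grid is None:
        K_grid = [1, 3, 5, 7, 9]
    if not k_grid and not K_grid:
        raise ValueError("both grids are empty")
    base = base_config or FitConfig()
    rows = []
    for k in k_grid:
        cfg = FitConfig(
            k1=k, k2=k, d=base.d, exponent_t=base.exponent_t, delta=base.delta,
            t_max=base.t_max, epsilon_clamp=base.epsilon_clamp, seed=base.seed,
        )
        r = cross_validate(dataset, cfg, classifier=fixed_K,
                           n_folds=n_folds, seed=seed)
        rows.append({"sweep": "k1=k2", "k1": k, "k2": k, "K": fixed_K,
                     "accuracy": r.accuracy, "l_bal": r.l_bal})
    for K in K_grid:
        cfg = FitConfig(
            k1=fixed_k, k2=fixed_k, d=base.d, exponent_t=base.exponent_t,
            delta=base.delta, t_max=base.t_max,
            epsilon_clamp=base.epsilon_clamp, seed=base.seed,
        )
        r = cross_validate(dataset, cfg, classifier=K,
                           n_folds=n_folds, seed=seed)
        rows.append({"sweep": "K", "k1": fixed_k, "k2": fixed_k, "K": K,
                     "accuracy": r.accuracy, "l_bal": r.l_bal})
    return pd.DataFrame(rows)
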