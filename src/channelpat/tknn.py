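"""tkNN: an ensemble of 60 kNN configurations with iterative majority voting.

The hyperparameter grid is k in 1..10, distance in {L1, L2}, and distance
weight in {equal, inverse, squared inverse}: 60 configurations, each
producing one cross-validated prediction vector with its accuracy.
Iterative majority voting (IMV) sorts the 60 vectors by descending
accuracy and, for every q in 3..60, takes the elementwise mode of the
top q, producing 58 voted vectors.  A greedy pass then returns the most
accurate of the pooled 118 outcomes.

The greedy pass scores voted outcomes on the same labels used to sort
the ensemble, mirroring the protocol this classifier defines.  That
accuracy is optimistically biased — the winner is selected on the very
labels it is scored on — and should be read as the protocol's headline
number, not an unbiased generalization estimate.

All 60 configurations share one stratified fold assignment so every
outcome predicts the same samples under the same splits.
"""

from __future__ import annotations

from dataclasses import dataclass
from itertools import product

import numpy as np
from sklearn.model_selection import StratifiedKFold
from sklearn.neighbors import KNeighborsClassifier
from sklearn.preprocessing import StandardScaler

__all__ = [
    "KnnConfig",
    "PredictionEnsemble",
    "TknnResult",
    "enumerate_configs",
    "assign_folds",
    "cv_predict",
    "predict_with_config",
    "imv",
    "greedy_final",
    "run_tknn",
]

_DISTANCES = ("L1", "L2")
_WEIGHTS = ("equal", "inverse", "squared_inverse")
_METRIC = {"L1": "manhattan", "L2": "euclidean"}


@dataclass(frozen=True)
class KnnConfig:
    """One kNN hyperparameter triple."""

    k: int
    distance: str  # L1 | L2
    weight: str  # equal | inverse | squared_inverse

    def __post_init__(self) -> None:
        if not 1 <= self.k <= 10:
            raise ValueError(f"k must be in 1..10, got {self.k}")
        if self.distance not in _DISTANCES:
            raise ValueError(f"distance must be one of {_DISTANCES}")
        if self.weight not in _WEIGHTS:
            raise ValueError(f"weight must be one of {_WEIGHTS}")


def enumerate_configs() -> list[KnnConfig]:
    """The 60 configurations in fixed order: k outer, distance middle, weight inner."""
    return [
        KnnConfig(k=k, distance=d, weight=w)
        for k, d, w in product(range(1, 11), _DISTANCES, _WEIGHTS)
    ]


def _inverse_weight(power: int):
    """Inverse-distance weights; exact matches dominate.

    If a query has zero-distance neighbors, those neighbors get weight 1
    and every other neighbor weight 0, so the prediction is the majority
    label among exact matches.
    """

    def weigh(dist: np.ndarray) -> np.ndarray:
        with np.errstate(divide="ignore"):
            w = 1.0 / dist**power
        exact = np.isinf(w)
        rows = exact.any(axis=1)
        w[rows] = exact[rows].astype(float)
        return w

    return weigh


def _make_knn(config: KnnConfig, n_train: int) -> KNeighborsClassifier:
    if config.weight == "equal":
        weights = "uniform"
    else:
        weights = _inverse_weight(1 if config.weight == "inverse" else 2)
    return KNeighborsClassifier(
        n_neighbors=min(config.k, n_train),
        metric=_METRIC[config.distance],
        weights=weights,
    )


def assign_folds(y, n_folds: int = 10, seed: int = 0) -> np.ndarray:
    """Stratified fold id per sample, shared by every configuration."""
    y = np.asarray(y)
    cv = StratifiedKFold(n_splits=n_folds, shuffle=True, random_state=seed)
    folds = np.empty(y.shape[0], dtype=np.int64)
    for f, (_, test) in enumerate(cv.split(np.zeros((y.shape[0], 1)), y)):
        folds[test] = f
    return folds


def cv_predict(
    X,
    y,
    config: KnnConfig,
    folds: np.ndarray,
    *,
    standardize: bool = True,
) -> tuple[np.ndarray, float]:
    """Cross-validated prediction vector and accuracy for one configuration.

    Each sample is predicted by a kNN fitted on the other folds; the
    z-scoring statistics come from the training folds only.
    """
    X = np.asarray(X, dtype=float)
    y = np.asarray(y)
    folds = np.asarray(folds)
    pred = np.empty(y.shape[0], dtype=y.dtype)
    for f in np.unique(folds):
        test = folds == f
        train = ~test
        y_train = y[train]
        if np.unique(y_train).size < np.unique(y).size:
            raise ValueError(f"fold {f} training split is missing a class")
        X_train, X_test = X[train], X[test]
        if standardize:
            scaler = StandardScaler().fit(X_train)
            X_train = scaler.transform(X_train)
            X_test = scaler.transform(X_test)
        clf = _make_knn(config, n_train=X_train.shape[0]).fit(X_train, y_train)
        pred[test] = clf.predict(X_test)
    return pred, float(np.mean(pred == y))


def predict_with_config(
    X_train,
    y_train,
    X_test,
    config: KnnConfig,
    *,
    standardize: bool = True,
) -> np.ndarray:
    """Fit one kNN configuration on a training set and predict new samples."""
    X_train = np.asarray(X_train, dtype=float)
    X_test = np.asarray(X_test, dtype=float)
    y_train = np.asarray(y_train)
    if standardize:
        scaler = StandardScaler().fit(X_train)
        X_train = scaler.transform(X_train)
        X_test = scaler.transform(X_test)
    clf = _make_knn(config, n_train=X_train.shape[0]).fit(X_train, y_train)
    return clf.predict(X_test)


@dataclass
class PredictionEnsemble:
    """60 classifier-wise outcomes plus the 58 IMV-voted outcomes."""

    configs: list[KnnConfig]
    classifier_preds: np.ndarray  # (60, n)
    classifier_accs: np.ndarray  # (60,)
    voted_preds: np.ndarray  # (58, n), row h is q = h + 3
    voted_accs: np.ndarray  # (58,)
    sort_order: np.ndarray  # accuracy-descending indices into the 60

    @property
    def n_outcomes(self) -> int:
        return self.classifier_preds.shape[0] + self.voted_preds.shape[0]


@dataclass
class TknnResult:
    """Greedy winner over the pooled 118 outcomes."""

    final_labels: np.ndarray
    final_accuracy: float
    source: str  # "classifier" | "voted"
    source_index: int  # config index (0-based) or q (3..60)
    config: KnnConfig | None = None

    def to_dict(self) -> dict:
        return {
            "final_accuracy": float(self.final_accuracy),
            "source": self.source,
            "source_index": int(self.source_index),
            "config": None
            if self.config is None
            else {"k": self.config.k, "distance": self.config.distance, "weight": self.config.weight},
            "final_labels": [str(v) for v in self.final_labels],
        }


def _mode_with_tiebreak(block: np.ndarray, labels: np.ndarray) -> np.ndarray:
    """Elementwise mode of the (q, n) block.

    Ties go to the label predicted by the most accurate contributing
    outcome (block rows are already in descending-accuracy order); if a
    tied label never appears earlier — impossible once q >= 1 — the
    smallest label wins.
    """
    q, n = block.shape
    counts = np.stack([(block == lab).sum(axis=0) for lab in labels])  # (K, n)
    maxc = counts.max(axis=0)
    tied = counts == maxc  # (K, n)
    out = np.empty(n, dtype=block.dtype)
    resolved = np.zeros(n, dtype=bool)
    n_tied = tied.sum(axis=0)
    # unique winners straight from argmax (labels sorted ascending)
    single = n_tied == 1
    out[single] = labels[np.argmax(tied[:, single], axis=0)]
    resolved |= single
    # ties: first row (most accurate outcome) whose label is among the tied
    for r in range(q):
        if resolved.all():
            break
        open_ = ~resolved
        row = block[r, open_]
        lab_pos = np.searchsorted(labels, row)
        is_tied = tied[lab_pos, np.nonzero(open_)[0]]
        idx = np.nonzero(open_)[0][is_tied]
        out[idx] = block[r, idx]
        resolved[idx] = True
    if not resolved.all():  # pragma: no cover - defensive
        open_ = ~resolved
        out[open_] = labels[np.argmax(tied[:, open_], axis=0)]
    return out


def imv(
    classifier_preds: np.ndarray,
    classifier_accs: np.ndarray,
    y=None,
) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    """Iterative majority voting over accuracy-sorted prediction vectors.

    For each q in 3..60 the voted vector is the elementwise mode of the
    top-q most accurate classifier outcomes.  Returns
    ``(voted_preds, voted_accs, sort_order)``; accuracies are NaN when
    ``y`` is not given.
    """
    preds = np.asarray(classifier_preds)
    accs = np.asarray(classifier_accs, dtype=float)
    m = preds.shape[0]
    if m < 3:
        raise ValueError("IMV needs at least 3 classifier outcomes")
    order = np.argsort(-accs, kind="stable")
    ranked = preds[order]
    labels = np.unique(preds)
    voted = np.empty((m - 2, preds.shape[1]), dtype=preds.dtype)
    for h, q in enumerate(range(3, m + 1)):
        voted[h] = _mode_with_tiebreak(ranked[:q], labels)
    if y is None:
        vacc = np.full(m - 2, np.nan)
    else:
        y = np.asarray(y)
        vacc = (voted == y[None, :]).mean(axis=1)
    return voted, vacc, order


def greedy_final(ensemble: PredictionEnsemble) -> TknnResult:
    """Most accurate of the pooled 118 outcomes.

    Ties break toward classifier-wise outcomes before voted ones, then
    toward the lower index, so the result is deterministic.
    """
    pooled = np.concatenate([ensemble.classifier_accs, ensemble.voted_accs])
    assert pooled.size == ensemble.n_outcomes
    best = int(np.argmax(pooled))  # first max: classifier block precedes voted
    n_cls = ensemble.classifier_preds.shape[0]
    if best < n_cls:
        return TknnResult(
            final_labels=ensemble.classifier_preds[best].copy(),
            final_accuracy=float(pooled[best]),
            source="classifier",
            source_index=best,
            config=ensemble.configs[best],
        )
    h = best - n_cls
    return TknnResult(
        final_labels=ensemble.voted_preds[h].copy(),
        final_accuracy=float(pooled[best]),
        source="voted",
        source_index=h + 3,  # q value
        config=None,
    )


def run_tknn(
    X,
    y,
    *,
    seed: int = 0,
    n_folds: int = 10,
    standardize: bool = True,
) -> tuple[PredictionEnsemble, TknnResult]:
    """Full tkNN pass: 60 CV prediction vectors, IMV, greedy winner."""
    X = np.asarray(X, dtype=float)
    y = np.asarray(y)
    folds = assign_folds(y, n_folds=n_folds, seed=seed)
    configs = enumerate_configs()
    preds = np.empty((len(configs), y.shape[0]), dtype=y.dtype)
    accs = np.empty(len(configs))
    for i, cfg in enumerate(configs):
        preds[i], accs[i] = cv_predict(X, y, cfg, folds, standardize=standardize)
    voted, vacc, order = imv(preds, accs, y)
    ensemble = PredictionEnsemble(
        configs=configs,
        classifier_preds=preds,
        classifier_accs=accs,
        voted_preds=voted,
        voted_accs=vacc,
        sort_order=order,
    )
    return ensemble, greedy_final(ensemble)
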