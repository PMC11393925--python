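"""Iterative neighborhood component analysis (INCA) feature selection.

Two stages:

1. **NCA weighting** — a diagonal feature weighting is learned by
   maximizing the regularized softmax leave-one-out neighbor-assignment
   objective.  With weights ``w`` the weighted distance between samples
   i and j is ``d_ij = sum_r w_r^2 |x_ir - x_jr|``; the probability that
   i picks j as its reference neighbor is
   ``p_ij = exp(-d_ij) / sum_{k != i} exp(-d_ik)``, and the objective is

       F(w) = (1/n) * sum_i sum_{j in class(i)} p_ij  -  lambda * sum_r w_r^2

   maximized with L-BFGS from ``w = 1``.  The reported per-feature
   weight is ``w_r^2`` (nonnegative; larger = more class-informative).

2. **Iterative prefix search** — features are ranked by descending
   weight and, for every subset size k in a configured range, the top-k
   prefix is scored by stratified cross-validated accuracy of a loss
   kNN (default 1-NN, Euclidean, z-scored with training-fold
   statistics).  The accuracy-maximizing prefix wins; ties go to the
   smallest size.

Features are z-scored internally before both stages; raw transition
histograms have heavy-tailed counts.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
from scipy.optimize import minimize
from sklearn.model_selection import StratifiedKFold, cross_val_score
from sklearn.neighbors import KNeighborsClassifier
from sklearn.pipeline import make_pipeline
from sklearn.preprocessing import StandardScaler

from .features import FeatureMatrix

__all__ = ["SelectionResult", "nca_weights", "inca_select"]


@dataclass
class SelectionResult:
    """Outcome of INCA selection.  All feature ids are 1-based bin indices."""

    ranked_indices: np.ndarray
    chosen_indices: np.ndarray
    per_size_accuracy: dict[int, float]
    chosen_size: int
    weights: np.ndarray = field(default=None, repr=False)

    def __post_init__(self) -> None:
        self.ranked_indices = np.asarray(self.ranked_indices, dtype=np.int64)
        self.chosen_indices = np.asarray(self.chosen_indices, dtype=np.int64)
        if not np.array_equal(self.chosen_indices, self.ranked_indices[: self.chosen_size]):
            raise ValueError("chosen_indices must be a prefix of ranked_indices")

    @property
    def chosen_accuracy(self) -> float:
        return self.per_size_accuracy[self.chosen_size]

    def to_dict(self) -> dict:
        return {
            "ranked_indices": self.ranked_indices.tolist(),
            "chosen_indices": self.chosen_indices.tolist(),
            "chosen_size": int(self.chosen_size),
            "chosen_accuracy": float(self.chosen_accuracy),
            "per_size_accuracy": {str(k): float(v) for k, v in self.per_size_accuracy.items()},
            "weights": None if self.weights is None else [float(w) for w in self.weights],
        }

    @classmethod
    def from_dict(cls, d: dict) -> "SelectionResult":
        return cls(
            ranked_indices=np.asarray(d["ranked_indices"]),
            chosen_indices=np.asarray(d["chosen_indices"]),
            per_size_accuracy={int(k): float(v) for k, v in d["per_size_accuracy"].items()},
            chosen_size=int(d["chosen_size"]),
            weights=None if d.get("weights") is None else np.asarray(d["weights"]),
        )


def _as_Xy(X, labels=None):
    if isinstance(X, FeatureMatrix):
        return np.asarray(X.X, dtype=float), np.asarray(X.labels)
    if labels is None:
        raise ValueError("labels required when X is a plain array")
    return np.asarray(X, dtype=float), np.asarray(labels)


def _zscore(X: np.ndarray) -> np.ndarray:
    mu = X.mean(axis=0)
    sd = X.std(axis=0)
    sd = np.where(sd > 0, sd, 1.0)
    return (X - mu) / sd


def nca_weights(
    X,
    labels=None,
    *,
    reg: float | None = None,
    max_iter: int = 100,
    standardize: bool = True,
) -> np.ndarray:
    """Learn nonnegative per-feature NCA weights.

    Parameters
    ----------
    X : FeatureMatrix or (n, p) array
    labels : array-like, required when X is a plain array
    reg : float, optional
        L2 regularization strength lambda; defaults to 1/n.
    max_iter : int
        L-BFGS iteration cap.
    standardize : bool
        z-score features before learning (default).

    Returns
    -------
    ndarray, shape (p,)
        One finite nonnegative weight per feature; higher means more
        class-informative.
    """
    Xa, y = _as_Xy(X, labels)
    n, p = Xa.shape
    classes, y_enc = np.unique(y, return_inverse=True)
    if classes.size < 2:
        raise ValueError("NCA weighting needs at least 2 classes")
    counts = np.bincount(y_enc)
    if counts.min() < 2:
        raise ValueError("NCA weighting needs at least 2 samples per class")
    if np.ptp(Xa, axis=0).max() == 0:
        warnings.warn("constant feature matrix: weights are degenerate", stacklevel=2)
    if standardize:
        Xa = _zscore(Xa)
    lam = (1.0 / n) if reg is None else float(reg)

    # pairwise per-feature absolute differences, A[i, j, r] = |x_ir - x_jr|
    A = np.abs(Xa[:, None, :] - Xa[None, :, :])
    same = (y_enc[:, None] == y_enc[None, :]).astype(float)
    np.fill_diagonal(same, 0.0)

    def neg_objective(w: np.ndarray):
        w2 = w * w
        d = A @ w2
        np.fill_diagonal(d, np.inf)  # p_ii = 0
        d -= d.min(axis=1, keepdims=True)  # stabilize exp
        P = np.exp(-d)
        np.fill_diagonal(P, 0.0)
        rowsum = P.sum(axis=1, keepdims=True)
        rowsum[rowsum == 0] = 1.0
        P /= rowsum
        p_i = (P * same).sum(axis=1)
        f = p_i.mean() - lam * w2.sum()
        # dF/dw_r = (2 w_r / n) sum_i [ p_i * sum_j P_ij A_ijr
        #                               - sum_{j ~ i} P_ij A_ijr ] - 2 lam w_r
        inner = np.einsum("i,ij,ijr->r", p_i, P, A) - np.einsum(
            "ij,ijr->r", P * same, A
        )
        g = (2.0 * w / n) * inner - 2.0 * lam * w
        return -f, -g

    res = minimize(
        neg_objective,
        x0=np.ones(p),
        jac=True,
        method="L-BFGS-B",
        options={"maxiter": max_iter},
    )
    w = res.x
    return w * w


def make_loss_knn(k: int = 1, metric: str = "euclidean"):
    """The kNN pipeline scored during the prefix search (z-score + kNN)."""
    return make_pipeline(
        StandardScaler(),
        KNeighborsClassifier(n_neighbors=k, metric=metric, weights="uniform"),
    )


def inca_select(
    X,
    labels=None,
    *,
    size_range: tuple[int, int] = (10, 196),
    seed: int = 0,
    n_folds: int = 10,
    loss_k: int = 1,
    loss_metric: str = "euclidean",
    nca_reg: float | None = None,
    nca_max_iter: int = 100,
) -> SelectionResult:
    """Pick the cross-validated-accuracy-maximizing prefix of NCA-ranked features.

    ``size_range = (lo, hi)`` inclusive; hi - lo + 1 candidate prefixes
    are evaluated (187 for the default 10..196 on a 196-feature matrix).
    Deterministic given ``seed`` (the stratified fold shuffle).
    Returned feature ids are 1-based bin indices.
    """
    Xa, y = _as_Xy(X, labels)
    n, p = Xa.shape
    lo, hi = int(size_range[0]), int(size_range[1])
    if not (1 <= lo <= hi):
        raise ValueError(f"invalid size range {size_range}")
    if hi > p:
        raise ValueError(f"range upper bound {hi} exceeds feature count {p}")
    w = nca_weights(Xa, y, reg=nca_reg, max_iter=nca_max_iter)
    order = np.argsort(-w, kind="stable")  # 0-based column order

    cv = StratifiedKFold(n_splits=n_folds, shuffle=True, random_state=seed)
    per_size: dict[int, float] = {}
    for k in range(lo, hi + 1):
        cols = order[:k]
        clf = make_loss_knn(k=loss_k, metric=loss_metric)
        acc = cross_val_score(clf, Xa[:, cols], y, cv=cv, scoring="accuracy").mean()
        per_size[k] = float(acc)
    sizes = np.array(sorted(per_size))
    accs = np.array([per_size[k] for k in sizes])
    chosen_size = int(sizes[int(np.argmax(accs))])  # first max = smallest size
    ranked_ids = order + 1  # 1-based bin indices
    return SelectionResult(
        ranked_indices=ranked_ids,
        chosen_indices=ranked_ids[:chosen_size],
        per_size_accuracy=per_size,
        chosen_size=chosen_size,
        weights=w,
    )
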