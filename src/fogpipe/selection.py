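"""Feature ranking: Relief-F and minimum-redundancy maximum-relevance (mRMR).

Both methods rank the full feature set against the binary Total-FOG vs
No-FOG labeling. Relief-F contrasts each sampled window's feature values
with its nearest same-class and other-class neighbours; mRMR greedily picks
features maximising mutual information with the class while penalising the
mean mutual information with the features already chosen (the MID
criterion). Both are exposed as sklearn-style estimators with ``fit`` /
``transform`` plus thin functional wrappers returning a
:class:`RankingResult`.
"""

from __future__ import annotations

import json
import logging
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
from scipy.spatial.distance import cdist
from sklearn.base import BaseEstimator, TransformerMixin
from sklearn.utils.validation import check_is_fitted

logger = logging.getLogger(__name__)


@dataclass
class RankingResult:
    """Ordered feature names (best first) with their scores."""

    method: str                       # "relieff" | "mrmr"
    ordered_features: list[str]
    scores: list[float]
    seed: int | None = None
    params: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        if len(self.ordered_features) != len(self.scores):
            raise ValueError("features and scores must be parallel lists")
        if len(set(self.ordered_features)) != len(self.ordered_features):
            raise ValueError("duplicate feature names in ranking")

    def top(self, k: int) -> list[str]:
        return self.ordered_features[:k]

    def to_json(self, path: str | Path) -> None:
        Path(path).write_text(json.dumps({
            "method": self.method,
            "params": self.params,
            "seed": self.seed,
            "ordered_features": self.ordered_features,
            "scores": self.scores,
        }, indent=1))

    @classmethod
    def from_json(cls, path: str | Path) -> "RankingResult":
        d = json.loads(Path(path).read_text())
        return cls(d["method"], d["ordered_features"], d["scores"],
                   d.get("seed"), d.get("params", {}))


def _as_array(X) -> tuple[np.ndarray, list[str]]:
    if isinstance(X, pd.DataFrame):
        return X.to_numpy(dtype=float), [str(c) for c in X.columns]
    X = np.asarray(X, dtype=float)
    return X, [f"f{i}" for i in range(X.shape[1])]


def _validate_labels(y) -> np.ndarray:
    y = np.asarray(y)
    classes = np.unique(y)
    if len(classes) < 2:
        raise ValueError("degenerate labels: need at least two classes")
    return y


class ReliefF(TransformerMixin, BaseEstimator):
    """Relief-F feature weighting for binary classification.

    Features are min-max normalised internally; for each of ``n_updates``
    instances sampled without replacement (cycling with fresh permutations if
    ``n_updates`` exceeds the number of rows), the ``n_neighbors`` nearest
    hits and misses under Manhattan distance shift each feature's weight
    down (hits) or up (misses, weighted by class priors).

    Attributes set by :meth:`fit`: ``feature_scores_`` (Relief-F weights),
    ``ranking_`` (column indices, best first), ``feature_names_``.
    """

    def __init__(self, n_neighbors: int = 200, n_updates: int = 2000,
                 n_features_to_select: int | None = None,
                 random_state: int | None = None, batch_size: int = 256):
        self.n_neighbors = n_neighbors
        self.n_updates = n_updates
        self.n_features_to_select = n_features_to_select
        self.random_state = random_state
        self.batch_size = batch_size

    def fit(self, X, y):
        X, names = _as_array(X)
        y = _validate_labels(y)
        n, p = X.shape
        if min(np.bincount(pd.factorize(y)[0])) < 2:
            raise ValueError("need at least 2 samples per class")
        rng = np.random.default_rng(self.random_state)

        lo, hi = X.min(axis=0), X.max(axis=0)
        span = hi - lo
        span[span == 0] = 1.0
        Xn = (X - lo) / span

        classes, y_idx = np.unique(y, return_inverse=True)
        priors = np.bincount(y_idx) / n
        class_rows = [np.where(y_idx == c)[0] for c in range(len(classes))]
        max_k = min(self.n_neighbors,
                    min(len(r) for r in class_rows) - 1)
        if max_k < self.n_neighbors:
            logger.warning("Relief-F k capped at %d (smallest class size - 1)", max_k)

        order = np.concatenate([rng.permutation(n)
                                for _ in range(-(-self.n_updates // n))])
        sampled = order[:self.n_updates]

        W = np.zeros(p)
        m = len(sampled)
        for start in range(0, m, self.batch_size):
            batch = sampled[start:start + self.batch_size]
            D = cdist(Xn[batch], Xn, metric="cityblock")
            for row, i in enumerate(batch):
                ci = y_idx[i]
                for c in range(len(classes)):
                    rows_c = class_rows[c]
                    d = D[row, rows_c]
                    if c == ci:
                        # exclude the instance itself
                        d = d.copy()
                        d[rows_c == i] = np.inf
                        k = min(max_k, len(rows_c) - 1)
                    else:
                        k = min(max_k, len(rows_c))
                    nn = rows_c[np.argpartition(d, k - 1)[:k]]
                    diff = np.abs(Xn[nn] - Xn[i]).sum(axis=0) / (m * k)
                    if c == ci:
                        W -= diff
                    else:
                        W += priors[c] / (1.0 - priors[ci]) * diff

        self.feature_scores_ = W
        self.ranking_ = np.lexsort((np.arange(p), -W))  # ties -> registry order
        self.feature_names_ = names
        self.n_features_in_ = p
        return self

    def transform(self, X):
        check_is_fitted(self, "ranking_")
        X, _ = _as_array(X)
        k = self.n_features_to_select or len(self.ranking_)
        return X[:, self.ranking_[:k]]

    def ranking_result(self, seed: int | None = None) -> RankingResult:
        check_is_fitted(self, "ranking_")
        return RankingResult(
            method="relieff",
            ordered_features=[self.feature_names_[i] for i in self.ranking_],
            scores=[float(self.feature_scores_[i]) for i in self.ranking_],
            seed=self.random_state if seed is None else seed,
            params={"k": self.n_neighbors, "n_updates": self.n_updates},
        )


def _discretize(X: np.ndarray, n_bins: int) -> np.ndarray:
    """Equal-frequency binning per column; constant columns get one bin."""
    codes = np.empty_like(X, dtype=np.int64)
    qs = np.linspace(0, 1, n_bins + 1)[1:-1]
    for j in range(X.shape[1]):
        edges = np.unique(np.quantile(X[:, j], qs))
        codes[:, j] = np.searchsorted(edges, X[:, j], side="right")
    return codes


def _mutual_information(a: np.ndarray, b: np.ndarray) -> float:
    """MI (nats) between two small-alphabet integer arrays via contingency."""
    na, nb = a.max() + 1, b.max() + 1
    joint = np.bincount(a * nb + b, minlength=na * nb).reshape(na, nb)
    joint = joint / joint.sum()
    pa = joint.sum(axis=1, keepdims=True)
    pb = joint.sum(axis=0, keepdims=True)
    nz = joint > 0
    return float((joint[nz] * np.log(joint[nz] / (pa @ pb)[nz])).sum())


class MRMR(TransformerMixin, BaseEstimator):
    """Greedy mRMR forward selection (MID criterion) on equal-frequency bins.

    Step 1 picks the feature with maximal mutual information with the class;
    each later step maximises relevance minus the mean mutual information
    with the already-selected features. Deterministic: ties resolve to the
    lowest column index.
    """

    def __init__(self, n_bins: int = 10, max_rank: int = 100,
                 n_features_to_select: int | None = None):
        self.n_bins = n_bins
        self.max_rank = max_rank
        self.n_features_to_select = n_features_to_select

    def fit(self, X, y):
        if self.n_bins < 2:
            raise ValueError("n_bins must be >= 2")
        X, names = _as_array(X)
        y = _validate_labels(y)
        n, p = X.shape
        codes = _discretize(X, self.n_bins)
        y_codes = pd.factorize(y)[0].astype(np.int64)

        relevance = np.array([_mutual_information(codes[:, j], y_codes)
                              for j in range(p)])
        n_select = min(self.max_rank, p)
        selected: list[int] = []
        scores: list[float] = []
        red_sum = np.zeros(p)
        available = np.ones(p, dtype=bool)
        for step in range(n_select):
            if step == 0:
                crit = relevance.copy()
            else:
                crit = relevance - red_sum / len(selected)
            crit[~available] = -np.inf
            j = int(np.argmax(crit))
            selected.append(j)
            scores.append(float(crit[j]))
            available[j] = False
            if step < n_select - 1:
                for cand in np.where(available)[0]:
                    red_sum[cand] += _mutual_information(codes[:, cand], codes[:, j])

        self.relevance_ = relevance
        self.ranking_ = np.array(selected)
        self.scores_ = np.array(scores)
        self.feature_names_ = names
        self.n_features_in_ = p
        return self

    def transform(self, X):
        check_is_fitted(self, "ranking_")
        X, _ = _as_array(X)
        k = self.n_features_to_select or len(self.ranking_)
        return X[:, self.ranking_[:k]]

    def ranking_result(self, seed: int | None = None) -> RankingResult:
        check_is_fitted(self, "ranking_")
        return RankingResult(
            method="mrmr",
            ordered_features=[self.feature_names_[i] for i in self.ranking_],
            scores=[float(s) for s in self.scores_],
            seed=seed,
            params={"n_bins": self.n_bins, "max_rank": self.max_rank},
        )


# ---------------------------------------------------------------------------
# functional wrappers over the estimators


def relieff_rank(X, y, k: int = 200, n_updates: int = 2000,
                 seed: int = 0) -> RankingResult:
    est = ReliefF(n_neighbors=k, n_updates=n_updates, random_state=seed)
    est.fit(X, y)
    return est.ranking_result(seed=seed)


def mrmr_rank(X, y, n_bins: int = 10, max_rank: int = 100) -> RankingResult:
    est = MRMR(n_bins=n_bins, max_rank=max_rank)
    est.fit(X, y)
    return est.ranking_result()
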