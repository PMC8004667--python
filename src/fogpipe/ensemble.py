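"""RUS-boosted ensembles of depth-limited decision trees.

Boosting follows the discrete AdaBoost weight-update, but each cycle's tree
is fitted on a rebalanced subset: every minority-class row plus a
weight-proportional random undersample of the majority class of equal size.
Undersampling happens only during training — prediction never resamples, so
the class imbalance of test data is untouched.

The split budget follows the ensemble-toolbox convention of capping the
*number* of splits with best-first growth (``split_budget="n_splits"``,
implemented as ``max_leaf_nodes = max_splits + 1``); a plain depth cap is
available as a documented alternative (``split_budget="depth"``).
"""

from __future__ import annotations

import json
import logging
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
from sklearn.base import BaseEstimator, ClassifierMixin
from sklearn.tree import DecisionTreeClassifier
from sklearn.utils.validation import check_is_fitted

from .selection import RankingResult

logger = logging.getLogger(__name__)

_ERR_EPS = 1e-10


@dataclass
class TrainConfig:
    """One point of the model grid: tree size, ranking, and feature count."""

    max_splits: int = 5
    n_cycles: int = 100
    learn_rate: float = 1.0
    top_k_features: int = 10
    ranking: RankingResult | None = None
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_cycles < 1 or self.n_cycles > 100:
            raise ValueError("n_cycles must lie in [1, 100]")
        if self.ranking is not None and self.top_k_features > len(self.ranking.ordered_features):
            raise ValueError("top_k_features exceeds ranking length")


class RUSBoostClassifier(ClassifierMixin, BaseEstimator):
    """Binary AdaBoost with per-cycle random undersampling of the majority class.

    Parameters
    ----------
    n_estimators : maximum number of boosting cycles (trees).
    max_splits : split budget per tree.
    split_budget : "n_splits" caps internal splits via best-first growth;
        "depth" caps tree depth instead.
    learning_rate : multiplier on each stage weight alpha.
    random_state : seed for the undersampling draws and tree tie-breaks.

    Fitted attributes: ``estimators_``, ``estimator_weights_``, ``classes_``,
    ``feature_names_in_`` (when fitted from a DataFrame).
    """

    def __init__(self, n_estimators: int = 100, max_splits: int = 5,
                 split_budget: str = "n_splits", learning_rate: float = 1.0,
                 threshold: float = 0.5, random_state: int | None = None):
        self.n_estimators = n_estimators
        self.max_splits = max_splits
        self.split_budget = split_budget
        self.learning_rate = learning_rate
        self.threshold = threshold
        self.random_state = random_state

    def _make_tree(self, seed: int) -> DecisionTreeClassifier:
        if self.split_budget == "n_splits":
            return DecisionTreeClassifier(max_leaf_nodes=self.max_splits + 1,
                                          random_state=seed)
        if self.split_budget == "depth":
            return DecisionTreeClassifier(max_depth=self.max_splits,
                                          random_state=seed)
        raise ValueError(f"unknown split_budget {self.split_budget!r}")

    def fit(self, X, y):
        if isinstance(X, pd.DataFrame):
            self.feature_names_in_ = np.asarray(X.columns, dtype=object)
            X = X.to_numpy(dtype=float)
        else:
            X = np.asarray(X, dtype=float)
        y = np.asarray(y)
        self.classes_ = np.unique(y)
        if len(self.classes_) != 2:
            raise ValueError("RUSBoostClassifier is binary; need exactly 2 classes")
        yb = (y == self.classes_[1]).astype(int)

        # canonical internal row order -> training invariant to input row order
        order = np.lexsort(tuple(X.T) + (yb,))
        X, yb = X[order], yb[order]
        n = len(yb)
        counts = np.bincount(yb, minlength=2)
        if counts.min() == 0:
            raise ValueError("minority class empty")
        minority = int(np.argmin(counts))
        min_rows = np.where(yb == minority)[0]
        maj_rows = np.where(yb != minority)[0]

        if np.all(X == X[0], axis=0).all():
            logger.warning("all features constant: falling back to a "
                           "single-leaf majority model")

        rng = np.random.default_rng(self.random_state)
        w = np.full(n, 1.0 / n)
        self.estimators_: list[DecisionTreeClassifier] = []
        self.estimator_weights_: list[float] = []
        for cycle in range(self.n_estimators):
            p_maj = w[maj_rows] / w[maj_rows].sum()
            draw = rng.choice(maj_rows, size=min(len(min_rows), len(maj_rows)),
                              replace=False, p=p_maj)
            subset = np.concatenate([min_rows, draw])
            tree = self._make_tree(int(rng.integers(2**31)))
            tree.fit(X[subset], yb[subset], sample_weight=w[subset])

            pred = tree.predict(X)
            miss = pred != yb
            err = float(w[miss].sum() / w.sum())
            if err >= 0.5:
                logger.debug("cycle %d: weighted error %.3f >= 0.5, stopping", cycle, err)
                break
            alpha = self.learning_rate * 0.5 * np.log((1 - err) / max(err, _ERR_EPS))
            self.estimators_.append(tree)
            self.estimator_weights_.append(float(alpha))
            if err <= _ERR_EPS:
                break
            w = w * np.exp(np.where(miss, alpha, -alpha))
            w /= w.sum()

        self._fallback_class_ = None
        if not self.estimators_:
            maj_label = int(np.argmax(counts))
            self._fallback_class_ = maj_label
            logger.warning("no tree achieved weighted error < 0.5; "
                           "predicting the majority class")
        self.n_features_in_ = X.shape[1]
        return self

    def decision_scores(self, X) -> np.ndarray:
        """Weighted positive-vote fraction in [0, 1]."""
        check_is_fitted(self, "classes_")
        if isinstance(X, pd.DataFrame):
            if hasattr(self, "feature_names_in_"):
                missing = [c for c in self.feature_names_in_ if c not in X.columns]
                if missing:
                    raise KeyError(f"missing feature columns: {missing}")
                X = X[list(self.feature_names_in_)]
            X = X.to_numpy(dtype=float)
        else:
            X = np.asarray(X, dtype=float)
        if self._fallback_class_ is not None:
            return np.full(len(X), float(self._fallback_class_))
        votes = np.array([t.predict(X) for t in self.estimators_], dtype=float)
        alphas = np.asarray(self.estimator_weights_)
        return (alphas[:, None] * votes).sum(axis=0) / alphas.sum()

    def predict_proba(self, X) -> np.ndarray:
        s = self.decision_scores(X)
        return np.column_stack([1 - s, s])

    def predict(self, X) -> np.ndarray:
        s = self.decision_scores(X)
        return self.classes_[(s >= self.threshold).astype(int)]


# ---------------------------------------------------------------------------
# named-feature wrapper + JSON serialisation


def _tree_to_dict(tree: DecisionTreeClassifier, feature_names: list[str]) -> dict:
    t = tree.tree_
    def node(i: int) -> dict:
        if t.children_left[i] == -1:
            counts = t.value[i][0]
            return {"leaf": True, "class_fractions": (counts / counts.sum()).tolist()}
        return {
            "leaf": False,
            "feature": feature_names[t.feature[i]],
            "threshold": float(t.threshold[i]),
            "left": node(t.children_left[i]),
            "right": node(t.children_right[i]),
        }
    return node(0)


def _eval_tree(node: dict, row: dict) -> int:
    while not node["leaf"]:
        node = node["left"] if row[node["feature"]] <= node["threshold"] else node["right"]
    fr = node["class_fractions"]
    return int(fr[1] >= fr[0])


@dataclass
class EnsembleModel:
    """A fitted ensemble bound to named feature columns."""

    clf: RUSBoostClassifier | None
    feature_subset: list[str]
    threshold: float = 0.5
    config: dict = field(default_factory=dict)
    _json_trees: list[dict] | None = None
    _json_alphas: list[float] | None = None

    def predict(self, X: pd.DataFrame) -> tuple[np.ndarray, np.ndarray]:
        """Per-row score in [0, 1] and binary vote; rows are never resampled."""
        missing = [c for c in self.feature_subset if c not in X.columns]
        if missing:
            raise KeyError(f"missing feature columns: {missing}")
        Xs = X[self.feature_subset]
        if self.clf is not None:
            scores = self.clf.decision_scores(Xs)
        else:
            alphas = np.asarray(self._json_alphas)
            rows = Xs.to_dict("records")
            votes = np.array([[_eval_tree(t, r) for r in rows]
                              for t in self._json_trees], dtype=float)
            scores = (alphas[:, None] * votes).sum(axis=0) / alphas.sum()
        return scores, scores >= self.threshold

    def to_json(self, path: str | Path) -> None:
        clf = self.clf
        if clf is None:
            trees, alphas = self._json_trees, self._json_alphas
        else:
            trees = [_tree_to_dict(t, list(self.feature_subset))
                     for t in clf.estimators_]
            alphas = list(clf.estimator_weights_)
        Path(path).write_text(json.dumps({
            "feature_subset": self.feature_subset,
            "threshold": self.threshold,
            "config": self.config,
            "stage_weights": alphas,
            "trees": trees,
        }, indent=1))

    @classmethod
    def from_json(cls, path: str | Path) -> "EnsembleModel":
        d = json.loads(Path(path).read_text())
        return cls(clf=None, feature_subset=d["feature_subset"],
                   threshold=d["threshold"], config=d.get("config", {}),
                   _json_trees=d["trees"], _json_alphas=d["stage_weights"])


def train_rusboost(X: pd.DataFrame, y, cfg: TrainConfig) -> EnsembleModel:
    """Fit the ensemble on the top-k features of ``cfg.ranking``.

    ``y`` is any binary labeling; the larger label value is the positive
    (target) class, matching the window-level Total-FOG target.
    """
    subset = (cfg.ranking.top(cfg.top_k_features) if cfg.ranking is not None
              else [str(c) for c in X.columns][:cfg.top_k_features])
    clf = RUSBoostClassifier(n_estimators=cfg.n_cycles, max_splits=cfg.max_splits,
                             learning_rate=cfg.learn_rate, random_state=cfg.seed)
    clf.fit(X[subset], np.asarray(y))
    return EnsembleModel(clf=clf, feature_subset=subset,
                         config={"max_splits": cfg.max_splits,
                                 "n_cycles": cfg.n_cycles,
                                 "learn_rate": cfg.learn_rate,
                                 "top_k_features": cfg.top_k_features,
                                 "seed": cfg.seed})
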