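"""Leave-one-freezer-out (LOFO) evaluation over the five window-label cases.

One model per fold is trained on the Case 1 target (Total-FOG vs No-FOG)
and then scored against all five case definitions; specificity is identical
across cases because the nontarget class (No-FOG) never changes. Nonfreezer
participants are always in the training set; their specificity is reported
separately from held-out folds of their own. Aggregate mean/SD cover the
freezer folds only.
"""

from __future__ import annotations

import json
import logging
from dataclasses import dataclass, field, asdict
from pathlib import Path

import numpy as np
import pandas as pd

from .ensemble import EnsembleModel, TrainConfig, train_rusboost
from .features import META_COLUMNS
from .selection import RankingResult, mrmr_rank, relieff_rank
from .windows import TOTAL_FOG_LABELS, Label

logger = logging.getLogger(__name__)


@dataclass(frozen=True)
class EvalCase:
    case_id: int
    target_labels: frozenset[str]

    @property
    def nontarget_labels(self) -> frozenset[str]:
        return frozenset({Label.NO_FOG.value})


#: the five target-class definitions; Case 1 is the composite Total-FOG
EVAL_CASES: tuple[EvalCase, ...] = (
    EvalCase(1, frozenset(l.value for l in TOTAL_FOG_LABELS)),
    EvalCase(2, frozenset({Label.PRE_FOG.value})),
    EvalCase(3, frozenset({Label.PRE_FOG.value, Label.PRE_FOG_TRANSITION.value})),
    EvalCase(4, frozenset({Label.PRE_FOG_TRANSITION.value})),
    EvalCase(5, frozenset({Label.FOG.value})),
)


def lofo_folds(freezer_map: dict[str, bool]) -> list[tuple[list[str], str]]:
    """One fold per freezer: (training participants, held-out freezer)."""
    freezers = sorted(p for p, f in freezer_map.items() if f)
    if not freezers:
        raise ValueError("no freezers: LOFO evaluation undefined")
    if len(freezer_map) < 2:
        raise ValueError("need at least 2 participants")
    return [([p for p in sorted(freezer_map) if p != held], held)
            for held in freezers]


def evaluate_case(predictions: np.ndarray, true_labels: np.ndarray,
                  case: EvalCase) -> dict:
    """Sensitivity/specificity for one case; out-of-case windows are excluded.

    ``predictions`` are binary target votes; ``true_labels`` are window label
    strings. With no target windows, sensitivity is ``None`` (never 100%).
    """
    predictions = np.asarray(predictions, dtype=bool)
    true_labels = np.asarray(true_labels)
    is_target = np.isin(true_labels, list(case.target_labels))
    is_nontarget = np.isin(true_labels, list(case.nontarget_labels))
    tp = int((predictions & is_target).sum())
    fn = int((~predictions & is_target).sum())
    fp = int((predictions & is_nontarget).sum())
    tn = int((~predictions & is_nontarget).sum())
    sens = tp / (tp + fn) if tp + fn else None
    spec = tn / (tn + fp) if tn + fp else None
    return {"case_id": case.case_id, "sensitivity": sens, "specificity": spec,
            "counts": {"tp": tp, "fn": fn, "fp": fp, "tn": tn}}


@dataclass
class EvalReport:
    """Per-held-out-participant metrics per case, plus freezer-only aggregates."""

    config: dict
    folds: list[dict] = field(default_factory=list)        # freezer folds
    nonfreezer_specificity: dict[str, float] = field(default_factory=dict)
    aggregates: dict = field(default_factory=dict)

    def aggregate(self) -> None:
        """Population mean/SD over freezer folds, per case."""
        self.aggregates = {}
        for case in EVAL_CASES:
            sens = [f["cases"][str(case.case_id)]["sensitivity"] for f in self.folds]
            spec = [f["cases"][str(case.case_id)]["specificity"] for f in self.folds]
            sens = [s for s in sens if s is not None]
            spec = [s for s in spec if s is not None]
            self.aggregates[str(case.case_id)] = {
                "sensitivity_mean": float(np.mean(sens)) if sens else None,
                "sensitivity_sd": float(np.std(sens)) if sens else None,
                "specificity_mean": float(np.mean(spec)) if spec else None,
                "specificity_sd": float(np.std(spec)) if spec else None,
            }

    def to_json(self, path: str | Path) -> None:
        Path(path).write_text(json.dumps(asdict(self), indent=1))

    def summary_frame(self) -> pd.DataFrame:
        """Held-out participants as rows, per-case sens/spec as columns."""
        rows = []
        for f in self.folds:
            row = {"participant": f["participant"]}
            for cid, m in f["cases"].items():
                row[f"case{cid}_sens"] = m["sensitivity"]
                row[f"case{cid}_spec"] = m["specificity"]
            rows.append(row)
        for p, s in self.nonfreezer_specificity.items():
            rows.append({"participant": p, "case1_spec": s})
        return pd.DataFrame(rows)


def _case1_targets(labels: pd.Series) -> np.ndarray:
    return labels.isin([l.value for l in TOTAL_FOG_LABELS]).to_numpy()


def _rank(method: str, X: pd.DataFrame, y: np.ndarray, seed: int,
          relieff_k: int = 200, relieff_updates: int = 2000) -> RankingResult:
    if method == "relieff":
        return relieff_rank(X, y, k=relieff_k, n_updates=relieff_updates, seed=seed)
    if method == "mrmr":
        return mrmr_rank(X, y)
    raise ValueError(f"unknown ranking method {method!r}")


def _feature_columns(features: pd.DataFrame) -> list[str]:
    return [c for c in features.columns if c not in META_COLUMNS]


def run_lofo(features: pd.DataFrame, freezer_map: dict[str, bool],
             method: str = "relieff", top_k: int = 10, max_splits: int = 5,
             n_cycles: int = 100, seed: int = 0,
             relieff_k: int = 200, relieff_updates: int = 2000,
             rankings: dict[str, RankingResult] | None = None,
             include_nonfreezers: bool = True) -> EvalReport:
    """Full LOFO pass for one configuration.

    Feature selection is re-run inside every fold on training participants
    only (no leakage); pass ``rankings`` (held-out participant -> ranking) to
    reuse rankings across configurations of a grid.
    """
    feat_cols = _feature_columns(features)
    report = EvalReport(config={"method": method, "top_k": top_k,
                                "max_splits": max_splits, "n_cycles": n_cycles,
                                "seed": seed, "n_features": len(feat_cols)})
    for train_ids, held in lofo_folds(freezer_map):
        train = features[features.participant_id.isin(train_ids)]
        test = features[features.participant_id == held]
        y_train = _case1_targets(train.label)
        ranking = (rankings or {}).get(held)
        if ranking is None:
            ranking = _rank(method, train[feat_cols], y_train, seed,
                            relieff_k, relieff_updates)
        model = train_rusboost(
            train[feat_cols], y_train,
            TrainConfig(max_splits=max_splits, n_cycles=n_cycles,
                        top_k_features=top_k, ranking=ranking, seed=seed))
        _, votes = model.predict(test[feat_cols])
        fold = {"participant": held,
                "cases": {str(c.case_id): evaluate_case(votes, test.label.to_numpy(), c)
                          for c in EVAL_CASES}}
        report.folds.append(fold)
        logger.info("fold %s: case1 sens=%s spec=%s", held,
                    fold["cases"]["1"]["sensitivity"], fold["cases"]["1"]["specificity"])

    if include_nonfreezers:
        for nf in sorted(p for p, f in freezer_map.items() if not f):
            spec = nonfreezer_specificity(features, freezer_map, nf, method=method,
                                          top_k=top_k, max_splits=max_splits,
                                          n_cycles=n_cycles, seed=seed,
                                          relieff_k=relieff_k,
                                          relieff_updates=relieff_updates)
            report.nonfreezer_specificity[nf] = spec
    report.aggregate()
    return report


def nonfreezer_specificity(features: pd.DataFrame, freezer_map: dict[str, bool],
                           nonfreezer: str, method: str = "relieff",
                           top_k: int = 10, max_splits: int = 5,
                           n_cycles: int = 100, seed: int = 0,
                           relieff_k: int = 200, relieff_updates: int = 2000) -> float:
    """Hold one nonfreezer out, train on everyone else, report specificity only."""
    if freezer_map[nonfreezer]:
        raise ValueError(f"{nonfreezer} is a freezer")
    feat_cols = _feature_columns(features)
    train = features[features.participant_id != nonfreezer]
    test = features[features.participant_id == nonfreezer]
    y_train = _case1_targets(train.label)
    ranking = _rank(method, train[feat_cols], y_train, seed,
                    relieff_k, relieff_updates)
    model = train_rusboost(
        train[feat_cols], y_train,
        TrainConfig(max_splits=max_splits, n_cycles=n_cycles,
                    top_k_features=top_k, ranking=ranking, seed=seed))
    _, votes = model.predict(test[feat_cols])
    res = evaluate_case(votes, test.label.to_numpy(), EVAL_CASES[0])
    return res["specificity"]


#: the model grid: both ranking methods x 8 feature counts x 2 split budgets
GRID_METHODS = ("relieff", "mrmr")
GRID_TOP_K = (5, 10, 15, 20, 25, 50, 75, 100)
GRID_MAX_SPLITS = (5, 10)


def run_grid(features: pd.DataFrame, freezer_map: dict[str, bool],
             seed: int = 0, n_cycles: int = 100,
             relieff_k: int = 200, relieff_updates: int = 2000
             ) -> tuple[EvalReport, list[dict]]:
    """Evaluate all 32 configurations under LOFO; return the best report.

    "Best" = highest mean balanced accuracy, (sensitivity + specificity)/2,
    over the freezer folds for Case 1. Per-fold rankings are computed once
    per method and shared across feature counts and split budgets.
    """
    feat_cols = _feature_columns(features)
    fold_rankings: dict[str, dict[str, RankingResult]] = {m: {} for m in GRID_METHODS}
    for train_ids, held in lofo_folds(freezer_map):
        train = features[features.participant_id.isin(train_ids)]
        y_train = _case1_targets(train.label)
        for m in GRID_METHODS:
            fold_rankings[m][held] = _rank(m, train[feat_cols], y_train, seed,
                                           relieff_k, relieff_updates)

    grid_rows: list[dict] = []
    best: tuple[float, EvalReport] | None = None
    for m in GRID_METHODS:
        for k in GRID_TOP_K:
            if k > len(feat_cols):
                continue
            for splits in GRID_MAX_SPLITS:
                rep = run_lofo(features, freezer_map, method=m, top_k=k,
                               max_splits=splits, n_cycles=n_cycles, seed=seed,
                               rankings=fold_rankings[m],
                               include_nonfreezers=False)
                agg = rep.aggregates["1"]
                score = (agg["sensitivity_mean"] + agg["specificity_mean"]) / 2
                grid_rows.append({"method": m, "top_k": k, "max_splits": splits,
                                  "balanced_accuracy": score,
                                  "sensitivity": agg["sensitivity_mean"],
                                  "specificity": agg["specificity_mean"]})
                if best is None or score > best[0]:
                    best = (score, rep)
    if best is None:
        raise ValueError("no grid configuration fits the supplied feature count")
    best_rep = best[1]
    for nf in sorted(p for p, f in freezer_map.items() if not f):
        best_rep.nonfreezer_specificity[nf] = nonfreezer_specificity(
            features, freezer_map, nf, method=best_rep.config["method"],
            top_k=best_rep.config["top_k"], max_splits=best_rep.config["max_splits"],
            n_cycles=n_cycles, seed=seed, relieff_k=relieff_k,
            relieff_updates=relieff_updates)
    return best_rep, grid_rows
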