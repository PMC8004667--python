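import numpy as np
import pandas as pd
import pytest

import fogpipe as fp
from fogpipe.evaluation import EVAL_CASES


def test_eval_cases_match_target_definitions():
    by_id = {c.case_id: c.target_labels for c in EVAL_CASES}
    assert by_id == {
        1: {"PRE_FOG", "PRE_FOG_TRANSITION", "FOG"},
        2: {"PRE_FOG"},
        3: {"PRE_FOG", "PRE_FOG_TRANSITION"},
        4: {"PRE_FOG_TRANSITION"},
        5: {"FOG"},
    }
    assert all(c.nontarget_labels == {"NO_FOG"} for c in EVAL_CASES)


def test_lofo_fold_structure():
    fm = {f"P{i:02d}": i <= 7 for i in range(1, 12)}  # 7 freezers, 4 non
    folds = fp.lofo_folds(fm)
    assert len(folds) == 7
    for train, held in folds:
        assert fm[held]
        assert held not in train
        assert len(train) == 10
        # nonfreezers always train
        assert all(p in train for p, isf in fm.items() if not isf)


def test_lofo_minimal_and_degenerate():
    assert len(fp.lofo_folds({"A": True, "B": False})) == 1
    with pytest.raises(ValueError, match="no freezers"):
        fp.lofo_folds({"A": False, "B": False})


def test_sensitivity_specificity_ratios():
    labels = np.array(["FOG"] * 100 + ["NO_FOG"] * 50)
    preds = np.array([True] * 70 + [False] * 30 + [False] * 45 + [True] * 5)
    res = fp.evaluate_case(preds, labels, EVAL_CASES[4])  # case 5: FOG
    assert res["sensitivity"] == pytest.approx(0.70)
    assert res["specificity"] == pytest.approx(0.90)
    assert res["counts"] == {"tp": 70, "fn": 30, "fp": 5, "tn": 45}


def test_all_negative_predictor():
    labels = np.array(["FOG"] * 10 + ["NO_FOG"] * 10)
    res = fp.evaluate_case(np.zeros(20, bool), labels, EVAL_CASES[4])
    assert res["sensitivity"] == 0.0
    assert res["specificity"] == 1.0


def test_zero_target_windows_reports_missing_sensitivity():
    labels = np.array(["NO_FOG"] * 10)
    res = fp.evaluate_case(np.zeros(10, bool), labels, EVAL_CASES[1])
    assert res["sensitivity"] is None
    assert res["specificity"] == 1.0


def test_out_of_case_windows_excluded():
    """Case 2 ignores FOG and transition windows entirely."""
    labels = np.array(["PRE_FOG", "FOG", "PRE_FOG_TRANSITION", "NO_FOG"])
    preds = np.array([True, True, True, False])
    res = fp.evaluate_case(preds, labels, EVAL_CASES[1])
    assert res["counts"]["tp"] + res["counts"]["fn"] == 1


def _toy_features(rng, n_participants=4, n_freezers=2, n_windows=120):
    """A small feature table where one feature separates Total-FOG windows."""
    rows = []
    for i in range(n_participants):
        pid = f"P{i + 1:02d}"
        freezer = i < n_freezers
        for j in range(n_windows):
            if freezer and j % 6 == 0:
                label = ("PRE_FOG", "PRE_FOG_TRANSITION", "FOG")[j % 3]
            else:
                label = "NO_FOG"
            target = label != "NO_FOG"
            rows.append({
                "participant_id": pid, "trial_id": "T01", "start_sample": j * 20,
                "label": label,
                "good": 3.0 * target + rng.standard_normal() * 0.3,
                "noise": rng.standard_normal(),
            })
    fm = {f"P{i + 1:02d}": i < n_freezers for i in range(n_participants)}
    return pd.DataFrame(rows), fm


def test_specificity_constant_across_cases(rng):
    features, fm = _toy_features(rng)
    rep = fp.run_lofo(features, fm, method="mrmr", top_k=2, max_splits=5,
                      n_cycles=20, seed=0)
    for fold in rep.folds:
        specs = {fold["cases"][str(c.case_id)]["specificity"]
                 for c in EVAL_CASES}
        assert len(specs) == 1


def test_case1_sensitivity_is_mixture_of_single_label_cases(rng):
    """Case 1 counts are the sums of the disjoint Cases 2, 4, 5 counts, so its
    sensitivity lies between their extremes."""
    features, fm = _toy_features(rng)
    rep = fp.run_lofo(features, fm, method="mrmr", top_k=2, max_splits=5,
                      n_cycles=20, seed=0)
    for fold in rep.folds:
        c = {cid: fold["cases"][cid] for cid in ("1", "2", "4", "5")}
        tp1 = c["1"]["counts"]["tp"]
        fn1 = c["1"]["counts"]["fn"]
        assert tp1 == sum(c[k]["counts"]["tp"] for k in ("2", "4", "5"))
        assert fn1 == sum(c[k]["counts"]["fn"] for k in ("2", "4", "5"))
        sens = [c[k]["sensitivity"] for k in ("2", "4", "5")
                if c[k]["sensitivity"] is not None]
        if sens and c["1"]["sensitivity"] is not None:
            assert min(sens) - 1e-12 <= c["1"]["sensitivity"] <= max(sens) + 1e-12


def test_aggregates_match_hand_computation(rng):
    features, fm = _toy_features(rng)
    rep = fp.run_lofo(features, fm, method="mrmr", top_k=2, max_splits=5,
                      n_cycles=20, seed=0)
    sens = [f["cases"]["1"]["sensitivity"] for f in rep.folds]
    agg = rep.aggregates["1"]
    assert agg["sensitivity_mean"] == pytest.approx(np.mean(sens))
    assert agg["sensitivity_sd"] == pytest.approx(np.std(sens))
    # nonfreezers excluded from folds, reported separately
    assert set(rep.nonfreezer_specificity) == {p for p, f in fm.items() if not f}
    assert len(rep.folds) == sum(fm.values())


def test_nonfreezer_specificity_and_report_round_trip(tmp_path, rng):
    features, fm = _toy_features(rng)
    spec = fp.nonfreezer_specificity(features, fm, "P03", method="mrmr",
                                     top_k=2, max_splits=5, n_cycles=10, seed=0)
    assert 0.0 <= spec <= 1.0
    rep = fp.run_lofo(features, fm, method="mrmr", top_k=2, max_splits=5,
                      n_cycles=10, seed=0)
    rep.to_json(tmp_path / "rep.json")
    frame = rep.summary_frame()
    assert {"participant", "case1_sens", "case1_spec"} <= set(frame.columns)


def test_grid_enumeration_and_best_selection(rng):
    features, fm = _toy_features(rng, n_windows=60)
    for i in range(4):  # pad to 6 feature columns so only top_k=5 fits
        features[f"pad{i}"] = rng.standard_normal(len(features))
    best, grid = fp.run_grid(features, fm, seed=0, n_cycles=5,
                             relieff_k=5, relieff_updates=50)
    # 2 methods x 1 feasible feature count (5 of the 8) x 2 split budgets
    assert len(grid) == 4
    assert {(g["method"], g["max_splits"]) for g in grid} == {
        ("relieff", 5), ("relieff", 10), ("mrmr", 5), ("mrmr", 10)}
    best_score = max(g["balanced_accuracy"] for g in grid)
    agg = best.aggregates["1"]
    assert (agg["sensitivity_mean"] + agg["specificity_mean"]) / 2 == \
        pytest.approx(best_score)
    from fogpipe.evaluation import GRID_MAX_SPLITS, GRID_METHODS, GRID_TOP_K
    assert len(GRID_METHODS) * len(GRID_TOP_K) * len(GRID_MAX_SPLITS) == 32


def test_no_leakage_training_excludes_held_out(rng):
    """The trained fold model is identical whether or not the held-out
    participant's rows are present in the table (pure function of train rows)."""
    features, fm = _toy_features(rng)
    held = "P01"
    rest = features[features.participant_id != held]
    fm_rest = dict(fm)
    y = rest.label != "NO_FOG"
    ranking = fp.mrmr_rank(rest[["good", "noise"]], y.to_numpy())
    model = fp.train_rusboost(rest[["good", "noise"]], y.to_numpy(),
                              fp.TrainConfig(top_k_features=2, ranking=ranking,
                                             seed=0))
    rep = fp.run_lofo(features, fm, method="mrmr", top_k=2, max_splits=5,
                      n_cycles=100, seed=0, include_nonfreezers=False)
    test = features[features.participant_id == held]
    _, votes = model.predict(test[["good", "noise"]])
    expected = fp.evaluate_case(votes, test.label.to_numpy(), EVAL_CASES[0])
    got = next(f for f in rep.folds if f["participant"] == held)["cases"]["1"]
    assert got == expected
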