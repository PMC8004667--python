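import numpy as np
import pytest

import fogpipe as fp
from fogpipe.features import (FFT_FEATURE_TYPES, WT_FEATURE_TYPES, FeatureName,
                              _TIME_PER_SIDE, fft_wt_signal_list)


# ---------------------------------------------------------------------------
# registry structure


def test_registry_cardinalities():
    both = fp.build_registry("both")
    pp = fp.build_registry("pp")
    imu = fp.build_registry("imu")
    assert len(both) == 861
    assert len(pp) == 333
    assert len(imu) == 528
    by_cat = {}
    for f in both:
        by_cat[f.category] = by_cat.get(f.category, 0) + 1
    assert by_cat == {"TIME": 25, "FFT": 304, "WT": 532}


def test_feature_type_grouping():
    """13 time-domain, 8 FFT, and 14 wavelet feature types."""
    both = fp.build_registry("both")
    types = {cat: {f.feature_type for f in both if f.category == cat}
             for cat in ("TIME", "FFT", "WT")}
    assert len(types["TIME"]) == 13
    assert len(types["FFT"]) == 8
    assert len(types["WT"]) == 14


def test_signal_list_is_38_disjoint_pp_imu():
    pairs = fft_wt_signal_list("both")
    assert len(pairs) == 38
    pp = set(fft_wt_signal_list("pp"))
    imu = set(fft_wt_signal_list("imu"))
    assert len(pp) == 14 and len(imu) == 24
    assert pp | imu == set(pairs) and not (pp & imu)


def test_registry_no_duplicates_and_round_trip():
    both = fp.build_registry("both")
    strs = [str(f) for f in both]
    assert len(set(strs)) == 861
    assert all(FeatureName.parse(s) == f for s, f in zip(strs, both))
    shifts = [f for f in both if f.feature_type == "n_weight_shifts"]
    assert len(shifts) == 1 and shifts[0].side == "both"


# ---------------------------------------------------------------------------
# pressure preprocessing


def _pressure_trial(grf_l, grf_r, cop_ap_l=None, fs=100.0):
    n = len(grf_l)
    z = np.zeros(n)
    channels = {"grf_left": np.asarray(grf_l, float),
                "grf_right": np.asarray(grf_r, float),
                "cop_ap_left": np.asarray(cop_ap_l, float) if cop_ap_l is not None else z.copy(),
                "cop_ml_left": z.copy(), "cop_ap_right": z.copy(),
                "cop_ml_right": z.copy()}
    return fp.GaitTrial("P", "T", fs, channels, [], False)


def test_grf_below_five_percent_zeroed():
    trial = _pressure_trial([10.0, 500.0], [990.0, 500.0])
    out = fp.preprocess_pressure(trial)
    assert out["left"]["grf"][0] == 0.0          # 10/1000 = 1% < 5%
    assert out["left"]["grf"][1] == 500.0
    assert out["right"]["grf"][0] == 990.0


def test_constant_cop_has_zero_derivatives():
    n = 50
    trial = _pressure_trial(np.full(n, 400.0), np.full(n, 400.0),
                            cop_ap_l=np.full(n, 12.3))
    out = fp.preprocess_pressure(trial)
    np.testing.assert_array_equal(out["left"]["cop_ap_vel"], 0.0)
    np.testing.assert_array_equal(out["left"]["cop_ap_acc"], 0.0)


def test_linear_cop_ramp_velocity():
    """A 2 mm/s AP ramp during full stance gives velocity 2 mm/s throughout."""
    fs, n = 100.0, 200
    ramp = 2.0 * np.arange(n) / fs
    trial = _pressure_trial(np.full(n, 400.0), np.full(n, 400.0), cop_ap_l=ramp)
    out = fp.preprocess_pressure(trial)
    np.testing.assert_allclose(out["left"]["cop_ap_vel"][1:], 2.0, atol=1e-9)


def test_swing_cop_held_from_last_stance():
    grf_l = np.array([400.0, 400.0, 0.0, 0.0, 400.0])
    trial = _pressure_trial(grf_l, np.full(5, 400.0),
                            cop_ap_l=np.array([1.0, 2.0, 99.0, 99.0, 5.0]))
    out = fp.preprocess_pressure(trial)
    np.testing.assert_array_equal(out["left"]["cop_ap"], [1.0, 2.0, 2.0, 2.0, 5.0])


def test_no_stance_raises():
    trial = _pressure_trial(np.zeros(10), np.full(10, 400.0))
    with pytest.raises(ValueError, match="no stance"):
        fp.preprocess_pressure(trial)


# ---------------------------------------------------------------------------
# time-domain features


def _time_windows(cop_ap_l=None, cop_ml_l=None, grf_l=None, grf_r=None, n=100):
    z = np.zeros(n)
    base = {"grf": np.full(n, 400.0), "cop_ap": z, "cop_ml": z,
            "cop_ap_vel": z, "cop_ml_vel": z, "cop_ap_acc": z, "cop_ml_acc": z}
    left = dict(base)
    right = dict(base)
    if cop_ap_l is not None:
        left["cop_ap"] = np.asarray(cop_ap_l, float)
    if cop_ml_l is not None:
        left["cop_ml"] = np.asarray(cop_ml_l, float)
    if grf_l is not None:
        left["grf"] = np.asarray(grf_l, float)
    if grf_r is not None:
        right["grf"] = np.asarray(grf_r, float)
    return {"left": left, "right": right}


def test_monotone_ramp_has_no_reversals():
    sw = _time_windows(cop_ap_l=np.linspace(0, 10, 100))
    out = fp.time_features(sw, fs=100.0)
    assert out["TIME|n_reversals|cop_ap|left"] == 0.0


def test_triangle_wave_reversal_count():
    """Three interior vertices -> three sign changes of the first difference."""
    x = np.interp(np.arange(100), [0, 25, 49, 73, 99], [0.0, 5.0, 0.0, 5.0, 0.0])
    out = fp.time_features(_time_windows(cop_ap_l=x), fs=100.0)
    assert out["TIME|n_reversals|cop_ap|left"] == 3.0


def test_weight_shift_counting():
    half = np.concatenate([np.full(50, 800.0), np.zeros(50)])
    out = fp.time_features(_time_windows(grf_l=half, grf_r=half[::-1]), fs=100.0)
    assert out["TIME|n_weight_shifts|grf|both"] == 1.0
    even = _time_windows(grf_l=np.full(100, 400.0), grf_r=np.full(100, 400.0))
    assert fp.time_features(even, fs=100.0)["TIME|n_weight_shifts|grf|both"] == 0.0


def test_ml_deviation_events():
    """One step of 3 mm in an otherwise flat ML trace -> one deviation sample."""
    x = np.zeros(100)
    x[50:] = 3.0
    out = fp.time_features(_time_windows(cop_ml_l=x), fs=100.0)
    assert out["TIME|n_deviations|cop_ml|left"] == 1.0
    assert out["TIME|deviation_duration|cop_ml|left"] == pytest.approx(0.01)
    assert out["TIME|deviation_length|cop_ml|left"] == pytest.approx(3.0)


def test_cv_zero_mean_convention():
    x = np.sin(np.linspace(0, 4 * np.pi, 100))  # near-zero mean
    out = fp.time_features(_time_windows(cop_ap_l=x * 1e-12), fs=100.0)
    assert out["TIME|cv_cop_ap|cop_ap|left"] == 0.0


# ---------------------------------------------------------------------------
# FFT features


def test_pure_sinusoid_spectrum():
    fs, n = 100.0, 100
    t = np.arange(n) / fs
    x = np.sin(2 * np.pi * 5 * t)
    out = fp.fft_features(x, fs)
    assert out["dominant_frequency"][0] == 5.0
    assert out["locomotion_power"][0] == pytest.approx(0.0, abs=1e-18)
    assert out["freeze_index"][0] > 1e6


def test_equal_two_tone_freeze_index_unity():
    fs, n = 100.0, 100
    t = np.arange(n) / fs
    x = np.sin(2 * np.pi * 2 * t) + np.sin(2 * np.pi * 5 * t)
    out = fp.fft_features(x, fs)
    assert out["freeze_index"][0] == pytest.approx(1.0, rel=1e-9)


def test_constant_signal_zero_power():
    """A DC-only signal carries no power once the DC bin is excluded (up to
    float round-off of the transform)."""
    out = fp.fft_features(np.full(100, 3.7), 100.0)
    assert out["total_power"][0] == pytest.approx(0.0, abs=1e-18)
    assert out["freeze_index"][0] == pytest.approx(0.0, abs=1e-9)


def test_band_powers_match_direct_dft(rng):
    """FFT band powers equal a direct O(N^2) DFT summation to 1e-9 rel tol."""
    fs, n = 100.0, 100
    k = np.arange(n)
    for _ in range(20):
        x = rng.standard_normal(n)
        out = fp.fft_features(x, fs)
        # direct DFT over non-negative bins
        freqs = np.arange(n // 2 + 1) * fs / n
        amp = np.abs(np.array([(x * np.exp(-2j * np.pi * f * k / n)).sum()
                               for f in range(n // 2 + 1)]))
        power = amp[1:] ** 2
        fr = freqs[1:]
        loco = power[(fr >= 0.5) & (fr < 3.0)].sum()
        freeze = power[(fr >= 3.0) & (fr <= 8.0)].sum()
        np.testing.assert_allclose(out["locomotion_power"][0], loco, rtol=1e-9)
        np.testing.assert_allclose(out["freeze_power"][0], freeze, rtol=1e-9)
        np.testing.assert_allclose(out["total_power"][0], power.sum(), rtol=1e-9)
        assert out["locomotion_power"][0] + out["freeze_power"][0] <= (
            out["total_power"][0] * (1 + 1e-12))


def test_fft_scale_covariance(rng):
    x = rng.standard_normal(100)
    a, b = fp.fft_features(x, 100.0), fp.fft_features(3.0 * x, 100.0)
    np.testing.assert_allclose(b["amp_max"], 3.0 * a["amp_max"], rtol=1e-12)
    np.testing.assert_allclose(b["total_power"], 9.0 * a["total_power"], rtol=1e-12)
    assert b["dominant_frequency"] == a["dominant_frequency"]
    np.testing.assert_allclose(b["freeze_index"], a["freeze_index"], rtol=1e-9)


# ---------------------------------------------------------------------------
# wavelet features


def test_haar_of_constant():
    out = fp.wt_features(np.full(100, 2.0))
    assert out["wt_dc_var"][0] == 0.0
    assert out["wt_ac_mean"][0] == pytest.approx(2.0 * np.sqrt(2.0))
    assert out["wt_dc_max"][0] == pytest.approx(0.0, abs=1e-12)


def test_haar_of_alternation():
    x = np.tile([1.0, -1.0], 50)
    out = fp.wt_features(x)
    assert out["wt_ac_max"][0] == pytest.approx(0.0, abs=1e-12)
    assert abs(out["wt_dc_mean"][0]) == pytest.approx(np.sqrt(2.0))


def test_haar_parseval(rng):
    """Orthonormal DWT: sum aC^2 + sum dC^2 = sum x^2."""
    for _ in range(10):
        x = rng.standard_normal(100)
        out = fp.wt_features(x)
        total = 50 * (out["wt_ac_energy_mean"][0] + out["wt_dc_energy_mean"][0])
        np.testing.assert_allclose(total, (x ** 2).sum(), rtol=1e-10)


def test_odd_window_rejected():
    with pytest.raises(ValueError):
        fp.wt_features(np.zeros(99))


# ---------------------------------------------------------------------------
# matrix assembly


def test_feature_matrix_shape_and_finiteness(small_cohort):
    _, trials = small_cohort
    trial = trials[0]
    windows = fp.generate_windows(trial)
    reg = fp.build_registry("both")
    mat = fp.extract_features([trial], windows, reg)
    assert mat.shape == (len(windows), 4 + 861)
    assert np.isfinite(mat[[str(f) for f in reg]].to_numpy()).all()


def test_empty_window_list_gives_header_only():
    reg = fp.build_registry("pp")
    mat = fp.extract_features([], [], reg)
    assert len(mat) == 0
    assert list(mat.columns[4:]) == [str(f) for f in reg]


def test_missing_channel_raises(small_cohort):
    _, trials = small_cohort
    trial = trials[0]
    broken = fp.GaitTrial(trial.participant_id, trial.trial_id, trial.fs,
                          {k: v for k, v in trial.channels.items()
                           if k != "acc_x_ankle_left"},
                          trial.episodes, trial.freezer)
    windows = fp.generate_windows(broken)
    with pytest.raises(KeyError, match="acc_x_ankle_left"):
        fp.extract_features([broken], windows, fp.build_registry("imu"))


def test_pp_only_matrix_has_333_feature_columns(small_cohort):
    _, trials = small_cohort
    trial = trials[0]
    windows = fp.generate_windows(trial)[:5]
    mat = fp.extract_features([trial], windows, fp.build_registry("pp"))
    assert mat.shape[1] - 4 == 333
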