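"""The 861-feature registry and its extraction from labeled windows.

Three feature families are computed per 1 s window:

* 25 time-domain features from the plantar-pressure channels only —
  anterior/posterior (AP) COP path reversals, mediolateral (ML) COP
  deviations, coefficients of variation of COP position/velocity/
  acceleration, and the between-feet weight-shift count;
* 8 FFT features for each of 38 input signals (total spectral power,
  dominant frequency, max/min/mean amplitude, locomotion-band 0.5-3 Hz and
  freeze-band 3-8 Hz power, and their ratio, the freeze index);
* 14 Haar discrete-wavelet features for each of the same 38 signals
  (variance, max/min/mean, and max/min/mean energy of the single-level
  approximation and detail coefficient vectors).

The 38 signals are, per side: GRF; COP position, velocity and acceleration
in AP and ML (14 plantar-pressure signals); and ankle/thigh 3-axis
acceleration and angular rate (24 IMU signals). Feature totals are 333 for
plantar pressure, 528 for IMU, 861 combined.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
import pandas as pd
import pywt

from .simulate import SIDES, GaitTrial
from .windows import LabeledWindow

logger = logging.getLogger(__name__)

_EPS_MEAN = 1e-9
_EPS_POWER = 1e-12

LOCOMOTION_BAND = (0.5, 3.0)   # [low, high) Hz
FREEZE_BAND = (3.0, 8.0)       # [low, high] Hz

#: per-side plantar-pressure signal names used for FFT/WT features (7 x 2 sides)
PP_SIGNALS = ("grf", "cop_ap", "cop_ml", "cop_ap_vel", "cop_ml_vel",
              "cop_ap_acc", "cop_ml_acc")
#: per-side IMU signal names (12 x 2 sides); these match raw channel names
#: once the side suffix is appended
IMU_SIGNALS = tuple(
    f"{kind}_{ax}_{loc}"
    for loc in ("ankle", "thigh")
    for kind in ("acc", "gyro")
    for ax in ("x", "y", "z")
)

# (feature_type, signal) pairs computed per side; plus the two-footed
# weight-shift count. 12 x 2 + 1 = 25 features over 13 distinct types.
_TIME_PER_SIDE = (
    ("n_reversals", "cop_ap"),
    ("reversal_duration", "cop_ap"),
    ("reversal_length", "cop_ap"),
    ("n_deviations", "cop_ml"),
    ("deviation_duration", "cop_ml"),
    ("deviation_length", "cop_ml"),
    ("cv_cop_ap", "cop_ap"),
    ("cv_cop_ml", "cop_ml"),
    ("cv_cop_ap_vel", "cop_ap_vel"),
    ("cv_cop_ml_vel", "cop_ml_vel"),
    ("cv_cop_ap_acc", "cop_ap_acc"),
    ("cv_cop_ml_acc", "cop_ml_acc"),
)

FFT_FEATURE_TYPES = ("total_power", "dominant_frequency", "amp_max", "amp_min",
                     "amp_mean", "locomotion_power", "freeze_power", "freeze_index")
WT_FEATURE_TYPES = ("wt_ac_var", "wt_dc_var",
                    "wt_ac_max", "wt_ac_min", "wt_ac_mean",
                    "wt_dc_max", "wt_dc_min", "wt_dc_mean",
                    "wt_ac_energy_max", "wt_ac_energy_min", "wt_ac_energy_mean",
                    "wt_dc_energy_max", "wt_dc_energy_min", "wt_dc_energy_mean")


@dataclass(frozen=True)
class FeatureName:
    """One column of the feature matrix: what was computed, on which signal."""

    category: str       # TIME | FFT | WT
    feature_type: str
    signal: str
    side: str           # left | right | both

    def __str__(self) -> str:
        return f"{self.category}|{self.feature_type}|{self.signal}|{self.side}"

    @classmethod
    def parse(cls, s: str) -> "FeatureName":
        category, feature_type, signal, side = s.split("|")
        return cls(category, feature_type, signal, side)


@dataclass(frozen=True)
class CopPreprocessConfig:
    """Swing-phase suppression and ML-deviation threshold for COP features."""

    grf_zero_fraction: float = 0.05
    deviation_threshold_mm: float = 0.5

    def __post_init__(self) -> None:
        if self.grf_zero_fraction <= 0 or self.deviation_threshold_mm <= 0:
            raise ValueError("thresholds must be positive")


def fft_wt_signal_list(sensors: str = "both") -> list[tuple[str, str]]:
    """Ordered (signal, side) pairs for the FFT/WT families."""
    pairs = []
    if sensors in ("both", "pp"):
        pairs += [(s, side) for side in SIDES for s in PP_SIGNALS]
    if sensors in ("both", "imu"):
        pairs += [(s, side) for side in SIDES for s in IMU_SIGNALS]
    return pairs


def build_registry(sensors: str = "both") -> list[FeatureName]:
    """Deterministically ordered feature registry.

    ``both`` -> 861 names (25 TIME + 8x38 FFT + 14x38 WT); ``pp`` -> 333;
    ``imu`` -> 528.
    """
    if sensors not in ("both", "pp", "imu"):
        raise ValueError(f"unknown sensor set {sensors!r}")
    names: list[FeatureName] = []
    if sensors in ("both", "pp"):
        for side in SIDES:
            names += [FeatureName("TIME", ft, sig, side) for ft, sig in _TIME_PER_SIDE]
        names.append(FeatureName("TIME", "n_weight_shifts", "grf", "both"))
    for sig, side in fft_wt_signal_list(sensors):
        names += [FeatureName("FFT", ft, sig, side) for ft in FFT_FEATURE_TYPES]
    for sig, side in fft_wt_signal_list(sensors):
        names += [FeatureName("WT", ft, sig, side) for ft in WT_FEATURE_TYPES]
    assert len(set(map(str, names))) == len(names)
    return names


# ---------------------------------------------------------------------------
# plantar-pressure preprocessing


def preprocess_pressure(trial: GaitTrial, cfg: CopPreprocessConfig | None = None
                        ) -> dict[str, dict[str, np.ndarray]]:
    """Derive per-side GRF and COP position/velocity/acceleration series.

    A foot's GRF below ``grf_zero_fraction`` of the two-foot total is zeroed
    (the limb is in swing) and its COP sample marked invalid; invalid COP
    samples are filled by holding the last valid value (leading invalids are
    backfilled). Velocity is the first difference times ``fs``, acceleration
    the second difference times ``fs**2``, each padded by replicating the
    first defined value.
    """
    cfg = cfg or CopPreprocessConfig()
    fs = trial.fs
    total = trial.channels["grf_left"] + trial.channels["grf_right"]
    out: dict[str, dict[str, np.ndarray]] = {}
    for side in SIDES:
        grf = trial.channels[f"grf_{side}"].copy()
        swing = grf < cfg.grf_zero_fraction * total
        grf[swing] = 0.0
        valid = grf > 0
        if not valid.any():
            raise ValueError(f"no stance data on side {side!r}")
        idx = np.where(valid, np.arange(len(grf)), -1)
        np.maximum.accumulate(idx, out=idx)
        first_valid = np.argmax(valid)
        idx[idx < 0] = first_valid
        side_out = {"grf": grf}
        for axis in ("ap", "ml"):
            cop = trial.channels[f"cop_{axis}_{side}"][idx]
            vel = np.diff(cop) * fs
            vel = np.concatenate([vel[:1], vel])
            acc = np.diff(vel) * fs
            acc = np.concatenate([acc[:1], acc])
            side_out[f"cop_{axis}"] = cop
            side_out[f"cop_{axis}_vel"] = vel
            side_out[f"cop_{axis}_acc"] = acc
        out[side] = side_out
    return out


# ---------------------------------------------------------------------------
# per-window feature families


def _reversal_stats(x: np.ndarray, fs: float) -> tuple[float, float, float]:
    """COP path direction reversals: sign changes of the first difference,
    with zero differences inheriting the previous sign. Duration and length
    total the time and absolute displacement between consecutive reversals."""
    d = np.diff(x)
    s = np.sign(d)
    nz = s != 0
    if not nz.any():
        return 0.0, 0.0, 0.0
    idx = np.where(nz, np.arange(len(s)), -1)
    np.maximum.accumulate(idx, out=idx)
    filled = np.where(idx >= 0, s[np.maximum(idx, 0)], 0.0)
    active = filled != 0
    pts = np.where(active[1:] & active[:-1] & (filled[1:] != filled[:-1]))[0] + 1
    n_rev = float(len(pts))
    if len(pts) < 2:
        return n_rev, 0.0, 0.0
    duration = float((pts[-1] - pts[0]) / fs)
    length = float(np.abs(np.diff(x[pts])).sum())
    return n_rev, duration, length


def _deviation_stats(x: np.ndarray, fs: float, threshold: float
                     ) -> tuple[float, float, float]:
    """ML COP deviations: maximal runs of samples whose first difference
    exceeds ``threshold`` in magnitude."""
    d = np.diff(x)
    dev = np.abs(d) > threshold
    if not dev.any():
        return 0.0, 0.0, 0.0
    edges = np.diff(dev.astype(np.int8))
    n_runs = float((edges == 1).sum() + int(dev[0]))
    duration = float(dev.sum() / fs)
    length = float(np.abs(d[dev]).sum())
    return n_runs, duration, length


def _cv(x: np.ndarray) -> float:
    m = abs(float(np.mean(x)))
    if m < _EPS_MEAN:
        return 0.0
    return float(np.std(x, ddof=1)) / m


def _n_weight_shifts(grf_left: np.ndarray, grf_right: np.ndarray) -> float:
    """Count of changes in which foot carries the strict majority (>50%) of
    total GRF; samples where neither foot does are ignored."""
    maj = np.where(grf_left > grf_right, 1, np.where(grf_right > grf_left, -1, 0))
    maj = maj[(maj != 0) & (grf_left + grf_right > 0)]
    if len(maj) < 2:
        return 0.0
    return float((np.diff(maj) != 0).sum())


def time_features(side_windows: dict[str, dict[str, np.ndarray]],
                  fs: float, cfg: CopPreprocessConfig | None = None
                  ) -> dict[str, float]:
    """The 25 time-domain plantar-pressure features for one window.

    ``side_windows`` maps side -> signal name -> 1-D window array (the seven
    derived plantar-pressure signals from :func:`preprocess_pressure`).
    """
    cfg = cfg or CopPreprocessConfig()
    out: dict[str, float] = {}
    for side in SIDES:
        sig = side_windows[side]
        n, dur, length = _reversal_stats(sig["cop_ap"], fs)
        out[str(FeatureName("TIME", "n_reversals", "cop_ap", side))] = n
        out[str(FeatureName("TIME", "reversal_duration", "cop_ap", side))] = dur
        out[str(FeatureName("TIME", "reversal_length", "cop_ap", side))] = length
        n, dur, length = _deviation_stats(sig["cop_ml"], fs, cfg.deviation_threshold_mm)
        out[str(FeatureName("TIME", "n_deviations", "cop_ml", side))] = n
        out[str(FeatureName("TIME", "deviation_duration", "cop_ml", side))] = dur
        out[str(FeatureName("TIME", "deviation_length", "cop_ml", side))] = length
        for ft, key in (("cv_cop_ap", "cop_ap"), ("cv_cop_ml", "cop_ml"),
                        ("cv_cop_ap_vel", "cop_ap_vel"), ("cv_cop_ml_vel", "cop_ml_vel"),
                        ("cv_cop_ap_acc", "cop_ap_acc"), ("cv_cop_ml_acc", "cop_ml_acc")):
            out[str(FeatureName("TIME", ft, key, side))] = _cv(sig[key])
    out[str(FeatureName("TIME", "n_weight_shifts", "grf", "both"))] = _n_weight_shifts(
        side_windows["left"]["grf"], side_windows["right"]["grf"])
    return out


def fft_features(windows: np.ndarray, fs: float) -> dict[str, np.ndarray]:
    """The 8 FFT features; vectorised over rows of ``windows`` (n_windows, L).

    The amplitude spectrum is the untapered DFT magnitude over non-negative
    frequencies; the DC bin is excluded from every feature. Band power sums
    squared amplitudes over bins with centre frequency in [0.5, 3) Hz
    (locomotion) or [3, 8] Hz (freeze); the freeze index is their ratio.
    """
    windows = np.atleast_2d(np.asarray(windows, dtype=float))
    n = windows.shape[1]
    amp = np.abs(np.fft.rfft(windows, axis=1))[:, 1:]
    freqs = np.fft.rfftfreq(n, d=1.0 / fs)[1:]
    power = amp ** 2
    loco = (freqs >= LOCOMOTION_BAND[0]) & (freqs < LOCOMOTION_BAND[1])
    freeze = (freqs >= FREEZE_BAND[0]) & (freqs <= FREEZE_BAND[1])
    loco_p = power[:, loco].sum(axis=1)
    freeze_p = power[:, freeze].sum(axis=1)
    return {
        "total_power": power.sum(axis=1),
        "dominant_frequency": freqs[np.argmax(amp, axis=1)],
        "amp_max": amp.max(axis=1),
        "amp_min": amp.min(axis=1),
        "amp_mean": amp.mean(axis=1),
        "locomotion_power": loco_p,
        "freeze_power": freeze_p,
        "freeze_index": freeze_p / (loco_p + _EPS_POWER),
    }


def wt_features(windows: np.ndarray) -> dict[str, np.ndarray]:
    """The 14 single-level orthonormal Haar DWT features; vectorised over rows."""
    windows = np.atleast_2d(np.asarray(windows, dtype=float))
    if windows.shape[1] % 2:
        raise ValueError("window length must be even for the Haar DWT")
    ac, dc = pywt.dwt(windows, "haar", axis=1)
    out = {}
    for tag, coef in (("ac", ac), ("dc", dc)):
        energy = coef ** 2
        out[f"wt_{tag}_var"] = coef.var(axis=1)
        out[f"wt_{tag}_max"] = coef.max(axis=1)
        out[f"wt_{tag}_min"] = coef.min(axis=1)
        out[f"wt_{tag}_mean"] = coef.mean(axis=1)
        out[f"wt_{tag}_energy_max"] = energy.max(axis=1)
        out[f"wt_{tag}_energy_min"] = energy.min(axis=1)
        out[f"wt_{tag}_energy_mean"] = energy.mean(axis=1)
    return out


# ---------------------------------------------------------------------------
# matrix assembly

META_COLUMNS = ("participant_id", "trial_id", "start_sample", "label")


def extract_features(trials: list[GaitTrial], windows: list[LabeledWindow],
                     registry: list[FeatureName] | None = None,
                     cfg: CopPreprocessConfig | None = None) -> pd.DataFrame:
    """One row per window, columns = metadata + the registry, in order.

    Raises if a window references a trial that was not supplied, or if a
    registry entry needs a channel the trial lacks.
    """
    registry = registry if registry is not None else build_registry("both")
    cfg = cfg or CopPreprocessConfig()
    reg_strs = [str(f) for f in registry]
    need_time = any(f.category == "TIME" for f in registry)
    spectral_pairs = sorted(
        {(f.signal, f.side) for f in registry if f.category in ("FFT", "WT")})
    trial_map = {(t.participant_id, t.trial_id): t for t in trials}

    by_trial: dict[tuple[str, str], list[LabeledWindow]] = {}
    for w in windows:
        key = (w.participant_id, w.trial_id)
        if key not in trial_map:
            raise KeyError(f"window references unknown trial {key}")
        by_trial.setdefault(key, []).append(w)

    frames = []
    n_done = 0
    for key, trial_windows in by_trial.items():
        trial = trial_map[key]
        starts = np.array([w.start_sample for w in trial_windows])
        length = trial_windows[0].end_sample - trial_windows[0].start_sample

        derived = None
        if need_time or any(sig in PP_SIGNALS for sig, _ in spectral_pairs):
            derived = preprocess_pressure(trial, cfg)

        def signal_series(sig: str, side: str) -> np.ndarray:
            if sig in PP_SIGNALS:
                return derived[side][sig]
            chan = f"{sig}_{side}"
            if chan not in trial.channels:
                raise KeyError(f"trial {key} lacks channel {chan!r}")
            return trial.channels[chan]

        cols: dict[str, np.ndarray] = {}
        for sig, side in spectral_pairs:
            series = signal_series(sig, side)
            win = np.lib.stride_tricks.sliding_window_view(series, length)[starts]
            for ft, vals in fft_features(win, trial.fs).items():
                cols[str(FeatureName("FFT", ft, sig, side))] = vals
            for ft, vals in wt_features(win).items():
                cols[str(FeatureName("WT", ft, sig, side))] = vals

        if need_time:
            time_rows = []
            for w in trial_windows:
                sw = {side: {sig: derived[side][sig][w.start_sample:w.end_sample]
                             for sig in PP_SIGNALS}
                      for side in SIDES}
                time_rows.append(time_features(sw, trial.fs, cfg))
            for name in time_rows[0]:
                cols[name] = np.array([r[name] for r in time_rows])

        meta = pd.DataFrame({
            "participant_id": [w.participant_id for w in trial_windows],
            "trial_id": [w.trial_id for w in trial_windows],
            "start_sample": starts,
            "label": [w.label.value for w in trial_windows],
        })
        frames.append(pd.concat(
            [meta, pd.DataFrame({name: cols[name] for name in reg_strs})], axis=1))
        n_done += len(trial_windows)
        if n_done // 1000 > (n_done - len(trial_windows)) // 1000:
            logger.info("extracted features for %d windows", n_done)

    if not frames:
        return pd.DataFrame(columns=list(META_COLUMNS) + reg_strs)
    out = pd.concat(frames, ignore_index=True)
    assert np.isfinite(out[reg_strs].to_numpy()).all(), "non-finite feature values"
    return out
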