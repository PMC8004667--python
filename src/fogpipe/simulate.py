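"""Synthetic multichannel gait data with freezing-of-gait (FOG) episodes.

Generates per-trial walking records that carry the statistical structure a
window-based FOG classifier relies on: periodic locomotion-band (0.5-3 Hz)
gait in every channel, a freeze-band (3-8 Hz) trembling component on the
shank IMUs and the centre of pressure (COP) during episodes, arrest of
left/right weight transfer during episodes, and a linear pre-freeze ramp
between the two regimes.

The signal model is deliberately simple — additive sinusoids plus Gaussian
noise — because every downstream feature depends only on band structure and
COP geometry, not on waveform realism.
"""

from __future__ import annotations

import csv
import json
import logging
import zlib
from dataclasses import dataclass, field, asdict
from pathlib import Path

import numpy as np

logger = logging.getLogger(__name__)

SIDES = ("left", "right")
IMU_LOCATIONS = ("ankle", "thigh")
IMU_AXES = ("x", "y", "z")

#: canonical raw-channel names, 30 in total:
#: per side GRF + COP (AP/ML), per ankle/thigh x side a 3-axis accelerometer
#: and a 3-axis gyroscope.
CHANNEL_NAMES: tuple[str, ...] = tuple(
    [f"{base}_{side}" for side in SIDES for base in ("grf", "cop_ap", "cop_ml")]
    + [
        f"{kind}_{ax}_{loc}_{side}"
        for side in SIDES
        for loc in IMU_LOCATIONS
        for kind in ("acc", "gyro")
        for ax in IMU_AXES
    ]
)

# per-channel base amplitudes: GRF in N (half body weight swing), COP in mm,
# accelerations in m/s^2, angular rates in deg/s
_CHANNEL_SCALE = {"grf": 350.0, "cop_ap": 80.0, "cop_ml": 15.0}
_IMU_SCALE = {("acc", "ankle"): 2.0, ("acc", "thigh"): 1.0,
              ("gyro", "ankle"): 100.0, ("gyro", "thigh"): 60.0}
_BODY_WEIGHT_N = 700.0
# trembling amplitude during FOG, as a fraction of the channel scale, before
# multiplication by freeze_band_gain; sized so freezing shifts power into the
# freeze band rather than simply removing it
_TREMBLE_FRACTION = 0.6
# log-sd of the per-participant gait / tremble amplitude factors, and the
# depth of the slow within-trial amplitude modulation (stride-to-stride and
# between-person variability keep absolute signal power from being a trivial
# class separator, as in real gait)
_AMP_LOG_SD = 0.35
_TREMBLE_LOG_SD = 0.3
_SLOW_MOD_DEPTH = 0.35
# per-participant anthropometrics: body weight and COP excursion (foot size)
_WEIGHT_LOG_SD = 0.15
_COP_SCALE_LOG_SD = 0.2


@dataclass(frozen=True)
class FogEpisode:
    """One freezing episode, from the failed step to the first effective step."""

    onset_s: float
    end_s: float

    def __post_init__(self) -> None:
        if not 0.0 <= self.onset_s < self.end_s:
            raise ValueError(
                f"invalid episode interval [{self.onset_s}, {self.end_s}]"
            )


@dataclass
class SimConfig:
    """Cohort-level simulation parameters.

    Defaults mirror the study conditions emulated here: 11 participants of
    whom 7 freeze, 100 Hz sampling, ~1 step/s per leg, and a 2 s pre-freeze
    segment ahead of each episode.
    """

    seed: int = 0
    n_participants: int = 11
    freezer_fraction: float = 7.0 / 11.0
    trial_duration_s: float = 60.0
    n_trials_per_participant: int = 2
    fs: float = 100.0
    step_freq_hz: float = 1.0
    fog_rate_per_min: float = 1.5
    fog_duration_s_range: tuple[float, float] = (3.0, 8.0)
    prefog_duration_s: float = 2.0
    freeze_band_gain: float = 1.0
    noise_sd: float = 0.05

    def __post_init__(self) -> None:
        if self.fs <= 0:
            raise ValueError("fs must be positive")
        lo, hi = self.fog_duration_s_range
        if not 0 < lo <= hi:
            raise ValueError("fog_duration_s_range must satisfy 0 < min <= max")
        if self.prefog_duration_s <= 0:
            raise ValueError("prefog_duration_s must be positive")
        if not 0.0 <= self.freezer_fraction <= 1.0:
            raise ValueError("freezer_fraction must lie in [0, 1]")
        if self.n_participants < 1 or self.n_trials_per_participant < 1:
            raise ValueError("participant and trial counts must be >= 1")
        if self.trial_duration_s <= 0:
            raise ValueError("trial_duration_s must be positive")


@dataclass
class GaitTrial:
    """One walking trial: 30 raw channels at ``fs`` Hz plus FOG annotations."""

    participant_id: str
    trial_id: str
    fs: float
    channels: dict[str, np.ndarray]
    episodes: list[FogEpisode]
    freezer: bool

    def __post_init__(self) -> None:
        if self.channels:
            lengths = {len(v) for v in self.channels.values()}
            if len(lengths) > 1:
                raise ValueError("all channel series must have equal length")
        if not self.freezer and self.episodes:
            raise ValueError("nonfreezer trials must have no episodes")
        eps = sorted(self.episodes, key=lambda e: e.onset_s)
        for a, b in zip(eps, eps[1:]):
            if b.onset_s < a.end_s:
                raise ValueError("episodes must be pairwise non-overlapping")
        self.episodes = eps

    @property
    def n_samples(self) -> int:
        return len(next(iter(self.channels.values()))) if self.channels else 0

    @property
    def duration_s(self) -> float:
        return self.n_samples / self.fs


def _stage_rng(seed: int, *tags) -> np.random.Generator:
    """Deterministic per-stage generator derived from the global seed."""
    h = zlib.crc32("|".join(str(t) for t in tags).encode()) % (2**31)
    return np.random.default_rng(np.random.SeedSequence([seed % (2**31), h]))


def place_episodes(config: SimConfig, rng: np.random.Generator) -> list[FogEpisode]:
    """Draw FOG episodes for one trial via a thinned Poisson process.

    Candidate onsets are uniform over the trial; a candidate is kept only if
    a full pre-freeze margin fits before it, it does not collide with the
    previous accepted episode (plus margin), and it ends inside the trial.
    """
    dur = config.trial_duration_s
    margin = config.prefog_duration_s
    n_candidates = rng.poisson(config.fog_rate_per_min * dur / 60.0)
    onsets = np.sort(rng.uniform(0.0, dur, size=n_candidates))
    lo, hi = config.fog_duration_s_range
    episodes: list[FogEpisode] = []
    last_end = 0.0
    for onset in onsets:
        length = rng.uniform(lo, hi)
        if onset < margin or onset < last_end + margin or onset + length > dur:
            logger.debug("episode candidate at %.2fs omitted (does not fit)", onset)
            continue
        episodes.append(FogEpisode(round(float(onset), 4), round(float(onset + length), 4)))
        last_end = onset + length
    if n_candidates and not episodes:
        logger.info("trial too short/crowded: all %d episode candidates omitted",
                    n_candidates)
    return episodes


def _freeze_intensity(n: int, fs: float, episodes: list[FogEpisode],
                      prefog_s: float) -> np.ndarray:
    """Per-sample freeze intensity: 0 in normal gait, linear 0->1 ramp over the
    pre-freeze segment, 1 inside the episode, 0 immediately after."""
    t = np.arange(n) / fs
    f = np.zeros(n)
    for ep in episodes:
        ramp = (t >= ep.onset_s - prefog_s) & (t < ep.onset_s)
        f[ramp] = (t[ramp] - (ep.onset_s - prefog_s)) / prefog_s
        f[(t >= ep.onset_s) & (t <= ep.end_s)] = 1.0
    return f


def synthesize_channels(trial_skeleton: GaitTrial, config: SimConfig,
                        rng: np.random.Generator | None = None) -> GaitTrial:
    """Fill in the 30 raw channels of a trial whose episodes are already placed.

    Outside episodes GRF alternates between feet at ``step_freq_hz`` with
    double-support overlap and the AP COP sweeps heel to toe each stance;
    during an episode weight oscillates without full transfer, AP COP
    excursion shrinks, and a freeze-band component scaled by
    ``freeze_band_gain`` is superimposed on shank IMU and COP channels.
    """
    if rng is None:
        rng = _stage_rng(config.seed, "channels", trial_skeleton.participant_id,
                         trial_skeleton.trial_id)
    fs = config.fs
    n = int(round(config.trial_duration_s * fs))
    t = np.arange(n) / fs
    f = _freeze_intensity(n, fs, trial_skeleton.episodes, config.prefog_duration_s)
    gain = max(float(config.freeze_band_gain), 0.0)
    noise_sd = max(float(config.noise_sd), 0.0)
    if gain != config.freeze_band_gain or noise_sd != config.noise_sd:
        logger.warning("negative gain/noise parameters clamped to 0")

    # stepping phase (drives weight transfer) halts while frozen; the limbs
    # keep attempting steps, so limb oscillation phase advances throughout
    phase0 = rng.uniform(0.0, 1.0)
    phase = phase0 + config.step_freq_hz * np.cumsum(1.0 - f) / fs
    phase_free = phase0 + config.step_freq_hz * t

    # amplitude variability: a per-participant gait/tremble magnitude and a
    # slow within-trial modulation of gait vigour
    p_rng = _stage_rng(config.seed, "participant-amp", trial_skeleton.participant_id)
    amp_loco = float(np.exp(_AMP_LOG_SD * p_rng.standard_normal()))
    amp_trem = float(np.exp(_TREMBLE_LOG_SD * p_rng.standard_normal()))
    body_weight = _BODY_WEIGHT_N * float(np.exp(_WEIGHT_LOG_SD * p_rng.standard_normal()))
    cop_factor = float(np.exp(_COP_SCALE_LOG_SD * p_rng.standard_normal()))
    f_slow = rng.uniform(0.05, 0.12)
    mod = amp_loco * (1.0 + _SLOW_MOD_DEPTH
                      * np.sin(2 * np.pi * f_slow * t + rng.uniform(0, 2 * np.pi)))
    # freeze-band trembling: two incommensurate tones inside 3-8 Hz
    trem_freqs = rng.uniform(4.0, 7.0, size=2)
    trem_phases = rng.uniform(0.0, 2 * np.pi, size=2)
    tremble = np.zeros(n)
    for fr, ph in zip(trem_freqs, trem_phases):
        tremble += np.sin(2 * np.pi * fr * t + ph)
    tremble *= f / len(trem_freqs)

    channels: dict[str, np.ndarray] = {}
    alt = np.tanh(3.0 * np.sin(2 * np.pi * phase))  # smoothed square wave
    # during a freeze full left/right transfer stops but weight still sways
    # at roughly the stepping rate, with a freeze-band wobble on top
    sway = np.sin(2 * np.pi * phase_free)
    share_left = (0.5 + mod * (0.45 * (1.0 - f) * alt + 0.2 * f * sway)
                  + 0.12 * gain * amp_trem * tremble)
    share_left = np.clip(share_left, 0.0, 1.0)
    total = body_weight * (1.0 + 0.05 * (1.0 - f) * np.sin(4 * np.pi * phase))
    for side, share in (("left", share_left), ("right", 1.0 - share_left)):
        grf = total * share + noise_sd * _CHANNEL_SCALE["grf"] * rng.standard_normal(n)
        channels[f"grf_{side}"] = np.maximum(grf, 0.0)

    for i, side in enumerate(SIDES):
        ph_free_side = phase_free + 0.5 * i
        for axis, scale_key in (("ap", "cop_ap"), ("ml", "cop_ml")):
            # heel->toe progression shrinks to a residual sway during FOG
            # (attempted steps), with the freeze-band tremble superimposed
            scale = _CHANNEL_SCALE[scale_key] * cop_factor
            base = scale * mod * (1.0 - 0.8 * f) * np.sin(
                2 * np.pi * ph_free_side + (0.7 if axis == "ml" else 0.0))
            trem = gain * amp_trem * _TREMBLE_FRACTION * scale * tremble
            noise = noise_sd * scale * rng.standard_normal(n)
            channels[f"cop_{axis}_{side}"] = base + trem + noise
        for loc in IMU_LOCATIONS:
            for kind in ("acc", "gyro"):
                scale = _IMU_SCALE[(kind, loc)]
                for j, ax in enumerate(IMU_AXES):
                    harmonic = 1 + (j % 2)  # 1 or 2 Hz at the default cadence
                    ph_ch = rng.uniform(0.0, 2 * np.pi)
                    # locomotion-band limb oscillation persists during FOG
                    # (the freeze arrests weight transfer, not limb motion),
                    # only mildly attenuated
                    base = scale * mod * (1.0 - 0.3 * f) * np.sin(
                        2 * np.pi * harmonic * ph_free_side + ph_ch)
                    trem = (gain * amp_trem * _TREMBLE_FRACTION * scale * tremble
                            if loc == "ankle" else 0.0)
                    noise = noise_sd * scale * rng.standard_normal(n)
                    channels[f"{kind}_{ax}_{loc}_{side}"] = base + trem + noise

    return GaitTrial(
        participant_id=trial_skeleton.participant_id,
        trial_id=trial_skeleton.trial_id,
        fs=fs,
        channels=channels,
        episodes=trial_skeleton.episodes,
        freezer=trial_skeleton.freezer,
    )


def simulate_cohort(config: SimConfig) -> list[GaitTrial]:
    """Generate the full cohort: deterministic given ``config.seed``.

    The first ``round(freezer_fraction * n_participants)`` participants (after
    a seeded shuffle of identifiers) are freezers and receive episodes from
    :func:`place_episodes`; the rest receive none.
    """
    n_freezers = int(round(config.freezer_fraction * config.n_participants))
    ids = [f"P{i + 1:02d}" for i in range(config.n_participants)]
    order = _stage_rng(config.seed, "freezer-assignment").permutation(config.n_participants)
    freezer_ids = {ids[i] for i in order[:n_freezers]}

    trials: list[GaitTrial] = []
    for pid in ids:
        for k in range(config.n_trials_per_participant):
            tid = f"T{k + 1:02d}"
            is_freezer = pid in freezer_ids
            episodes = (
                place_episodes(config, _stage_rng(config.seed, "episodes", pid, tid))
                if is_freezer else []
            )
            skeleton = GaitTrial(pid, tid, config.fs, {}, episodes, is_freezer)
            trials.append(synthesize_channels(skeleton, config))
    return trials


# ---------------------------------------------------------------------------
# disk I/O: one CSV per trial (columns = channels) + one JSON sidecar


def save_trial(trial: GaitTrial, out_dir: str | Path) -> tuple[Path, Path]:
    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    stem = f"{trial.participant_id}_{trial.trial_id}"
    csv_path = out_dir / f"{stem}.csv"
    names = [c for c in CHANNEL_NAMES if c in trial.channels]
    with open(csv_path, "w", newline="") as fh:
        writer = csv.writer(fh)
        writer.writerow(names)
        writer.writerows(np.column_stack([trial.channels[c] for c in names]).tolist())
    meta = {
        "participant_id": trial.participant_id,
        "trial_id": trial.trial_id,
        "fs": trial.fs,
        "freezer": trial.freezer,
        "episodes": [{"onset_s": e.onset_s, "end_s": e.end_s} for e in trial.episodes],
    }
    json_path = out_dir / f"{stem}.json"
    json_path.write_text(json.dumps(meta, indent=1))
    return csv_path, json_path


def load_trial(csv_path: str | Path) -> GaitTrial:
    csv_path = Path(csv_path)
    meta = json.loads(csv_path.with_suffix(".json").read_text())
    data = np.genfromtxt(csv_path, delimiter=",", names=True)
    channels = {name: np.asarray(data[name], dtype=float) for name in data.dtype.names}
    return GaitTrial(
        participant_id=meta["participant_id"],
        trial_id=meta["trial_id"],
        fs=float(meta["fs"]),
        channels=channels,
        episodes=[FogEpisode(e["onset_s"], e["end_s"]) for e in meta["episodes"]],
        freezer=bool(meta["freezer"]),
    )


def save_cohort(trials: list[GaitTrial], out_dir: str | Path) -> list[Path]:
    return [save_trial(t, out_dir)[0] for t in trials]


def load_cohort(data_dir: str | Path) -> list[GaitTrial]:
    return [load_trial(p) for p in sorted(Path(data_dir).glob("*.csv"))]
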