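"""Sliding-window segmentation and four-way FOG labeling.

Each trial is cut into 1 s windows advanced by 0.2 s. A window is labeled
FOG when it lies entirely inside an episode, PRE_FOG when it lies entirely
inside the 2 s segment before an onset, PRE_FOG_TRANSITION when it straddles
the onset while staying inside pre-freeze + episode, and NO_FOG otherwise —
including windows that also touch ordinary walking before the pre-freeze
segment or after the episode end.

Convention: a window occupies the closed time interval
``[start_s, start_s + length_s]`` and episodes the closed ``[onset, end]``;
the pre-freeze segment is the half-open ``[onset - prefog_s, onset)``. With
onsets on the 0.2 s grid this reproduces the canonical episode geometry of
5 PRE_FOG and 5 PRE_FOG_TRANSITION windows per episode.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from enum import Enum

from .simulate import FogEpisode, GaitTrial

logger = logging.getLogger(__name__)

_EPS = 1e-9


class Label(str, Enum):
    NO_FOG = "NO_FOG"
    PRE_FOG = "PRE_FOG"
    PRE_FOG_TRANSITION = "PRE_FOG_TRANSITION"
    FOG = "FOG"


#: the composite training target: every window carrying pre-freeze or freeze data
TOTAL_FOG_LABELS = frozenset({Label.PRE_FOG, Label.PRE_FOG_TRANSITION, Label.FOG})


@dataclass(frozen=True)
class WindowSpec:
    length_s: float = 1.0
    hop_s: float = 0.2
    prefog_s: float = 2.0

    def __post_init__(self) -> None:
        if not 0 < self.hop_s <= self.length_s:
            raise ValueError("require 0 < hop_s <= length_s")
        if self.prefog_s < self.length_s:
            raise ValueError("prefog_s must be >= length_s")


@dataclass(frozen=True)
class LabeledWindow:
    participant_id: str
    trial_id: str
    start_sample: int
    end_sample: int
    label: Label


def label_window(start_s: float, end_s: float, episodes: list[FogEpisode],
                 spec: WindowSpec) -> Label:
    """Label one window against a list of episodes.

    Zero-length (degenerate) episodes contribute nothing. A window qualifying
    as PRE_FOG for one episode is demoted to NO_FOG if it intersects the
    interior of another episode (it then contains freeze data from that one).
    """
    eps = [e for e in episodes if e.end_s - e.onset_s > _EPS]
    for e in eps:
        if start_s >= e.onset_s - _EPS and end_s <= e.end_s + _EPS:
            return Label.FOG
    for e in eps:
        pre_start = e.onset_s - spec.prefog_s
        if (start_s >= pre_start - _EPS and end_s <= e.end_s + _EPS
                and start_s < e.onset_s - _EPS and end_s >= e.onset_s - _EPS):
            return Label.PRE_FOG_TRANSITION
    for e in eps:
        pre_start = e.onset_s - spec.prefog_s
        if start_s >= pre_start - _EPS and end_s < e.onset_s - _EPS:
            if any(start_s < o.end_s - _EPS and end_s > o.onset_s + _EPS
                   for o in eps if o is not e):
                continue
            return Label.PRE_FOG
    return Label.NO_FOG


def generate_windows(trial: GaitTrial, spec: WindowSpec | None = None) -> list[LabeledWindow]:
    """Windows start at samples 0, H, 2H, ...; count = floor((N - L) / H) + 1."""
    spec = spec or WindowSpec()
    length = int(round(spec.length_s * trial.fs))
    hop = int(round(spec.hop_s * trial.fs))
    n = trial.n_samples
    if n < length:
        logger.warning("trial %s/%s shorter than one window; no windows emitted",
                       trial.participant_id, trial.trial_id)
        return []
    out = []
    for start in range(0, n - length + 1, hop):
        lab = label_window(start / trial.fs, (start + length) / trial.fs,
                           trial.episodes, spec)
        out.append(LabeledWindow(trial.participant_id, trial.trial_id,
                                 start, start + length, lab))
    return out
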