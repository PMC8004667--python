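import json

import numpy as np
import pytest

import fogpipe as fp


@pytest.fixture(scope="session")
def small_cohort():
    """Tiny 4-participant cohort (2 freezers) for fast structural tests."""
    cfg = fp.SimConfig(seed=7, n_participants=4, freezer_fraction=0.5,
                       trial_duration_s=30.0, n_trials_per_participant=1,
                       fog_rate_per_min=4.0)
    return cfg, fp.simulate_cohort(cfg)


@pytest.fixture(scope="session")
def study_cohort():
    """The default study-scale cohort: 11 participants, 7 freezers."""
    cfg = fp.SimConfig(seed=1)
    trials = fp.simulate_cohort(cfg)
    return cfg, trials


@pytest.fixture(scope="session")
def study_features(study_cohort):
    """Full 861-column feature matrix for the study-scale cohort."""
    cfg, trials = study_cohort
    windows = [w for t in trials for w in fp.generate_windows(t)]
    feats = fp.extract_features(trials, windows, fp.build_registry("both"))
    freezer_map = {t.participant_id: t.freezer for t in trials}
    return feats, freezer_map


@pytest.fixture(scope="session")
def study_lofo_report(study_features):
    """LOFO evaluation of the Relief-F / top-10 / 5-splits configuration."""
    feats, freezer_map = study_features
    return fp.run_lofo(feats, freezer_map, method="relieff", top_k=10,
                       max_splits=5, seed=0)


@pytest.fixture()
def rng():
    return np.random.default_rng(42)
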