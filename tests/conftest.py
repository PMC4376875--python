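"""Shared fixtures: small paradigm configs and session-scoped simulated runs.

Simulated EEG is expensive relative to the rest of the suite, so the runs
that several tests analyse (the strong-responder and the silent-subject
hybrid evaluations) are built once per session. Problem sizes are kept at
desk scale: 3-4 runs per evaluation, 12 trials per run as in the paradigm.
"""

import numpy as np
import pandas as pd
import pytest

from hybridbci import (
    ParadigmConfig,
    SubjectProfile,
    make_schedule,
    simulate_recording,
)
from hybridbci.evaluation import p300_path, ssvep_path
from hybridbci.montage import ALL_CHANNELS
from hybridbci.paradigm import EventLog
from hybridbci.simulate import Recording


@pytest.fixture(scope="session")
def small_config():
    """Single-panel config with 2 repetitions and 6 trials for cheap unit tests."""
    return ParadigmConfig.experiment1(
        flicker_freq=12.0, n_repetitions=2, n_trials_per_run=6, sampling_rate=512.0
    )


@pytest.fixture(scope="session")
def strong_profile():
    return SubjectProfile.strong()


def simulate_runs(config, profile, n_runs, seed0):
    return [
        simulate_recording(make_schedule(config, seed0 + 2 * k), profile, config, seed0 + 2 * k + 1)
        for k in range(n_runs)
    ]


@pytest.fixture(scope="session")
def exp3_strong_runs(strong_profile):
    """Four two-panel runs from the strong-responder profile (train 2, test 2)."""
    config = ParadigmConfig.experiment3()
    return config, simulate_runs(config, strong_profile, 4, seed0=100)


@pytest.fixture(scope="session")
def exp3_silent_runs():
    """Four two-panel runs with no evoked activity at all (chance-level data)."""
    config = ParadigmConfig.experiment3()
    return config, simulate_runs(config, SubjectProfile.silent(), 4, seed0=300)


@pytest.fixture(scope="session")
def exp3_strong_epochs(exp3_strong_runs):
    _, runs = exp3_strong_runs
    return [p300_path(r, run_id=i) for i, r in enumerate(runs)]


@pytest.fixture(scope="session")
def exp3_silent_epochs(exp3_silent_runs):
    _, runs = exp3_silent_runs
    return [p300_path(r, run_id=i) for i, r in enumerate(runs)]


@pytest.fixture(scope="session")
def exp3_strong_ssvep(exp3_strong_runs):
    _, runs = exp3_strong_runs
    return [ssvep_path(r) for r in runs[2:]]


@pytest.fixture(scope="session")
def exp3_silent_ssvep(exp3_silent_runs):
    _, runs = exp3_silent_runs
    return [ssvep_path(r) for r in runs[2:]]


def toy_recording(n_channels=3, n_samples=2048, fs=256.0, flash_onsets=(1.0, 3.0, 5.0),
                  target_icons=(0,), data=None, labels=None):
    """Tiny hand-built recording with one single-icon-per-flash event log.

    Each flash is its own repetition of icon ``i % n_icons`` on panel 0; the
    cued icon of the single trial is ``target_icons[0]``.
    """
    if labels is None:
        labels = [f"ch{i}" for i in range(n_channels)]
    if data is None:
        data = np.zeros((n_channels, n_samples))
    n_icons = max(2, max(target_icons) + 1)
    flashes = pd.DataFrame(
        {
            "onset": flash_onsets,
            "duration": [0.25] * len(flash_onsets),
            "icon": [i % n_icons for i in range(len(flash_onsets))],
            "panel": 0,
            "repetition": [i // n_icons + 1 for i in range(len(flash_onsets))],
            "trial": 0,
        }
    )
    trials = pd.DataFrame(
        {
            "trial": [0],
            "target_icon": [target_icons[0]],
            "target_panel": [0],
            "cue_onset": [0.0],
            "flicker_onset": [0.5],
            "oddball_onset": [1.0],
            "trial_end": [n_samples / fs],
        }
    )
    events = EventLog(trials=trials, flashes=flashes, config=None)
    return Recording(data=data, channel_labels=labels, sampling_rate=fs, events=events)


@pytest.fixture
def rng():
    return np.random.default_rng(12345)


@pytest.fixture(scope="session")
def exp2_power_table(strong_profile):
    """Harmonic-power table over all 4 frequencies x {pure, hybrid}, one subject."""
    from hybridbci import run_experiment2

    return run_experiment2(strong_profile, seed=500)


def hybrid_evaluation(runs, seed=0, n_r_values=range(1, 11)):
    """Train-on-2 hybrid evaluation over a list of two-panel recordings."""
    from hybridbci import build_detection_table, crossvalidate_runs, detect_run_ssvep
    from hybridbci.evaluation import p300_path as _p300_path
    from hybridbci.evaluation import ssvep_path as _ssvep_path

    epoch_runs = [_p300_path(r, run_id=i) for i, r in enumerate(runs)]
    p300_rows = crossvalidate_runs(epoch_runs, "train-2-test-6", seed=seed, n_r_values=n_r_values)
    ssvep_rows = pd.concat(
        [
            detect_run_ssvep(_ssvep_path(r), n_r_values=n_r_values, run_label=k)
            for k, r in enumerate(runs[2:], start=2)
        ],
        ignore_index=True,
    )
    return build_detection_table(p300_rows, ssvep_rows)


@pytest.fixture(scope="session")
def exp3_strong_table(exp3_strong_runs):
    _, runs = exp3_strong_runs
    return hybrid_evaluation(runs, seed=7)


@pytest.fixture(scope="session")
def exp3_silent_table(exp3_silent_runs):
    _, runs = exp3_silent_runs
    return hybrid_evaluation(runs, seed=8)
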