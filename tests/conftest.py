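import numpy as np
import pytest

from dynfnc import SynthConfig, generate_cohort
from dynfnc.dfnc import sliding_window_fnc
from dynfnc.networks import NetworkPartition, extract_network_timecourses


@pytest.fixture(scope="session")
def three_state_cohort():
    """Well-separated 3-state cohort: 20 subjects, 200 timepoints."""
    cfg = SynthConfig(
        n_subjects_per_group={"HC": 10, "TLE": 10},
        n_roi_gm=60,
        n_roi_wm=40,
        k1_true=6,
        k2_true=4,
        ks_true=3,
        n_timepoints=200,
        window_length_tr=20,
        dwell_mean_windows=60,
        noise_sd=0.5,
        seed=11,
    )
    cohort, truth = generate_cohort(cfg)
    return cfg, cohort, truth


@pytest.fixture(scope="session")
def three_state_windows(three_state_cohort):
    """Windowed FNC of the 3-state cohort using the planted partition."""
    cfg, cohort, truth = three_state_cohort
    gm = NetworkPartition("GM", cfg.k1_true, truth.roi_to_network["GM"], 0.0)
    wm = NetworkPartition("WM", cfg.k2_true, truth.roi_to_network["WM"], 0.0)
    tcs, names = extract_network_timecourses(cohort, gm, wm)
    windowed = [
        sliding_window_fnc(tcs[i], cfg.window_length_tr, cfg.step_tr, subject=cohort.subjects[i])
        for i in range(cohort.n_subjects)
    ]
    return windowed, names


@pytest.fixture()
def rng():
    return np.random.default_rng(1234)
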