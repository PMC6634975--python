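"""Shared fixtures: small synthetic sessions generated at test time."""

import numpy as np
import pytest

from wmpop import core_data as cd
from wmpop import synthetic as syn


@pytest.fixture(scope="session")
def dnms_cohort():
    """Four-subject interleaved-laser DNMS cohort, 120 trials each."""
    spec = syn.BehaviorGenSpec(n_subjects=4, n_trials_per_subject=120)
    design = syn.TrialDesign(delays_s=(8.0,), laser_scheme="interleaved_trial")
    return syn.simulate_behavior_cohort(spec, design, seed=101)


@pytest.fixture(scope="session")
def small_session():
    """Single-subject session with 8 units, half sample-selective."""
    spec = syn.BehaviorGenSpec(n_subjects=1, n_trials_per_subject=80)
    design = syn.TrialDesign(delays_s=(8.0,))
    trials = syn.simulate_behavior_cohort(spec, design, seed=202)
    neurons = syn.make_population(8, 0.5, seed=203)
    spikes = syn.simulate_session(neurons, trials, seed=204)
    return trials, spikes, neurons


@pytest.fixture(scope="session")
def binned_small(small_session):
    trials, spikes, _ = small_session
    return cd.bin_spikes(spikes, trials, 0.2, 0.2, (-1.0, 9.0)), trials


def make_binned(rates: np.ndarray, bin_width: float = 0.2,
                window_start: float = -1.0) -> cd.BinnedRateMatrix:
    """Wrap a (units x trials x bins) array in a BinnedRateMatrix."""
    n_units, n_trials, n_bins = rates.shape
    return cd.BinnedRateMatrix(
        rates=np.asarray(rates, dtype=float), bin_width_s=bin_width,
        step_s=bin_width,
        window=(window_start, window_start + n_bins * bin_width),
        unit_ids=[f"u{i}" for i in range(n_units)],
        trial_ids=list(range(1, n_trials + 1)))
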