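"""Shared fixtures: ground-truth model, pulse library, synthetic cohorts.

Everything is generated programmatically at session scope; the heavy pieces
(steady states, noiseless training targets, small single-cell cohorts) are
computed once and shared.
"""

import numpy as np
import pytest

from nfkbdyn.calibrate import ObjectiveSpec
from nfkbdyn.features import fit_gaussian_sum
from nfkbdyn.model import run_to_steady_state, simulate_response
from nfkbdyn.params import default_parameters
from nfkbdyn.synthetic import generate_cohort, make_pulse_condition_library
from nfkbdyn.trajectories import NFkBTrajectory

TRAIN_CONDITIONS = ["control", "1x6-like", "4x1.5-like", "1x30-like"]
EP_CONDITIONS = ["1x6-like", "1x15-like", "4x1.5-like"]


@pytest.fixture(scope="session")
def truth():
    """Ground-truth chromatin-model parameter set (package defaults)."""
    return default_parameters("d2fc2")


@pytest.fixture(scope="session")
def library():
    return make_pulse_condition_library()


@pytest.fixture(scope="session")
def gaussian_fits(library):
    return {name: fit_gaussian_sum(ci) for name, ci in library.items()}


@pytest.fixture(scope="session")
def steady_truth(truth):
    return run_to_steady_state("d2fc2", truth)


@pytest.fixture(scope="session")
def truth_sims(truth, library, gaussian_fits, steady_truth):
    """Noiseless condition-average simulations from the ground truth."""
    out = {}
    for name, ci in library.items():
        out[name] = simulate_response("d2fc2", truth, gaussian_fits[name],
                                      steady_state=steady_truth, times_min=ci.times)
    return out


@pytest.fixture(scope="session")
def training_spec(library, gaussian_fits, truth_sims):
    """Noiseless 4-condition training set generated from the ground truth."""
    training = {}
    for cond in TRAIN_CONDITIONS:
        target = NFkBTrajectory(library[cond].times, truth_sims[cond].fold_change,
                                condition=cond)
        training[cond] = (gaussian_fits[cond], target)
    return ObjectiveSpec(training)


@pytest.fixture(scope="session")
def ep_cohort(truth, library):
    """Small single-cell cohort over the emergent-property conditions."""
    return generate_cohort(truth, [library[c] for c in EP_CONDITIONS],
                           n_cells_per_condition=8, ci_jitter=0.1,
                           noise_sd=0.02, seed=3)


@pytest.fixture(scope="session")
def prediction_cohort(truth, library):
    """Noisy cohort for single-cell prediction benchmarking.

    Includes a 20% extrinsic-noise subpopulation whose responses are not
    predictable from their CI inputs, giving the elbow classification a
    genuine low-quality tail to calibrate against.
    """
    return generate_cohort(truth, [library[c] for c in ("1x6-like", "4x1.5-like")],
                           n_cells_per_condition=10, ci_jitter=0.12,
                           noise_sd=0.05, seed=17, extrinsic_fraction=0.2)


@pytest.fixture()
def rng():
    return np.random.default_rng(12345)
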