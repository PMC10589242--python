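import numpy as np
import pytest

from graspsupp import (
    GraspPolicy,
    ObjectModel,
    ObserverModel,
    build_intensity_grid,
    simulate_trajectory,
)
from graspsupp.design import TrialSpec


@pytest.fixture(scope="session")
def grid():
    return build_intensity_grid()


@pytest.fixture
def noise_free_policy():
    return GraspPolicy(separation_amplitude=1.0, rule="predictive", kinematic_noise_sd=0.0)


@pytest.fixture
def quiet_object():
    return ObjectModel(roll_noise_sd_deg=0.0)


@pytest.fixture
def default_observer():
    return ObserverModel()


def make_grasp_spec(trial_id=10, md="L", position="left", intensity=28.35, part="mixed"):
    return TrialSpec(
        trial_id=trial_id,
        block="grasping",
        mass_distribution=md,
        object_position=position,
        intensity_um=intensity,
        part=part,
    )


@pytest.fixture
def clean_trial(noise_free_policy, quiet_object):
    """One noise-free synthetic grasping trial with stored ground truth."""
    return simulate_trajectory(
        make_grasp_spec(md="L"), prev_md="R", policy=noise_free_policy, obj=quiet_object, seed=3
    )


def binomial_tables(rng, observer, condition, levels, reps, n_catch):
    """Simulated yes/no counts for one condition at the given per-level counts."""
    from graspsupp import DetectionTable

    x = np.concatenate([[0.0], np.asarray(levels, dtype=float)])
    n = np.array([n_catch] + [reps] * len(levels))
    p = np.array([observer.p_yes(xi, condition) for xi in x])
    k = rng.binomial(n, p)
    return DetectionTable(condition, x, k, n)
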