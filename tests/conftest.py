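import numpy as np
import pytest

from braindyn.io import concatenate, standardize
from braindyn.simulate import SimulationConfig, simulate_cohort


def build_cohort(config: SimulationConfig):
    """Simulate, standardize and concatenate a cohort."""
    manifest, series, truth = simulate_cohort(config)
    dataset = concatenate([standardize(ts) for ts in series], manifest)
    return manifest, series, dataset, truth


def truth_state_means(dataset, truth, manifest, n_states):
    """Ground-truth state means in the standardized analysis space."""
    z = np.concatenate([truth.paths[sid] for sid in manifest.subject_ids])
    return np.vstack([dataset.data[z == k].mean(axis=0) for k in range(n_states)])


@pytest.fixture(scope="session")
def small_cohort():
    """Tiny homogeneous 3-state cohort used across modules."""
    config = SimulationConfig(
        k_true=3,
        n_regions=5,
        n_timepoints=100,
        n_patients=4,
        n_controls=4,
        control_stickiness=0.9,
        patient_stickiness=0.9,
        suppression_factor=1.0,
        suppressed_states=(),
        covariate_target_state=1,
        seed=11,
    )
    return build_cohort(config)


@pytest.fixture(scope="session")
def planted_cohort():
    """Two-group cohort with suppressed states, faster patient switching
    and a planted covariate, at a reduced spatial scale."""
    config = SimulationConfig(
        k_true=6,
        n_regions=10,
        n_timepoints=200,
        n_patients=36,
        n_controls=30,
        suppressed_states=(5, 6),
        covariate_target_state=4,
        seed=23,
    )
    return build_cohort(config)
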