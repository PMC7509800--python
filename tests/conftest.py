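import numpy as np
import pytest

from alertfmri import bold_synth, taskdesign


@pytest.fixture(scope="session")
def default_design():
    return taskdesign.generate_task_design(seed=1)


@pytest.fixture(scope="session")
def small_design():
    """Reduced schedule used by the Monte-Carlo tests (2 runs of 5+5 trials)."""
    return taskdesign.generate_task_design(
        n_runs=2, n_cue_per_run=5, n_cuestim_per_run=5, seed=1
    )


@pytest.fixture(scope="session")
def small_grid():
    """10^3-voxel box (30 mm at 3-mm voxels), 8 full cubes, seeded networks."""
    return bold_synth.plant_networks(bold_synth.default_grid(shape=(10, 10, 10)))


@pytest.fixture(scope="session")
def full_grid():
    """20^3-voxel box (60 mm), 64 full cubes, seeded networks."""
    return bold_synth.plant_networks(bold_synth.default_grid(shape=(20, 20, 20)))


@pytest.fixture(scope="session")
def noiseless_spec():
    return bold_synth.CohortSpec(
        n_subjects=4, noise_sd_pct=0.0, drift_amplitude_pct=0.0, seed=3
    )
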