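import numpy as np
import pytest

from cervimetry.synth import (SWEDesign, TrajectoryModel, FibreParams,
                              simulate_swe_dataset, simulate_fibre_image)


@pytest.fixture(scope="session")
def small_design_frame():
    """A small complete exam table: 1+1 animals, 3 hours, 2 ops, 2 reps."""
    design = SWEDesign(n_animals_control=1, n_animals_treated=1,
                       hours=(0.0, 12.0, 24.0), n_operators=2,
                       n_replicates=2, pixels_per_roi=50, seed=11)
    return simulate_swe_dataset(design)


@pytest.fixture(scope="session")
def aligned_image():
    return simulate_fibre_image(
        FibreParams(dispersion_sd=0.0, waviness_amp=0.0, mean_orientation=0.0,
                    background_sd=0.0), seed=7)


@pytest.fixture()
def rng():
    return np.random.default_rng(1234)
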