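import dataclasses

import numpy as np
import pytest

from leafchl.simulate import (
    DESIGN_2019_2020,
    GEN_EXP1,
    TrialDesign,
    generate_trial,
    make_benchmark_suite,
)


@pytest.fixture(scope="session")
def benchmarks():
    return make_benchmark_suite(seed=1)


#: A thinned 2019-2020-style design used where only structure matters:
#: 3 entries x 1 date x 2 irrigation x 2 reps = 12 plots, 3 collections,
#: 2 leaves/plot, 2 samples/leaf -> 36 units, 72 leaves, 144 samples.
SMALL_DESIGN = TrialDesign("exp1", n_entries=3, n_planting_dates=1,
                           n_irrigation_levels=2, n_replicates=2,
                           n_collections=3, leaves_per_plot=2, samples_per_leaf=2)


@pytest.fixture(scope="session")
def small_trial():
    return generate_trial(SMALL_DESIGN, GEN_EXP1, seed=7)


@pytest.fixture(scope="session")
def full_exp1_trial():
    """The complete 2019-2020-style design (5832 samples, 2916 leaves)."""
    return generate_trial(DESIGN_2019_2020, GEN_EXP1, seed=11)


@pytest.fixture(scope="session")
def vegetation_spectrum():
    """One noiseless, vegetation-like synthetic reflectance spectrum."""
    from leafchl.simulate import generate_spectrum

    return generate_spectrum(30.0, 6.0, water=1.0, noise_sd=0.0)
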