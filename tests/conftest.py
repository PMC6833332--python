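import numpy as np
import pytest
from hypothesis import settings

import replisen as rs

settings.register_profile("suite", derandomize=True, max_examples=25, deadline=None)
settings.load_profile("suite")

#: desk-scale GA budget used throughout the suite (defaults are 200x300)
GA_SMALL = dict(population_size=60, generations=40)


@pytest.fixture(scope="session")
def ref():
    """Packaged optimised reference parameter set (params, marker params)."""
    return rs.reference_parameters()


@pytest.fixture(scope="session")
def noiseless_dataset(ref):
    """Single-replicate noise-free dataset from the reference parameters."""
    params, mparams = ref
    design = rs.DesignSpec(replicates=1, noise={m: 0.0 for m in rs.MARKERS})
    return rs.generate_dataset(params, mparams, design)


@pytest.fixture(scope="session")
def noisy_dataset(ref):
    """Triplicate dataset at the default noise levels."""
    params, mparams = ref
    return rs.generate_dataset(params, mparams, rs.DesignSpec(seed=42))


@pytest.fixture
def ga_small():
    return rs.GAConfig(**GA_SMALL)


@pytest.fixture
def ga_tiny():
    return rs.GAConfig(population_size=12, generations=5)


@pytest.fixture(scope="session")
def recovery_fit(noiseless_dataset):
    """GA + gradient fit to the noise-free dataset (parameter recovery)."""
    model = rs.SenescenceMarkerModel(noiseless_dataset)
    return model.fit(seed=1, ga_config=rs.GAConfig(population_size=60, generations=60),
                     refine=True, n_refine=2)


@pytest.fixture(scope="session")
def noisy_baseline_fit(noisy_dataset):
    """Full-data fit to the noisy dataset, warm start for design/N refits."""
    model = rs.SenescenceMarkerModel(noisy_dataset)
    return model.fit(seed=7, ga_config=rs.GAConfig(**GA_SMALL), refine=True, n_refine=2)


@pytest.fixture(scope="session")
def ref_trajectory(ref):
    """Reference-parameter trajectory over 5000 h on a 1 h grid."""
    params, _ = ref
    return rs.simulate(params, 5000.0, np.linspace(0.0, 5000.0, 5001))
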