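import numpy as np
import pytest

import stardiff as sd


def small_params(**kw):
    """Reduced problem size for unit tests: fewer fragments, shallower depth."""
    defaults = dict(
        n_fragments=400,
        library_size_log_mean=float(np.log(4e4)),
        seed=11,
    )
    defaults.update(kw)
    return sd.SimulationParams(**defaults)


@pytest.fixture(scope="session")
def planted_sim():
    """One seeded experiment with planted genotype and temperature effects."""
    return sd.simulate_experiment(small_params())


@pytest.fixture(scope="session")
def null_sim():
    """Exchangeable dataset: no genotype or temperature effects planted."""
    return sd.simulate_experiment(small_params(pi_de=0.0, k_wild=0, k_ins=0, seed=12))


@pytest.fixture(scope="session")
def ambient_contrast(planted_sim):
    """Filtered ambient-library matrix plus the wild/ins library lists."""
    matrix, meta, truth = planted_sim
    filt = sd.filter_expressed(matrix)
    wild = meta.libraries(genotype="wild", treatment="ambient")
    ins = meta.libraries(genotype="ins", treatment="ambient")
    return filt.select_libraries(wild + ins), wild, ins, truth
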