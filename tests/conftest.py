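import numpy as np
import pytest

from ligandsense import LigandMixture, sample_trace


@pytest.fixture
def standard_mixture() -> LigandMixture:
    """Well-separated two-ligand mixture: r_c/r_nc = 0.1, equal on-rates."""
    return LigandMixture.two_species(
        k_c=1.0, r_c=0.1, c_c=0.5, k_nc=1.0, r_nc=1.0, c_nc=0.5
    )


@pytest.fixture
def standard_trace(standard_mixture):
    return sample_trace(standard_mixture, 3000, seed=42)


def replicate_traces(mixture, n_events, n_replicates, seed):
    """Deterministic stream of replicate traces for ensemble tests."""
    for rep in range(n_replicates):
        rng = np.random.default_rng(np.random.SeedSequence((seed, rep)))
        yield sample_trace(mixture, n_events, rng)
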