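import numpy as np
import pytest

from misti import simulate as sim


@pytest.fixture(scope="session")
def small_panel():
    """251-sample LD panel: 5 blocks of 10 variants, moderate LD."""
    spec = sim.LDSpec(n_blocks=5, block_size=10, within_block_rho=0.6, seed=7)
    return sim.simulate_ld_genotypes(251, spec, sample_seed=8), spec


@pytest.fixture(scope="session")
def big_panel():
    """5,000-sample panel for empirical moment checks."""
    spec = sim.LDSpec(n_blocks=4, block_size=5, within_block_rho=0.7,
                      maf_low=0.3, maf_high=0.3, seed=3)
    return sim.simulate_ld_genotypes(5000, spec), spec
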