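import numpy as np
import pytest

from mswsim.datasets import gefitinib_pc9_seascape
from mswsim.seascape import FitnessSeascape, LogisticCurve, generate_tradeoff_seascape


@pytest.fixture(scope="session")
def pc9():
    """Empirical four-genotype NSCLC/gefitinib Hill seascape."""
    return gefitinib_pc9_seascape()


@pytest.fixture(scope="session")
def tradeoff():
    """Seeded random two-allele tradeoff seascape."""
    return generate_tradeoff_seascape(n_sites=2, rng_seed=42)


@pytest.fixture()
def flat_seascape():
    """Two-allele seascape with identical drug-independent curves (neutral)."""
    curve = LogisticCurve(g_drugless=0.2, ic50=1e9, nu=-1e8)  # ~flat at 0.2 for any conc
    return FitnessSeascape({f"{i:02b}": curve for i in range(4)})


@pytest.fixture(scope="session")
def rng():
    return np.random.default_rng(12345)
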