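import numpy as np
import pytest

from excitonbath import OUConfig, diagonalize, generate_ou_site_energies
from excitonbath.fmo import reference_hamiltonian


@pytest.fixture(scope="session")
def fmo_result():
    """Exciton decomposition of the embedded FMO Hamiltonian (default variant)."""
    return diagonalize(reference_hamiltonian())


@pytest.fixture(scope="session")
def ou_paper_scale():
    """One paper-scale OU realization: 20 ps at 0.5 fs, trimer, 300 K."""
    config = OUConfig(
        lambda_reorg=100.0, tau_corr=15.0, temperature=300.0,
        time_step=0.5, n_steps=40_000, n_monomers=3, seed=2024,
    )
    return config, generate_ou_site_energies(config)


@pytest.fixture
def rng():
    return np.random.default_rng(1234)
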