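import numpy as np
import pytest
from hypothesis import HealthCheck, settings

settings.register_profile(
    "ci",
    derandomize=True,
    max_examples=25,
    deadline=None,
    suppress_health_check=[HealthCheck.too_slow],
)
settings.load_profile("ci")


@pytest.fixture(scope="session")
def planted_toy():
    """10-residue scaffold with an ideal disulfide pair planted at (2, 8)."""
    from cryostab.synthetic import synth_toy_structure

    return synth_toy_structure(10, planted_pair=(2, 8), seed=7)


@pytest.fixture(scope="session")
def planted_profile(planted_toy):
    """RMSF profile of the planted toy with hot planted residues."""
    from cryostab.flexibility import rmsf_profile
    from cryostab.synthetic import synth_trajectory

    amplitudes = {
        rid: (0.5 if rid[1] in (2, 8) else 0.15)
        for rid in planted_toy.residue_ids()
    }
    ens = synth_trajectory(planted_toy, amplitudes, n_frames=200, seed=11)
    return rmsf_profile(ens)


@pytest.fixture(scope="session")
def basis():
    from cryostab.cd_deconv import reference_basis

    return reference_basis()


@pytest.fixture()
def rng():
    return np.random.default_rng(12345)
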