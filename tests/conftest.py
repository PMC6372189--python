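import numpy as np
import pytest

from eicotriage import FamilySpec, generate_family, generate_helix_bundle


@pytest.fixture(scope="session")
def small_family():
    """A 30%-identity family of 5 orthologs with a planted 5-residue motif."""
    spec = FamilySpec(
        root_length=120,
        n_orthologs=5,
        target_identity=30.0,
        motif_positions=(12, 40, 65, 90, 110),
        motif_letters=("Y", "K", "H", "D", "E"),
        indel_rate=0.02,
        motif_equivalence_prob=0.1,
        seed=42,
    )
    return spec, generate_family(spec)


@pytest.fixture(scope="session")
def helix_bundle():
    return generate_helix_bundle(4, 25)


@pytest.fixture
def rng():
    return np.random.default_rng(12345)
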