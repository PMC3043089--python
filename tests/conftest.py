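import numpy as np
import pytest

from trpmhc.structures import annotate_roles, parse_pdb, truncate_complex, write_pdb
from trpmhc.synth import TOY_ROLE_MAP, ToyComplexSpec, generate_toy_complex


@pytest.fixture(scope="session")
def toy_spec():
    return ToyComplexSpec(theta_true=72.0, n_ring_pairs=8, seed=11, complex_id="toy")


@pytest.fixture(scope="session")
def toy_complex(toy_spec):
    """A clean (noise-free) annotated toy complex plus its truth record."""
    return generate_toy_complex(toy_spec)


@pytest.fixture(scope="session")
def toy_units(toy_complex):
    """The toy complex split into its pMHC-interface and TR units."""
    structure, _ = toy_complex
    return truncate_complex(structure)


@pytest.fixture(scope="session")
def toy_roundtrip(toy_complex):
    """The toy complex after a PDB write/parse round trip, re-annotated."""
    structure, _ = toy_complex
    reparsed = parse_pdb(write_pdb(structure), structure_id=structure.id)
    return annotate_roles(reparsed, TOY_ROLE_MAP)


def rigid_transform(rng: np.random.Generator):
    """A random proper rotation + translation (helper for invariance tests)."""
    a = rng.normal(size=(3, 3))
    q, r = np.linalg.qr(a)
    q *= np.sign(np.diag(r))
    if np.linalg.det(q) < 0:
        q[:, 0] = -q[:, 0]
    t = rng.normal(scale=20.0, size=3)
    return q, t
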