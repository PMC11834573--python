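"""Shared fixtures: small random molecules, toy complexes, tiny configs."""

import numpy as np
import pytest

from pairbind.complexes import ComplexConfig
from pairbind.encoder import EncoderConfig
from pairbind.geometry import Molecule
from pairbind.synthetic import SyntheticSpec, generate_dataset, generate_molecules


def random_molecule(rng: np.random.Generator, m: int = 8) -> Molecule:
    """Random well-separated molecule (no collinear stencils a.s.)."""
    coords = rng.normal(0, 3, (m, 3))
    # push apart any close pair: plausible molecules keep atoms > ~1.2 Å
    for _ in range(200):
        d = np.linalg.norm(coords[:, None] - coords[None, :], axis=-1)
        np.fill_diagonal(d, np.inf)
        i, j = np.unravel_index(np.argmin(d), d.shape)
        if d[i, j] >= 1.2:
            break
        coords[i] += rng.normal(0, 1, 3)
    types = list(rng.choice(["C", "N", "O", "H", "S"], size=m))
    return Molecule(atom_types=types, coords=coords)


def random_rigid_motion(rng: np.random.Generator):
    """A uniform random rotation and translation."""
    q, r = np.linalg.qr(rng.normal(size=(3, 3)))
    q = q * np.sign(np.diag(r))
    if np.linalg.det(q) < 0:
        q[:, 0] = -q[:, 0]
    t = rng.normal(0, 10, 3)
    return q, t


@pytest.fixture()
def rng():
    # function-scoped: every test draws the same stream regardless of
    # execution order
    return np.random.default_rng(1234)


@pytest.fixture(scope="session")
def tiny_spec():
    return SyntheticSpec(seed=7)


@pytest.fixture(scope="session")
def small_molecules(tiny_spec):
    return generate_molecules(tiny_spec, seed=5, n=12)


@pytest.fixture(scope="session")
def toy_complexes(tiny_spec):
    return generate_dataset(tiny_spec, seed=6, n=10)


@pytest.fixture(scope="session")
def tiny_encoder_config():
    return EncoderConfig.tiny(seed=0)


@pytest.fixture(scope="session")
def tiny_complex_config():
    return ComplexConfig(ligand=EncoderConfig.tiny(seed=0),
                         protein=EncoderConfig.tiny(seed=1),
                         trunk_layers=2, seed=0)
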