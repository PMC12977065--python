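import numpy as np
import pytest

from racerts.fixtures import make_metal_toy, make_sn2_toy
from racerts.structure_io import Ensemble, Member, Structure


@pytest.fixture(scope="session")
def sn2_rigid():
    return make_sn2_toy(0)


@pytest.fixture(scope="session")
def sn2_tail2():
    return make_sn2_toy(2)


@pytest.fixture(scope="session")
def sn2_tail3():
    return make_sn2_toy(3)


@pytest.fixture(scope="session")
def metal_toy():
    return make_metal_toy()


@pytest.fixture
def rng():
    return np.random.default_rng(1234)


def random_structure(rng, n_atoms=5, symbols=None):
    symbols = symbols or ["C"] * n_atoms
    return Structure(symbols, rng.normal(scale=2.0, size=(len(symbols), 3)))


_DIRECTIONS = np.array([
    [0, 0, 0], [1, 0, 0], [0, 1, 0], [0, 0, 1],
    [-1, 0, 0], [0, -1, 0], [0, 0, -1],
], dtype=float)


def distinct_conformers(base, n, scale=8.0):
    """Conformers with pairwise-large internal differences: atom 0 is pushed
    along n distinct directions (no rigid-motion degeneracy)."""
    assert n <= len(_DIRECTIONS)
    out = []
    for k in range(n):
        coords = base.coords.copy()
        coords[0] = coords[0] + scale * _DIRECTIONS[k]
        out.append(base.with_coords(coords))
    return out


def random_ensemble(rng, base=None, n_members=5, spread=0.3):
    """Perturbed copies of one structure with random ascending-ish energies."""
    base = base if base is not None else random_structure(rng)
    members = []
    for k in range(n_members):
        coords = base.coords + rng.normal(scale=spread, size=base.coords.shape)
        members.append(Member(base.with_coords(coords), float(rng.normal(scale=3.0)), f"m{k}"))
    members.sort(key=lambda m: m.energy)
    return Ensemble(members)
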