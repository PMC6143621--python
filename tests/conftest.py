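import numpy as np
import pytest

from precondopt import (
    FixtureSpec,
    ForceField,
    ForceFieldCalculator,
    Structure,
    make_fixture,
)


@pytest.fixture
def chain():
    """Perturbed stiff/soft chain molecule with its toy force field."""
    structure, terms = make_fixture(FixtureSpec("chain-molecule", n=8, perturbation=0.05, seed=7))
    return structure, ForceField(terms)


@pytest.fixture
def chain_calc(chain):
    structure, ff = chain
    return structure, ff, ForceFieldCalculator(ff)


@pytest.fixture
def random_structure():
    def factory(n=4, seed=0, scale=1.5, periodic=False):
        rng = np.random.default_rng(seed)
        pos = rng.normal(0.0, 1.0, (n, 3)) * scale
        if periodic:
            cell = np.eye(3) * 10.0
            return Structure(["C"] * n, pos % 10.0, cell=cell, pbc=np.ones(3, dtype=bool))
        return Structure(["C"] * n, pos)

    return factory


def fd_gradient(fn, x, h=1e-6):
    """Central-difference gradient of a scalar function of a flat vector."""
    g = np.zeros_like(x)
    for i in range(len(x)):
        xp, xm = x.copy(), x.copy()
        xp[i] += h
        xm[i] -= h
        g[i] = (fn(xp) - fn(xm)) / (2.0 * h)
    return g
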