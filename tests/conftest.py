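"""Shared fixtures: toy systems, bases and datasets, all generated at run
time from fixed seeds (no stored data files)."""

import numpy as np
import pytest

import pipfrag as pf
from pipfrag.synthetic import (
    make_surrogate,
    reference_geometry,
    sample_dataset,
    toy_fragmentation,
)


@pytest.fixture(scope="session")
def a3bc_ref():
    return reference_geometry("a3bc")


@pytest.fixture(scope="session")
def a3bc_basis():
    frag = toy_fragmentation("a3bc")
    return pf.generate_basis(frag, 3, 5)


@pytest.fixture(scope="session")
def a3bc_dataset(a3bc_ref):
    pes = make_surrogate(a3bc_ref.species, "pairwise", seed=3)
    return sample_dataset(pes, a3bc_ref, 80, sigma=0.06, e_cutoff=12000.0, seed=5)


@pytest.fixture(scope="session")
def a3bc_fit(a3bc_dataset, a3bc_basis):
    return pf.fit_coefficients(a3bc_dataset, a3bc_basis, gradient_weight=1.0)


@pytest.fixture(scope="session")
def a2b2cd_ref():
    return reference_geometry("a2b2cd")


def random_geometry(rng, species, scale=3.0, min_sep=1.0):
    """A random geometry with all pair distances above ``min_sep`` bohr."""
    n = len(species)
    while True:
        coords = rng.uniform(-scale, scale, size=(n, 3))
        g = pf.Geometry(tuple(species), coords)
        if g.distances().min() > min_sep:
            return g


@pytest.fixture
def rng():
    return np.random.default_rng(20240117)
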