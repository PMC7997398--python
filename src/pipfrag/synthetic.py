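"""Surrogate analytic surfaces and dataset sampling.

The reference studies fit ab initio energies and gradients of 12- and
10-atom molecules; those electronic-structure datasets are not shipped
anywhere, so this module provides analytic stand-ins with the same
structure — permutational invariance, energies confined below a cutoff
around a minimum, exact gradients — on toy systems small enough for
brute-force oracles.

Two surrogate families:

* ``pairwise``: a sum of pair Morse potentials D (1 - e^{-alpha (r - r0)})^2
  with parameters keyed by the unordered species pair, hence exactly
  invariant under any same-species atom permutation.
* ``pip-combo``: a known linear combination of a PIP basis — fitting that
  basis to sampled data must recover the predictions exactly, the
  end-to-end self-consistency check.

Sampling emulates how the real datasets were built (geometries from
dynamics confined below an energy ceiling, clustered near the global
minimum): Gaussian Cartesian displacements from a reference structure,
accepted only while the energy stays below the cutoff.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Optional, Sequence

import numpy as np

from .basis import basis_jacobian, evaluate_basis
from .geometry import (
    DataRecord,
    Dataset,
    Geometry,
    morse_jacobian,
    morse_variables,
    pair_order,
)


@dataclass(frozen=True)
class MorsePairParams:
    depth: float  # D, cm^-1
    alpha: float  # bohr^-1
    r0: float  # bohr


class SurrogatePES:
    """Analytic surrogate with energy (cm^-1) and gradient (cm^-1/bohr)."""

    def energy(self, geom: Geometry) -> float:
        raise NotImplementedError

    def gradient(self, geom: Geometry) -> np.ndarray:
        raise NotImplementedError


class PairwiseMorsePES(SurrogatePES):
    """Sum over atom pairs of Morse potentials keyed by species pair."""

    def __init__(self, params: dict[frozenset, MorsePairParams], seed: int):
        self.params = params
        self.seed = seed

    def _pair_params(self, geom: Geometry):
        for (i, j) in pair_order(geom.n_atoms):
            key = frozenset((geom.species[i - 1], geom.species[j - 1]))
            yield (i, j), self.params[key]

    def energy(self, geom: Geometry) -> float:
        r = geom.distances()
        total = 0.0
        for l, ((i, j), p) in enumerate(self._pair_params(geom)):
            total += p.depth * (1.0 - np.exp(-p.alpha * (r[l] - p.r0))) ** 2
        return total

    def gradient(self, geom: Geometry) -> np.ndarray:
        r = geom.distances()
        grad = np.zeros(3 * geom.n_atoms)
        for l, ((i, j), p) in enumerate(self._pair_params(geom)):
            ex = np.exp(-p.alpha * (r[l] - p.r0))
            dV_dr = 2.0 * p.depth * (1.0 - ex) * p.alpha * ex
            u = (geom.coords[i - 1] - geom.coords[j - 1]) / r[l]
            grad[3 * (i - 1) : 3 * i] += dV_dr * u
            grad[3 * (j - 1) : 3 * j] -= dV_dr * u
        return grad


class PipComboPES(SurrogatePES):
    """A fixed linear combination of a PIP basis (exact member of the model
    space, so fits recover it to solver precision)."""

    def __init__(self, basis, coefficients: np.ndarray, lam: float, seed: int):
        if len(coefficients) != len(basis.pips):
            raise ValueError("coefficient/basis size mismatch")
        self.basis = basis
        self.coefficients = np.asarray(coefficients, dtype=float)
        self.lam = lam
        self.seed = seed

    def energy(self, geom: Geometry) -> float:
        x = morse_variables(geom, self.lam)
        return float(self.coefficients @ evaluate_basis(self.basis, x))

    def gradient(self, geom: Geometry) -> np.ndarray:
        x = morse_variables(geom, self.lam)
        J = basis_jacobian(self.basis, x)
        M = morse_jacobian(geom, self.lam)
        return np.asarray(M.T @ (self.coefficients @ J)).ravel()


def make_surrogate(
    species: Sequence[str],
    mode: str = "pairwise",
    seed: int = 0,
    basis=None,
    coefficients: Optional[np.ndarray] = None,
    lam: float = 2.0,
) -> SurrogatePES:
    """Deterministic surrogate construction.

    ``pairwise``: Morse parameters drawn once per species pair from ranges
    typical of covalent/nonbonded interactions (D in 15000-45000 cm^-1,
    alpha in 0.8-1.3 bohr^-1, r0 in 1.9-3.2 bohr).  ``pip-combo``: supply
    ``basis``; coefficients default to standard-normal scaled by 100 cm^-1.
    """
    if len(species) < 2:
        raise ValueError("need at least 2 atoms")
    rng = np.random.default_rng(seed)
    if mode == "pairwise":
        params: dict[frozenset, MorsePairParams] = {}
        for key in sorted(
            {frozenset((a, b)) for a in species for b in species},
            key=lambda k: tuple(sorted(k)),
        ):
            params[key] = MorsePairParams(
                depth=float(rng.uniform(15000.0, 45000.0)),
                alpha=float(rng.uniform(0.8, 1.3)),
                r0=float(rng.uniform(1.9, 3.2)),
            )
        return PairwiseMorsePES(params, seed)
    if mode == "pip-combo":
        if basis is None:
            raise ValueError("pip-combo mode requires a basis")
        if coefficients is None:
            coefficients = 100.0 * rng.standard_normal(len(basis.pips))
        return PipComboPES(basis, coefficients, lam, seed)
    raise ValueError(f"unknown surrogate mode {mode!r}")


class SamplingError(RuntimeError):
    """Accept-reject sampling starved; suggests larger sigma or cutoff."""


def surrogate_minimum(
    pes: SurrogatePES, start: Geometry
) -> tuple[Geometry, float]:
    """The surrogate's local minimum nearest ``start`` and its energy."""
    from scipy.optimize import minimize

    species = start.species

    def fun(flat):
        return pes.energy(Geometry(species, flat.reshape(-1, 3)))

    def jac(flat):
        return pes.gradient(Geometry(species, flat.reshape(-1, 3)))

    res = minimize(fun, start.coords.ravel(), jac=jac, method="BFGS",
                   options={"gtol": 1e-8})
    return Geometry(species, res.x.reshape(-1, 3)), float(res.fun)


def sample_dataset(
    pes: SurrogatePES,
    reference: Geometry,
    n: int,
    sigma: float = 0.08,
    e_cutoff: float = 10000.0,
    seed: int = 0,
    max_attempts_per_record: int = 200,
) -> Dataset:
    """Accept-reject sampling of geometries below an energy ceiling.

    The sampling center is the surrogate's own minimum (located by local
    minimization from ``reference``), emulating datasets whose geometries
    cluster around the global-minimum well.  Gaussian displacements (std
    ``sigma`` bohr per Cartesian component) are drawn around that center
    and kept iff the energy lies within ``e_cutoff`` of the minimum.
    Stored energies are relative to the surrogate minimum (so they lie in
    [0, e_cutoff]); every record carries the analytic gradient.
    Reproducible under ``seed``.
    """
    if n < 1:
        raise ValueError("n must be >= 1")
    if sigma <= 0:
        raise ValueError("sigma must be positive")
    if e_cutoff <= 0:
        raise ValueError("e_cutoff must lie above the minimum energy")
    rng = np.random.default_rng(seed)
    center, e_ref = surrogate_minimum(pes, reference)
    records = []
    attempts = 0
    budget = max_attempts_per_record * n
    while len(records) < n:
        if attempts >= budget:
            raise SamplingError(
                f"accepted {len(records)}/{n} after {attempts} draws; "
                "increase sigma acceptance window or e_cutoff"
            )
        attempts += 1
        disp = rng.normal(0.0, sigma, size=center.coords.shape)
        geom = Geometry(center.species, center.coords + disp)
        e = pes.energy(geom) - e_ref
        if e <= e_cutoff:
            records.append(DataRecord(geom, e, pes.gradient(geom)))
    return Dataset(records)


# --- toy systems: small enough for brute-force oracles ---------------------

#: 5-atom methyl-like molecule: three permutable H on a C, plus an N.
A3BC_SPECIES = ("H", "H", "H", "C", "N")

#: 6-atom molecule with two permutable H and two permutable O.
A2B2CD_SPECIES = ("H", "H", "O", "O", "C", "N")


def _tetra_units():
    s = np.sqrt(2.0)
    return np.array(
        [
            [-1.0 / 3.0, 2.0 * s / 3.0, 0.0],
            [-1.0 / 3.0, -s / 3.0, np.sqrt(2.0 / 3.0)],
            [-1.0 / 3.0, -s / 3.0, -np.sqrt(2.0 / 3.0)],
        ]
    )


def reference_geometry(system: str) -> Geometry:
    """Reference structures for the shipped toy systems (bohr)."""
    if system == "a3bc":
        c = np.zeros(3)
        n = np.array([2.74, 0.0, 0.0])
        h = c + 2.06 * _tetra_units()  # H's pointing away from N (negative x)
        coords = np.vstack([h, c, n])
        return Geometry(A3BC_SPECIES, coords)
    if system == "a2b2cd":
        c = np.zeros(3)
        o1 = np.array([1.15, 2.05, 0.0])
        o2 = np.array([1.15, -2.05, 0.0])
        nn = np.array([-2.77, 0.0, 0.0])
        h1 = nn + np.array([-0.95, 1.52, 0.35])
        h2 = nn + np.array([-0.95, -1.52, -0.35])
        coords = np.vstack([h1, h2, o1, o2, c, nn])
        return Geometry(A2B2CD_SPECIES, coords)
    raise ValueError(f"unknown toy system {system!r} (choose a3bc or a2b2cd)")


def toy_fragmentation(system: str):
    """Natural symmetry blocks of the toy systems (as full-molecule specs)."""
    from .symmetry import FragmentSpec, SymmetrySpec

    if system == "a3bc":
        spec = SymmetrySpec.from_sizes([3, 1, 1], [1, 2, 3, 4, 5])
        return FragmentSpec((1, 2, 3, 4, 5), spec)
    if system == "a2b2cd":
        spec = SymmetrySpec.from_sizes([2, 2, 1, 1], [1, 2, 3, 4, 5, 6])
        return FragmentSpec((1, 2, 3, 4, 5, 6), spec)
    raise ValueError(f"unknown toy system {system!r}")
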