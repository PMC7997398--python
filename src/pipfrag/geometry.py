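"""Molecular geometries, Morse variables, and their Cartesian derivatives.

A geometry is a set of N atoms with Cartesian coordinates in bohr.  The
regression variables of the whole package are Morse variables

    x_l = exp(-r_l / lambda)

one per unordered atom pair, with the pairs in a fixed canonical
(lexicographic) order.  Morse variables decay to zero with distance, which
is what makes fragmented bases possible: pairs of atoms that are always far
apart contribute variables that are numerically zero and can be dropped.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from typing import Optional

import numpy as np
from scipy import sparse

from .constants import DEFAULT_LAMBDA


class DegenerateGeometryError(ValueError):
    """Two atoms coincide: the interatomic distance is zero."""


class InvalidPairError(ValueError):
    """An atom-pair index is out of range or degenerate (i == j)."""


def n_pairs(n_atoms: int) -> int:
    """Number of unordered atom pairs, N(N-1)/2."""
    if n_atoms < 2:
        raise ValueError(f"need at least 2 atoms, got {n_atoms}")
    return n_atoms * (n_atoms - 1) // 2


def pair_order(n_atoms: int) -> list[tuple[int, int]]:
    """Canonical ordering of unordered atom pairs.

    Pairs (i, j) with 1 <= i < j <= N are listed lexicographically:
    (1,2), (1,3), ..., (1,N), (2,3), ...  Atom indices are 1-based,
    matching the conventional numbering of molecular diagrams.
    """
    if n_atoms < 2:
        raise InvalidPairError(f"need at least 2 atoms, got {n_atoms}")
    return [(i, j) for i in range(1, n_atoms + 1) for j in range(i + 1, n_atoms + 1)]


def pair_index(i: int, j: int, n_atoms: int) -> int:
    """1-based position of the unordered pair (i, j) in canonical order."""
    if i == j:
        raise InvalidPairError(f"degenerate pair ({i}, {j})")
    if not (1 <= i <= n_atoms and 1 <= j <= n_atoms):
        raise InvalidPairError(f"pair ({i}, {j}) out of range for N={n_atoms}")
    a, b = (i, j) if i < j else (j, i)
    # pairs with first index < a: sum_{k<a} (N-k); then offset within row a
    return (a - 1) * n_atoms - (a - 1) * a // 2 + (b - a)


@dataclass(frozen=True)
class Geometry:
    """Cartesian geometry: species labels plus an (N, 3) coordinate array in bohr."""

    species: tuple[str, ...]
    coords: np.ndarray  # (N, 3), bohr

    def __post_init__(self):
        coords = np.asarray(self.coords, dtype=float)
        if coords.ndim != 2 or coords.shape[1] != 3:
            raise ValueError(f"coords must be (N, 3), got {coords.shape}")
        if coords.shape[0] != len(self.species):
            raise ValueError(
                f"{len(self.species)} species but {coords.shape[0]} coordinate rows"
            )
        if coords.shape[0] < 2:
            raise ValueError("a geometry needs at least 2 atoms")
        if not np.isfinite(coords).all():
            raise ValueError("non-finite coordinates")
        object.__setattr__(self, "species", tuple(self.species))
        object.__setattr__(self, "coords", coords)

    @property
    def n_atoms(self) -> int:
        return self.coords.shape[0]

    def distances(self) -> np.ndarray:
        """Pair distances r_l in canonical pair order (bohr)."""
        d = self.coords[:, None, :] - self.coords[None, :, :]
        r = np.sqrt((d * d).sum(axis=2))
        iu = np.triu_indices(self.n_atoms, k=1)
        return r[iu]

    def permuted(self, perm: dict[int, int]) -> "Geometry":
        """Geometry with atoms relabelled by ``perm`` (1-based atom -> image).

        Atom ``a`` of the result carries the coordinates of ``perm^{-1}(a)``,
        i.e. the atoms are swapped in place; species must match across each
        swap for the result to be physically meaningful (not enforced here —
        symmetry blocks may deliberately span distinct elements).
        """
        n = self.n_atoms
        new = np.empty_like(self.coords)
        new_sp = list(self.species)
        for a in range(1, n + 1):
            b = perm.get(a, a)
            new[b - 1] = self.coords[a - 1]
            new_sp[b - 1] = self.species[a - 1]
        return Geometry(tuple(new_sp), new)


@dataclass(frozen=True)
class MorseVector:
    """Morse variables x_l = exp(-r_l/lambda) in canonical pair order."""

    values: np.ndarray
    lam: float

    def __post_init__(self):
        object.__setattr__(self, "values", np.asarray(self.values, dtype=float))


def morse_variables(
    geom: Geometry, lam: float = DEFAULT_LAMBDA, strict: bool = True
) -> MorseVector:
    """Morse variables of a geometry.

    With ``strict`` (the fitting path) coincident atoms raise
    :class:`DegenerateGeometryError`; otherwise (exploratory evaluation)
    a warning is emitted and x = 1 is returned for the degenerate pair.
    """
    if lam <= 0:
        raise ValueError(f"lambda must be positive, got {lam}")
    r = geom.distances()
    if np.any(r == 0.0):
        if strict:
            raise DegenerateGeometryError("coincident atoms (r = 0)")
        warnings.warn("coincident atoms: Morse variable equals 1 exactly")
    return MorseVector(np.exp(-r / lam), lam)


def morse_jacobian(
    geom: Geometry, lam: float = DEFAULT_LAMBDA, strict: bool = True
) -> sparse.csr_matrix:
    """Sparse Jacobian d x_l / d a_{j,k} of shape (n_pairs, 3N).

    Row l has nonzero entries only in the 6 Cartesian slots of the two atoms
    of pair l:

        d x_l / d a_{j,k} = -(x_l / lambda) (a_{j,k} - a_{j',k}) / r_l

    where j' is the partner atom.  Entries for atoms not in the pair are
    structurally absent.
    """
    if lam <= 0:
        raise ValueError(f"lambda must be positive, got {lam}")
    n = geom.n_atoms
    pairs = pair_order(n)
    r = geom.distances()
    if strict and np.any(r == 0.0):
        raise DegenerateGeometryError("coincident atoms (r = 0)")
    x = np.exp(-r / lam)
    rows, cols, vals = [], [], []
    for l, (i, j) in enumerate(pairs):
        diff = geom.coords[i - 1] - geom.coords[j - 1]
        pref = -(x[l] / lam) / r[l]
        for k in range(3):
            rows.append(l)
            cols.append(3 * (i - 1) + k)
            vals.append(pref * diff[k])
            rows.append(l)
            cols.append(3 * (j - 1) + k)
            vals.append(-pref * diff[k])
    return sparse.csr_matrix(
        (vals, (rows, cols)), shape=(len(pairs), 3 * n)
    )


@dataclass(frozen=True)
class DataRecord:
    """One fitting point: a geometry, its energy (cm^-1), optionally a gradient."""

    geometry: Geometry
    energy: float
    gradient: Optional[np.ndarray] = None  # (3N,), cm^-1/bohr

    def __post_init__(self):
        if self.gradient is not None:
            g = np.asarray(self.gradient, dtype=float)
            if g.shape != (3 * self.geometry.n_atoms,):
                raise ValueError(
                    f"gradient must have {3 * self.geometry.n_atoms} components, "
                    f"got {g.shape}"
                )
            object.__setattr__(self, "gradient", g)


@dataclass
class Dataset:
    """A homogeneous collection of data records (same atom count and species)."""

    records: list[DataRecord] = field(default_factory=list)

    def __post_init__(self):
        if self.records:
            sp = self.records[0].geometry.species
            for k, rec in enumerate(self.records):
                if rec.geometry.species != sp:
                    raise ValueError(
                        f"record {k} species {rec.geometry.species} != {sp}"
                    )

    def __len__(self) -> int:
        return len(self.records)

    def __iter__(self):
        return iter(self.records)

    @property
    def species(self) -> tuple[str, ...]:
        return self.records[0].geometry.species

    @property
    def n_atoms(self) -> int:
        return self.records[0].geometry.n_atoms

    @property
    def energies(self) -> np.ndarray:
        return np.array([r.energy for r in self.records])

    @property
    def has_gradients(self) -> bool:
        return all(r.gradient is not None for r in self.records)
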