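"""Monomial symmetrization: PIP bases and their evaluation schemes.

A permutationally invariant polynomial (PIP) is the sum of a monomial in
the Morse variables over its orbit under the induced pair-permutation
group.  A basis is one PIP per orbit, for all monomials of total degree 0
through the configured maximum (the degree-0 orbit is the constant term
and is counted as a basis member).

Monomials are stored sparsely as sorted tuples of ``(pair_index, exponent)``
with 0-based pair indices in the PARENT molecule's canonical pair order, so
that fragment bases can be merged without re-indexing.

Generation is enumerative: all exponent vectors up to the maximum degree
are listed and exactly the canonical (lexicographically least in their
orbit) ones are kept, one per orbit.  The closed-form orbit count of
:func:`pipfrag.symmetry.burnside_count` is the independent check on the
result's size.
"""

from __future__ import annotations

import itertools
import json
from dataclasses import dataclass
from typing import Sequence

import numpy as np

from .geometry import MorseVector, n_pairs, pair_order
from .symmetry import (
    FragmentSpec,
    SymmetrySpec,
    build_group,
    induced_pair_action,
)

# A sparse monomial: sorted tuple of (0-based pair index, positive exponent).
SparseMonomial = tuple[tuple[int, int], ...]


def monomial_degree(m: SparseMonomial) -> int:
    return sum(e for _, e in m)


def apply_action_sparse(m: SparseMonomial, act: np.ndarray) -> SparseMonomial:
    """Image of a sparse monomial under an induced pair action."""
    return tuple(sorted((int(act[l]), e) for l, e in m))


def dense_key(m: SparseMonomial, n_vars: int) -> bytes:
    """Dense exponent vector as bytes; byte comparison is lexicographic order."""
    arr = bytearray(n_vars)
    for l, e in m:
        arr[l] = e
    return bytes(arr)


def canonical_monomial(
    m: SparseMonomial, actions: Sequence[np.ndarray], n_vars: int
) -> SparseMonomial:
    """Lexicographically least image of ``m`` over the group (orbit representative).

    Comparison is lexicographic on the dense exponent vector.  Two
    monomials share a representative iff they lie in one orbit.
    """
    return min(_orbit(m, actions), key=lambda t: dense_key(t, n_vars))


def _orbit(m: SparseMonomial, actions: Sequence[np.ndarray]) -> set[SparseMonomial]:
    return {apply_action_sparse(m, act) for act in actions}


@dataclass(frozen=True)
class PIP:
    """One permutationally invariant polynomial: an orbit of monomials.

    The PIP's value at a Morse vector x is the sum over orbit members of
    the monomial products.  ``representative`` is the canonically least
    member; the full sorted ``orbit`` is the identity of the polynomial as
    a function and is the key used for duplicate detection across
    fragments.
    """

    degree: int
    representative: SparseMonomial
    orbit: tuple[SparseMonomial, ...]

    @property
    def key(self) -> tuple[SparseMonomial, ...]:
        return self.orbit

    @property
    def is_constant(self) -> bool:
        return self.degree == 0

    def variables(self) -> set[int]:
        return {l for m in self.orbit for l, _ in m}

    def value(self, x: np.ndarray) -> float:
        """Direct orbit-sum evaluation (the defining semantics).

        Factors within each monomial and terms across the orbit are
        accumulated in sorted-value order.  Permuting the input by a group
        element permutes the factor/term multisets onto themselves, so the
        result is bit-for-bit invariant under allowed permutations — not
        merely invariant up to floating-point reassociation.
        """
        terms = []
        for m in self.orbit:
            prod = 1.0
            for f in sorted(x[l] ** e for l, e in m):
                prod *= f
            terms.append(prod)
        terms.sort()
        total = 0.0
        for t in terms:
            total += t
        return total


def sort_key(p: PIP, n_vars: int) -> tuple:
    """Grade-lexicographic ordering key: degree, then canonical
    representative, then (to break ties between distinct orbits that share
    a representative across different fragment groups) the full orbit."""
    return (
        p.degree,
        dense_key(p.representative, n_vars),
        tuple(dense_key(m, n_vars) for m in p.orbit),
    )


@dataclass
class FragmentBasis:
    """The PIP basis of one fragment, in parent pair indexing.

    ``pips`` are ordered grade-lexicographically (degree, then canonical
    representative); the constant term is first.
    """

    pips: list[PIP]
    n_atoms: int  # parent atom count
    fragment: FragmentSpec
    max_degree: int

    def __len__(self) -> int:
        return len(self.pips)

    @property
    def variables(self) -> list[int]:
        """Sorted 0-based parent pair indices the basis touches (fragment pairs)."""
        al = self.fragment.atoms
        pairs = pair_order(self.n_atoms)
        idx = {p: k for k, p in enumerate(pairs)}
        out = set()
        for i in range(len(al)):
            for j in range(i + 1, len(al)):
                a, b = sorted((al[i], al[j]))
                out.add(idx[(a, b)])
        return sorted(out)


def _enumerate_exponents(n_vars: int, max_degree: int) -> np.ndarray:
    """All exponent vectors with total degree <= max_degree, as (M, n_vars) int16."""
    chunks = [np.zeros((1, n_vars), dtype=np.int16)]
    for deg in range(1, max_degree + 1):
        combos = list(itertools.combinations_with_replacement(range(n_vars), deg))
        arr = np.zeros((len(combos), n_vars), dtype=np.int16)
        rows = np.repeat(np.arange(len(combos)), deg)
        cols = np.fromiter((v for c in combos for v in c), dtype=np.int64)
        np.add.at(arr, (rows, cols), 1)
        chunks.append(arr)
    return np.vstack(chunks)


def _canonical_mask(E: np.ndarray, inverse_actions: Sequence[np.ndarray]) -> np.ndarray:
    """Boolean mask of rows that are lexicographically least in their orbit."""
    M = E.shape[0]
    mask = np.ones(M, dtype=bool)
    rows = np.arange(M)
    for inv in inverse_actions:
        img = E[:, inv]
        diff = img - E
        nz = diff != 0
        first = np.argmax(nz, axis=1)
        val = diff[rows, first]
        differs = nz.any(axis=1)
        mask &= ~(differs & (val < 0))
    return mask


def generate_basis(
    frag: FragmentSpec, max_degree: int, parent_n_atoms: int
) -> FragmentBasis:
    """Enumerate the fragment's PIP basis up to ``max_degree``.

    Monomials live in the fragment's own C(k, 2) pair variables; canonical
    representatives are selected under the fragment group's induced action
    and orbits are then re-expressed in parent pair indices via the
    fragment atom list.  The resulting size always equals
    ``burnside_count(frag.symmetry_local, k, max_degree)``.
    """
    atoms = frag.atoms
    k = len(atoms)
    if k < 2:
        raise ValueError("fragment must have at least 2 atoms")
    if max(atoms) > parent_n_atoms:
        raise ValueError(
            f"fragment atom {max(atoms)} exceeds parent size {parent_n_atoms}"
        )
    # local relabelling: parent atom -> 1..k in listed order
    local_of = {a: t + 1 for t, a in enumerate(atoms)}
    local_spec = frag.symmetry.relabelled(local_of)
    group = build_group(local_spec)
    actions = [induced_pair_action(g, k) for g in group]
    inverse_actions = [np.argsort(a) for a in actions]

    E = _enumerate_exponents(n_pairs(k), max_degree)
    reps = E[_canonical_mask(E, inverse_actions)]

    # map local pair index -> parent pair index
    parent_pairs = pair_order(parent_n_atoms)
    parent_idx = {p: t for t, p in enumerate(parent_pairs)}
    local_pairs = pair_order(k)
    loc2par = np.array(
        [
            parent_idx[tuple(sorted((atoms[i - 1], atoms[j - 1])))]
            for (i, j) in local_pairs
        ]
    )

    nv_parent = n_pairs(parent_n_atoms)
    pips = []
    for r in reps:
        nz = np.nonzero(r)[0]
        base: SparseMonomial = tuple((int(l), int(r[l])) for l in nz)
        orbit_local = set()
        for act in actions:
            orbit_local.add(tuple(sorted((int(act[l]), e) for l, e in base)))
        orbit_parent = tuple(
            sorted(
                (tuple(sorted((int(loc2par[l]), e) for l, e in m)) for m in orbit_local),
                key=lambda m: dense_key(m, nv_parent),
            )
        )
        pips.append(PIP(int(r.sum()), orbit_parent[0], orbit_parent))
    pips.sort(key=lambda p: sort_key(p, nv_parent))
    return FragmentBasis(pips, parent_n_atoms, frag, max_degree)


# ---------------------------------------------------------------------------
# Evaluation scheme: monomials computed once, by recursive products, PIPs as
# sums of monomial entries — the factorized evaluation strategy.
# ---------------------------------------------------------------------------


@dataclass
class EvaluationScheme:
    """Straight-line program evaluating a PIP basis.

    Instructions, in topological order (each references only earlier
    entries):

    - ``("const",)``: the value 1 (the empty monomial / constant PIP).
    - ``("var", l)``: Morse variable x_l (parent pair index l).
    - ``("mul", a, b)``: product of entries a and b — how higher-degree
      monomials are factorized into previously computed ones.
    - ``("sum", (i1, i2, ...))``: sum of earlier entries — a PIP as the sum
      of its orbit's monomial entries.

    ``outputs[i]`` is the instruction index holding the value of basis
    member i.
    """

    instructions: list[tuple]
    outputs: list[int]
    n_atoms: int

    def evaluate(self, x: np.ndarray) -> np.ndarray:
        vals = np.empty(len(self.instructions))
        for k, ins in enumerate(self.instructions):
            op = ins[0]
            if op == "const":
                vals[k] = 1.0
            elif op == "var":
                vals[k] = x[ins[1]]
            elif op == "mul":
                vals[k] = vals[ins[1]] * vals[ins[2]]
            else:  # sum
                vals[k] = vals[list(ins[1])].sum()
        return vals[self.outputs]

    def to_json(self) -> str:
        return json.dumps(
            {
                "n_atoms": self.n_atoms,
                "instructions": [list(i) if i[0] != "sum" else ["sum", list(i[1])]
                                 for i in self.instructions],
                "outputs": self.outputs,
            }
        )

    @classmethod
    def from_json(cls, text: str) -> "EvaluationScheme":
        obj = json.loads(text)
        instructions = []
        for ins in obj["instructions"]:
            if ins[0] == "sum":
                instructions.append(("sum", tuple(ins[1])))
            elif ins[0] == "const":
                instructions.append(("const",))
            else:
                instructions.append((ins[0], *ins[1:]))
        return cls(instructions, list(obj["outputs"]), obj["n_atoms"])


def build_evaluation_scheme(basis) -> EvaluationScheme:
    """Compile a basis (fragment or merged) into an :class:`EvaluationScheme`.

    Every distinct orbit monomial is computed exactly once; monomials of
    degree >= 2 are products of two previously computed monomials (split by
    peeling one power of the first variable), so shared sub-monomials are
    reused across the whole basis rather than re-evaluated per PIP.
    """
    instructions: list[tuple] = []
    index_of: dict[SparseMonomial, int] = {}

    def emit(ins: tuple) -> int:
        instructions.append(ins)
        return len(instructions) - 1

    def mono_entry(m: SparseMonomial) -> int:
        if m in index_of:
            return index_of[m]
        if len(m) == 0:
            k = emit(("const",))
        elif len(m) == 1 and m[0][1] == 1:
            k = emit(("var", m[0][0]))
        else:
            l0, e0 = m[0]
            head: SparseMonomial = ((l0, 1),)
            if e0 == 1:
                tail = m[1:]
            else:
                tail = ((l0, e0 - 1),) + m[1:]
            a = mono_entry(head)
            b = mono_entry(tail)
            k = emit(("mul", a, b))
        index_of[m] = k
        return k

    outputs = []
    for p in basis.pips:
        terms = tuple(mono_entry(m) for m in p.orbit)
        if len(terms) == 1:
            outputs.append(terms[0])
        else:
            outputs.append(emit(("sum", terms)))
    return EvaluationScheme(instructions, outputs, basis.n_atoms)


def evaluate_basis(basis, morse: MorseVector | np.ndarray) -> np.ndarray:
    """Direct orbit-sum values of every PIP at a Morse vector.

    This is the defining (oracle) evaluation path; compile with
    :func:`build_evaluation_scheme` for the fast path.  Raises if the Morse
    vector does not cover all variables the basis touches.
    """
    x = morse.values if isinstance(morse, MorseVector) else np.asarray(morse)
    needed = max((l for p in basis.pips for m in p.orbit for l, _ in m), default=-1)
    if needed >= len(x):
        raise ValueError(
            f"basis touches variable {needed} but Morse vector has {len(x)}"
        )
    return np.array([p.value(x) for p in basis.pips])


def basis_jacobian(basis, morse: MorseVector | np.ndarray, n_vars: int | None = None) -> np.ndarray:
    """Dense Jacobian dP_i/dx_l of shape (n_p, n_vars).

    Uses d(x^e)/dx_l = e_l * x^e / x_l, valid since Morse variables are
    strictly positive.
    """
    x = morse.values if isinstance(morse, MorseVector) else np.asarray(morse)
    if n_vars is None:
        n_vars = len(x)
    J = np.zeros((len(basis.pips), n_vars))
    for i, p in enumerate(basis.pips):
        for m in p.orbit:
            prod = 1.0
            for l, e in m:
                prod *= x[l] ** e
            for l, e in m:
                J[i, l] += e * prod / x[l]
    return J


# ---------------------------------------------------------------------------
# Basis serialization (structured text, JSON)
# ---------------------------------------------------------------------------


def basis_to_json(basis, extra: dict | None = None) -> str:
    """Serialize a basis: per PIP its degree and orbit exponent maps over
    parent pair indices, plus the compiled evaluation scheme."""
    scheme = build_evaluation_scheme(basis)
    obj = {
        "n_atoms": basis.n_atoms,
        "max_degree": getattr(basis, "max_degree", None),
        "pips": [
            {
                "index": i,
                "degree": p.degree,
                "orbit": [[[l, e] for l, e in m] for m in p.orbit],
            }
            for i, p in enumerate(basis.pips)
        ],
        "scheme": json.loads(scheme.to_json()),
    }
    if extra:
        obj.update(extra)
    return json.dumps(obj)


def pips_from_json(text: str) -> tuple[list[PIP], int, dict]:
    """Inverse of :func:`basis_to_json`; returns (pips, n_atoms, raw object)."""
    obj = json.loads(text)
    nv = n_pairs(int(obj["n_atoms"]))
    pips = []
    for rec in obj["pips"]:
        orbit = tuple(
            sorted(
                (tuple((int(l), int(e)) for l, e in m) for m in rec["orbit"]),
                key=lambda m: dense_key(m, nv),
            )
        )
        pips.append(PIP(int(rec["degree"]), orbit[0], orbit))
    return pips, int(obj["n_atoms"]), obj
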