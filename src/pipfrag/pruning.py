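"""Post-fit basis shrinking and growth scored at maximum Morse values.

The score of a polynomial is its value at the vector of per-variable
maxima over the fitting dataset — an upper-envelope proxy for how much the
term can ever contribute.  Pruning removes the lowest-scoring terms (never
the constant); extension forms pairwise products of existing PIPs up to a
target degree, re-symmetrizes them into canonical orbits, discards those
already present, and adds the highest-scoring newcomers.  Both operations
preserve whatever permutational invariance the input basis had.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .basis import PIP, apply_action_sparse, dense_key
from .fragments import MergedBasis, merged_from_pips
from .geometry import Dataset, morse_variables, n_pairs
from .symmetry import build_group, induced_pair_action


@dataclass(frozen=True)
class VariableMaxima:
    """Per-variable maximum Morse value over a dataset, for the retained
    variables of a basis (values in (0, 1])."""

    variables: tuple[int, ...]  # 0-based parent pair indices
    maxima: np.ndarray
    lam: float

    def full_vector(self, n_vars: int) -> np.ndarray:
        """Length-n_vars vector with zeros at excluded variables."""
        out = np.zeros(n_vars)
        out[list(self.variables)] = self.maxima
        return out


def max_morse_values(
    ds: Dataset, variables, lam: float = 2.0
) -> VariableMaxima:
    """Elementwise maximum of the Morse variables over all records."""
    if len(ds) == 0:
        raise ValueError("empty dataset")
    variables = tuple(variables)
    maxima = None
    for rec in ds:
        x = morse_variables(rec.geometry, lam).values[list(variables)]
        maxima = x if maxima is None else np.maximum(maxima, x)
    return VariableMaxima(variables, maxima, lam)


def score_pips(basis, maxima: VariableMaxima) -> np.ndarray:
    """Each PIP evaluated at the maxima vector."""
    xmax = maxima.full_vector(n_pairs(basis.n_atoms))
    return np.array([p.value(xmax) for p in basis.pips])


def prune_basis(
    basis: MergedBasis, maxima: VariableMaxima, k_remove: int
) -> MergedBasis:
    """Remove the ``k_remove`` lowest-scoring polynomials.

    The constant term is never removable; score ties are broken by
    removing the higher-index polynomial first.  The result is renumbered.
    """
    if not (0 <= k_remove < len(basis.pips)):
        raise ValueError(
            f"k_remove must be in [0, {len(basis.pips)}), got {k_remove}"
        )
    scores = score_pips(basis, maxima)
    # sort by (score asc, index desc): low scores first, ties resolved by
    # discarding the higher index first
    order = sorted(
        range(len(basis.pips)),
        key=lambda i: (scores[i], -i),
    )
    removable = [i for i in order if not basis.pips[i].is_constant]
    drop = set(removable[:k_remove])
    kept = [p for i, p in enumerate(basis.pips) if i not in drop]
    return merged_from_pips(basis, kept)


def extend_basis(
    basis: MergedBasis,
    maxima: VariableMaxima,
    target_degree: int,
    k_add: int,
) -> MergedBasis:
    """Add up to ``k_add`` new polynomials built as products of existing ones.

    Candidates are pairwise products of nonconstant PIPs with combined
    degree <= ``target_degree``.  A product of invariants is invariant but
    generally spans several monomial orbits of the allowed group, so each
    product is decomposed into canonical orbits before scoring; orbits
    already in the basis are discarded.  The ``k_add`` highest-scoring
    candidates are added (ties broken toward the canonically smaller
    orbit), and the result is renumbered.
    """
    if target_degree < basis.max_degree:
        raise ValueError(
            f"target_degree {target_degree} below basis max degree {basis.max_degree}"
        )
    nv = n_pairs(basis.n_atoms)
    group = build_group(basis.allowed_blocks)
    actions = [induced_pair_action(g, basis.n_atoms) for g in group]
    existing = {p.key for p in basis.pips}
    candidates: dict[tuple, PIP] = {}
    pips = [p for p in basis.pips if not p.is_constant]
    for i, a in enumerate(pips):
        for b in pips[i:]:
            deg = a.degree + b.degree
            if deg > target_degree:
                continue
            monos = {
                tuple(
                    sorted(
                        {
                            l: e for l, e in _mono_product(ma, mb).items()
                        }.items()
                    )
                )
                for ma in a.orbit
                for mb in b.orbit
            }
            while monos:
                m = monos.pop()
                orbit = {apply_action_sparse(m, act) for act in actions}
                monos -= orbit
                orb = tuple(sorted(orbit, key=lambda t: dense_key(t, nv)))
                if orb in existing or orb in candidates:
                    continue
                candidates[orb] = PIP(sum(e for _, e in m), orb[0], orb)
    if not candidates:
        raise ValueError("zero extension candidates at this target degree")
    xmax = maxima.full_vector(nv)
    ranked = sorted(
        candidates.values(),
        key=lambda p: (-p.value(xmax), dense_key(p.representative, nv), p.orbit),
    )
    added = ranked[:k_add]
    return merged_from_pips(
        basis, list(basis.pips) + added, max_degree=target_degree
    )


def _mono_product(ma, mb) -> dict[int, int]:
    out: dict[int, int] = {}
    for l, e in ma:
        out[l] = out.get(l, 0) + e
    for l, e in mb:
        out[l] = out.get(l, 0) + e
    return out
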