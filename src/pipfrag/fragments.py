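"""Merging fragment bases: variable union, duplicate deletion, renumbering.

The fitted surface of a fragmented molecule is a single linear expansion
over the union of the fragments' PIP bases, all expressed in the parent's
pair indexing.  Fragments overlap, so the union contains duplicates — two
fragments sharing atoms produce literally identical polynomials over the
shared pair variables — and those are deleted here.

Two PIPs are duplicates iff their full orbit monomial sets over parent
pair indices coincide (identical functions).  The canonical orbit — not
the representative alone — is the dedup key: fragments with different
symmetry blocks can give the same representative with different orbits,
which are different functions and must both be kept.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Sequence

from .basis import PIP, FragmentBasis, sort_key
from .geometry import n_pairs, pair_order
from .symmetry import FragmentSpec, SymmetrySpec, parent_allowed_blocks


def union_variables(
    fragments: Sequence[FragmentSpec], parent_n_atoms: int
) -> tuple[list[int], list[tuple[int, int]]]:
    """Retained and excluded pair variables of a fragmentation.

    Retained = union over fragments of intra-fragment pairs (0-based parent
    pair indices, sorted); excluded = the remaining parent pairs, returned
    as 1-based (i, j) atom tuples.  Pairs of atoms never co-fragmented get
    Morse variables that are assumed zero and drop out of the basis.
    """
    pairs = pair_order(parent_n_atoms)
    idx = {p: k for k, p in enumerate(pairs)}
    retained: set[int] = set()
    for frag in fragments:
        al = frag.atoms
        for i in range(len(al)):
            for j in range(i + 1, len(al)):
                a, b = sorted((al[i], al[j]))
                retained.add(idx[(a, b)])
    excluded = [pairs[k] for k in range(len(pairs)) if k not in retained]
    return sorted(retained), excluded


@dataclass
class MergedBasis:
    """Deduplicated, renumbered union of fragment PIP bases.

    ``pips`` are in grade-lexicographic order over parent pair indices.
    ``provenance[i]`` lists the fragment indices whose bases contained PIP
    i; ``renumbering[f]`` maps fragment f's local PIP indices to merged
    indices.  ``allowed_blocks`` is the largest parent-level symmetry
    consistent with all fragments — the group under which any surface
    fitted in this basis is invariant.
    """

    pips: list[PIP]
    n_atoms: int
    fragments: tuple[FragmentSpec, ...]
    variables: list[int]
    excluded_pairs: list[tuple[int, int]]
    provenance: list[tuple[int, ...]]
    renumbering: list[dict[int, int]]
    duplicate_count: int
    max_degree: int
    allowed_blocks: SymmetrySpec

    def __len__(self) -> int:
        return len(self.pips)

    def keys(self) -> set:
        return {p.key for p in self.pips}

    def counts_report(self) -> dict:
        """The counts a merge run logs: sizes, duplicates, variables."""
        return {
            "n_atoms": self.n_atoms,
            "max_degree": self.max_degree,
            "n_fragments": len(self.fragments),
            "fragment_sizes": [len(r) for r in self.renumbering],
            "retained_variables": len(self.variables),
            "excluded_pairs": len(self.excluded_pairs),
            "concatenated": len(self.pips) + self.duplicate_count,
            "duplicates_removed": self.duplicate_count,
            "unique": len(self.pips),
        }


def merge_and_deduplicate(bases: Sequence[FragmentBasis]) -> MergedBasis:
    """Merge fragment bases, delete duplicated polynomials, renumber.

    First occurrence (in fragment list order) of each canonical orbit key
    wins; exactly one constant term survives since every fragment's
    constant has the same (empty) orbit.  The result is independent of
    fragment order up to renumbering.
    """
    if not bases:
        raise ValueError("no bases to merge")
    n_atoms = bases[0].n_atoms
    max_degree = max(b.max_degree for b in bases)
    for b in bases:
        if b.n_atoms != n_atoms:
            raise ValueError("bases disagree on parent atom count")
    fragments = tuple(b.fragment for b in bases)
    variables, excluded = union_variables(fragments, n_atoms)

    by_key: dict[tuple, PIP] = {}
    prov: dict[tuple, list[int]] = {}
    frag_local: list[list[tuple]] = []  # per fragment: local index -> key
    total = 0
    for f, b in enumerate(bases):
        local_keys = []
        for p in b.pips:
            total += 1
            k = p.key
            local_keys.append(k)
            if k not in by_key:
                by_key[k] = p
                prov[k] = [f]
            elif f not in prov[k]:
                prov[k].append(f)
        frag_local.append(local_keys)

    # Advisory consistency: an inconsistent fragmentation still merges, but
    # no parent-level invariance can be promised — the allowed group is then
    # trivial.
    try:
        allowed = parent_allowed_blocks(fragments)
    except Exception:
        allowed = SymmetrySpec(())

    nv = n_pairs(n_atoms)
    merged = sorted(by_key.values(), key=lambda p: sort_key(p, nv))
    index_of = {p.key: i for i, p in enumerate(merged)}
    renumbering = [
        {j: index_of[k] for j, k in enumerate(local)} for local in frag_local
    ]
    provenance = [tuple(prov[p.key]) for p in merged]
    return MergedBasis(
        pips=merged,
        n_atoms=n_atoms,
        fragments=fragments,
        variables=variables,
        excluded_pairs=excluded,
        provenance=provenance,
        renumbering=renumbering,
        duplicate_count=total - len(merged),
        max_degree=max_degree,
        allowed_blocks=allowed,
    )


def merged_from_pips(
    template: MergedBasis, pips: Sequence[PIP], max_degree: int | None = None
) -> MergedBasis:
    """A new MergedBasis with the same fragmentation metadata but a
    different PIP list (used by pruning/extension); re-sorted, renumbered,
    duplicate-free."""
    nv = n_pairs(template.n_atoms)
    seen: dict[tuple, PIP] = {}
    for p in pips:
        seen.setdefault(p.key, p)
    ordered = sorted(seen.values(), key=lambda p: sort_key(p, nv))
    return MergedBasis(
        pips=ordered,
        n_atoms=template.n_atoms,
        fragments=template.fragments,
        variables=template.variables,
        excluded_pairs=template.excluded_pairs,
        provenance=[()] * len(ordered),
        renumbering=[],
        duplicate_count=0,
        max_degree=max_degree if max_degree is not None else template.max_degree,
        allowed_blocks=template.allowed_blocks,
    )
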