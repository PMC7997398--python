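"""Permutational symmetry: groups, their action on pair variables, and counting.

A symmetry specification lists blocks of atoms that are allowed to permute
among one another, e.g. ``{3, 1, 1, 1, 1, 1, 1}`` with atom listing
``{1, 2, 3, 4, 5, 6, 7, 8, 9}`` declares that atoms 1-3 (a methyl's
hydrogens) permute and the rest are fixed.  The group is the direct product
of the symmetric groups on each block.

An atom permutation sigma induces a permutation of the pair variables,
(i, j) -> (sigma(i), sigma(j)) as unordered pairs; every invariance notion
in this package is phrased through that induced action.

:func:`burnside_count` counts monomial orbits in closed form (averaging
fixed-point counts over the group via the cycle structure of the induced
action) and serves as the independent oracle for the sizes of enumeratively
generated bases.
"""

from __future__ import annotations

import itertools
import math
from dataclasses import dataclass, field
from typing import Mapping, Sequence

import numpy as np

from .geometry import pair_order


class SymmetrySpecError(ValueError):
    """Invalid symmetry specification (duplicate atoms, bad block sizes...)."""


@dataclass(frozen=True)
class SymmetrySpec:
    """Permuting blocks of (1-based) atom indices.

    ``blocks`` stores the atoms grouped by block, e.g. ``((1, 2, 3), (4,),
    (5,))``.  Singleton blocks are allowed but contribute nothing to the
    group; atoms absent from every block are implicitly fixed.
    """

    blocks: tuple[tuple[int, ...], ...]

    def __post_init__(self):
        blocks = tuple(tuple(int(a) for a in b) for b in self.blocks)
        flat = [a for b in blocks for a in b]
        if any(len(b) < 1 for b in blocks):
            raise SymmetrySpecError("empty block")
        if len(set(flat)) != len(flat):
            raise SymmetrySpecError(f"duplicate atom indices in {blocks}")
        if any(a < 1 for a in flat):
            raise SymmetrySpecError("atom indices are 1-based positive integers")
        object.__setattr__(self, "blocks", blocks)

    @classmethod
    def from_sizes(
        cls, sizes: Sequence[int], atom_listing: Sequence[int]
    ) -> "SymmetrySpec":
        """Build from block sizes plus a flat atom listing, e.g.
        ``from_sizes([3, 1, 1, 1, 1, 1, 1], [1, 2, 3, 4, 5, 6, 7, 8, 9])``."""
        if sum(sizes) != len(atom_listing):
            raise SymmetrySpecError(
                f"block sizes sum to {sum(sizes)} but {len(atom_listing)} atoms listed"
            )
        blocks, k = [], 0
        for s in sizes:
            if s < 1:
                raise SymmetrySpecError(f"block size {s} < 1")
            blocks.append(tuple(atom_listing[k : k + s]))
            k += s
        return cls(tuple(blocks))

    @classmethod
    def trivial(cls) -> "SymmetrySpec":
        return cls(())

    @property
    def sizes(self) -> tuple[int, ...]:
        return tuple(len(b) for b in self.blocks)

    @property
    def atoms(self) -> tuple[int, ...]:
        return tuple(a for b in self.blocks for a in b)

    @property
    def order(self) -> int:
        """Group order: product of block factorials."""
        return math.prod(math.factorial(len(b)) for b in self.blocks)

    def permuting_blocks(self) -> tuple[tuple[int, ...], ...]:
        """Blocks of size >= 2 (the ones that generate nontrivial permutations)."""
        return tuple(b for b in self.blocks if len(b) >= 2)

    def relabelled(self, mapping: Mapping[int, int]) -> "SymmetrySpec":
        return SymmetrySpec(tuple(tuple(mapping[a] for a in b) for b in self.blocks))


@dataclass(frozen=True)
class FragmentSpec:
    """A fragment: an ordered list of parent atom indices plus its symmetry."""

    atoms: tuple[int, ...]
    symmetry: SymmetrySpec

    def __post_init__(self):
        atoms = tuple(int(a) for a in self.atoms)
        if len(atoms) < 2:
            raise SymmetrySpecError("a fragment needs at least 2 atoms")
        if len(set(atoms)) != len(atoms):
            raise SymmetrySpecError(f"duplicate atoms in fragment {atoms}")
        missing = set(self.symmetry.atoms) - set(atoms)
        if missing:
            raise SymmetrySpecError(
                f"symmetry references atoms {sorted(missing)} outside fragment"
            )
        object.__setattr__(self, "atoms", atoms)

    @property
    def n_atoms(self) -> int:
        return len(self.atoms)


@dataclass(frozen=True)
class PermutationGroup:
    """A finite group of atom permutations, each a dict {atom: image}
    (atoms not listed are fixed)."""

    elements: tuple[dict, ...]

    def __len__(self) -> int:
        return len(self.elements)

    def __iter__(self):
        return iter(self.elements)

    @property
    def order(self) -> int:
        return len(self.elements)


def build_group(spec: SymmetrySpec) -> PermutationGroup:
    """Direct product of symmetric groups on the spec's blocks."""
    per_block = [list(itertools.permutations(b)) for b in spec.blocks]
    elements = []
    for combo in itertools.product(*per_block):
        g: dict[int, int] = {}
        for blk, img in zip(spec.blocks, combo):
            for a, b in zip(blk, img):
                if a != b:
                    g[a] = b
        elements.append(g)
    if not elements:
        elements = [{}]
    return PermutationGroup(tuple(elements))


def induced_pair_action(perm: Mapping[int, int], n_atoms: int) -> np.ndarray:
    """Permutation of pair-variable positions induced by an atom permutation.

    Returns a 0-based array ``act`` with ``act[l] = l'`` meaning variable l
    (pair (i, j)) maps to variable l' (pair (sigma(i), sigma(j))).  Applying
    it to an exponent vector e gives the image f with ``f[act] = e``.
    """
    pairs = pair_order(n_atoms)
    idx = {p: k for k, p in enumerate(pairs)}
    domain = set(perm)
    image = set(perm.values())
    if domain != image:
        raise ValueError(f"not a bijection: domain {domain} != image {image}")
    act = np.empty(len(pairs), dtype=np.int64)
    for k, (i, j) in enumerate(pairs):
        a, b = perm.get(i, i), perm.get(j, j)
        if a > b:
            a, b = b, a
        act[k] = idx[(a, b)]
    return act


def pair_actions(group: PermutationGroup, n_atoms: int) -> list[np.ndarray]:
    return [induced_pair_action(g, n_atoms) for g in group]


@dataclass(frozen=True)
class Violation:
    fragment_index: int
    block: tuple[int, ...]
    present: tuple[int, ...]
    missing: tuple[int, ...]
    reason: str


@dataclass
class ValidationReport:
    passed: bool
    violations: list[Violation] = field(default_factory=list)

    def __str__(self) -> str:
        if self.passed:
            return "PASS"
        lines = ["FAIL"]
        for v in self.violations:
            lines.append(
                f"  fragment {v.fragment_index}: block {v.block} — {v.reason} "
                f"(present {v.present}, missing {v.missing})"
            )
        return "\n".join(lines)


def validate_fragmentation(
    parent: SymmetrySpec, fragments: Sequence[FragmentSpec]
) -> ValidationReport:
    """Check the permutational-consistency rule for a fragmentation.

    Atoms assigned to permute with one another at the parent level must
    appear together whenever they appear in any fragment, and must there be
    assigned to a single permuting block of that fragment's symmetry.
    Violations are reported, not raised: choosing lower symmetry than the
    molecule admits is legitimate, so validation is advisory by default.
    """
    violations: list[Violation] = []
    for block in parent.permuting_blocks():
        bset = set(block)
        for fi, frag in enumerate(fragments):
            fset = set(frag.atoms)
            present = tuple(sorted(bset & fset))
            if not present:
                continue
            missing = tuple(sorted(bset - fset))
            if missing:
                violations.append(
                    Violation(
                        fi, block, present, missing,
                        "parent permuting block only partially present",
                    )
                )
                continue
            # block fully present: must sit inside one permuting block
            hit = [
                fb for fb in frag.symmetry.blocks if bset <= set(fb)
            ]
            if not hit:
                violations.append(
                    Violation(
                        fi, block, present, (),
                        "block atoms present but not assigned to one "
                        "permuting block of the fragment",
                    )
                )
    return ValidationReport(not violations, violations)


def parent_allowed_blocks(fragments: Sequence[FragmentSpec]) -> SymmetrySpec:
    """Largest parent-level block structure consistent with all fragments.

    Two atoms are allowed to permute at the parent level when some fragment
    assigns them to one block; the relation is closed transitively.  The
    resulting spec is validated against every fragment and is the group
    under which a fitted fragmented surface is invariant.
    """
    parent_of: dict[int, int] = {}

    def find(a: int) -> int:
        while parent_of.get(a, a) != a:
            parent_of[a] = parent_of.get(parent_of[a], parent_of[a])
            a = parent_of[a]
        return a

    def union(a: int, b: int) -> None:
        ra, rb = find(a), find(b)
        if ra != rb:
            parent_of[ra] = rb

    for frag in fragments:
        for block in frag.symmetry.permuting_blocks():
            for a in block[1:]:
                union(block[0], a)
    groups: dict[int, list[int]] = {}
    for frag in fragments:
        for block in frag.symmetry.permuting_blocks():
            for a in block:
                groups.setdefault(find(a), []).append(a)
    blocks = tuple(
        tuple(sorted(set(v))) for _, v in sorted(groups.items())
    )
    spec = SymmetrySpec(blocks)
    report = validate_fragmentation(spec, fragments)
    if not report.passed:
        raise SymmetrySpecError(
            "fragment symmetries are mutually inconsistent:\n" + str(report)
        )
    return spec


def _cycle_lengths(perm: np.ndarray) -> list[int]:
    n = len(perm)
    seen = np.zeros(n, dtype=bool)
    out = []
    for s in range(n):
        if seen[s]:
            continue
        length, c = 0, s
        while not seen[c]:
            seen[c] = True
            c = perm[c]
            length += 1
        out.append(length)
    return out


def burnside_count(
    spec: SymmetrySpec,
    n_atoms: int,
    max_degree: int,
    include_constant: bool = True,
) -> int:
    """Number of monomial orbits of total degree <= max_degree, in closed form.

    For each group element the number of monomials it fixes equals the
    number of exponent assignments constant on each cycle of its induced
    pair action, i.e. the number of solutions of sum_c e_c * L_c <= d over
    nonnegative integers (a coin-counting recurrence over the cycle lengths
    L_c).  Averaging over the group (Burnside / Cauchy-Frobenius) gives the
    orbit count.  No monomial is ever enumerated, which makes this the
    independent oracle for the enumerative basis generator.
    """
    if max_degree < 0:
        raise ValueError("max_degree must be >= 0")
    group = build_group(spec)
    total = 0
    for g in group:
        act = induced_pair_action(g, n_atoms)
        counts = [0] * (max_degree + 1)
        counts[0] = 1
        for L in _cycle_lengths(act):
            for deg in range(L, max_degree + 1):
                counts[deg] += counts[deg - L]
        total += sum(counts)
    orbits = total // group.order
    assert total % group.order == 0
    return orbits if include_constant else orbits - 1
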