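"""Reference fragmentation schemes for N-methylacetamide and glycine.

These encode the standard worked examples of the fragmented-basis method:

* *trans*-N-methylacetamide (NMA, CH3-NH-CO-CH3, 12 atoms).  Numbering:
  atoms 1-3 and 10-12 are the two methyl hydrogen triples; 4-9 are the
  backbone C, N, H(N), C, O, C atoms.  Only the hydrogens within each
  methyl are assigned to permute (the carbons could permute by the
  consistency rule but are deliberately left unpermuted).
* glycine (NH2-CH2-COOH, 10 atoms).  Numbering: 1 N, 2-3 amine H, 4 C
  (alpha), 5-6 methylene H, 7 carboxyl C, 8 carbonyl O, 9 hydroxyl O,
  10 hydroxyl H.  Blocks: the NH2 pair, the CH2 pair, and the two oxygens.

Also included: published harmonic wavenumbers for the glycine global
minimum — the DFT (B3LYP/aug-cc-pVDZ) benchmark alongside values from
third-order PIP surfaces (full molecule and three-fragment) — used as the
worked example for frequency mean-absolute-error bookkeeping.
"""

from __future__ import annotations

from .symmetry import FragmentSpec, SymmetrySpec

_S = SymmetrySpec.from_sizes

NMA_N_ATOMS = 12
GLYCINE_N_ATOMS = 10


def nma_full() -> list[FragmentSpec]:
    """Full-molecule NMA: one 12-atom fragment, symmetry {3,3,1,1,1,1,1,1}."""
    spec = _S([3, 3, 1, 1, 1, 1, 1, 1], [1, 2, 3, 10, 11, 12, 4, 5, 6, 7, 8, 9])
    return [FragmentSpec(tuple(range(1, 13)), spec)]


def nma_two_fragment() -> list[FragmentSpec]:
    """CH3-NHC-CO and C-NH-CO-CH3: two 9-atom fragments, {3,1,1,1,1,1,1} each."""
    return [
        FragmentSpec(
            (1, 2, 3, 4, 5, 6, 7, 8, 9),
            _S([3, 1, 1, 1, 1, 1, 1], [1, 2, 3, 4, 5, 6, 7, 8, 9]),
        ),
        FragmentSpec(
            (10, 11, 12, 4, 5, 6, 7, 8, 9),
            _S([3, 1, 1, 1, 1, 1, 1], [10, 11, 12, 4, 5, 6, 7, 8, 9]),
        ),
    ]


def nma_three_fragment() -> list[FragmentSpec]:
    """CH3-NH-C, N-CO-CH3 ({3,1,1,1,1} each) and C-NH-CO-C (no symmetry)."""
    return [
        FragmentSpec(
            (1, 2, 3, 4, 5, 6, 8), _S([3, 1, 1, 1, 1], [1, 2, 3, 4, 5, 6, 8])
        ),
        FragmentSpec(
            (10, 11, 12, 5, 7, 8, 9), _S([3, 1, 1, 1, 1], [10, 11, 12, 5, 7, 8, 9])
        ),
        FragmentSpec((4, 5, 6, 7, 8, 9), SymmetrySpec.trivial()),
    ]


def glycine_full() -> list[FragmentSpec]:
    """Full-molecule glycine: symmetry {2,2,2,1,1,1,1} (NH2, CH2, OO blocks)."""
    spec = _S([2, 2, 2, 1, 1, 1, 1], [2, 3, 5, 6, 8, 9, 1, 4, 7, 10])
    return [FragmentSpec(tuple(range(1, 11)), spec)]


def glycine_two_fragment() -> list[FragmentSpec]:
    """NH2-CH2 ({2,2,1,1}) and CH2-COOH ({2,2,1,1,1})."""
    return [
        FragmentSpec((2, 3, 5, 6, 1, 4), _S([2, 2, 1, 1], [2, 3, 5, 6, 1, 4])),
        FragmentSpec(
            (5, 6, 8, 9, 4, 7, 10), _S([2, 2, 1, 1, 1], [5, 6, 8, 9, 4, 7, 10])
        ),
    ]


def glycine_three_fragment() -> list[FragmentSpec]:
    """The two-fragment scheme plus NH2-COOH ({2,2,1,1,1})."""
    return glycine_two_fragment() + [
        FragmentSpec(
            (2, 3, 8, 9, 1, 7, 10), _S([2, 2, 1, 1, 1], [2, 3, 8, 9, 1, 7, 10])
        )
    ]


NAMED_SCHEMES = {
    "nma-full": nma_full,
    "nma-2frag": nma_two_fragment,
    "nma-3frag": nma_three_fragment,
    "glycine-full": glycine_full,
    "glycine-2frag": glycine_two_fragment,
    "glycine-3frag": glycine_three_fragment,
}

SCHEME_N_ATOMS = {
    "nma-full": NMA_N_ATOMS,
    "nma-2frag": NMA_N_ATOMS,
    "nma-3frag": NMA_N_ATOMS,
    "glycine-full": GLYCINE_N_ATOMS,
    "glycine-2frag": GLYCINE_N_ATOMS,
    "glycine-3frag": GLYCINE_N_ATOMS,
}

#: Harmonic wavenumbers (cm^-1) for the glycine global minimum: the DFT
#: benchmark and two third-order PIP surfaces, 24 modes each, matched order.
GLYCINE_FREQUENCIES = {
    "ab_initio": (
        61.7, 211.6, 256.0, 461.3, 512.3, 630.2, 648.4, 816.9, 908.3, 912.2,
        1122.6, 1160.9, 1176.2, 1297.8, 1371.8, 1385.0, 1437.3, 1656.6,
        1803.6, 3045.9, 3083.7, 3493.8, 3567.1, 3735.2,
    ),
    "third_order_full": (
        100.1, 231.2, 260.6, 466.1, 526.0, 631.6, 647.7, 820.6, 906.5, 918.4,
        1124.4, 1161.0, 1178.2, 1291.0, 1370.1, 1379.0, 1444.4, 1664.2,
        1793.3, 3037.3, 3041.3, 3466.4, 3547.5, 3704.1,
    ),
    "third_order_three_fragment": (
        34.7, 209.9, 238.6, 459.3, 531.6, 574.2, 641.6, 810.7, 898.5, 942.2,
        1129.3, 1148.4, 1158.1, 1288.2, 1357.7, 1374.2, 1443.7, 1674.6,
        1787.7, 3017.7, 3058.7, 3457.3, 3540.6, 3719.5,
    ),
}
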