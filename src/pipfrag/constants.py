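"""Physical constants and unit conversions (CODATA 2018).

Internal units throughout the package: lengths in bohr, energies in cm^-1,
gradients in cm^-1/bohr, masses in unified atomic mass units (u).
"""

#: Bohr radius in Angstrom.
BOHR_TO_ANGSTROM = 0.529177210903
ANGSTROM_TO_BOHR = 1.0 / BOHR_TO_ANGSTROM

#: Hartree expressed in cm^-1.
HARTREE_TO_CM = 219474.6313632
CM_TO_HARTREE = 1.0 / HARTREE_TO_CM

#: Unified atomic mass unit in electron masses.
AMU_TO_ME = 1822.888486209

#: Default Morse range parameter (bohr).
DEFAULT_LAMBDA = 2.0

#: Atomic masses (u) of the most abundant isotope, for harmonic analysis.
ATOMIC_MASSES = {
    "H": 1.00782503207,
    "D": 2.01410177785,
    "C": 12.0,
    "N": 14.0030740048,
    "O": 15.9949146196,
    "F": 18.99840322,
    "S": 31.97207100,
    "Cl": 34.96885268,
}
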