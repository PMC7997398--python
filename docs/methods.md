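# Methods

## Model

The potential is a linear expansion V = Σᵢ cᵢ pᵢ(**x**) in
permutationally invariant polynomials (PIPs) of Morse variables
x_l = exp(−r_l/λ), with one variable per unordered atom pair in a fixed
lexicographic order ((1,2), (1,3), …).  Internally all lengths are bohr,
energies cm⁻¹, gradients cm⁻¹/bohr, masses u.  λ defaults to 2 bohr (the
conventional choice; configurable everywhere it appears).  Energies in
datasets are treated as opaque cm⁻¹ values — absolute or relative to any
reference — since only differences and derivatives matter to the fit.

### Symmetry and PIP semantics

A symmetry specification is a list of atom blocks; the group is the
direct product of symmetric groups on the blocks, acting on pair
variables by (i,j) → (σ(i),σ(j)).  A PIP is *defined* as the sum of a
monomial over its orbit under this induced action.  Basis generation is
enumerative: all exponent vectors up to the maximum total degree are
listed (vectorized over numpy), and exactly those that are the
lexicographically least member of their orbit are kept.  The degree-0
orbit (the constant) is a basis member and is included in every count;
this convention is what reproduces standard published basis sizes.

Orbit counting by Burnside's lemma is implemented independently of the
generator: for each group element the number of fixed monomials of
degree ≤ d is the number of exponent assignments constant on each cycle
of its induced pair action (a coin-counting recurrence over cycle
lengths), averaged over the group.  The two routes must agree exactly;
the test suite enforces this on the published schemes and on random
specifications.

### Fragmentation and merging

Fragments are user-declared atom subsets with their own symmetry
blocks; fragment bases are generated in fragment-local variables and
re-expressed in parent pair indices.  Merging keeps the union, deleting
duplicates, where the duplicate key is the **full canonical orbit** over
parent pair indices, not the representative alone: fragments with
different blocks can produce the same representative with different
orbits, and only identical orbits are identical functions.  One constant
survives (all fragments share the empty orbit).  The merged basis is
renumbered grade-lexicographically (degree, then dense-vector order of
the representative, then the orbit as a tie-break), so renumbering is
deterministic and independent of fragment input order.

The consistency rule — atoms assigned to permute together must appear
together, inside one block, wherever they appear — is validated but
advisory: choosing *lower* symmetry than the molecule admits is
legitimate and common (e.g. declining to permute chemically equivalent
heavy atoms), and an inconsistent fragmentation still merges, with the
guaranteed invariance group reduced accordingly.  The "parent allowed
blocks" (the largest block structure consistent with all fragments) are
derived by transitively closing the fragments' block relations; a
surface fitted in the merged basis is invariant under exactly that
group.

### Fitting

The design matrix has one energy row per record (basis values) and, for
records with gradients, 3N rows per record assembled by the chain rule
through the sparse Morse Jacobian (∂x_l/∂a_{j,k} is nonzero only for the
two atoms of pair l).  Gradient rows and targets carry a weight w_g
(default 1; 0 omits them — the weighting any given study used is
generally unstated, so it is exposed rather than guessed).  The solve is
`numpy.linalg.lstsq` (SVD) with relative cutoff 1e-10 (configurable):
minimal-norm least squares tolerates the exact rank deficiency of
duplicate-containing bases, which is what makes "concatenated and
deduplicated bases give identical predictions" checkable.  An optional
min-zero energy shift is stored in the fit and added back on evaluation.

Gradient evaluation branches per atom: ∂V/∂a_{j,k} touches only the
N−1 variables whose pair contains atom j; the unbranched dense chain
rule is retained as a reference path and the two agree to ~1e-12.

### Numerical choices

* **Bit-exact permutation invariance.**  Direct orbit-sum evaluation
  accumulates the factors of each monomial and the terms of each orbit
  in sorted-value order.  Permuting the input by a group element maps
  those multisets onto themselves, so basis values — and hence V — are
  invariant *exactly* in floating point, not merely to reassociation
  error.  This matters because PIP fits routinely carry coefficients of
  magnitude 10⁶–10⁸ with heavy cancellation; invariance tied to
  reassociation would degrade with coefficient size.
* **Evaluation scheme.**  The compiled fast path computes every distinct
  orbit monomial once — degree ≥ 2 monomials as products of two earlier
  entries — and each PIP as a sum of monomial entries; it is required by
  test to match the direct orbit sums to 1e-10 and is the serialized
  artifact (JSON) that stands in for generated source code.  Derivation
  of deeper polynomial-times-polynomial recursions is treated purely as
  an optimization and is not attempted beyond monomial sharing.
* **Minimization.**  BFGS on Cartesians with the analytic gradient
  (default tolerance ‖∇V‖∞ < 1e-3 cm⁻¹/bohr, appropriate for surfaces
  with cm⁻¹-scale fit noise), followed by Newton polishing with the
  pseudo-inverted finite-difference Hessian when tighter tolerances are
  requested (the rigid-motion null space is handled by the SVD cutoff).
* **Hessian.**  Central differences of the *analytic* gradient (default
  step 1e-4 bohr), symmetrized as (H+Hᵀ)/2 — one differentiation level
  less noisy than double-differencing energies.
* **Frequencies.**  Eigenvalues of M^{−1/2} H M^{−1/2} in atomic units,
  converted via 219 474.63 cm⁻¹/hartree; negative-curvature modes are
  reported as magnitudes with an imaginary flag.  Linearity (5 vs 6
  rigid modes) is detected from the principal moments of inertia.
* **Degenerate geometries.**  Coincident atoms (r = 0, x = 1 exactly)
  are an error on fitting paths and a warning on evaluation paths.

### Pruning and extension

Polynomials are scored by their value at the vector of per-variable
maxima over the dataset — an upper envelope of the term's possible
contribution in the sampled region.  Pruning removes the k lowest
scores (never the constant; ties discard the higher index first).
Extension forms pairwise products of nonconstant PIPs up to the target
degree, decomposes each product into canonical orbits of the allowed
group *before* scoring (a product of invariants is invariant but
generally spans several orbits of the merged variable set), discards
orbits already present, and adds the k highest scorers (ties broken
toward the canonically smaller orbit).  Both operations renumber and
provably preserve the basis's permutational invariance.

## Synthetic data

The generator stands in for ab initio datasets (which are not shipped
with published studies of this method) while preserving their structure:
permutational symmetry, exact gradients, energies confined below a
ceiling around a minimum.

* **Pairwise-Morse surrogate**: Σ over pairs of D(1−e^{−α(r−r₀)})² with
  parameters keyed by unordered species pair, drawn once per seed from
  D ∈ [15 000, 45 000] cm⁻¹, α ∈ [0.8, 1.3] bohr⁻¹, r₀ ∈ [1.9, 3.2] bohr
  — covalent-bond-scale wells.  Exactly invariant under any same-species
  permutation, and *outside* the PIP model space (realistic fit
  residuals).
* **PIP-combo surrogate**: a fixed linear combination of a given basis —
  inside the model space by construction, so fitting must recover its
  predictions to solver precision (the end-to-end self-consistency
  oracle).

Sampling draws Gaussian Cartesian displacements (default σ = 0.08 bohr)
around the surrogate's own minimum and accepts a draw iff its energy
lies within the cutoff (default 10 000 cm⁻¹) of that minimum; stored
energies are relative to the minimum.  This reproduces the qualitative
shape of dynamics-sampled datasets — most points near the bottom of the
well, none above the ceiling — without modeling dynamics.  What it does
*not* emulate: anharmonic mode coupling of real wells, multiple
conformers, dissociative tails, or electronic-structure noise; passing
tests therefore demonstrate the machinery (counting, symmetrization,
merging, regression, derivatives), not chemical accuracy on real data.

Two toy systems ship: a 5-atom methyl-like A₃BC molecule (H₃CN) and a
6-atom A₂B₂CD molecule (H₂O₂CN), both small enough for brute-force
oracles (exhaustive orbit enumeration, value-based duplicate detection,
full finite-difference checks).

Test and example problem sizes (5–12 atoms, 40–80 records, bases up to
~47 000 terms for counting and ~100 terms for fitting) were chosen so
every oracle comparison stays brute-forceable; they are not limits of
the implementation.

## Known limitations

* Only direct products of symmetric groups on atom blocks are supported
  (the universe of this method); no general point-group machinery.
* Fragment discovery is the user's job; the package validates but never
  proposes fragmentations.
* Published fit errors (RMSE/RMSG) on real molecules are not
  reproducible here because the underlying ab initio datasets and the
  gradient weighting used are unavailable; the package anchors those
  behaviours to surrogates and invariants instead.
* The evaluation scheme optimizes monomial reuse only; wall-clock
  claims about deeper recursive factorizations are out of scope.
* No anharmonic analysis and no transition-state search; minima only.
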