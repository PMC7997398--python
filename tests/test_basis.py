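"""Monomial canonicalization, basis generation, and evaluation schemes."""

import math

import numpy as np
import pytest

import pipfrag as pf
from pipfrag.basis import (
    apply_action_sparse,
    build_evaluation_scheme,
    canonical_monomial,
    dense_key,
    evaluate_basis,
)
from pipfrag.symmetry import FragmentSpec, SymmetrySpec
from tests.conftest import random_geometry

S = SymmetrySpec.from_sizes


class TestCanonicalMonomial:
    def test_orbit_members_share_representative(self):
        spec = S([3], [1, 2, 3])
        group = pf.build_group(spec)
        actions = [pf.induced_pair_action(g, 3) for g in group]
        m = ((0, 1),)  # x(1,2)
        rep = canonical_monomial(m, actions, 3)
        for act in actions:
            img = apply_action_sparse(m, act)
            assert canonical_monomial(img, actions, 3) == rep

    def test_trivial_group_identity(self):
        actions = [np.arange(6)]
        m = ((2, 3), (5, 1))
        assert canonical_monomial(m, actions, 6) == m

    def test_full_triangle_orbit(self):
        """Atoms {1,2,3} fully permuting: the orbit of x(1,2) is all three
        pair variables."""
        spec = S([3], [1, 2, 3])
        group = pf.build_group(spec)
        actions = [pf.induced_pair_action(g, 3) for g in group]
        orbit = {apply_action_sparse(((0, 1),), act) for act in actions}
        assert orbit == {((0, 1),), ((1, 1),), ((2, 1),)}


class TestGenerateBasis:
    def test_two_atom_no_symmetry(self):
        frag = FragmentSpec((1, 2), SymmetrySpec(()))
        basis = pf.generate_basis(frag, 3, 2)
        assert len(basis) == 4  # 1, x, x^2, x^3
        degrees = [p.degree for p in basis.pips]
        assert degrees == [0, 1, 2, 3]

    def test_single_pair_values(self):
        frag = FragmentSpec((1, 2), SymmetrySpec(()))
        basis = pf.generate_basis(frag, 3, 2)
        vals = evaluate_basis(basis, np.array([0.5]))
        np.testing.assert_allclose(vals, [1.0, 0.5, 0.25, 0.125])

    @pytest.mark.parametrize(
        "atoms,sizes,listing,degree",
        [
            ((2, 3, 5, 6, 1, 4), [2, 2, 1, 1], [2, 3, 5, 6, 1, 4], 3),
            ((1, 2, 3, 4, 5), [3, 1, 1], [1, 2, 3, 4, 5], 4),
            ((1, 2, 3, 4), [2, 2], [1, 2, 3, 4], 3),
        ],
    )
    def test_size_matches_burnside_oracle(self, atoms, sizes, listing, degree):
        frag = FragmentSpec(atoms, S(sizes, listing))
        basis = pf.generate_basis(frag, degree, max(atoms))
        local = {a: i + 1 for i, a in enumerate(atoms)}
        oracle = pf.burnside_count(
            frag.symmetry.relabelled(local), len(atoms), degree
        )
        assert len(basis) == oracle

    def test_trivial_group_completeness(self):
        """With no symmetry the basis is every monomial: C(n_vars+d, d)."""
        frag = FragmentSpec((1, 2, 3, 4), SymmetrySpec(()))
        basis = pf.generate_basis(frag, 3, 4)
        assert len(basis) == math.comb(6 + 3, 3)

    def test_constant_is_first(self, a3bc_basis):
        assert a3bc_basis.pips[0].is_constant
        assert sum(p.is_constant for p in a3bc_basis.pips) == 1

    def test_orbit_invariants(self, a3bc_basis):
        group = pf.build_group(a3bc_basis.fragment.symmetry)
        actions = [pf.induced_pair_action(g, 5) for g in group]
        for p in a3bc_basis.pips[:30]:
            degrees = {sum(e for _, e in m) for m in p.orbit}
            assert degrees == {p.degree} or (p.degree == 0 and p.orbit == ((),))
            assert group.order % len(p.orbit) == 0
            for act in actions:
                assert {apply_action_sparse(m, act) for m in p.orbit} == set(p.orbit)

    def test_single_atom_fragment_rejected(self):
        with pytest.raises(Exception):
            FragmentSpec((1,), SymmetrySpec(()))


class TestEvaluationScheme:
    def test_power_chain(self):
        frag = FragmentSpec((1, 2), SymmetrySpec(()))
        basis = pf.generate_basis(frag, 3, 2)
        scheme = build_evaluation_scheme(basis)
        np.testing.assert_allclose(
            scheme.evaluate(np.array([0.5])), [1.0, 0.5, 0.25, 0.125]
        )
        muls = [ins for ins in scheme.instructions if ins[0] == "mul"]
        assert len(muls) == 2  # x^2 = x*x, x^3 = x*x^2

    def test_topological_order(self, a3bc_basis):
        scheme = build_evaluation_scheme(a3bc_basis)
        for k, ins in enumerate(scheme.instructions):
            if ins[0] == "mul":
                assert ins[1] < k and ins[2] < k
            elif ins[0] == "sum":
                assert all(t < k for t in ins[1])

    def test_matches_direct_orbit_sums(self, a3bc_basis, rng):
        scheme = build_evaluation_scheme(a3bc_basis)
        for _ in range(100):
            g = random_geometry(rng, ["H", "H", "H", "C", "N"])
            x = pf.morse_variables(g)
            direct = evaluate_basis(a3bc_basis, x)
            fast = scheme.evaluate(x.values)
            assert np.abs(direct - fast).max() < 1e-10

    def test_json_round_trip(self, a3bc_basis, rng):
        scheme = build_evaluation_scheme(a3bc_basis)
        back = pf.EvaluationScheme.from_json(scheme.to_json())
        g = random_geometry(rng, ["H", "H", "H", "C", "N"])
        x = pf.morse_variables(g).values
        np.testing.assert_array_equal(scheme.evaluate(x), back.evaluate(x))


class TestEvaluateBasis:
    def test_constant_pip_is_one(self, a3bc_basis, rng):
        g = random_geometry(rng, ["H", "H", "H", "C", "N"])
        vals = evaluate_basis(a3bc_basis, pf.morse_variables(g))
        assert vals[0] == 1.0

    def test_degree_one_triangle_value(self):
        """The symmetrized degree-1 PIP over an equilateral H3 triangle at
        r = 2 bohr, lambda = 2 equals 3/e."""
        frag = FragmentSpec((1, 2, 3), S([3], [1, 2, 3]))
        basis = pf.generate_basis(frag, 1, 3)
        s = 2.0
        g = pf.Geometry(
            ("H", "H", "H"),
            [[0, 0, 0], [s, 0, 0], [s / 2, s * math.sqrt(3) / 2, 0]],
        )
        vals = evaluate_basis(basis, pf.morse_variables(g, 2.0))
        assert len(vals) == 2
        assert vals[1] == pytest.approx(3 * math.exp(-1.0), rel=1e-12)

    def test_permutation_invariance(self, a3bc_basis, rng):
        group = pf.build_group(a3bc_basis.fragment.symmetry)
        for _ in range(10):
            g = random_geometry(rng, ["H", "H", "H", "C", "N"])
            base = evaluate_basis(a3bc_basis, pf.morse_variables(g))
            for perm in group:
                vals = evaluate_basis(
                    a3bc_basis, pf.morse_variables(g.permuted(perm))
                )
                assert np.abs(vals - base).max() < 1e-12

    def test_missing_variable_rejected(self, a3bc_basis):
        with pytest.raises(ValueError):
            evaluate_basis(a3bc_basis, np.ones(3))


class TestBasisJacobian:
    def test_matches_finite_differences(self, a3bc_basis, rng):
        g = random_geometry(rng, ["H", "H", "H", "C", "N"])
        x = pf.morse_variables(g).values
        J = pf.basis_jacobian(a3bc_basis, x)
        h = 1e-7
        for l in range(len(x)):
            xp, xm = x.copy(), x.copy()
            xp[l] += h
            xm[l] -= h
            fd = (
                evaluate_basis(a3bc_basis, xp) - evaluate_basis(a3bc_basis, xm)
            ) / (2 * h)
            np.testing.assert_allclose(J[:, l], fd, rtol=1e-5, atol=1e-8)
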