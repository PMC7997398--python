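"""Design matrix assembly, least-squares fitting, and surface evaluation."""

import numpy as np
import pytest

import pipfrag as pf
from pipfrag.fitting import design_matrix, rms_metrics
from pipfrag.fragments import merge_and_deduplicate
from pipfrag.symmetry import FragmentSpec, SymmetrySpec
from pipfrag.synthetic import make_surrogate, sample_dataset
from tests.conftest import random_geometry

S = SymmetrySpec.from_sizes


class TestDesignMatrix:
    def test_row_counts(self, a3bc_dataset, a3bc_basis):
        A, b = design_matrix(a3bc_dataset, a3bc_basis, gradient_weight=1.0)
        n = len(a3bc_dataset)
        assert A.shape == (n + n * 15, len(a3bc_basis))
        assert b.shape == (n + n * 15,)

    def test_zero_weight_omits_gradient_rows(self, a3bc_dataset, a3bc_basis):
        A, b = design_matrix(a3bc_dataset, a3bc_basis, gradient_weight=0.0)
        assert A.shape == (len(a3bc_dataset), len(a3bc_basis))

    def test_gradient_rows_match_finite_differences(self, a3bc_basis, rng):
        """Each gradient row is the Cartesian derivative of the energy-row
        entries, checked by central differences."""
        g = random_geometry(rng, ["H", "H", "H", "C", "N"])
        ds = pf.Dataset([pf.DataRecord(g, 0.0, np.zeros(15))])
        A, _ = design_matrix(ds, a3bc_basis, gradient_weight=1.0)
        h = 1e-5
        flat = g.coords.ravel()
        for k in range(15):
            fp, fm = flat.copy(), flat.copy()
            fp[k] += h
            fm[k] -= h
            ep = pf.evaluate_basis(
                a3bc_basis,
                pf.morse_variables(pf.Geometry(g.species, fp.reshape(-1, 3))),
            )
            em = pf.evaluate_basis(
                a3bc_basis,
                pf.morse_variables(pf.Geometry(g.species, fm.reshape(-1, 3))),
            )
            fd = (ep - em) / (2 * h)
            np.testing.assert_allclose(A[1 + k], fd, rtol=1e-5, atol=1e-10)


class TestFitCoefficients:
    def test_exact_linear_combination_recovered(self, a3bc_basis, rng):
        """Data generated as an exact basis combination is refit to
        numerical precision."""
        coeffs = 50.0 * rng.normal(size=len(a3bc_basis))
        pes = make_surrogate(
            ["H", "H", "H", "C", "N"], "pip-combo", seed=11,
            basis=a3bc_basis, coefficients=coeffs,
        )
        ref = pf.reference_geometry("a3bc")
        ds = sample_dataset(pes, ref, 40, sigma=0.08, e_cutoff=1e9, seed=2)
        assert len(ds) * (1 + 15) > len(a3bc_basis)
        fit = pf.fit_coefficients(ds, a3bc_basis)
        assert fit.rmse < 1e-6
        for rec in ds.records[:5]:
            assert pf.evaluate_potential(fit, rec.geometry) == pytest.approx(
                rec.energy, abs=1e-6
            )

    def test_duplicate_insensitivity(self, a3bc_basis, a3bc_dataset, rng):
        """Fitting with a duplicate-containing concatenated basis gives the
        same predictions as the deduplicated basis (minimal-norm SVD
        tolerates the rank deficiency), and identical training RMSE/RMSG on
        noisy data — mirroring equal error columns for original vs
        deduplicated bases."""
        b = a3bc_basis
        dup = merge_and_deduplicate([b, b])
        assert dup.duplicate_count == len(b)

        class Doubled:
            pips = b.pips + b.pips
            n_atoms = 5

        # exactly representable target: pointwise predictions coincide
        coeffs = 50.0 * rng.normal(size=len(b))
        pes = make_surrogate(
            ["H", "H", "H", "C", "N"], "pip-combo", seed=13,
            basis=b, coefficients=coeffs,
        )
        ds = sample_dataset(
            pes, pf.reference_geometry("a3bc"), 40, sigma=0.08,
            e_cutoff=1e9, seed=4,
        )
        fit_dedup = pf.fit_coefficients(ds, b)
        fit_doubled = pf.fit_coefficients(ds, Doubled())
        for rec in ds.records[:10]:
            v1 = pf.evaluate_potential(fit_dedup, rec.geometry)
            v2 = pf.evaluate_potential(fit_doubled, rec.geometry)
            assert abs(v1 - v2) < 1e-8

        # noisy target (surrogate outside the model space): identical
        # training errors well beyond printed precision
        fit1 = pf.fit_coefficients(a3bc_dataset, b)
        fit2 = pf.fit_coefficients(a3bc_dataset, Doubled())
        assert fit2.rmse == pytest.approx(fit1.rmse, rel=1e-6)
        assert fit2.rmsg == pytest.approx(fit1.rmsg, rel=1e-6)

    def test_zero_data_zero_fit(self, a3bc_dataset, a3bc_basis):
        zero = pf.Dataset(
            [
                pf.DataRecord(r.geometry, 0.0, np.zeros(15))
                for r in a3bc_dataset.records[:20]
            ]
        )
        fit = pf.fit_coefficients(zero, a3bc_basis)
        assert np.allclose(fit.coefficients, 0.0)
        assert fit.rmse == 0.0
        assert fit.rmsg == 0.0

    def test_empty_dataset_rejected(self, a3bc_basis):
        with pytest.raises(ValueError):
            pf.fit_coefficients(pf.Dataset([]), a3bc_basis)

    def test_nested_basis_rmse_monotone(self, a3bc_dataset):
        """Enlarging the basis never increases training RMSE."""
        frag = pf.FragmentSpec((1, 2, 3, 4, 5), S([3, 1, 1], [1, 2, 3, 4, 5]))
        rmses = []
        for deg in (1, 2, 3):
            b = pf.generate_basis(frag, deg, 5)
            # energy-only: RMSE is the minimized objective
            rmses.append(
                pf.fit_coefficients(a3bc_dataset, b, gradient_weight=0.0).rmse
            )
        assert rmses[0] >= rmses[1] >= rmses[2]


class TestEvaluate:
    def test_constant_only(self, a3bc_basis, rng):
        c = np.zeros(len(a3bc_basis))
        c[0] = 1234.5
        fit = pf.FitResult(c, a3bc_basis, 2.0, 1.0, 0.0, None)
        g = random_geometry(rng, ["H", "H", "H", "C", "N"])
        assert pf.evaluate_potential(fit, g) == pytest.approx(1234.5)
        assert np.allclose(pf.evaluate_gradient(fit, g), 0.0, atol=1e-12)

    def test_potential_invariance_under_allowed_permutations(
        self, a3bc_fit, a3bc_dataset
    ):
        """V is unchanged by any allowed permutation, checked at in-domain
        geometries (where |V| is on the fitted energy scale)."""
        group = pf.build_group(a3bc_fit.basis.fragment.symmetry)
        for rec in a3bc_dataset.records[:5]:
            g = rec.geometry
            v0 = pf.evaluate_potential(a3bc_fit, g)
            for perm in group:
                v = pf.evaluate_potential(a3bc_fit, g.permuted(perm))
                assert abs(v - v0) < 1e-9

    def test_gradient_matches_finite_differences(self, a3bc_fit, rng):
        g = random_geometry(rng, ["H", "H", "H", "C", "N"])
        grad = pf.evaluate_gradient(a3bc_fit, g)
        h = 1e-5
        flat = g.coords.ravel()
        fd = np.empty_like(grad)
        for k in range(flat.size):
            fp, fm = flat.copy(), flat.copy()
            fp[k] += h
            fm[k] -= h
            fd[k] = (
                pf.evaluate_potential(
                    a3bc_fit, pf.Geometry(g.species, fp.reshape(-1, 3))
                )
                - pf.evaluate_potential(
                    a3bc_fit, pf.Geometry(g.species, fm.reshape(-1, 3))
                )
            ) / (2 * h)
        scale = max(np.abs(grad).max(), 1.0)
        assert np.abs(grad - fd).max() / scale < 1e-6

    def test_translation_invariance(self, a3bc_fit, rng):
        """Distance-based surface: gradient components sum to zero per axis."""
        g = random_geometry(rng, ["H", "H", "H", "C", "N"])
        grad = pf.evaluate_gradient(a3bc_fit, g).reshape(-1, 3)
        assert np.abs(grad.sum(axis=0)).max() < 1e-8

    def test_branched_equals_unbranched(self, a3bc_fit, rng):
        for _ in range(10):
            g = random_geometry(rng, ["H", "H", "H", "C", "N"])
            gb = pf.evaluate_gradient(a3bc_fit, g, branched=True)
            gu = pf.evaluate_gradient(a3bc_fit, g, branched=False)
            assert np.abs(gb - gu).max() < 1e-12 * max(1.0, np.abs(gu).max())


class TestRmsMetrics:
    def test_plus_minus_one_residuals(self, a3bc_basis):
        g1 = pf.reference_geometry("a3bc")
        c = np.zeros(len(a3bc_basis))
        c[0] = 5.0  # predicts V = 5 everywhere
        fit = pf.FitResult(c, a3bc_basis, 2.0, 1.0, 0.0, None)
        ds = pf.Dataset([pf.DataRecord(g1, 6.0), pf.DataRecord(g1, 4.0)])
        rmse, rmsg = rms_metrics(fit, ds)
        assert rmse == pytest.approx(1.0)
        assert rmsg is None

    def test_training_rmse_stored(self, a3bc_fit, a3bc_dataset):
        rmse, rmsg = rms_metrics(a3bc_fit, a3bc_dataset)
        assert rmse == pytest.approx(a3bc_fit.rmse, rel=1e-12)
        assert rmsg == pytest.approx(a3bc_fit.rmsg, rel=1e-12)
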