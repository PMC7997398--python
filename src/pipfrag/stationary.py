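"""Stationary-point and harmonic analysis on a fitted surface.

Minima are located by quasi-Newton descent on the Cartesian coordinates
with the analytic gradient; the Hessian is built by central finite
differences of that analytic gradient (one differentiation level less
noisy than double-differencing energies); harmonic wavenumbers come from
the eigenvalues of the mass-scaled Hessian M^{-1/2} H M^{-1/2}.  Six
eigenvalues (five for a linear molecule) are near zero — rigid
translations and rotations — and are split off by magnitude after
linearity detection via the principal moments of inertia.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Optional, Sequence

import numpy as np
from scipy.optimize import minimize

from .constants import AMU_TO_ME, ATOMIC_MASSES, HARTREE_TO_CM
from .fitting import FitResult, evaluate_gradient, evaluate_potential
from .geometry import Geometry


class MinimizationError(RuntimeError):
    """Gradient descent failed to reach the tolerance; carries the last iterate."""

    def __init__(self, message: str, last_geometry: Geometry):
        super().__init__(message)
        self.last_geometry = last_geometry


def minimize_geometry(
    fit: FitResult,
    start: Geometry,
    tol: float = 1e-3,
    max_iter: int = 2000,
) -> Geometry:
    """Locate a minimum of the fitted surface near ``start``.

    BFGS on the flattened Cartesians with the analytic gradient; converged
    when the max-norm of the gradient is below ``tol`` (cm^-1/bohr).
    """
    species = start.species

    def fun(flat: np.ndarray) -> float:
        return evaluate_potential(fit, Geometry(species, flat.reshape(-1, 3)))

    def jac(flat: np.ndarray) -> np.ndarray:
        return evaluate_gradient(fit, Geometry(species, flat.reshape(-1, 3)))

    res = minimize(
        fun,
        start.coords.ravel(),
        jac=jac,
        method="BFGS",
        options={"gtol": tol, "maxiter": max_iter},
    )
    x = res.x
    # BFGS line searches stall near machine precision of the energy; a few
    # Newton steps (pseudo-inverse Hessian, null space = rigid motions)
    # polish the gradient down to tight tolerances.
    for _ in range(25):
        g = jac(x)
        if np.abs(g).max() <= tol:
            break
        H = hessian(fit, Geometry(species, x.reshape(-1, 3)))
        dx = np.linalg.lstsq(H, -g, rcond=1e-10)[0]
        if fun(x + dx) <= fun(x):
            x = x + dx
        else:
            x = x + 0.2 * dx
    geom = Geometry(species, x.reshape(-1, 3))
    if np.abs(evaluate_gradient(fit, geom)).max() > tol:
        raise MinimizationError(
            f"no convergence in {max_iter} iterations "
            f"(|grad|_inf = {np.abs(evaluate_gradient(fit, geom)).max():.3e})",
            geom,
        )
    return geom


def hessian(fit: FitResult, geom: Geometry, step: float = 1e-4) -> np.ndarray:
    """Symmetric (3N, 3N) Hessian in cm^-1/bohr^2 by central differences of
    the analytic gradient, symmetrized as (H + H^T)/2."""
    n3 = 3 * geom.n_atoms
    H = np.empty((n3, n3))
    flat = geom.coords.ravel()
    for k in range(n3):
        fp = flat.copy()
        fp[k] += step
        fm = flat.copy()
        fm[k] -= step
        gp = evaluate_gradient(fit, Geometry(geom.species, fp.reshape(-1, 3)))
        gm = evaluate_gradient(fit, Geometry(geom.species, fm.reshape(-1, 3)))
        H[k] = (gp - gm) / (2 * step)
    return 0.5 * (H + H.T)


def harmonic_frequencies(
    H: np.ndarray, masses: Sequence[float]
) -> tuple[np.ndarray, np.ndarray]:
    """Wavenumbers from a Cartesian Hessian.

    ``H`` in cm^-1/bohr^2; ``masses`` in u (one per atom).  Returns
    ``(wavenumbers, imaginary)``: all 3N wavenumbers in cm^-1 sorted
    ascending, with negative-curvature modes reported as the magnitude of
    the imaginary wavenumber and flagged True in ``imaginary``.
    """
    if not np.isfinite(H).all():
        raise ValueError("non-finite Hessian")
    masses = np.asarray(masses, dtype=float)
    if np.any(masses <= 0):
        raise ValueError("masses must be positive")
    # cm^-1/bohr^2 -> hartree/bohr^2, u -> m_e: eigenvalues in atomic units
    # of angular frequency squared; sqrt then hartree -> cm^-1.
    m3 = np.repeat(masses * AMU_TO_ME, 3)
    Hw = (H / HARTREE_TO_CM) / np.sqrt(np.outer(m3, m3))
    eig = np.linalg.eigvalsh(Hw)
    wavenumbers = np.sqrt(np.abs(eig)) * HARTREE_TO_CM
    imaginary = eig < 0
    order = np.argsort(np.where(imaginary, -wavenumbers, wavenumbers))
    return wavenumbers[order], imaginary[order]


def is_linear(geom: Geometry, masses: Sequence[float], rel_tol: float = 1e-6) -> bool:
    """Linearity by principal moments of inertia: smallest moment
    negligible relative to the largest."""
    masses = np.asarray(masses, dtype=float)
    com = (masses[:, None] * geom.coords).sum(axis=0) / masses.sum()
    d = geom.coords - com
    I = np.zeros((3, 3))
    for m, v in zip(masses, d):
        I += m * ((v @ v) * np.eye(3) - np.outer(v, v))
    mom = np.linalg.eigvalsh(I)
    return mom[0] < rel_tol * max(mom[2], 1e-300)


def masses_for(species: Sequence[str]) -> np.ndarray:
    try:
        return np.array([ATOMIC_MASSES[s] for s in species])
    except KeyError as exc:
        raise KeyError(f"no tabulated mass for species {exc}") from exc


@dataclass
class HarmonicResult:
    """Minimized geometry, Hessian, and the harmonic spectrum.

    ``vibrational`` drops the 6 (5 if linear) smallest-magnitude modes;
    ``near_zero`` holds those removed translation/rotation wavenumbers.
    """

    geometry: Geometry
    energy: float
    hessian: np.ndarray
    wavenumbers: np.ndarray  # all 3N, ascending
    imaginary: np.ndarray
    vibrational: np.ndarray
    near_zero: np.ndarray
    linear: bool


def harmonic_analysis(
    fit: FitResult,
    start: Geometry,
    masses: Optional[Sequence[float]] = None,
    tol: float = 1e-3,
    step: float = 1e-4,
) -> HarmonicResult:
    """Minimize, build the Hessian, and split vibrations from rigid modes."""
    if masses is None:
        masses = masses_for(start.species)
    geom = minimize_geometry(fit, start, tol=tol)
    H = hessian(fit, geom, step=step)
    wn, imag = harmonic_frequencies(H, masses)
    linear = is_linear(geom, masses)
    n_rigid = 5 if linear else 6
    mag = np.abs(wn)
    rigid_idx = np.argsort(mag)[:n_rigid]
    keep = np.ones(len(wn), dtype=bool)
    keep[rigid_idx] = False
    return HarmonicResult(
        geometry=geom,
        energy=evaluate_potential(fit, geom),
        hessian=H,
        wavenumbers=wn,
        imaginary=imag,
        vibrational=wn[keep],
        near_zero=wn[~keep],
        linear=linear,
    )


def mae_frequencies(
    reference: Sequence[float], test: Sequence[float]
) -> float:
    """Mean absolute difference of two matched-mode frequency lists (cm^-1)."""
    ref = np.asarray(reference, dtype=float)
    tst = np.asarray(test, dtype=float)
    if ref.shape != tst.shape:
        raise ValueError(f"length mismatch: {ref.shape} vs {tst.shape}")
    return float(np.mean(np.abs(ref - tst)))
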