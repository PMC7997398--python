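"""Joint linear least-squares fitting of energies and gradients.

The surface is V(a) = sum_i c_i p_i(x(a)) with x the Morse variables of
the Cartesian geometry a.  Energies contribute one design-matrix row per
record; Cartesian gradients, when present, contribute 3N rows per record
with entries obtained by the chain rule

    dV/da_{j,k} = sum_i c_i sum_l (dp_i/dx_l)(dx_l/da_{j,k})

where dx_l/da_{j,k} is nonzero only when atom j belongs to pair l.  The
solve is a minimal-norm SVD least squares with a relative cutoff, which
tolerates the rank deficiency of duplicate-containing bases: predictions
from concatenated and deduplicated bases coincide exactly.

Gradient evaluation of a fitted surface branches per atom: the inner sum
over l touches only the N-1 pair variables containing that atom, the rest
being structural zeros.
"""

from __future__ import annotations

import hashlib
from dataclasses import dataclass
from typing import Optional

import numpy as np

from .basis import basis_jacobian, evaluate_basis
from .geometry import (
    Dataset,
    Geometry,
    MorseVector,
    morse_jacobian,
    morse_variables,
    n_pairs,
    pair_index,
)

DEFAULT_SVD_CUTOFF = 1e-10


@dataclass
class FitResult:
    """Linear PIP expansion coefficients plus training metrics.

    ``rmse`` is over energies (cm^-1); ``rmsg`` over all gradient
    components (cm^-1/bohr), None when the training set had no gradients.
    ``energy_shift`` was subtracted from the target energies before the
    solve (0 unless shifting was requested) and is added back on
    evaluation.
    """

    coefficients: np.ndarray
    basis: object  # FragmentBasis | MergedBasis
    lam: float
    gradient_weight: float
    rmse: float
    rmsg: Optional[float]
    energy_shift: float = 0.0
    svd_cutoff: float = DEFAULT_SVD_CUTOFF

    def __post_init__(self):
        if len(self.coefficients) != len(self.basis.pips):
            raise ValueError(
                f"{len(self.coefficients)} coefficients for "
                f"{len(self.basis.pips)} basis functions"
            )


def design_matrix(
    ds: Dataset,
    basis,
    gradient_weight: float = 1.0,
    lam: float = 2.0,
) -> tuple[np.ndarray, np.ndarray]:
    """Assemble (A, b): energy rows first, then gradient rows per record.

    Gradient rows and their targets are scaled by ``gradient_weight``;
    weight 0 omits them entirely.
    """
    if ds.n_atoms != basis.n_atoms:
        raise ValueError(
            f"dataset has {ds.n_atoms} atoms, basis expects {basis.n_atoms}"
        )
    n_p = len(basis.pips)
    rows, targets = [], []
    for rec in ds:
        x = morse_variables(rec.geometry, lam)
        rows.append(evaluate_basis(basis, x))
        targets.append(rec.energy)
    if gradient_weight != 0.0:
        for rec in ds:
            if rec.gradient is None:
                continue
            x = morse_variables(rec.geometry, lam)
            J = basis_jacobian(basis, x)  # (n_p, n_pairs)
            M = morse_jacobian(rec.geometry, lam)  # (n_pairs, 3N) sparse
            G = (M.T @ J.T).T  # (n_p, 3N)
            rows.extend((gradient_weight * G.T))
            targets.extend(gradient_weight * rec.gradient)
    return np.array(rows), np.array(targets)


def fit_coefficients(
    ds: Dataset,
    basis,
    gradient_weight: float = 1.0,
    lam: float = 2.0,
    svd_cutoff: float = DEFAULT_SVD_CUTOFF,
    shift_energies: bool = False,
) -> FitResult:
    """Minimal-norm least-squares fit of the PIP expansion to a dataset."""
    if len(ds) == 0:
        raise ValueError("empty dataset")
    shift = float(min(r.energy for r in ds)) if shift_energies else 0.0
    if shift:
        ds = Dataset(
            [type(r)(r.geometry, r.energy - shift, r.gradient) for r in ds]
        )
    A, b = design_matrix(ds, basis, gradient_weight, lam)
    c, *_ = np.linalg.lstsq(A, b, rcond=svd_cutoff)
    fit = FitResult(
        coefficients=c,
        basis=basis,
        lam=lam,
        gradient_weight=gradient_weight,
        rmse=0.0,
        rmsg=None,
        energy_shift=shift,
        svd_cutoff=svd_cutoff,
    )
    fit.rmse, fit.rmsg = rms_metrics(fit, ds, _shift_applied=True)
    return fit


def evaluate_potential(fit: FitResult, geom: Geometry) -> float:
    """V = sum_i c_i p_i(x) + energy shift, in cm^-1."""
    x = morse_variables(geom, fit.lam, strict=False)
    return float(fit.coefficients @ evaluate_basis(fit.basis, x)) + fit.energy_shift


def evaluate_gradient(
    fit: FitResult, geom: Geometry, branched: bool = True
) -> np.ndarray:
    """Cartesian gradient of the fitted surface, (3N,) in cm^-1/bohr.

    ``branched=True`` (default) loops atoms and touches only the pair
    variables containing each atom; ``branched=False`` is the plain dense
    chain rule, kept as the reference path — the two are numerically
    identical.
    """
    x = morse_variables(geom, fit.lam, strict=False)
    J = basis_jacobian(fit.basis, x)  # (n_p, n_pairs)
    g_vars = fit.coefficients @ J  # dV/dx_l
    n = geom.n_atoms
    if not branched:
        M = morse_jacobian(geom, fit.lam)
        return np.asarray(M.T @ g_vars).ravel()
    lam = fit.lam
    r = geom.distances()
    grad = np.zeros(3 * n)
    xv = x.values
    for j in range(1, n + 1):
        acc = np.zeros(3)
        for jp in range(1, n + 1):
            if jp == j:
                continue
            l = pair_index(min(j, jp), max(j, jp), n) - 1
            if g_vars[l] == 0.0:
                continue
            diff = geom.coords[j - 1] - geom.coords[jp - 1]
            dxl = -(xv[l] / lam) * diff / r[l]  # d x_l / d a_{j,:}
            acc += g_vars[l] * dxl
        grad[3 * (j - 1) : 3 * j] = acc
    return grad


def rms_metrics(
    fit: FitResult, ds: Dataset, _shift_applied: bool = False
) -> tuple[float, Optional[float]]:
    """(RMSE over energies, RMSG over gradient components or None)."""
    e_res, g_res = [], []
    for rec in ds:
        v = evaluate_potential(fit, rec.geometry)
        if _shift_applied:
            v -= fit.energy_shift
        e_res.append(v - rec.energy)
        if rec.gradient is not None:
            g_res.extend(evaluate_gradient(fit, rec.geometry) - rec.gradient)
    rmse = float(np.sqrt(np.mean(np.square(e_res))))
    rmsg = float(np.sqrt(np.mean(np.square(g_res)))) if g_res else None
    return rmse, rmsg


def coefficients_to_text(fit: FitResult) -> str:
    """Plain-text coefficient file: header with basis checksum, lambda,
    order, gradient weight; then one indexed coefficient per line."""
    from .basis import basis_to_json

    checksum = hashlib.sha256(basis_to_json(fit.basis).encode()).hexdigest()[:16]
    lines = [
        f"# basis_checksum {checksum}",
        f"# lambda {fit.lam}",
        f"# max_degree {getattr(fit.basis, 'max_degree', 'unknown')}",
        f"# gradient_weight {fit.gradient_weight}",
        f"# energy_shift {float(fit.energy_shift)!r}",
        f"# rmse {float(fit.rmse)!r}",
        f"# rmsg {None if fit.rmsg is None else float(fit.rmsg)!r}",
    ]
    for i, c in enumerate(fit.coefficients):
        lines.append(f"{i} {float(c)!r}")
    return "\n".join(lines) + "\n"


def coefficients_from_text(text: str, basis) -> FitResult:
    """Parse a coefficient file back into a :class:`FitResult`."""
    header: dict[str, str] = {}
    coeffs: list[float] = []
    for ln in text.splitlines():
        if not ln.strip():
            continue
        if ln.startswith("#"):
            parts = ln[1:].split(None, 1)
            if len(parts) == 2:
                header[parts[0]] = parts[1].strip()
        else:
            _, v = ln.split()
            coeffs.append(float(v))
    rmsg = header.get("rmsg", "None")
    return FitResult(
        coefficients=np.array(coeffs),
        basis=basis,
        lam=float(header.get("lambda", 2.0)),
        gradient_weight=float(header.get("gradient_weight", 1.0)),
        rmse=float(header.get("rmse", "nan")),
        rmsg=None if rmsg == "None" else float(rmsg),
        energy_shift=float(header.get("energy_shift", 0.0)),
    )
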