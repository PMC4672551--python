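"""Normalising ecological trade-offs on the community matrix.

Niche space is saturated: a species that evolves to compete less with one
species must compete more with others.  This is enforced by conserving each
species' total interaction budget — the sum of the non-self entries in its
row and in its column of the community matrix stays at its initial value
``Q_i < 0``.  After each selection update, an alternating (Sinkhorn-style)
row/column rescaling restores both sums:

    row pass:     omega_ij <- Q_i * omega_ij / sum_{j != i} omega_ij
    column pass:  omega_ij <- Q_j * omega_ij / sum_{i != j} omega_ij

Self-interactions (the diagonal, fixed at -1) are untouched.  The passes
alternate until the summed squared change between iterations falls below a
tolerance and both residuals are within tolerance.  Because selection only
weakens entries while the budget is conserved, the net effect of selection
plus normalisation is that some interactions weaken, some strengthen and
some are left unchanged — the signed, Hebbian-like redistribution.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np

from .dynamics import CommunityMatrix

__all__ = [
    "normalize",
    "conservation_report",
    "symmetrize",
    "ConservationReport",
    "NormalizationError",
]


class NormalizationError(RuntimeError):
    pass


def _rescale_rows(omega: np.ndarray, Q: np.ndarray) -> None:
    """In-place: scale each row's off-diagonal entries to sum to Q_i."""
    diag = np.diag(omega).copy()
    sums = omega.sum(axis=1) - diag
    small = np.abs(sums) < 1e-15
    if np.any(small):
        rows = np.nonzero(small)[0].tolist()
        raise NormalizationError(
            f"off-diagonal row sum vanishes for rows {rows}; cannot rescale"
        )
    omega *= (Q / sums)[:, None]
    np.fill_diagonal(omega, diag)


def normalize(
    matrix: CommunityMatrix,
    tol: float = 1e-5,
    max_iter: int = 1000,
) -> CommunityMatrix:
    """Alternating row/column rescaling restoring the conserved budgets Q.

    Iterates (row pass then column pass) until the summed squared change of
    all entries between consecutive iterations is below ``tol`` and the
    worst row/column residual is below ``tol``.  Returns a new matrix; the
    diagonal is bit-identical to the input's.
    """
    omega = matrix.omega.copy()
    Q = matrix.Q
    if np.any(omega[~np.eye(omega.shape[0], dtype=bool)] >= 0):
        warnings.warn(
            "community matrix has non-negative off-diagonal entries; "
            "normalisation assumes strictly competitive interactions",
            RuntimeWarning,
            stacklevel=2,
        )
    # the budget sums cannot be restored beyond machine precision, so the
    # residual criterion is floored near it while `tol` can go arbitrarily low
    residual_tol = max(tol, 32 * np.finfo(float).eps * max(1.0, float(np.abs(Q).max())))
    for _ in range(max_iter):
        previous = omega.copy()
        _rescale_rows(omega, Q)          # rows to Q_i
        omega = omega.T.copy()
        _rescale_rows(omega, Q)          # columns to Q_i
        omega = omega.T.copy()
        change = float(((omega - previous) ** 2).sum())
        result = CommunityMatrix(omega.copy(), Q.copy())
        residual = max(
            np.abs(result.offdiag_row_sums() - Q).max(),
            np.abs(result.offdiag_col_sums() - Q).max(),
        )
        if change < tol and residual < residual_tol:
            break
    else:
        raise NormalizationError(
            f"normalisation did not converge in {max_iter} iterations "
            f"(last change {change:.3g}, residual {residual:.3g})"
        )
    offdiag = omega[~np.eye(omega.shape[0], dtype=bool)]
    if np.any(offdiag >= 0):
        warnings.warn(
            "normalised matrix has interaction coefficients that reached zero "
            "or went positive; dynamics may become unstable",
            RuntimeWarning,
            stacklevel=2,
        )
    return result


@dataclass
class ConservationReport:
    max_row_residual: float
    max_col_residual: float
    max_asymmetry: float
    min_offdiag: float
    max_offdiag: float


def conservation_report(matrix: CommunityMatrix) -> ConservationReport:
    """Residuals of the conserved budgets, symmetry deviation and entry range."""
    row = float(np.abs(matrix.offdiag_row_sums() - matrix.Q).max())
    col = float(np.abs(matrix.offdiag_col_sums() - matrix.Q).max())
    off = matrix.omega[~np.eye(matrix.n_species, dtype=bool)]
    return ConservationReport(
        max_row_residual=row,
        max_col_residual=col,
        max_asymmetry=matrix.max_asymmetry(),
        min_offdiag=float(off.min()),
        max_offdiag=float(off.max()),
    )


def symmetrize(matrix: CommunityMatrix) -> CommunityMatrix:
    """Replace off-diagonals by the average of the matrix and its transpose."""
    omega = 0.5 * (matrix.omega + matrix.omega.T)
    np.fill_diagonal(omega, np.diag(matrix.omega))
    return CommunityMatrix(omega, matrix.Q.copy())
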