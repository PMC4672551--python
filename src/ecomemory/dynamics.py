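"""Fast-timescale ecological dynamics.

Generalised Lotka-Volterra competition for a community of ``N`` species with
densities ``x_i >= 0``, community matrix ``omega`` (per-capita fitness effect
of species ``j`` on ``i``, self-effect fixed at -1) and environment-dependent
carrying capacities ``k_i``:

    dx_i/dt = (m_i * x_i / k_i) * (k_i + sum_j omega_ij * x_j)

The sum runs over all ``j`` including ``j = i`` (``omega_ii = -1``), so a
single isolated species follows the logistic equation with equilibrium
``x = k``.  Growth is multiplicative in ``x_i``: a species at zero density
stays at zero, and densities are clamped at zero after every step.

Integration is forward Euler with a configurable step ``dt`` (default 1.0,
one "iteration" of the dynamics).  With symmetric competitive matrices the
dynamics have only fixed-point attractors, so equilibration iterates until
either a step budget ``tau`` is exhausted or the update falls below a
stopping tolerance.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np

__all__ = [
    "EcosystemState",
    "CommunityMatrix",
    "GrowthParams",
    "EquilibrationResult",
    "lv_rate",
    "euler_step",
    "equilibrate",
]


@dataclass
class EcosystemState:
    """Vector of non-negative species densities at an (integer) time."""

    densities: np.ndarray
    time: int = 0

    def __post_init__(self) -> None:
        self.densities = np.asarray(self.densities, dtype=float)
        if self.densities.ndim != 1:
            raise ValueError("densities must be a 1-D vector")
        if not np.all(np.isfinite(self.densities)):
            raise ValueError("densities must be finite")
        if np.any(self.densities < 0):
            raise ValueError("densities must be non-negative")

    @property
    def n_species(self) -> int:
        return self.densities.size

    def copy(self) -> "EcosystemState":
        return EcosystemState(self.densities.copy(), self.time)


@dataclass
class CommunityMatrix:
    """Interaction matrix with fixed self-interactions and conserved budgets.

    ``omega[i, j]`` is the per-capita effect of species ``j`` on the growth
    of species ``i``, relative to the self-effect (``omega[i, i] = -1``,
    never modified).  ``Q[i]`` is the conserved sum of the non-self entries
    of row/column ``i`` (negative: the species' total competitive burden).
    """

    omega: np.ndarray
    Q: np.ndarray = field(default=None)  # type: ignore[assignment]

    def __post_init__(self) -> None:
        self.omega = np.asarray(self.omega, dtype=float)
        if self.omega.ndim != 2 or self.omega.shape[0] != self.omega.shape[1]:
            raise ValueError("omega must be a square matrix")
        if not np.all(np.isfinite(self.omega)):
            raise ValueError("omega must be finite")
        if not np.allclose(np.diag(self.omega), -1.0):
            raise ValueError("diagonal of omega must be -1")
        np.fill_diagonal(self.omega, -1.0)
        if self.Q is None:
            # conserved budget defaults to the current non-self row sums
            self.Q = self.offdiag_row_sums()
        else:
            self.Q = np.asarray(self.Q, dtype=float)
            if self.Q.shape != (self.n_species,):
                raise ValueError("Q must be a length-N vector")

    @property
    def n_species(self) -> int:
        return self.omega.shape[0]

    def offdiag_row_sums(self) -> np.ndarray:
        return self.omega.sum(axis=1) - np.diag(self.omega)

    def offdiag_col_sums(self) -> np.ndarray:
        return self.omega.sum(axis=0) - np.diag(self.omega)

    def max_asymmetry(self) -> float:
        return float(np.abs(self.omega - self.omega.T).max())

    def is_symmetric(self, tol: float = 1e-12) -> bool:
        return self.max_asymmetry() <= tol

    def copy(self) -> "CommunityMatrix":
        return CommunityMatrix(self.omega.copy(), self.Q.copy())


def uniform_community(n: int, offdiag: float = -0.2) -> CommunityMatrix:
    """Initial community matrix: -1 on the diagonal, ``offdiag`` elsewhere."""
    if offdiag >= 0:
        raise ValueError("off-diagonal interactions must be competitive (< 0)")
    omega = np.full((n, n), offdiag, dtype=float)
    np.fill_diagonal(omega, -1.0)
    return CommunityMatrix(omega)


@dataclass
class GrowthParams:
    """Intrinsic growth rates ``m`` and carrying capacities ``k`` (both > 0)."""

    m: np.ndarray
    k: np.ndarray

    def __post_init__(self) -> None:
        self.m = np.atleast_1d(np.asarray(self.m, dtype=float))
        self.k = np.atleast_1d(np.asarray(self.k, dtype=float))
        if self.m.shape != self.k.shape:
            raise ValueError("m and k must have the same length")
        if np.any(self.m <= 0) or np.any(self.k <= 0):
            raise ValueError("m and k must be strictly positive")


def _check_dims(state: EcosystemState, matrix: CommunityMatrix, growth: GrowthParams) -> None:
    n = state.n_species
    if matrix.n_species != n or growth.m.size != n:
        raise ValueError(
            f"dimension mismatch: state N={n}, matrix N={matrix.n_species}, "
            f"growth N={growth.m.size}"
        )


def lv_rate(state: EcosystemState, matrix: CommunityMatrix, growth: GrowthParams) -> np.ndarray:
    """Density change rates dx_i/dt = (m_i x_i / k_i)(k_i + sum_j omega_ij x_j)."""
    _check_dims(state, matrix, growth)
    x = state.densities
    if not np.all(np.isfinite(x)):
        raise ValueError("non-finite densities")
    return (growth.m * x / growth.k) * (growth.k + matrix.omega @ x)


def euler_step(
    state: EcosystemState,
    matrix: CommunityMatrix,
    growth: GrowthParams,
    dt: float = 1.0,
) -> EcosystemState:
    """One forward-Euler step, clamping densities at zero."""
    if dt <= 0:
        raise ValueError("dt must be positive")
    x = state.densities + dt * lv_rate(state, matrix, growth)
    if not np.all(np.isfinite(x)):
        raise FloatingPointError(
            "non-finite densities after Euler step: numerical blow-up, reduce dt"
        )
    np.maximum(x, 0.0, out=x)
    return EcosystemState(x, state.time + 1)


@dataclass
class EquilibrationResult:
    """Outcome of :func:`equilibrate`.

    ``n_steps`` is the number of Euler steps actually taken; ``residual`` is
    the final max-norm of ``dt * rate``; ``converged`` is False when the step
    budget was exhausted with the residual still above tolerance.
    """

    state: EcosystemState
    n_steps: int
    residual: float
    converged: bool


def equilibrate(
    state: EcosystemState,
    matrix: CommunityMatrix,
    growth: GrowthParams,
    tau: int = 5000,
    dt: float = 1.0,
    stop_tol: float = 1e-9,
) -> EquilibrationResult:
    """Iterate the dynamics up to ``tau`` Euler steps toward a fixed point.

    Stops early once the max-norm update ``|dt * rate|`` drops below
    ``stop_tol``; pass ``stop_tol=0`` to always run the full budget.
    """
    if tau < 0:
        raise ValueError("tau must be non-negative")
    _check_dims(state, matrix, growth)
    x = state.densities.copy()
    m_over_k = growth.m / growth.k
    omega = matrix.omega
    k = growth.k
    residual = np.inf
    min_residual = np.inf
    steps = 0
    for steps in range(1, tau + 1):
        delta = dt * (m_over_k * x) * (k + omega @ x)
        if not np.all(np.isfinite(delta)):
            raise FloatingPointError(
                "non-finite update during equilibration: numerical blow-up, reduce dt"
            )
        x += delta
        np.maximum(x, 0.0, out=x)
        residual = float(np.abs(delta).max())
        if steps > tau // 2:
            # past the transient, the residual should shrink monotonically
            min_residual = min(min_residual, residual)
        if residual < stop_tol:
            break
    else:
        steps = tau
    if tau == 0:
        steps, residual = 0, 0.0
    converged = residual <= stop_tol or stop_tol == 0.0
    if not converged and residual > 10.0 * min_residual:
        warnings.warn(
            "equilibration residual is oscillating or growing instead of "
            f"decaying (final {residual:.3g} vs best {min_residual:.3g}); "
            "consider reducing dt",
            RuntimeWarning,
            stacklevel=2,
        )
    return EquilibrationResult(
        state=EcosystemState(x, state.time + steps),
        n_steps=steps,
        residual=residual,
        converged=converged,
    )
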