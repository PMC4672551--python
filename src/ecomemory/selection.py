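"""Individual-level selection on interaction coefficients, and Hebb's rule.

A mutant of species ``i`` whose interaction with species ``j`` is weakened by
``g`` (toward zero, i.e. less competitive) invades at a per-capita rate
advantage

    s = (m_i / k_ie) * g * x_j

relative to the resident.  Beneficial mutations arise at rate ``mu`` per
individual per generation, so the supply is ``x_i * mu``, and the expected
per-generation change ("rate of adaptation") of ``omega_ij`` is
``v_ij = x_i * mu * P``, with ``P`` the fixation probability of one new
mutation.  Three population-genetic regimes are supported:

serial
    No interference between segregating alleles; ``P = s``, so
    ``v_ij = (m_i/k_ie) * g * mu * x_i * x_j``.
linked_linear
    Interference between linked genes on a linear genome of total map
    length ``R`` Morgans (Weissman & Barton):
    ``v_ij = 2*beta*mu*x_i*x_j / (1 + 4*beta*mu*x_i*x_j / R)``,
    with ``beta = m_i*g/k_ie``.
facultative
    Unlinked loci in facultative sexuals with small outcrossing rate
    ``r_out`` (Neher et al.):
    ``v_ij = x_i*mu*s^2 * (1 - 4*x_i*mu*s^2/r_out^2)``, valid while
    ``r_out^2/s^2 >> 4*x_i*mu``.

All three vanish when ``x_i * x_j = 0`` and increase with the product of the
two densities: species that occur together "wire" together, which is the
Hebbian (unsupervised correlation) learning rule.  :func:`hebb_delta` builds
the reference Hebbian update on a signed ±1 encoding of a community state,
and :func:`hebb_agreement` scores an evolved change matrix against it.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass
from typing import Optional

import numpy as np

from .dynamics import EcosystemState, GrowthParams

__all__ = [
    "RateModelParams",
    "DeltaMatrix",
    "selection_coefficient",
    "adaptation_rate_serial",
    "adaptation_rate_linked",
    "adaptation_rate_facultative",
    "selection_delta",
    "hebb_delta",
    "hebb_agreement",
    "sign_encode",
    "HebbAgreement",
]

RATE_MODELS = ("serial", "linked_linear", "facultative")

#: the facultative-outcrossing formula requires r_out^2/s^2 >> 4*x_i*mu;
#: a warning fires when the ratio falls below this safety factor
FACULTATIVE_VALIDITY_FACTOR = 10.0


@dataclass
class RateModelParams:
    """Choice of rate-of-adaptation model and its parameters.

    ``g``: per-mutation change of an interaction coefficient (dimensionless).
    ``mu``: beneficial mutation rate per individual per generation.
    ``R``: total genetic map length in Morgans (linked_linear only).
    ``r_out``: outcrossing rate (facultative only).
    """

    model: str = "serial"
    g: float = 0.01
    mu: float = 1e-5
    R: Optional[float] = None
    r_out: Optional[float] = None

    def __post_init__(self) -> None:
        if self.model not in RATE_MODELS:
            raise ValueError(f"unknown rate model {self.model!r}; choose from {RATE_MODELS}")
        if self.g <= 0 or self.mu <= 0:
            raise ValueError("g and mu must be strictly positive")
        if self.model == "linked_linear":
            if self.R is None or self.R <= 0:
                raise ValueError("linked_linear model requires map length R > 0")
        if self.model == "facultative":
            if self.r_out is None or self.r_out <= 0:
                raise ValueError("facultative model requires outcrossing rate r_out > 0")


@dataclass
class DeltaMatrix:
    """Proposed per-generation changes to the community matrix.

    Off-diagonal entries are >= 0 (selection only weakens competition;
    redistribution toward stronger competition happens later through the
    normalising trade-offs); the diagonal is identically zero.
    """

    delta: np.ndarray

    def __post_init__(self) -> None:
        self.delta = np.asarray(self.delta, dtype=float)
        if self.delta.ndim != 2 or self.delta.shape[0] != self.delta.shape[1]:
            raise ValueError("delta must be square")
        if np.any(np.diag(self.delta) != 0):
            raise ValueError("diagonal of delta must be zero (self-interactions fixed)")
        if np.any(self.delta < 0):
            raise ValueError("selection deltas must be non-negative")


def _check_positive(m_i: float, k_ie: float, g: float) -> None:
    if m_i <= 0 or k_ie <= 0 or g <= 0:
        raise ValueError("m_i, k_ie and g must be strictly positive")


def selection_coefficient(m_i: float, k_ie: float, g: float, x_j: float) -> float:
    """Per-capita invasion-rate advantage s = (m_i/k_ie) * g * x_j."""
    _check_positive(m_i, k_ie, g)
    if np.any(np.asarray(x_j) < 0):
        raise ValueError("densities must be non-negative")
    return m_i / k_ie * g * x_j


def adaptation_rate_serial(x_i, x_j, m_i: float, k_ie: float, params: RateModelParams):
    """v_ij = (m_i/k_ie) * g * mu * x_i * x_j (no interference)."""
    _check_positive(m_i, k_ie, params.g)
    return x_i * params.mu * selection_coefficient(m_i, k_ie, params.g, x_j)


def adaptation_rate_linked(x_i, x_j, m_i: float, k_ie: float, params: RateModelParams):
    """v_ij = 2*beta*mu*x_i*x_j / (1 + 4*beta*mu*x_i*x_j/R), beta = m_i*g/k_ie."""
    _check_positive(m_i, k_ie, params.g)
    if params.R is None or params.R <= 0:
        raise ValueError("map length R must be strictly positive")
    beta = m_i * params.g / k_ie
    v0 = 2.0 * beta * params.mu * np.asarray(x_i) * np.asarray(x_j)
    return v0 / (1.0 + 2.0 * v0 / params.R)


def adaptation_rate_facultative(x_i, x_j, m_i: float, k_ie: float, params: RateModelParams):
    """v_ij = x_i*mu*s^2 * (1 - 4*x_i*mu*s^2/r_out^2), s = beta*x_j."""
    _check_positive(m_i, k_ie, params.g)
    if params.r_out is None or params.r_out <= 0:
        raise ValueError("outcrossing rate r_out must be strictly positive")
    beta = m_i * params.g / k_ie
    s = beta * np.asarray(x_j, dtype=float)
    x_i = np.asarray(x_i, dtype=float)
    s_sq = s**2
    with np.errstate(divide="ignore", invalid="ignore"):
        ratio = np.where(s_sq > 0, params.r_out**2 / s_sq, np.inf)
    bound = 4.0 * x_i * params.mu
    bad = ratio < FACULTATIVE_VALIDITY_FACTOR * bound
    if np.any(bad):
        worst = float(np.min(np.where(bound > 0, ratio / np.maximum(bound, 1e-300), np.inf)))
        warnings.warn(
            "facultative rate model outside its validity region: "
            f"r_out^2/s^2 / (4 x_i mu) = {worst:.3g} < {FACULTATIVE_VALIDITY_FACTOR}",
            RuntimeWarning,
            stacklevel=2,
        )
    return x_i * params.mu * s_sq * (1.0 - 4.0 * x_i * params.mu * s_sq / params.r_out**2)


_RATE_FUNCS = {
    "serial": adaptation_rate_serial,
    "linked_linear": adaptation_rate_linked,
    "facultative": adaptation_rate_facultative,
}


def selection_delta(
    state: EcosystemState,
    growth: GrowthParams,
    params: RateModelParams,
) -> DeltaMatrix:
    """Rate-of-adaptation matrix for every ordered pair of species.

    ``delta[i, j]`` is the chosen rate model evaluated at the equilibrated
    densities ``(x_i, x_j)`` with the growth parameters of species ``i`` in
    the currently active environment; the diagonal is zero.  Applied
    additively to the community matrix, these move competitive coefficients
    toward zero (only direct effects on individual fitness are selected).
    """
    x = state.densities
    n = x.size
    if growth.m.size != n:
        raise ValueError("growth parameters and state have different lengths")
    func = _RATE_FUNCS[params.model]
    xi = x[:, None]  # rows: focal (mutating) species i
    xj = x[None, :]
    # m_i, k_ie vary along rows only
    if params.model == "serial":
        delta = (growth.m / growth.k)[:, None] * params.g * params.mu * xi * xj
    else:
        delta = np.empty((n, n), dtype=float)
        for i in range(n):
            delta[i, :] = func(x[i], x, growth.m[i], growth.k[i], params)
    np.fill_diagonal(delta, 0.0)
    return DeltaMatrix(delta)


def sign_encode(densities: np.ndarray) -> np.ndarray:
    """±1 encoding of a density vector relative to its mean (ties map to +1)."""
    x = np.asarray(densities, dtype=float)
    return np.where(x >= x.mean(), 1.0, -1.0)


def hebb_delta(sigma: np.ndarray, r: float) -> np.ndarray:
    """Hebb's rule on a ±1 state: off-diagonal entries r*sigma_i*sigma_j.

    Returns a signed matrix (a reference for comparison, not a
    :class:`DeltaMatrix`, whose entries are one-signed).
    """
    sigma = np.asarray(sigma, dtype=float)
    if not np.all(np.isin(sigma, (-1.0, 1.0))):
        raise ValueError("sigma entries must be -1 or +1")
    if r <= 0:
        raise ValueError("learning rate r must be positive")
    mat = r * np.outer(sigma, sigma)
    np.fill_diagonal(mat, 0.0)
    return mat


@dataclass
class HebbAgreement:
    """Agreement between an evolved net change and the Hebbian reference."""

    sign_match_fraction: Optional[float]  # None when every entry is in the dead band
    pearson_correlation: float
    n_compared: int


def hebb_agreement(
    evolved_net_change: np.ndarray,
    hebb_change: np.ndarray,
    dead_band_rel: float = 1e-12,
) -> HebbAgreement:
    """Sign-match fraction and correlation of two change matrices.

    Diagonals are excluded.  An off-diagonal entry is excluded from sign
    matching when its magnitude in *either* matrix falls below that matrix's
    dead band (``dead_band_rel`` times the matrix's largest magnitude), so
    numerical zeros are never classified.
    """
    a = np.asarray(evolved_net_change, dtype=float)
    b = np.asarray(hebb_change, dtype=float)
    if a.shape != b.shape or a.ndim != 2 or a.shape[0] != a.shape[1]:
        raise ValueError("change matrices must be square and of equal shape")
    off = ~np.eye(a.shape[0], dtype=bool)
    av, bv = a[off], b[off]
    if av.std() == 0.0 or bv.std() == 0.0:
        corr = float("nan")
    else:
        corr = float(np.corrcoef(av, bv)[0, 1])

    def live(v):
        peak = np.abs(v).max()
        if peak == 0.0:
            return np.zeros(v.shape, dtype=bool)
        return np.abs(v) >= dead_band_rel * peak

    keep = live(av) & live(bv)
    if not keep.any():
        return HebbAgreement(None, corr, 0)
    frac = float(np.mean(np.sign(av[keep]) == np.sign(bv[keep])))
    return HebbAgreement(frac, corr, int(keep.sum()))
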