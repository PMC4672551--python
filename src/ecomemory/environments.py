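"""Environment patterns, carrying-capacity forcing and switching schedules.

An environment is a ±1 pattern ``xi`` over the ``N`` species: relative to
the neutral environment E0 (all capacities ``k0``), species with
``xi_i = +1`` get an elevated carrying capacity ``k0 + alpha`` and species
with ``xi_i = -1`` a depressed one ``k0 - alpha``.  Patterns here stand in
for the arbitrary pictograms of a field study: balanced random ±1 vectors,
optionally with a prescribed pairwise overlap, or loaded from a text grid /
PGM image (see :mod:`ecomemory.io`).

During training the environment alternates through a schedule: ``T``
generations in each environment before switching.  For hysteresis
experiments the forcing is interpolated linearly between two patterns.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import List, Optional, Sequence

import numpy as np

__all__ = [
    "EnvironmentPattern",
    "ForcingSchedule",
    "generate_patterns",
    "carrying_capacities",
    "interpolate_forcing",
    "env_at",
    "complement_state",
]


@dataclass
class EnvironmentPattern:
    """±1 vector marking species with elevated (+1) / depressed (-1) capacity."""

    xi: np.ndarray
    label: str = ""

    def __post_init__(self) -> None:
        self.xi = np.asarray(self.xi, dtype=float)
        if self.xi.ndim != 1:
            raise ValueError("pattern must be a 1-D vector")
        if not np.all(np.isin(self.xi, (-1.0, 1.0))):
            raise ValueError("pattern entries must be exactly -1 or +1")

    @property
    def n_species(self) -> int:
        return self.xi.size

    def overlap(self, other: "EnvironmentPattern") -> float:
        """Normalised dot product in [-1, 1]."""
        return float(self.xi @ other.xi) / self.n_species


def _balanced_pattern(n: int, rng: np.random.Generator) -> np.ndarray:
    """Random ±1 vector with +1/-1 counts differing by at most one."""
    n_plus = n // 2 + (n % 2)
    xi = np.full(n, -1.0)
    xi[rng.choice(n, size=n_plus, replace=False)] = 1.0
    return xi


def generate_patterns(
    N: int,
    n_patterns: int,
    seed: int,
    target_overlap: Optional[float] = None,
) -> List[EnvironmentPattern]:
    """Deterministic balanced random patterns, optionally at a set overlap.

    When ``target_overlap`` is given, every pair of returned patterns has a
    normalised dot product within ``2/N`` of the target (achieved by
    flipping entries of fresh balanced draws in sign-balanced pairs, which
    keeps each pattern balanced).
    """
    if N < 2:
        raise ValueError("need at least two species")
    if n_patterns < 1:
        raise ValueError("need at least one pattern")
    if target_overlap is not None and not -1.0 <= target_overlap <= 1.0:
        raise ValueError("target_overlap must lie in [-1, 1]")
    rng = np.random.default_rng(seed)
    patterns: List[EnvironmentPattern] = [
        EnvironmentPattern(_balanced_pattern(N, rng), label="E1")
    ]
    for p in range(1, n_patterns):
        label = f"E{p + 1}"
        if target_overlap is None:
            patterns.append(EnvironmentPattern(_balanced_pattern(N, rng), label=label))
            continue
        xi = _steer_overlap(patterns, N, rng, target_overlap)
        patterns.append(EnvironmentPattern(xi, label=label))
    return patterns


def _steer_overlap(
    existing: Sequence[EnvironmentPattern],
    N: int,
    rng: np.random.Generator,
    target: float,
    max_tries: int = 2000,
) -> np.ndarray:
    """Draw a balanced pattern whose overlap with every existing pattern is
    within 2/N of ``target``; greedy pair-flips preserve balance."""
    tol = 2.0 / N
    for _ in range(max_tries):
        xi = _balanced_pattern(N, rng)
        for _ in range(4 * N):
            offs = [xi @ q.xi / N - target for q in existing]
            worst = int(np.argmax(np.abs(offs)))
            if abs(offs[worst]) <= tol:
                break
            ref = existing[worst].xi
            # flip one (+1,-1) pair of xi entries chosen to move the worst
            # overlap toward the target without changing the balance
            direction = -np.sign(offs[worst])  # +1: raise overlap with ref
            plus = np.nonzero((xi == 1.0) & (ref == -direction))[0]
            minus = np.nonzero((xi == -1.0) & (ref == direction))[0]
            if plus.size == 0 or minus.size == 0:
                break
            xi[rng.choice(plus)] = -1.0
            xi[rng.choice(minus)] = 1.0
        offs = [abs(xi @ q.xi / N - target) for q in existing]
        if max(offs) <= tol:
            return xi
    raise ValueError(
        f"could not generate a balanced pattern with pairwise overlap "
        f"{target} +/- {tol} against {len(existing)} existing pattern(s)"
    )


def carrying_capacities(
    pattern: Optional[EnvironmentPattern],
    k0: float,
    alpha: float,
    N: Optional[int] = None,
) -> np.ndarray:
    """Capacity vector k_i = k0 + alpha*xi_i.

    The neutral environment E0 (``pattern=None``, requires ``N``) gives all
    ``k0``.  Requires ``k0 > alpha >= 0`` so capacities stay positive.
    """
    if alpha < 0 or alpha >= k0:
        raise ValueError("need k0 > alpha >= 0 for positive capacities")
    if pattern is None:
        if N is None:
            raise ValueError("the neutral environment needs an explicit N")
        return np.full(N, float(k0))
    return k0 + alpha * pattern.xi


def interpolate_forcing(
    p1: EnvironmentPattern,
    p2: EnvironmentPattern,
    lam: float,
    k0: float,
    alpha: float,
) -> np.ndarray:
    """Linear forcing ramp k_i = k0 + alpha*((1-lam)*xi1_i + lam*xi2_i)."""
    if not 0.0 <= lam <= 1.0:
        raise ValueError("lambda must lie in [0, 1]")
    if p1.n_species != p2.n_species:
        raise ValueError("patterns must have the same length")
    if alpha < 0 or alpha >= k0:
        raise ValueError("need k0 > alpha >= 0 for positive capacities")
    return k0 + alpha * ((1.0 - lam) * p1.xi + lam * p2.xi)


@dataclass
class ForcingSchedule:
    """Cyclic environment schedule: ``T`` generations per label."""

    T: int = 1
    sequence: Sequence[str] = field(default_factory=lambda: ("E1", "E2"))

    def __post_init__(self) -> None:
        if self.T < 1:
            raise ValueError("T must be at least 1")
        if len(self.sequence) < 1:
            raise ValueError("schedule needs at least one environment")


def env_at(schedule: ForcingSchedule, generation: int) -> str:
    """Environment label active at a generation (first label at generation 0)."""
    if generation < 0:
        raise ValueError("generation must be non-negative")
    return schedule.sequence[(generation // schedule.T) % len(schedule.sequence)]


def complement_state(state_pattern: np.ndarray) -> np.ndarray:
    """Mirror a vector through its mean: 2*mean(E) - E (an involution)."""
    e = np.asarray(state_pattern, dtype=float)
    return 2.0 * e.mean() - e
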