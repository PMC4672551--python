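"""Eco-evolutionary training loop and memory experiments.

Each evolutionary generation separates timescales strictly:

1. the active environment sets the carrying capacities;
2. species densities are reset to the initial density ``s0`` and the
   ecological dynamics run to equilibrium (fast timescale);
3. selection proposes per-generation changes to all interaction
   coefficients in proportion to the rate of adaptation at the equilibrium
   densities (slow timescale);
4. the changes are added to the community matrix and the normalising
   trade-offs restore every species' conserved interaction budget
   (followed by symmetrisation, since the studied regime is symmetric).

Repeating this while the environment alternates between forcing patterns
imprints a distributed memory of those patterns in the community matrix:
the unforced dynamics acquire attractors whose sign structure (densities
above/below the community mean) matches the past environments.  The probe
constructors (:func:`cue_init`, :func:`corrupt_init`, :func:`mixture_init`)
and :func:`hysteresis_sweep` interrogate that memory; Monte-Carlo
:func:`sample_attractors` maps the attractor landscape.

The absolute rate of adaptation is phenomenological — only relative rates
across species pairs shape which interactions strengthen or weaken — so the
per-generation update carries a free scale factor ``update_gain``.  The
shipped presets calibrate it analytically: a memory becomes self-sustaining
(an attractor in the neutral environment) once the accumulated Hebbian
component D of the matrix crosses D* = (1 + omega_offdiag) / N, and with an
effective per-generation Hebb step eta = update_gain * (m g / k0) * mu the
training run crosses that threshold with a comfortable margin (see
docs/methods.md).
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, replace, asdict
from typing import Dict, List, Optional, Sequence, Tuple

import numpy as np

from .constraints import conservation_report, normalize, symmetrize
from .dynamics import (
    CommunityMatrix,
    EcosystemState,
    EquilibrationResult,
    GrowthParams,
    equilibrate,
    uniform_community,
)
from .environments import (
    EnvironmentPattern,
    ForcingSchedule,
    carrying_capacities,
    env_at,
    generate_patterns,
    interpolate_forcing,
)
from .selection import RateModelParams, selection_delta, sign_encode

__all__ = [
    "EvoConfig",
    "GenerationRecord",
    "Trajectory",
    "AttractorSet",
    "run_evolution",
    "sample_attractors",
    "overlap_score",
    "cue_init",
    "corrupt_init",
    "mixture_init",
    "pattern_state",
    "hysteresis_sweep",
    "HysteresisResult",
    "attractor_census",
    "CensusRow",
]


@dataclass
class EvoConfig:
    """All model and protocol parameters.

    Defaults are the full-scale study conditions: 400 species, growth rate
    0.5, initial density 0.1, neutral capacity 10 with forcing amplitude
    0.1, environment switching every generation, 5000 ecological steps per
    generation, per-mutation effect 0.01 and beneficial mutation rate 1e-5,
    off-diagonal interactions initialised at -0.2 (budgets Q_i equal to
    their initial row sums).  ``desk_scale`` is a reduced configuration for
    interactive work and the test suite.
    """

    N: int = 400
    m: float = 0.5
    s0: float = 0.1
    k0: float = 10.0
    alpha: float = 0.1
    T: int = 1
    tau: int = 5000
    dt: float = 1.0
    g: float = 0.01
    mu: float = 1e-5
    rate_model: str = "serial"
    R: Optional[float] = None        # linked_linear map length (Morgans)
    r_out: Optional[float] = None    # facultative outcrossing rate
    omega_offdiag0: float = -0.2
    update_gain: float = 1.0
    n_generations: int = 800
    env_sequence: Tuple[str, ...] = ("E1", "E2")
    pattern_seed: int = 12345
    sample_seed: int = 67890
    stop_tol: float = 1e-9
    norm_tol: float = 1e-5
    norm_max_iter: int = 1000
    cluster_tol: float = 1e-3
    filter_margin: float = 0.5
    probe_tau: Optional[int] = None
    apply_symmetrize: bool = True
    snapshot_stride: int = 50

    def __post_init__(self) -> None:
        if self.N < 1:
            raise ValueError("N must be positive")
        for name in ("m", "s0", "k0", "dt", "g", "mu", "update_gain"):
            if getattr(self, name) <= 0:
                raise ValueError(f"{name} must be strictly positive")
        if not 0 <= self.alpha < self.k0:
            raise ValueError("need k0 > alpha >= 0")
        if self.T < 1:
            raise ValueError("T must be at least 1")
        if self.tau < 0 or self.n_generations < 0:
            raise ValueError("tau and n_generations must be non-negative")
        if self.omega_offdiag0 >= 0:
            raise ValueError("initial off-diagonal interactions must be negative")
        if self.snapshot_stride < 1:
            raise ValueError("snapshot_stride must be at least 1")
        # validates the model name and model-specific parameters
        self.rate_params()

    def rate_params(self) -> RateModelParams:
        return RateModelParams(
            model=self.rate_model, g=self.g, mu=self.mu, R=self.R, r_out=self.r_out
        )

    def growth(self, k: np.ndarray) -> GrowthParams:
        return GrowthParams(m=np.full(self.N, self.m), k=k)

    def schedule(self) -> ForcingSchedule:
        return ForcingSchedule(T=self.T, sequence=self.env_sequence)

    def effective_probe_tau(self) -> int:
        """Step budget for attractor sampling, probes and sweeps.

        Defaults to ``tau``; near the memory-formation threshold the
        dynamics slow down critically, so presets set a larger budget here
        than for the training loop."""
        return self.probe_tau if self.probe_tau is not None else self.tau

    def uniform_equilibrium(self) -> float:
        """Fixed-point density of the initial uniform community in E0."""
        return self.k0 / (1.0 + abs(self.omega_offdiag0) * (self.N - 1))

    def hebb_step(self) -> float:
        """Effective per-generation Hebb learning step
        eta = update_gain * (m g / k0) * mu."""
        return self.update_gain * self.m * self.g / self.k0 * self.mu

    def patterns(self, n: Optional[int] = None) -> List[EnvironmentPattern]:
        n_pat = n if n is not None else max(
            1, len({lbl for lbl in self.env_sequence if lbl != "E0"})
        )
        return generate_patterns(self.N, n_pat, self.pattern_seed)

    @classmethod
    def paper_scale(cls, **overrides) -> "EvoConfig":
        """Full-scale protocol (400 species, 5000 ecological steps, 800
        generations).  update_gain gives an effective Hebb step eta = 5e-4
        per generation, placing the memory-formation threshold
        D* = (1 + omega_offdiag)/N in the middle of the run."""
        cfg = dict(update_gain=cls._gain_for_eta(5e-4), probe_tau=10000)
        cfg.update(overrides)
        return cls(**cfg)

    @classmethod
    def desk_scale(cls, **overrides) -> "EvoConfig":
        """Reduced protocol: 100 species, 1500 ecological steps, 300
        generations; eta = 1.2e-3 puts the memory-formation threshold
        around generation 140 of single-environment training.  Probes get
        a deeper step budget because dynamics slow down critically near
        the threshold."""
        cfg = dict(
            N=100,
            tau=1500,
            probe_tau=8000,
            n_generations=300,
            update_gain=cls._gain_for_eta(0.0012),
        )
        cfg.update(overrides)
        return cls(**cfg)

    @staticmethod
    def _gain_for_eta(
        eta: float, m: float = 0.5, g: float = 0.01, k0: float = 10.0, mu: float = 1e-5
    ) -> float:
        return eta * k0 / (m * g * mu)

    def to_dict(self) -> dict:
        d = asdict(self)
        d["env_sequence"] = list(self.env_sequence)
        return d

    def with_updates(self, **overrides) -> "EvoConfig":
        return replace(self, **overrides)


# ---------------------------------------------------------------------------
# training loop

@dataclass
class GenerationRecord:
    generation: int
    env_label: str
    densities: np.ndarray
    n_steps: int
    converged: bool
    overlaps: Dict[str, float]
    max_row_residual: float
    max_col_residual: float
    max_asymmetry: float


@dataclass
class Trajectory:
    config: EvoConfig
    patterns: List[EnvironmentPattern]
    records: List[GenerationRecord]
    snapshots: List[Tuple[int, CommunityMatrix]]
    final_matrix: CommunityMatrix


def _capacities_for(
    label: str, patterns: Sequence[EnvironmentPattern], config: EvoConfig
) -> np.ndarray:
    if label == "E0":
        return carrying_capacities(None, config.k0, config.alpha, N=config.N)
    by_label = {p.label: p for p in patterns}
    if label not in by_label:
        raise ValueError(f"schedule references unknown environment {label!r}")
    return carrying_capacities(by_label[label], config.k0, config.alpha)


def _equilibrate_in(
    x0: np.ndarray, matrix: CommunityMatrix, k: np.ndarray, config: EvoConfig
) -> EquilibrationResult:
    return equilibrate(
        EcosystemState(x0),
        matrix,
        config.growth(k),
        tau=config.tau,
        dt=config.dt,
        stop_tol=config.stop_tol,
    )


def run_evolution(
    config: EvoConfig,
    initial_matrix: Optional[CommunityMatrix] = None,
    patterns: Optional[Sequence[EnvironmentPattern]] = None,
) -> Trajectory:
    """Run the equilibrate -> select -> normalise loop for ``n_generations``.

    The snapshot at generation ``gen`` is the matrix *entering* that
    generation (so the generation-0 snapshot is the initial matrix); the
    matrix after the last update is stored both as a final snapshot and in
    ``final_matrix``.
    """
    if patterns is None:
        patterns = config.patterns()
    patterns = list(patterns)
    matrix = (
        initial_matrix.copy()
        if initial_matrix is not None
        else uniform_community(config.N, config.omega_offdiag0)
    )
    if matrix.n_species != config.N:
        raise ValueError("initial matrix size does not match config.N")
    schedule = config.schedule()
    rate_params = config.rate_params()
    records: List[GenerationRecord] = []
    snapshots: List[Tuple[int, CommunityMatrix]] = []
    x0 = np.full(config.N, config.s0)
    for gen in range(config.n_generations):
        if gen % config.snapshot_stride == 0:
            snapshots.append((gen, matrix.copy()))
        label = env_at(schedule, gen)
        k = _capacities_for(label, patterns, config)
        eq = _equilibrate_in(x0, matrix, k, config)
        growth = config.growth(k)
        delta = selection_delta(eq.state, growth, rate_params)
        matrix.omega += config.update_gain * delta.delta
        matrix = normalize(matrix, tol=config.norm_tol, max_iter=config.norm_max_iter)
        if config.apply_symmetrize:
            matrix = symmetrize(matrix)
        report = conservation_report(matrix)
        records.append(
            GenerationRecord(
                generation=gen,
                env_label=label,
                densities=eq.state.densities.copy(),
                n_steps=eq.n_steps,
                converged=eq.converged,
                overlaps={
                    p.label: overlap_score(eq.state, p) for p in patterns
                },
                max_row_residual=report.max_row_residual,
                max_col_residual=report.max_col_residual,
                max_asymmetry=report.max_asymmetry,
            )
        )
    snapshots.append((config.n_generations, matrix.copy()))
    return Trajectory(
        config=config,
        patterns=patterns,
        records=records,
        snapshots=snapshots,
        final_matrix=matrix,
    )


# ---------------------------------------------------------------------------
# attractor measurement

def overlap_score(state: EcosystemState, pattern: EnvironmentPattern) -> float:
    """Signed similarity in [-1, 1]: mean of sign(x_i - mean(x)) * xi_i."""
    sigma = sign_encode(state.densities)
    return float(sigma @ pattern.xi) / pattern.n_species


@dataclass
class AttractorSet:
    """Distinct equilibria found by Monte-Carlo sampling.

    ``basin_counts[a]`` is the number of retained samples that converged to
    attractor ``a``; ``overlaps[a][p]`` is the overlap score of attractor
    ``a`` against the ``p``-th stored pattern.
    ``n_complement_captured`` counts samples discarded because they
    equilibrated onto the mirror image of a stored pattern (see
    :func:`sample_attractors`).
    """

    attractors: List[EcosystemState]
    basin_counts: List[int]
    overlaps: List[List[float]]
    n_complement_captured: int = 0

    @property
    def n_attractors(self) -> int:
        return len(self.attractors)


#: a sampled equilibrium counts as captured by a mirror-image attractor when
#: its sign pattern is a near-perfect anti-match of a stored pattern ...
_COMPLEMENT_OVERLAP = -0.9
#: ... and its deviation from the community mean is macroscopic (this keeps
#: sub-threshold states, whose tiny tilt can anti-align by chance, counted)
_COMPLEMENT_AMPLITUDE = 0.2


def sample_attractors(
    matrix: CommunityMatrix,
    n_samples: int,
    seed: int,
    config: EvoConfig,
    patterns: Sequence[EnvironmentPattern] = (),
    filter_patterns: Optional[Sequence[EnvironmentPattern]] = None,
) -> AttractorSet:
    """Monte-Carlo census of the attractors in the neutral environment E0.

    Initial densities are uniform on (0, 2*x_bar] where ``x_bar`` is the
    uniform-community equilibrium.  Draws are retained only when they lie
    closer to each filter pattern than to its complement — equivalently,
    when the dot product with the ±1 pattern is positive — which excludes
    the mirror-image attractors that any correlation-encoded memory also
    possesses.  Draws essentially on that decision boundary commit to
    either side unpredictably, so retention additionally requires the dot
    product to clear ``config.filter_margin`` standard deviations of its
    sampling distribution.  Because the basins interleave, a rare filtered
    draw can still equilibrate onto a mirror-image state; such complement
    captures are precluded from the census as well (counted in
    ``n_complement_captured``) — they are identified as macroscopic
    near-perfect anti-matches of a stored pattern, so genuine mixed or
    degraded attractors are never discarded.  Retained draws are
    equilibrated (with the probe step budget) and clustered by max-norm
    distance below ``config.cluster_tol``.
    """
    if n_samples < 0:
        raise ValueError("n_samples must be non-negative")
    if filter_patterns is None:
        filter_patterns = patterns
    rng = np.random.default_rng(seed)
    x_bar = config.uniform_equilibrium()
    # dot(x0, xi) for balanced xi has sd sqrt(N/3)*x_bar under the draws
    dot_sd = math.sqrt(config.N / 3.0) * x_bar
    threshold = config.filter_margin * dot_sd
    k0_vec = carrying_capacities(None, config.k0, config.alpha, N=config.N)
    probe_config = config.with_updates(tau=config.effective_probe_tau())
    reps: List[np.ndarray] = []
    counts: List[int] = []
    retained = 0
    attempts = 0
    n_complement = 0
    max_attempts = max(100 * n_samples, 1000)
    while retained < n_samples and attempts < max_attempts:
        attempts += 1
        x0 = rng.uniform(0.0, 2.0 * x_bar, size=config.N)
        x0[x0 == 0.0] = 1e-12  # open interval: growth is multiplicative
        if any(float(x0 @ p.xi) <= threshold for p in filter_patterns):
            continue
        eq = _equilibrate_in(x0, matrix, k0_vec, probe_config)
        x_eq = eq.state.densities
        mean_eq = float(x_eq.mean())
        amplitude = (
            float(np.linalg.norm(x_eq - mean_eq)) / (math.sqrt(config.N) * mean_eq)
            if mean_eq > 0
            else 0.0
        )
        if amplitude >= _COMPLEMENT_AMPLITUDE and any(
            overlap_score(eq.state, p) <= _COMPLEMENT_OVERLAP for p in filter_patterns
        ):
            n_complement += 1
            continue
        retained += 1
        for idx, rep in enumerate(reps):
            if np.abs(x_eq - rep).max() < config.cluster_tol:
                counts[idx] += 1
                break
        else:
            reps.append(x_eq.copy())
            counts.append(1)
    order = np.argsort(counts)[::-1]
    reps = [reps[i] for i in order]
    counts = [counts[i] for i in order]
    return AttractorSet(
        attractors=[EcosystemState(r) for r in reps],
        basin_counts=counts,
        overlaps=[
            [overlap_score(EcosystemState(r), p) for p in patterns] for r in reps
        ],
        n_complement_captured=n_complement,
    )


def relax_in_neutral(
    state: EcosystemState, matrix: CommunityMatrix, config: EvoConfig
) -> EquilibrationResult:
    """Equilibrate a probe state in the neutral environment E0 (no forcing),
    using the probe step budget."""
    k0_vec = carrying_capacities(None, config.k0, config.alpha, N=config.N)
    probe_config = config.with_updates(tau=config.effective_probe_tau())
    return _equilibrate_in(state.densities, matrix, k0_vec, probe_config)


# ---------------------------------------------------------------------------
# probe initial conditions (never exactly zero: growth is multiplicative)

_HIGH_FACTOR = 1.5
_LOW_FACTOR = 0.1


def pattern_state(pattern: EnvironmentPattern, config: EvoConfig) -> EcosystemState:
    """Density vector expressing a pattern: high density (1.5*x_bar) where
    xi = +1, low density (0.1*x_bar) where xi = -1."""
    x_bar = config.uniform_equilibrium()
    x = np.where(pattern.xi > 0, _HIGH_FACTOR * x_bar, _LOW_FACTOR * x_bar)
    return EcosystemState(x)


def cue_init(
    pattern: EnvironmentPattern,
    fraction_present: float,
    baseline: float,
    config: EvoConfig,
    seed: int = 0,
) -> EcosystemState:
    """Partial-stimulus state: a random ``ceil(fraction*N)`` subset of
    species at pattern-consistent high/low densities, the rest at a uniform
    ``baseline`` density."""
    if not 0.0 <= fraction_present <= 1.0:
        raise ValueError("fraction_present must lie in [0, 1]")
    if baseline <= 0:
        raise ValueError("baseline must be positive (never exactly zero)")
    rng = np.random.default_rng(seed)
    n_cue = math.ceil(fraction_present * config.N)
    full = pattern_state(pattern, config).densities
    x = np.full(config.N, float(baseline))
    if n_cue > 0:
        cue = rng.choice(config.N, size=n_cue, replace=False)
        x[cue] = full[cue]
    return EcosystemState(x)


def corrupt_init(
    pattern: EnvironmentPattern,
    fraction_randomized: float,
    seed: int,
    config: EvoConfig,
) -> EcosystemState:
    """Pattern state with a random subset re-drawn at random high/low values."""
    if not 0.0 <= fraction_randomized <= 1.0:
        raise ValueError("fraction_randomized must lie in [0, 1]")
    rng = np.random.default_rng(seed)
    x = pattern_state(pattern, config).densities.copy()
    n_bad = math.ceil(fraction_randomized * config.N)
    if n_bad > 0:
        bad = rng.choice(config.N, size=n_bad, replace=False)
        x_bar = config.uniform_equilibrium()
        coin = rng.integers(0, 2, size=n_bad).astype(bool)
        x[bad] = np.where(coin, _HIGH_FACTOR * x_bar, _LOW_FACTOR * x_bar)
    return EcosystemState(x)


def mixture_init(
    p1: EnvironmentPattern,
    p2: EnvironmentPattern,
    ratio: float,
    config: EvoConfig,
    seed: int = 0,
) -> EcosystemState:
    """State agreeing with ``p1`` on a fraction ``ratio`` of species and
    with ``p2`` elsewhere.

    The random assignment (decided by ``seed``) is stratified over the
    species where the two patterns agree and where they disagree, so the
    realized resemblance matches the nominal ratio exactly instead of
    fluctuating by a sampling error comparable to a small ratio imbalance.
    ``seed`` is also the documented tie-break at ratio 0.5.
    """
    if p1.n_species != p2.n_species:
        raise ValueError("patterns must have the same length")
    if not 0.0 <= ratio <= 1.0:
        raise ValueError("ratio must lie in [0, 1]")
    rng = np.random.default_rng(seed)
    take1 = np.zeros(config.N, dtype=bool)
    for group in (np.nonzero(p1.xi == p2.xi)[0], np.nonzero(p1.xi != p2.xi)[0]):
        n1 = round(ratio * group.size)
        if n1 > 0:
            take1[rng.choice(group, size=n1, replace=False)] = True
    s1 = pattern_state(p1, config).densities
    s2 = pattern_state(p2, config).densities
    return EcosystemState(np.where(take1, s1, s2))


# ---------------------------------------------------------------------------
# hysteresis

@dataclass
class HysteresisResult:
    """Up/down response curves of a linear forcing ramp between two patterns.

    Curves are overlap scores against the start pattern ``p1``;
    ``loop_area`` is the trapezoid integral of |up - down| over lambda.
    ``up_steps`` / ``down_steps`` are the relaxation lengths (Euler steps to
    equilibrium) at each forcing level, a critical-slowing-down diagnostic.
    """

    lambdas: np.ndarray
    up_overlap_p1: np.ndarray
    down_overlap_p1: np.ndarray
    up_overlap_p2: np.ndarray
    down_overlap_p2: np.ndarray
    up_steps: np.ndarray
    down_steps: np.ndarray
    loop_area: float


def hysteresis_sweep(
    matrix: CommunityMatrix,
    p1: EnvironmentPattern,
    p2: EnvironmentPattern,
    n_lambda_steps: int,
    config: EvoConfig,
    start_state: Optional[EcosystemState] = None,
) -> HysteresisResult:
    """Sweep the forcing linearly p1 -> p2 and back, carrying the state.

    The state equilibrated at each forcing level seeds the next level, so a
    bistable (memory-holding) community traces different branches on the
    way up and the way down.
    """
    if n_lambda_steps < 2:
        raise ValueError("need at least two lambda steps")
    lambdas = np.linspace(0.0, 1.0, n_lambda_steps)
    state = start_state.copy() if start_state is not None else pattern_state(p1, config)
    probe_config = config.with_updates(tau=config.effective_probe_tau())

    def sweep(lams: np.ndarray, state: EcosystemState):
        o1, o2, steps = [], [], []
        for lam in lams:
            k = interpolate_forcing(p1, p2, float(lam), config.k0, config.alpha)
            eq = _equilibrate_in(state.densities, matrix, k, probe_config)
            state = eq.state
            o1.append(overlap_score(state, p1))
            o2.append(overlap_score(state, p2))
            steps.append(eq.n_steps)
        return np.array(o1), np.array(o2), np.array(steps), state

    up1, up2, up_steps, state = sweep(lambdas, state)
    down1, down2, down_steps, _ = sweep(lambdas[::-1], state)
    down1, down2, down_steps = down1[::-1], down2[::-1], down_steps[::-1]
    loop_area = float(np.trapezoid(np.abs(up1 - down1), lambdas))
    return HysteresisResult(
        lambdas=lambdas,
        up_overlap_p1=up1,
        down_overlap_p1=down1,
        up_overlap_p2=up2,
        down_overlap_p2=down2,
        up_steps=up_steps,
        down_steps=down_steps,
        loop_area=loop_area,
    )


# ---------------------------------------------------------------------------
# census over evolutionary time

@dataclass
class CensusRow:
    generation: int
    n_attractors: int
    basin_counts: List[int]
    overlaps: List[List[float]]
    distances: List[float]  # Euclidean distance of each attractor from x_bar


def attractor_census(
    trajectory: Trajectory,
    n_samples: int,
    seed: int,
    config: Optional[EvoConfig] = None,
    stride: int = 1,
) -> List[CensusRow]:
    """Monte-Carlo attractor census at every ``stride``-th stored snapshot."""
    if not trajectory.snapshots:
        return []
    cfg = config if config is not None else trajectory.config
    patterns = trajectory.patterns
    x_bar = cfg.uniform_equilibrium()
    rows: List[CensusRow] = []
    for gen, matrix in trajectory.snapshots[::stride]:
        aset = sample_attractors(
            matrix, n_samples, seed, cfg, patterns=patterns
        )
        rows.append(
            CensusRow(
                generation=gen,
                n_attractors=aset.n_attractors,
                basin_counts=aset.basin_counts,
                overlaps=aset.overlaps,
                distances=[
                    float(np.linalg.norm(a.densities - x_bar))
                    for a in aset.attractors
                ],
            )
        )
    return rows
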