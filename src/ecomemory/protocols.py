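"""Named experimental protocols.

These are the package's reference experiments, shared by the CLI, the test
suite and the reproduction script:

``experiment1``
    Single-environment training: the community evolves for 300 generations
    under constant E1 forcing (100 species).  The trained community holds
    an E1-shaped attractor regardless of subsequent forcing.
``experiment2``
    Alternating-environment training: forcing switches between two
    orthogonal patterns every generation for 400 generations (200 species).
    The trained community holds two attractors, one per pattern, and
    supports recall, repair, classification and hysteresis probes.
``longrun``
    Experiment 2 continued to 480 generations with snapshots every 40
    generations, covering the full life cycle of the memory: one attractor
    (naive) -> two attractors (trained) -> one attractor (the correlation
    feedback overruns the stored pair and a merged state takes over).

Calibration notes.  A stored pattern becomes self-sustaining once its
accumulated Hebbian component D in the community matrix exceeds
D* = (1 + omega_offdiag) / N, and the pure two-attractor regime survives
up to roughly 2 D*, beyond which the merged (union) state dominates; the
training lengths and per-generation Hebb steps below are chosen so each
protocol ends in the regime it studies.  Two-pattern protocols use 200
species: the row/column renormalisation couples stored patterns at order
1/N, and at 100 species that cross-talk erodes the two-attractor window.
Exactly orthogonal balanced patterns make the protocols seed-invariant up
to species relabeling (the model is permutation-symmetric), so only the
Monte-Carlo probe streams vary with the seed.
"""

from __future__ import annotations

from typing import List, Optional, Tuple

import numpy as np

from .dynamics import CommunityMatrix, uniform_community
from .environments import EnvironmentPattern, generate_patterns
from .experiments import EvoConfig, Trajectory, run_evolution

__all__ = [
    "experiment1_config",
    "experiment2_config",
    "longrun_config",
    "hebb_cycle_config",
    "protocol_patterns",
    "run_experiment",
]

#: per-generation effective Hebb steps (see module docstring)
_ETA_EXPT1 = 0.0012
_ETA_EXPT2 = 0.00063


def experiment1_config(pattern_seed: int = 12345, sample_seed: int = 67890) -> EvoConfig:
    """Constant-E1 training, 100 species, 300 generations."""
    return EvoConfig.desk_scale(
        env_sequence=("E1",),
        update_gain=EvoConfig._gain_for_eta(_ETA_EXPT1),
        pattern_seed=pattern_seed,
        sample_seed=sample_seed,
    )


def experiment2_config(pattern_seed: int = 12345, sample_seed: int = 67890) -> EvoConfig:
    """Alternating E1/E2 training, 200 species, 400 generations."""
    return EvoConfig.desk_scale(
        N=200,
        n_generations=400,
        env_sequence=("E1", "E2"),
        update_gain=EvoConfig._gain_for_eta(_ETA_EXPT2),
        pattern_seed=pattern_seed,
        sample_seed=sample_seed,
    )


def longrun_config(pattern_seed: int = 12345, sample_seed: int = 67890) -> EvoConfig:
    """Experiment 2 extended through the breakdown of the two-attractor
    regime, with snapshots every 40 generations."""
    cfg = experiment2_config(pattern_seed, sample_seed)
    return cfg.with_updates(n_generations=480, snapshot_stride=40)


def hebb_cycle_config(
    rate_model: str = "serial",
    pattern_seed: int = 12345,
    R: Optional[float] = None,
    r_out: Optional[float] = None,
) -> EvoConfig:
    """One full E1/E2 training cycle at the desk community size with unit
    update gain, for comparing the evolved change against Hebb's rule."""
    if rate_model == "linked_linear" and R is None:
        R = 1.0
    if rate_model == "facultative" and r_out is None:
        r_out = 0.01
    return EvoConfig.desk_scale(
        n_generations=2,
        env_sequence=("E1", "E2"),
        update_gain=1.0,
        rate_model=rate_model,
        R=R,
        r_out=r_out,
        snapshot_stride=1,
        pattern_seed=pattern_seed,
    )


def protocol_patterns(config: EvoConfig, n: int = 2) -> List[EnvironmentPattern]:
    """Patterns for the named protocols: balanced and exactly orthogonal."""
    return generate_patterns(config.N, n, config.pattern_seed, target_overlap=0.0)


def run_experiment(
    config: EvoConfig,
    patterns: Optional[List[EnvironmentPattern]] = None,
) -> Tuple[Trajectory, List[EnvironmentPattern]]:
    """Train from the uniform initial community under a protocol config."""
    if patterns is None:
        patterns = protocol_patterns(config)
    initial = uniform_community(config.N, config.omega_offdiag0)
    trajectory = run_evolution(config, initial_matrix=initial, patterns=patterns)
    return trajectory, patterns
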