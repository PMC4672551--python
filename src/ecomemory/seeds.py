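"""Seed management: one master seed, independent named streams."""

from __future__ import annotations

from typing import Tuple

import numpy as np

__all__ = ["derive_seeds"]


def derive_seeds(master_seed: int) -> Tuple[int, int]:
    """Derive the (pattern, sampling/probe) seed pair from one master seed.

    Uses numpy's SeedSequence spawning so the two streams are statistically
    independent; both derived seeds fit in 31 bits.
    """
    children = np.random.SeedSequence(master_seed).spawn(2)
    return tuple(int(c.generate_state(1)[0] % (2**31)) for c in children)  # type: ignore[return-value]
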