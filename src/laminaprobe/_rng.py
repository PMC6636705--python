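"""Seed handling.

One root seed per run; every stochastic component draws from its own child
stream spawned from the root `SeedSequence`, so adding a component never
perturbs the streams of the others.
"""

from __future__ import annotations

import numpy as np

__all__ = ["as_rng", "child_seeds", "spawn_rngs"]


def as_rng(seed) -> np.random.Generator:
    """Return a Generator from a seed, SeedSequence or existing Generator."""
    if isinstance(seed, np.random.Generator):
        return seed
    return np.random.default_rng(seed)


def child_seeds(root_seed: int, n: int) -> list[int]:
    """Derive `n` independent 31-bit child seeds from a root seed."""
    ss = np.random.SeedSequence(root_seed)
    return [int(s.generate_state(1)[0] % (2**31)) for s in ss.spawn(n)]


def spawn_rngs(root_seed: int, n: int) -> list[np.random.Generator]:
    """Spawn `n` independent Generators from one root seed."""
    return [np.random.default_rng(s) for s in np.random.SeedSequence(root_seed).spawn(n)]
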