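"""Seeding helpers.

Every stochastic operation takes an integer seed and derives independent
sub-streams from it with :func:`substream`, so that (a) identical seeds give
bit-identical output and (b) enlarging a sample extends it row-wise without
perturbing earlier rows (each logical source of randomness draws from its
own stream, and NumPy generators fill arrays sequentially).
"""

from __future__ import annotations

import numpy as np

__all__ = ["substream"]


def substream(seed: int, key: int) -> np.random.Generator:
    """Return a generator for sub-stream ``key`` of ``seed``.

    Distinct keys give statistically independent streams (SeedSequence
    spawning), and the mapping is stable across processes and platforms.
    """
    seed = int(seed)
    if seed < 0:
        raise ValueError("seed must be non-negative")
    return np.random.default_rng(np.random.SeedSequence(entropy=seed, spawn_key=(int(key),)))
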