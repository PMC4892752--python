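"""Deterministic RNG substreams.

One root seed governs a whole run; every stochastic stage draws from a
named child stream so that stages are reproducible independently of the
order in which they execute.
"""

from __future__ import annotations

import numpy as np

__all__ = ["child_rng", "child_seed"]


def child_rng(seed: int, *key: int) -> np.random.Generator:
    """Return a Generator for the substream identified by ``key``.

    Parameters
    ----------
    seed : int
        Root seed of the run.
    key : int
        Non-negative integers naming the substream (e.g. subject index,
        task index). The same (seed, key) always yields the same stream.
    """
    if any(k < 0 for k in key):
        raise ValueError("substream keys must be non-negative integers")
    return np.random.default_rng(np.random.SeedSequence(seed, spawn_key=tuple(key)))


def child_seed(seed: int, *key: int) -> int:
    """A derived integer seed (< 2**31) for APIs that want a plain int."""
    return int(child_rng(seed, *key).integers(0, 2**31 - 1))
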