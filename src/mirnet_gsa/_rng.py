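"""Seed-substream plumbing.

All randomness in the package flows from a single integer seed through
named substreams, so each simulation stage (annotation, genotypes,
effects, expression, ...) is independently reproducible.
"""
from __future__ import annotations

import numpy as np

# Fixed order: the position of a name in this tuple is its spawn key.
STREAMS: tuple[str, ...] = (
    "annotation",
    "networks",
    "genotypes",
    "effects",
    "noise",
    "expression",
    "permutation",
    "random_networks",
)


def substream(seed: int, name: str) -> np.random.Generator:
    """Return a Generator for the named substream of ``seed``.

    Identical (seed, name) pairs always yield identical streams, and
    distinct names yield statistically independent streams.
    """
    try:
        key = STREAMS.index(name)
    except ValueError:
        raise KeyError(f"unknown substream {name!r}; known: {STREAMS}") from None
    ss = np.random.SeedSequence(int(seed), spawn_key=(key,))
    return np.random.default_rng(ss)


def as_generator(rng: int | np.random.Generator | None) -> np.random.Generator:
    """Coerce ``rng`` (Generator, seed int, or None) to a Generator."""
    if isinstance(rng, np.random.Generator):
        return rng
    return np.random.default_rng(rng)
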