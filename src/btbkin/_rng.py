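"""Named random substreams.

All randomness in the package flows from one top-level integer seed. Each
artifact (standards table, perfusion series, section, autoradiograph, ...)
draws from its own named substream so that adding a new output to a run
never perturbs the numbers of an existing one.
"""

from __future__ import annotations

import zlib

import numpy as np

__all__ = ["substream"]


def substream(seed: int, name: str) -> np.random.Generator:
    """Return a Generator keyed by (seed, name).

    The stream depends only on the seed and the name, not on creation
    order, so independent artifacts are reproducible in isolation.
    """
    if seed < 0:
        raise ValueError(f"seed must be non-negative, got {seed}")
    return np.random.default_rng([int(seed), zlib.crc32(name.encode("utf-8"))])
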