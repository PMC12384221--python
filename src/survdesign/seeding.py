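"""Reproducible random-stream management.

All randomness in the package flows from a single master seed through
`numpy.random.SeedSequence` spawn keys.  Substreams are derived with
stable integer keys (scenario family, scenario index, process tag), so
running a subset of scenarios reproduces exactly the numbers the full
grid would produce, and adding new scenarios never perturbs old ones.
"""

from __future__ import annotations

import numpy as np

__all__ = ["as_seed_sequence", "substream", "generator"]


def as_seed_sequence(seed) -> np.random.SeedSequence:
    """Coerce an int, SeedSequence or Generator-compatible seed."""
    if isinstance(seed, np.random.SeedSequence):
        return seed
    if isinstance(seed, np.random.Generator):
        raise TypeError(
            "pass an integer or SeedSequence, not a Generator: substream "
            "derivation needs spawnable entropy")
    return np.random.SeedSequence(seed)


def substream(master_seed, *key: int) -> np.random.SeedSequence:
    """Child seed sequence for a stable integer key path."""
    root = as_seed_sequence(master_seed)
    return np.random.SeedSequence(entropy=root.entropy,
                                  spawn_key=tuple(int(k) for k in key))


def generator(master_seed, *key: int) -> np.random.Generator:
    """Generator on the substream identified by ``key``."""
    return np.random.default_rng(substream(master_seed, *key))
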