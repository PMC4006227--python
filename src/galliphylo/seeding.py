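"""Deterministic seed derivation.

Every stochastic component takes an explicit seed derived from one master
seed by a fixed rule, so any single replicate can be reproduced in isolation:

    derive_seed(master, *path)

where ``path`` is a tuple of small nonnegative integers naming the component
(stage index, locus index, replicate index, ...).  The rule is
``numpy.random.SeedSequence(master, spawn_key=path)`` reduced to one uint32
(mapped away from zero so the result is usable where zero seeds are
rejected).  No component ever draws from a global generator.
"""

from __future__ import annotations

import numpy as np


def derive_seed(master: int, *path: int) -> int:
    """A stable 32-bit seed for the component addressed by ``path``."""
    ss = np.random.SeedSequence(int(master), spawn_key=tuple(int(p) for p in path))
    val = int(ss.generate_state(1, np.uint32)[0])
    return val if val != 0 else 1


def rng_for(master: int, *path: int) -> np.random.Generator:
    return np.random.default_rng(derive_seed(master, *path))
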