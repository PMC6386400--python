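"""Named random substreams derived from one master seed.

Every stochastic routine in the package draws from a generator created by
:func:`substream`, so a single master seed reproduces a whole run bitwise
while keeping the streams for cohort generation, ELM initialisation,
cross-validation splits, permutations and Monte-Carlo cluster simulation
statistically independent of one another.
"""

from __future__ import annotations

import zlib

import numpy as np


def substream(master_seed: int, name: str) -> np.random.Generator:
    """Deterministic, name-keyed child generator of ``master_seed``."""
    key = zlib.crc32(name.encode("utf-8"))
    return np.random.default_rng(np.random.SeedSequence([int(master_seed), key]))


def substream_seed(master_seed: int, name: str) -> int:
    """A 31-bit integer seed for libraries that take plain int seeds."""
    return int(substream(master_seed, name).integers(0, 2**31 - 1))
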