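"""Named deterministic RNG streams.

Every stochastic artifact of the simulator draws from its own stream, derived
from the master seed plus a stable string key (CRC32 of the key name). Adding
a new artifact therefore never perturbs the random draws of existing ones,
and identical (seed, key) pairs reproduce bit-identical output on any
platform.
"""

from __future__ import annotations

import zlib

import numpy as np

__all__ = ["stream"]


def stream(master_seed: int, key: str) -> np.random.Generator:
    """Return the RNG stream for artifact `key` under `master_seed`."""
    entropy = [int(master_seed) & 0x7FFFFFFF, zlib.crc32(key.encode("utf-8"))]
    return np.random.default_rng(np.random.SeedSequence(entropy))
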