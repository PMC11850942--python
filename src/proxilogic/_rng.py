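"""Per-generator random streams.

Each synthetic-data generator draws from its own stream derived from
(seed, generator name), so adding or reordering generators never perturbs
the output of the others.
"""

from __future__ import annotations

import zlib

import numpy as np


def stream(seed: int, name: str) -> np.random.Generator:
    """Return a Generator keyed to (seed, name)."""
    key = zlib.crc32(name.encode("utf-8"))
    return np.random.default_rng(np.random.SeedSequence([int(seed), key]))
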