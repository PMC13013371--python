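"""Named random substreams off a single master seed.

Every source of randomness in the package (corpus generation, split
subsampling, weight initialization, batch sampling, rendering noise) draws
from its own named substream so that changing one stage never perturbs
another, and a full experiment is bitwise reproducible from one integer.
"""

from __future__ import annotations

import hashlib

import numpy as np


def substream_seed(master_seed: int, *names: object) -> int:
    """Derive a stable 31-bit seed for the substream named by ``names``."""
    key = ":".join(str(n) for n in (master_seed, *names))
    digest = hashlib.sha256(key.encode("utf-8")).digest()
    return int.from_bytes(digest[:4], "big") % (2**31)


def substream(master_seed: int, *names: object) -> np.random.Generator:
    """A numpy Generator seeded from a named substream of the master seed."""
    return np.random.default_rng(substream_seed(master_seed, *names))
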