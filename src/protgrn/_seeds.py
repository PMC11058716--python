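"""Deterministic per-stage seed derivation from one root seed.

Every stochastic stage derives its Generator from the run's root seed plus a
stable stage label, so a run manifest (root seed + parameters) fully
determines all outputs.
"""

from __future__ import annotations

import zlib

import numpy as np


def stage_seed(root_seed: int, *labels) -> int:
    """A 31-bit seed derived from the root seed and stage labels."""
    key = "/".join(str(x) for x in labels)
    h = zlib.crc32(key.encode("utf8"))
    ss = np.random.SeedSequence([int(root_seed) & 0x7FFFFFFF, h])
    return int(ss.generate_state(1)[0] & 0x7FFFFFFF)


def stage_rng(root_seed: int, *labels) -> np.random.Generator:
    return np.random.default_rng(stage_seed(root_seed, *labels))
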