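"""Small shared helpers: deterministic seed derivation and label plumbing."""

from __future__ import annotations

import zlib

import numpy as np

MAX_SEED = 2**31  # keep derived seeds in int32 range


def derive_seed(seed: int, *keys) -> int:
    """Derive a child seed deterministically from a base seed and context keys.

    String keys are hashed with crc32 so that the derivation is stable across
    processes and Python versions (unlike ``hash``).
    """
    ints = [int(seed) % MAX_SEED]
    for k in keys:
        if isinstance(k, str):
            ints.append(zlib.crc32(k.encode("utf8")))
        else:
            ints.append(int(k) % MAX_SEED)
    ss = np.random.SeedSequence(ints)
    return int(ss.generate_state(1, np.uint32)[0] % MAX_SEED)


def rng_from(seed: int, *keys) -> np.random.Generator:
    return np.random.default_rng(derive_seed(seed, *keys))
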