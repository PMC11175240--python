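"""Deterministic seed derivation shared by all stochastic stages."""

import hashlib

import numpy as np


def derive_seed(global_seed: int, *tags) -> int:
    """Derive a stable sub-seed (< 2**31) from a global seed and string tags."""
    key = ":".join([str(int(global_seed))] + [str(t) for t in tags])
    digest = hashlib.sha256(key.encode("utf-8")).digest()
    return int.from_bytes(digest[:4], "big") % (2**31)


def spawn_rng(global_seed: int, *tags) -> np.random.Generator:
    """A Generator seeded from :func:`derive_seed`."""
    return np.random.default_rng(derive_seed(global_seed, *tags))
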