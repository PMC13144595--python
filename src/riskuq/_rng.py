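"""Hierarchical seeding helpers.

One master seed per experiment; every stochastic operation derives its own
child generator from the master seed plus a string path, so adding or
reordering stages never silently shifts the random stream of another stage.
"""

from __future__ import annotations

import hashlib

import numpy as np


def _key_to_int(key: object) -> int:
    digest = hashlib.blake2b(str(key).encode("utf-8"), digest_size=4).digest()
    return int.from_bytes(digest, "little")


def child_seed_sequence(seed: int, *keys: object) -> np.random.SeedSequence:
    """SeedSequence for ``seed`` specialised by a path of string/int keys."""
    return np.random.SeedSequence([int(seed)] + [_key_to_int(k) for k in keys])


def derive_rng(seed: int, *keys: object) -> np.random.Generator:
    """Child generator for a (seed, path) pair; stable across runs."""
    return np.random.default_rng(child_seed_sequence(seed, *keys))


def derive_int_seed(seed: int, *keys: object) -> int:
    """A plain integer child seed below 2**31 (for APIs that take ints)."""
    return int(child_seed_sequence(seed, *keys).generate_state(1)[0] % (2**31))
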