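"""Deterministic seed derivation.

Every stochastic step (undersampling, outer split, K-means, each of the t
inner scoring splits, each learner fit) draws its seed from the master seed
through :func:`derive_seed`, keyed by a path of strings/integers naming the
step. The scheme is counter-based (numpy ``SeedSequence`` with a spawn key),
so runs are reproducible and independent steps get decorrelated streams.
"""

from __future__ import annotations

import zlib

import numpy as np

__all__ = ["derive_seed"]

_MOD = 2**31


def _key_to_int(key: str | int) -> int:
    if isinstance(key, str):
        return zlib.crc32(key.encode("utf-8"))
    return int(key) & 0xFFFFFFFF


def derive_seed(master_seed: int, *path: str | int) -> int:
    """Map ``(master_seed, path...)`` to a seed in ``[0, 2**31)``.

    The same inputs always yield the same seed; distinct paths yield
    statistically independent seeds.
    """
    spawn_key = tuple(_key_to_int(k) for k in path)
    ss = np.random.SeedSequence(entropy=int(master_seed), spawn_key=spawn_key)
    return int(ss.generate_state(1)[0] % _MOD)
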