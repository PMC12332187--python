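"""Deterministic child-seed derivation.

Every stochastic operation derives its generator from a master seed plus a
stable entity token, so end-to-end runs are bit-identical and independent of
call order.
"""

from __future__ import annotations

import zlib

import numpy as np


def derive_seed(master: int, *tokens: object) -> int:
    """A stable 31-bit child seed from a master seed and hashable tokens."""
    payload = repr((int(master),) + tokens).encode()
    return zlib.crc32(payload) & 0x7FFFFFFF


def child_rng(master: int, *tokens: object) -> np.random.Generator:
    return np.random.default_rng(derive_seed(master, *tokens))
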