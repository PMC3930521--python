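"""Deterministic random-stream derivation.

Every stochastic routine in the package draws from a stream derived from one
master seed plus a short textual label (test name, population pair, replicate
index), so results are reproducible regardless of the order in which the
computations run.
"""

from __future__ import annotations

import hashlib

import numpy as np


def derive_seed(master_seed: int, *tokens) -> int:
    """Stable 31-bit child seed from a master seed and labelling tokens."""
    payload = repr((int(master_seed),) + tuple(str(t) for t in tokens)).encode()
    digest = hashlib.sha256(payload).digest()
    return int.from_bytes(digest[:4], "big") % (2**31)


def derive_rng(master_seed: int, *tokens) -> np.random.Generator:
    return np.random.default_rng(derive_seed(master_seed, *tokens))
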