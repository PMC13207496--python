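"""Stable seed derivation.

Child seeds are derived from a master seed plus a tuple of string-able context
parts via SHA-256, so adding new components or reordering loops never perturbs
the random stream of an existing component.
"""

import hashlib

import numpy as np


def child_seed(*parts) -> int:
    """Derive a deterministic 31-bit seed from (master_seed, *context)."""
    payload = "|".join(str(p) for p in parts).encode()
    return int.from_bytes(hashlib.sha256(payload).digest()[:4], "little") % (2**31)


def child_rng(*parts) -> np.random.Generator:
    return np.random.default_rng(child_seed(*parts))
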