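"""Deterministic sub-seed derivation.

Every stage of a pipeline run draws its randomness from a sub-seed derived
from the master seed and a stage name, so adding or reordering stages never
reshuffles the randomness of existing stages.
"""

from __future__ import annotations

import hashlib

__all__ = ["derive_seed"]

_MOD = 2**31  # keep derived seeds in int32 range


def derive_seed(master_seed: int, stage: str) -> int:
    """Derive a stable 31-bit sub-seed from ``master_seed`` and a stage label."""
    digest = hashlib.sha256(f"{int(master_seed)}:{stage}".encode()).digest()
    return int.from_bytes(digest[:8], "big") % _MOD
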