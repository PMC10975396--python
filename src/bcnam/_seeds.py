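"""Deterministic seed derivation for pipeline stages.

A single master seed is mapped to per-stage seeds through a keyed hash of the
stage label, so adding or reordering stages never perturbs the random stream
of any other stage.
"""

from __future__ import annotations

import hashlib

__all__ = ["derive_seed"]


def derive_seed(master: int, label: str) -> int:
    """Derive a stage seed (< 2**31) from a master seed and a stage label."""
    digest = hashlib.blake2b(
        f"{int(master)}:{label}".encode(), digest_size=8
    ).digest()
    return int.from_bytes(digest, "little") % (2**31)
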