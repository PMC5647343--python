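"""Deterministic seed derivation for replicate-level reproducibility."""

from __future__ import annotations

import hashlib

__all__ = ["derive_seed"]


def derive_seed(master: int, *tags: object) -> int:
    """A stable 31-bit seed derived from a master seed and context tags.

    Re-running any single replicate with its derived seed reproduces it
    bit-for-bit, independent of the other replicates.
    """
    key = ":".join([str(int(master))] + [str(t) for t in tags])
    digest = hashlib.sha256(key.encode("utf-8")).digest()
    return int.from_bytes(digest[:4], "big") % (2**31)
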