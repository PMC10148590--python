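"""Shared helpers: reproducible per-stage seed derivation."""

from __future__ import annotations

import hashlib

__all__ = ["stage_seed"]


def stage_seed(global_seed: int, stage: str) -> int:
    """A deterministic, stage-specific seed derived from the global one.

    Hashing keeps the streams of different stages independent while every
    run with the same global seed reproduces them exactly.
    """
    digest = hashlib.sha256(f"{int(global_seed)}:{stage}".encode()).digest()
    return int.from_bytes(digest[:4], "big") % (2**31 - 1)
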