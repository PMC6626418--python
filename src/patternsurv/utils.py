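"""Small shared helpers."""

from __future__ import annotations

import hashlib


def derive_seed(master: int, label: str) -> int:
    """Deterministically derive a stage seed from a master seed and a label.

    Stable across processes and platforms (unlike ``hash``), so pipeline
    stages can be re-run in isolation with reproducible randomness.
    """
    digest = hashlib.sha256(f"{int(master)}:{label}".encode()).digest()
    return int.from_bytes(digest[:4], "big")
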