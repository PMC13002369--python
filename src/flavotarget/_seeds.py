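"""Deterministic per-stage seed derivation.

Every stochastic operation in the package derives its own integer seed from
(global seed, stage name) so that one top-level seed reproduces the whole
pipeline bit-for-bit while stages stay statistically independent.
"""

from __future__ import annotations

import hashlib

#: numpy Generator and scikit-learn both accept seeds below 2**31.
MAX_SEED = 2**31 - 1


def child_seed(seed: int, stage: str) -> int:
    """Derive a stage-specific seed from a global seed.

    Uses SHA-256 of ``"{seed}:{stage}"`` so the mapping is stable across
    Python versions and processes (``hash()`` is salted; never use it here).
    """
    digest = hashlib.sha256(f"{int(seed)}:{stage}".encode()).digest()
    return int.from_bytes(digest[:4], "big") % MAX_SEED
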