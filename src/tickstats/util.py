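"""Shared helpers: deterministic child-seed derivation."""

from __future__ import annotations

import zlib

import numpy as np


def child_seed(master_seed: int, *names: str) -> int:
    """Derive a reproducible, order-independent child seed.

    Each (master seed, name path) pair maps to its own stream, so adding a
    new consumer never perturbs another's randomness.
    """
    tag = zlib.crc32("/".join(names).encode("utf-8"))
    return int(np.random.SeedSequence([master_seed, tag]).generate_state(1)[0])
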