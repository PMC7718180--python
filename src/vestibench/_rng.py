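"""Deterministic seed derivation.

One top-level seed expands into per-component seeds through a stable hash of
a component label, so every stage (generator, folds, each model on each fold)
is independently reproducible.  Derived seeds stay below 2**31.
"""

from __future__ import annotations

import zlib

import numpy as np


def derive_seed(master: int, label: str) -> int:
    """A stable per-component seed in [0, 2**31) from a master seed + label."""
    ss = np.random.SeedSequence([int(master) & 0x7FFFFFFF, zlib.crc32(label.encode())])
    return int(ss.generate_state(1)[0] % (2 ** 31))
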