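"""Hierarchical seed derivation.

One master seed governs every stochastic stage.  Stage seeds are derived by
mixing the master seed with a CRC32 of the stage name through numpy's
SeedSequence, so stages can be re-run independently yet reproducibly and
adding a stage never perturbs the streams of existing ones.
"""

from __future__ import annotations

import zlib

import numpy as np

__all__ = ["derive_seed", "stage_rng"]


def derive_seed(master: int, stage: str) -> int:
    """Derive a deterministic 31-bit seed for ``stage`` from ``master``."""
    if master < 0:
        raise ValueError("master seed must be non-negative")
    key = zlib.crc32(stage.encode("utf-8"))
    ss = np.random.SeedSequence(entropy=[int(master), key])
    return int(ss.generate_state(1, dtype=np.uint32)[0] & 0x7FFFFFFF)


def stage_rng(master: int, stage: str) -> np.random.Generator:
    """A Generator seeded for one named pipeline stage."""
    return np.random.default_rng(derive_seed(master, stage))
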