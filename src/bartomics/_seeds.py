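"""Deterministic fan-out of one global seed into per-stage streams."""

from __future__ import annotations

import zlib

import numpy as np


def stage_seed(global_seed: int, stage: str, index: int = 0) -> int:
    """Derive a reproducible 31-bit seed for a named stage.

    The stage name is hashed with CRC32 (stable across processes, unlike
    Python's randomised ``hash``) and mixed with the global seed through a
    SeedSequence, so stages can be re-run independently yet reproducibly.
    """
    tag = zlib.crc32(stage.encode("utf-8"))
    ss = np.random.SeedSequence([int(global_seed) & 0x7FFFFFFF, tag, int(index)])
    return int(ss.generate_state(1)[0] % (2 ** 31))
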