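"""Seed-substream helpers.

All randomness in the package flows from a single integer seed; each stage
derives its own independent stream from the top-level seed plus a stage name,
so stages can be re-run in isolation and still reproduce a full-pipeline run.
"""

from __future__ import annotations

import zlib

import numpy as np

_MOD = 2**31


def substream_seed(seed: int, name: str) -> int:
    """Derive a stable per-stage integer seed (< 2**31) from ``seed`` and a name."""
    ss = np.random.SeedSequence([int(seed) % _MOD, zlib.crc32(name.encode("utf-8"))])
    return int(ss.generate_state(1)[0] % _MOD)


def substream_rng(seed: int, name: str) -> np.random.Generator:
    """A ``numpy.random.Generator`` seeded from the named substream."""
    return np.random.default_rng(substream_seed(seed, name))
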