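"""Deterministic random-stream fan-out.

One root integer seed is fanned out into independent, *named* substreams
so each pipeline stage (sampling, placement, rendering noise, run-out,
...) can be re-run on its own with stable randomness.  No global numpy
state is ever touched.
"""

from __future__ import annotations

import zlib

import numpy as np

__all__ = ["substream", "substream_seed"]


def substream_seed(root_seed: int, *tags: str | int) -> np.random.SeedSequence:
    """SeedSequence for the substream named by ``tags`` under ``root_seed``."""
    if root_seed < 0:
        raise ValueError("seed must be a non-negative integer")
    entropy = [int(root_seed)]
    for tag in tags:
        if isinstance(tag, str):
            entropy.append(zlib.crc32(tag.encode("utf-8")))
        else:
            entropy.append(int(tag))
    return np.random.SeedSequence(entropy)


def substream(root_seed: int, *tags: str | int) -> np.random.Generator:
    """Generator for the named substream (PCG64)."""
    return np.random.default_rng(substream_seed(root_seed, *tags))
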