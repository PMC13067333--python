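"""Seed bookkeeping: one root seed, named independent substreams."""

from __future__ import annotations

import zlib

import numpy as np

__all__ = ["substream"]


def _key(name: str) -> int:
    # stable across processes/platforms (unlike hash())
    return zlib.crc32(name.encode("utf-8"))


def substream(seed: int, *names: str | int) -> np.random.Generator:
    """Return a Generator for the substream addressed by ``names``.

    The same (seed, names) pair always yields an identical stream, and
    distinct name paths yield statistically independent streams, so every
    stage of a pipeline (schedule, noise, permutations, ...) can draw from
    its own generator without interfering with the others.
    """
    keys = [_key(n) if isinstance(n, str) else int(n) for n in names]
    ss = np.random.SeedSequence(entropy=int(seed), spawn_key=tuple(keys))
    return np.random.default_rng(ss)
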