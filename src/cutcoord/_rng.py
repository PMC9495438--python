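"""Seeded random-number substreams.

All stochastic code in the package draws from named substreams derived from a
single top-level integer seed, so that any artifact can be regenerated
bit-identically from (seed, stream name) alone.
"""

from __future__ import annotations

import zlib

import numpy as np

__all__ = ["substream", "child_seed"]


def _key(token: object) -> int:
    return zlib.crc32(str(token).encode("utf-8"))


def substream(seed: int, *names: object) -> np.random.Generator:
    """Return a Generator for the substream identified by ``names``.

    The same (seed, names) pair always yields an identically-seeded
    generator; distinct name tuples yield statistically independent streams.
    """
    entropy = [int(seed)] + [_key(n) for n in names]
    return np.random.default_rng(np.random.SeedSequence(entropy))


def child_seed(seed: int, *names: object) -> int:
    """A derived integer seed (< 2**31) for code that wants a plain int."""
    entropy = [int(seed)] + [_key(n) for n in names]
    return int(np.random.SeedSequence(entropy).generate_state(1)[0] % (2**31))
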