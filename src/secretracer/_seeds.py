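"""Named random substreams derived from one master seed.

Every stochastic stage draws from ``substream(master, name)`` so stages can
be rerun in isolation and still reproduce the full-pipeline results.  The
substream key is a CRC32 of the stage name folded into a numpy SeedSequence
spawn key, so adding a stage never perturbs the streams of existing ones.
"""

from __future__ import annotations

import zlib

import numpy as np

__all__ = ["substream", "substream_int"]


def substream(master_seed: int, name: str) -> np.random.Generator:
    """Return a Generator for the named substream of ``master_seed``."""
    key = zlib.crc32(name.encode("utf-8")) & 0x7FFFFFFF
    return np.random.default_rng(np.random.SeedSequence(int(master_seed), spawn_key=(key,)))


def substream_int(master_seed: int, name: str) -> int:
    """A 31-bit integer seed for libraries that take int seeds (sklearn)."""
    return int(substream(master_seed, name).integers(2**31))
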