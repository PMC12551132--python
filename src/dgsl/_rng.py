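"""Named, reproducible random substreams derived from one master seed.

Every source of randomness in the package (initialization, fold shuffling,
negative sampling, pair sampling, pseudo-edge insertion, edge dropping,
cold-start selection) draws from its own substream so that experiments are
independently reproducible: changing how many pairs one experiment samples
never perturbs another experiment run under the same master seed.
"""

from __future__ import annotations

import zlib

import numpy as np

__all__ = ["substream", "substream_seed"]


def _name_key(name: str) -> int:
    # crc32 is stable across platforms and python versions, unlike hash()
    return zlib.crc32(name.encode("utf-8"))


def substream_seed(master_seed: int, name: str, index: int = 0) -> np.random.SeedSequence:
    """SeedSequence for the substream ``name`` (optionally step-indexed)."""
    return np.random.SeedSequence(entropy=int(master_seed), spawn_key=(_name_key(name), int(index)))


def substream(master_seed: int, name: str, index: int = 0) -> np.random.Generator:
    """Fresh Generator for the named substream of ``master_seed``."""
    return np.random.Generator(np.random.PCG64(substream_seed(master_seed, name, index)))
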