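"""Named, reproducible random substreams derived from one master seed.

Every stage of a pipeline (scenario generation, solver tie-breaks, network
initialisation, simulation, vote tie-breaking) draws from its own named
stream so stages can be re-run in isolation without perturbing each other.
"""

from __future__ import annotations

import zlib

import numpy as np

__all__ = ["substream", "subseed"]


def subseed(master_seed: int, name: str) -> int:
    """A deterministic 31-bit integer seed for the named substream."""
    tag = zlib.crc32(name.encode("utf-8"))
    ss = np.random.SeedSequence(entropy=int(master_seed) & 0x7FFFFFFF, spawn_key=(tag,))
    return int(ss.generate_state(1)[0] & 0x7FFFFFFF)


def substream(master_seed: int, name: str) -> np.random.Generator:
    """A numpy Generator seeded from ``(master_seed, name)``."""
    return np.random.default_rng(subseed(master_seed, name))
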