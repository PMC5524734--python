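"""Seed plumbing: one user-facing integer, per-stage substreams."""

from __future__ import annotations

import numpy as np


def as_seedseq(seed) -> np.random.SeedSequence:
    """Accept an int or an existing SeedSequence (e.g. a spawned substream)."""
    if isinstance(seed, np.random.SeedSequence):
        return seed
    return np.random.SeedSequence(seed)
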