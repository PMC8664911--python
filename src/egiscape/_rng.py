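"""Named, reproducible random substreams.

Every stage of the pipeline draws from its own substream derived from one
root seed, so stages can be re-run in isolation without perturbing each
other's randomness.
"""

from __future__ import annotations

import hashlib

import numpy as np

__all__ = ["substream", "generator"]


def substream(seed: int, name: str) -> np.random.SeedSequence:
    """Return a SeedSequence for stage `name` derived from `seed`.

    The name is hashed into the entropy pool so distinct stage names give
    statistically independent streams while staying fully deterministic.
    """
    tag = int.from_bytes(
        hashlib.blake2b(name.encode("utf-8"), digest_size=4).digest(), "little"
    )
    return np.random.SeedSequence([int(seed), tag])


def generator(seed: int, name: str) -> np.random.Generator:
    """Convenience wrapper: a Generator on the named substream."""
    return np.random.default_rng(substream(seed, name))
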