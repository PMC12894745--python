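"""Named random substreams derived from a single pipeline seed.

Every stochastic stage draws from ``rng_for(seed, "stage-name", ...)``
so a run is fully reproducible from one integer and no stage perturbs
another's stream.
"""

from __future__ import annotations

import hashlib

import numpy as np


def _name_entropy(names: tuple) -> list[int]:
    digest = hashlib.blake2b("/".join(map(str, names)).encode(), digest_size=16).digest()
    return [int.from_bytes(digest[i : i + 4], "little") for i in range(0, 16, 4)]


def rng_for(seed: int, *names) -> np.random.Generator:
    """Generator for the substream identified by ``names`` under ``seed``."""
    return np.random.default_rng(np.random.SeedSequence([int(seed)] + _name_entropy(names)))


def child_seed(seed: int, *names) -> int:
    """31-bit integer seed for libraries that take a plain int (e.g. sklearn)."""
    return int(rng_for(seed, *names).integers(2**31))
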