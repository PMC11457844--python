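"""Named substreams off a single root seed.

Every stochastic stage draws from its own substream so that adding or
reordering one stage never perturbs the draws of another, while a single
integer seed still reproduces the whole cohort byte-for-byte.
"""

from __future__ import annotations

import hashlib

import numpy as np


def substream(seed: int, *names: str) -> np.random.Generator:
    """Return a Generator keyed by ``seed`` and a stable hash of ``names``."""
    digest = hashlib.sha256("/".join(names).encode("utf-8")).digest()
    key = int.from_bytes(digest[:4], "big")
    return np.random.default_rng(np.random.SeedSequence([int(seed), key]))


def child_seed(seed: int, *names: str) -> int:
    """A derived integer seed below 2**31, for APIs that take a plain int."""
    digest = hashlib.sha256(("seed:" + "/".join(names)).encode("utf-8")).digest()
    return (int(seed) ^ int.from_bytes(digest[:4], "big")) % (2**31)
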