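"""Named, reproducible random substreams.

All randomness in the package flows from one top-level integer seed.  Each
stage pulls its own generator via :func:`substream`, so rerunning a single
stage reproduces its draws regardless of what other stages did.
"""

from __future__ import annotations

import hashlib

import numpy as np

__all__ = ["substream", "child_seed"]


def _name_entropy(name: str) -> list[int]:
    digest = hashlib.sha256(name.encode("utf-8")).digest()
    # four 32-bit words are plenty of entropy for stream separation
    return [int.from_bytes(digest[i : i + 4], "little") for i in range(0, 16, 4)]


def substream(seed: int, name: str) -> np.random.Generator:
    """Return a Generator for stage `name` derived from the master `seed`."""
    ss = np.random.SeedSequence(entropy=[int(seed), *_name_entropy(name)])
    return np.random.default_rng(ss)


def child_seed(seed: int, name: str) -> int:
    """A derived integer seed (< 2**31) for APIs that want a plain int."""
    ss = np.random.SeedSequence(entropy=[int(seed), *_name_entropy(name)])
    return int(ss.generate_state(1, dtype=np.uint32)[0] % (2**31))
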