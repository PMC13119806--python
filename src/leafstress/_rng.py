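"""Named random substreams derived from one master seed.

Every stochastic stage pulls its generator from :func:`substream`, keyed by a
stable stage name, so regenerating one stage never perturbs another and a
fixed master seed reproduces every stream bit-identically.
"""

from __future__ import annotations

import zlib

import numpy as np


def substream(seed: int, name: str) -> np.random.Generator:
    """Return a Generator for the named substream of ``seed``.

    The stream key is a CRC32 of the name, entropy-mixed with the master
    seed through :class:`numpy.random.SeedSequence`.
    """
    key = zlib.crc32(name.encode("utf-8"))
    return np.random.default_rng(np.random.SeedSequence([int(seed) & 0x7FFFFFFF, key]))
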