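"""Counter-based seed fan-out.

Every stochastic operation in the package takes either an integer seed or a
ready ``numpy.random.Generator``.  A single master seed is expanded into
independent per-purpose streams by hashing the purpose label into the
``SeedSequence`` entropy, so rerunning one stage never perturbs another.
"""

from __future__ import annotations

import zlib

import numpy as np


def _key(label: str) -> int:
    return zlib.crc32(label.encode("utf-8"))


def spawn(seed: int | np.random.Generator, *labels: str | int) -> np.random.Generator:
    """Derive an independent Generator from ``seed`` and a sequence of labels.

    Integer labels are used as-is; strings are CRC32-hashed.  The same
    (seed, labels) pair always yields the same stream.
    """
    if isinstance(seed, np.random.Generator):
        return seed
    entropy = [int(seed)] + [_key(l) if isinstance(l, str) else int(l) for l in labels]
    return np.random.default_rng(np.random.SeedSequence(entropy))
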