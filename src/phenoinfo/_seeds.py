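"""Deterministic seed derivation.

A single user-facing seed is expanded into independent per-component streams
through :class:`numpy.random.SeedSequence` keyed by a stable label counter, so
that e.g. adding one more gene to a simulation never perturbs the draws of the
other genes.
"""

from __future__ import annotations

import zlib

import numpy as np

__all__ = ["child_seed", "rng_for"]


def child_seed(root_seed: int, *labels: object) -> np.random.SeedSequence:
    """Derive a child SeedSequence from ``root_seed`` and a label path.

    Labels (strings or integers) are hashed with crc32 so that the derived
    stream depends only on the label values, not on call order.
    """
    keys = []
    for lab in labels:
        if isinstance(lab, (int, np.integer)):
            keys.append(int(lab) & 0xFFFFFFFF)
        else:
            keys.append(zlib.crc32(str(lab).encode()))
    return np.random.SeedSequence(entropy=int(root_seed) & 0x7FFFFFFF, spawn_key=tuple(keys))


def rng_for(root_seed: int, *labels: object) -> np.random.Generator:
    """A Generator seeded from :func:`child_seed`."""
    return np.random.default_rng(child_seed(root_seed, *labels))
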