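"""Deterministic seed derivation.

All randomness in a run flows from one root seed. Child seeds are derived
with ``child_seed(root, *labels)``: each string label is hashed with CRC-32
(stable across processes, unlike ``hash``) and the pair (root, label hashes)
feeds a :class:`numpy.random.SeedSequence`. Derived seeds are reduced mod
2**31 so they are valid for every downstream consumer (scikit-learn included).
"""

from __future__ import annotations

import zlib

import numpy as np

__all__ = ["child_seed", "child_rng"]


def child_seed(root: int, *labels: str | int) -> int:
    """Derive a deterministic child seed from ``root`` and a label path."""
    entropy = [int(root) & 0xFFFFFFFF]
    for lab in labels:
        if isinstance(lab, str):
            entropy.append(zlib.crc32(lab.encode("utf-8")))
        else:
            entropy.append(int(lab) & 0xFFFFFFFF)
    return int(np.random.SeedSequence(entropy).generate_state(1)[0] % (2**31))


def child_rng(root: int, *labels: str | int) -> np.random.Generator:
    """A :class:`numpy.random.Generator` seeded by :func:`child_seed`."""
    return np.random.default_rng(child_seed(root, *labels))
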