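"""Deterministic random-stream derivation.

All randomness in the package flows from one master seed.  Named
substreams are derived by hashing string labels into extra entropy words
of a :class:`numpy.random.SeedSequence`, so that every stage (and every
cohort within a stage) draws from an independent, reproducible stream
regardless of the order in which stages run.
"""

from __future__ import annotations

import hashlib

import numpy as np

__all__ = ["substream", "substream_seed"]


def _label_word(label: object) -> int:
    digest = hashlib.sha256(str(label).encode("utf-8")).digest()
    return int.from_bytes(digest[:4], "big") & 0x7FFFFFFF


def substream(master_seed: int, *labels: object) -> np.random.Generator:
    """Return a Generator for the substream named by ``labels``.

    The derivation is ``SeedSequence([master_seed, h(label_1), ...])``
    where ``h`` is the first four bytes of SHA-256 of the label text.
    Identical (seed, labels) always yields an identical stream.
    """
    entropy = [int(master_seed) & 0x7FFFFFFF] + [_label_word(l) for l in labels]
    return np.random.default_rng(np.random.SeedSequence(entropy))


def substream_seed(master_seed: int, *labels: object) -> int:
    """A plain integer seed (< 2**31) derived from a named substream."""
    return int(substream(master_seed, *labels).integers(0, 2**31 - 1))
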