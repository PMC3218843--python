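"""Nucleotide encoding and seeded RNG streams shared across modules.

Bases are encoded A=0, C=1, G=2, T=3, N=4 so that complementation is
``3 - code`` for real bases. 'N' never matches anything, including itself.
"""

from __future__ import annotations

import zlib

import numpy as np

ALPHABET = "ACGTN"
A, C, G, T, N = range(5)

_ENCODE = np.full(256, N, dtype=np.uint8)
for _i, _b in enumerate(ALPHABET):
    _ENCODE[ord(_b)] = _i
    _ENCODE[ord(_b.lower())] = _i

# complement; N stays N
_COMPLEMENT = np.array([T, G, C, A, N], dtype=np.uint8)

_DECODE = np.frombuffer(ALPHABET.encode(), dtype=np.uint8)


def encode(seq: str) -> np.ndarray:
    """Encode a nucleotide string into a uint8 array."""
    return _ENCODE[np.frombuffer(seq.encode("ascii"), dtype=np.uint8)]


def decode(arr: np.ndarray) -> str:
    return _DECODE[arr].tobytes().decode("ascii")


def complement(arr: np.ndarray) -> np.ndarray:
    return _COMPLEMENT[arr]


def revcomp(arr: np.ndarray) -> np.ndarray:
    return _COMPLEMENT[arr][::-1]


def revcomp_str(seq: str) -> str:
    return decode(revcomp(encode(seq)))


def stream(seed: int, name: str) -> np.random.Generator:
    """Named, independent RNG stream derived from a single global seed.

    Each purpose ("template", "variants", "reads", "qualities", ...) gets a
    reproducible generator that does not interact with the others, so e.g.
    regenerating reads does not perturb the injected variants.
    """
    tag = zlib.crc32(name.encode("utf-8"))
    return np.random.default_rng(np.random.SeedSequence((int(seed), tag)))
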