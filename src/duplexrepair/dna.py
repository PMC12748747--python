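"""Small DNA string utilities shared across the package.

Sequences are plain upper-case strings; all coordinates are 0-based
half-open unless stated otherwise.
"""

from __future__ import annotations

import numpy as np

DNA_BASES = "ACGT"
_COMPLEMENT = str.maketrans("ACGTNacgtn", "TGCANtgcan")

#: numpy array of the four bases, used by vectorised sequence generation
_BASE_ARRAY = np.frombuffer(DNA_BASES.encode(), dtype=np.uint8)


def complement(seq: str) -> str:
    """Base-wise complement, preserving orientation."""
    return seq.translate(_COMPLEMENT)


def revcomp(seq: str) -> str:
    """Reverse complement of ``seq``."""
    return seq.translate(_COMPLEMENT)[::-1]


def is_dna(seq: str, alphabet: frozenset = frozenset(DNA_BASES)) -> bool:
    return all(base in alphabet for base in seq)


def hamming(a: str, b: str) -> int:
    """Number of mismatched positions between equal-length strings."""
    if len(a) != len(b):
        raise ValueError("hamming distance requires equal-length strings")
    return sum(x != y for x, y in zip(a, b))


def random_dna(rng: np.random.Generator, n: int) -> str:
    """Uniform random DNA string of length ``n``."""
    if n == 0:
        return ""
    idx = rng.integers(0, 4, size=n)
    return _BASE_ARRAY[idx].tobytes().decode()


def encode(seq: str) -> np.ndarray:
    """Byte-encode a sequence for vectorised comparisons."""
    return np.frombuffer(seq.encode(), dtype=np.uint8)
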