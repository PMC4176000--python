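"""Nucleotide-string utilities shared across the package.

Sequences are plain upper-case ACGT strings; hot paths (sliding-window
Hamming scans) go through uint8 numpy views of the same strings.
"""

from __future__ import annotations

import numpy as np

ALPHABET = "ACGT"

_COMPLEMENT = str.maketrans("ACGTN", "TGCAN")


def revcomp(seq: str) -> str:
    """Reverse complement of a nucleotide string."""
    return seq.translate(_COMPLEMENT)[::-1]


def complement(base: str) -> str:
    return base.translate(_COMPLEMENT)


def encode(seq: str) -> np.ndarray:
    """View a nucleotide string as a uint8 array (ASCII codes)."""
    return np.frombuffer(seq.encode("ascii"), dtype=np.uint8)


def random_seq(rng: np.random.Generator, length: int) -> str:
    return "".join(np.array(list(ALPHABET))[rng.integers(0, 4, size=length)])


def mutate_base(rng: np.random.Generator, base: str) -> str:
    """Substitute `base` by one of the three other nucleotides, uniformly."""
    choices = [b for b in ALPHABET if b != base]
    return choices[rng.integers(0, 3)]


def hamming_scan(haystack: np.ndarray, needle: np.ndarray) -> np.ndarray:
    """Mismatch count of `needle` against every full-length window of `haystack`.

    Returns an array of length ``len(haystack) - len(needle) + 1`` (empty when
    the haystack is shorter than the needle).
    """
    n, k = len(haystack), len(needle)
    if n < k:
        return np.zeros(0, dtype=np.int64)
    windows = np.lib.stride_tricks.sliding_window_view(haystack, k)
    return (windows != needle).sum(axis=1)
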