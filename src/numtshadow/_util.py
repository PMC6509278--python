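"""Small sequence helpers shared across modules."""

from __future__ import annotations

import numpy as np

BASES = "ACGT"

_COMPLEMENT = str.maketrans("ACGTacgtN", "TGCAtgcaN")

# byte -> 0..3 code; anything non-ACGT maps to 255 and is ignored downstream
_ENCODE = np.full(256, 255, dtype=np.uint8)
for _i, _b in enumerate(BASES):
    _ENCODE[ord(_b)] = _i
_BASE_BYTES = np.frombuffer(BASES.encode("ascii"), dtype=np.uint8)


def revcomp(seq: str) -> str:
    """Reverse complement of a DNA string."""
    return seq.translate(_COMPLEMENT)[::-1]


def encode(seq: str) -> np.ndarray:
    """Encode a DNA string as a uint8 array with A,C,G,T -> 0,1,2,3."""
    return _ENCODE[np.frombuffer(seq.encode("ascii"), dtype=np.uint8)]


def decode(codes: np.ndarray) -> str:
    """Inverse of :func:`encode` for arrays containing only codes 0..3."""
    return _BASE_BYTES[codes].tobytes().decode("ascii")


def random_dna(rng: np.random.Generator, n: int) -> str:
    """Uniform random DNA string of length ``n``."""
    return decode(rng.integers(0, 4, size=n, dtype=np.uint8))


def wrapped_slice(seq: str, start: int, end: int) -> str:
    """Slice ``seq`` as a circle: ``start`` in [0, len), ``end`` may exceed len.

    The slice length must not exceed the sequence length.
    """
    n = len(seq)
    span = end - start
    if span > n:
        raise ValueError("wrapped slice longer than the sequence")
    if span < 0:
        raise ValueError("end must be >= start")
    start %= n
    stop = start + span
    if stop <= n:
        return seq[start:stop]
    return seq[start:] + seq[: stop - n]


def arc_contains(outer_start: int, outer_end: int, inner_start: int, inner_end: int, length: int) -> bool:
    """True if the circular arc [inner_start, inner_end) lies within [outer_start, outer_end).

    Arcs are half-open with ``end >= start``; ``end`` may exceed ``length`` to
    denote wrapping past the origin.
    """
    inner_len = inner_end - inner_start
    outer_len = outer_end - outer_start
    if inner_len == 0:
        return True
    if outer_len >= length:
        return True
    if inner_len > outer_len:
        return False
    rel = (inner_start - outer_start) % length
    return rel + inner_len <= outer_len
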