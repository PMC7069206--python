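"""DNA 2-bit encoding, canonical k-mers and overlapping reference windows.

A reference sequence is divided into windows of ``window_len`` bp in which
consecutive windows overlap by exactly ``k - 1`` bp, so every k-mer of the
sequence belongs to exactly one window apart from the duplicated overlap.
The window is the unit of database locations, hit counting and coverage.

Bases are encoded 2 bits each (A=0, C=1, G=2, T=3, most-significant base
first); a k-mer is represented by the numerically smaller of its own code
and the code of its reverse complement ("canonical" form), which makes all
downstream hashing strand-neutral. k-mers containing any character outside
``ACGT`` (case-insensitive) are skipped.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from typing import NamedTuple

import numpy as np

logger = logging.getLogger(__name__)

#: byte value -> 2-bit base code; 255 marks an invalid (ambiguous) base
BASE_LUT = np.full(256, 255, dtype=np.uint8)
for _i, _c in enumerate(b"ACGT"):
    BASE_LUT[_c] = _i
    BASE_LUT[_c + 32] = _i  # lower case: soft-masking is ignored

INVALID_BASE = np.uint8(255)


class AmbiguousKmerError(ValueError):
    """Raised when a k-mer contains a character outside {A, C, G, T}."""


@dataclass(frozen=True)
class BuildParams:
    """Database construction parameters.

    Parameters
    ----------
    k : int
        k-mer length in bp (1..31 so a k-mer fits in 62 bits).
    window_len : int
        Window length ``l`` in bp; chosen close to the expected read length.
    sketch_size : int
        Number ``s`` of smallest hash values kept per window/read.
    max_locations : int
        Cap on the number of (target, window) locations stored per key;
        keys exceeding the cap are considered uninformative and deleted
        when the database is finalized.
    """

    k: int = 16
    window_len: int = 128
    sketch_size: int = 8
    max_locations: int = 254

    def __post_init__(self) -> None:
        if not 0 < self.k <= 31:
            raise ValueError(f"k must be in [1, 31], got {self.k}")
        if self.k > self.window_len:
            raise ValueError("window_len must be >= k")
        if not 1 <= self.sketch_size <= self.window_len - self.k + 1:
            raise ValueError("sketch_size must be in [1, window_len - k + 1]")
        if self.max_locations < 1:
            raise ValueError("max_locations must be >= 1")

    @property
    def stride(self) -> int:
        """Distance between window starts; consecutive windows overlap by k-1."""
        return self.window_len - self.k + 1


class WindowCoord(NamedTuple):
    """0-based half-open coordinates of one reference window."""

    window_id: int
    start: int
    end: int


def encode_bases(seq: str) -> np.ndarray:
    """Encode a DNA string as an array of 2-bit base codes (255 = invalid)."""
    raw = np.frombuffer(seq.encode("ascii", errors="replace"), dtype=np.uint8)
    return BASE_LUT[raw]


def canonical_codes(bases: np.ndarray, k: int) -> tuple[np.ndarray, np.ndarray]:
    """Canonical k-mer codes for every position of an encoded sequence.

    Returns ``(codes, valid)`` with one entry per k-mer start position
    (``len(bases) - k + 1`` positions). ``codes`` holds the canonical 2-bit
    encoding as uint64; ``valid`` is False wherever the k-mer contains an
    invalid base (such codes are meaningless and must be skipped).
    """
    n_pos = len(bases) - k + 1
    if n_pos <= 0:
        return (np.empty(0, dtype=np.uint64), np.empty(0, dtype=bool))
    b = bases.astype(np.uint64)
    fwd = np.zeros(n_pos, dtype=np.uint64)
    rc = np.zeros(n_pos, dtype=np.uint64)
    three = np.uint64(3)
    for j in range(k):
        col = b[j : j + n_pos] & three
        fwd = (fwd << np.uint64(2)) | col
        rc = rc | ((three - col) << np.uint64(2 * j))
    inv = np.concatenate(([0], np.cumsum(bases > 3)))
    valid = (inv[k : k + n_pos] - inv[:n_pos]) == 0
    return np.minimum(fwd, rc), valid


def canonical_kmer_code(kmer: str) -> int:
    """2-bit code of the canonical (strand-neutral) form of one k-mer.

    Returns the numerically smaller of the forward and reverse-complement
    encodings. Raises :class:`AmbiguousKmerError` for non-ACGT characters.
    """
    bases = encode_bases(kmer)
    codes, valid = canonical_codes(bases, len(kmer))
    if codes.size != 1:
        raise ValueError("canonical_kmer_code expects a single k-mer string")
    if not valid[0]:
        raise AmbiguousKmerError(f"ambiguous k-mer: {kmer!r}")
    return int(codes[0])


def reverse_complement(seq: str) -> str:
    comp = str.maketrans("ACGTacgt", "TGCAtgca")
    return seq.translate(comp)[::-1]


def extract_windows(sequence_length: int, params: BuildParams) -> list[WindowCoord]:
    """Divide a sequence of the given length into overlapping windows.

    Windows start at multiples of ``stride = window_len - k + 1`` so that
    consecutive windows share exactly ``k - 1`` bp. A truncated final window
    is emitted only while it still holds at least one k-mer (length >= k).
    Sequences shorter than k yield no windows (with a logged warning).
    """
    if sequence_length < params.k:
        logger.warning(
            "sequence of length %d is shorter than k=%d; no windows",
            sequence_length,
            params.k,
        )
        return []
    windows = []
    start = 0
    wid = 0
    while start <= sequence_length - params.k:
        end = min(start + params.window_len, sequence_length)
        windows.append(WindowCoord(wid, start, end))
        wid += 1
        start += params.stride
    return windows
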