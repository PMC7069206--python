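"""Minhash sketching of windows and reads.

Every canonical k-mer of a sequence is hashed with a fixed 64-bit mixing
function and the ``s`` smallest distinct hash values form the sequence's
*sketch*. Because the same deterministic hash orders the k-mers of every
sequence, the relative overlap of two bottom-s sketches estimates the
Jaccard index of the underlying full k-mer sets.

The mixing function is a splitmix64-style finalizer with fixed published
constants. It is a bijection on 64 bits (add, xorshift and odd-constant
multiply are each invertible), so distinct canonical codes can never
collide, and it has no seed: databases stay valid across runs and machines.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Sequence

import numpy as np

from .kmers import BuildParams, canonical_codes, encode_bases

#: sentinel marking "no value" slots in batch hashing (never a real hash
#: in practice; excluded from every sketch)
SENTINEL = np.uint64(0xFFFFFFFFFFFFFFFF)

_MASK64 = (1 << 64) - 1
_ADD = 0x9E3779B97F4A7C15
_MUL1 = 0xBF58476D1CE4E5B9
_MUL2 = 0x94D049BB133111EB


def h1_mix(code: int) -> int:
    """64-bit avalanche mix of a canonical k-mer code (scalar form)."""
    z = (code + _ADD) & _MASK64
    z ^= z >> 30
    z = (z * _MUL1) & _MASK64
    z ^= z >> 27
    z = (z * _MUL2) & _MASK64
    z ^= z >> 31
    return z


def h1_mix_array(codes: np.ndarray) -> np.ndarray:
    """Vectorized :func:`h1_mix` over a uint64 array."""
    z = codes + np.uint64(_ADD)
    z = z ^ (z >> np.uint64(30))
    z = z * np.uint64(_MUL1)
    z = z ^ (z >> np.uint64(27))
    z = z * np.uint64(_MUL2)
    z = z ^ (z >> np.uint64(31))
    return z


@dataclass(frozen=True)
class Sketch:
    """Bottom-s minhash sketch: ascending distinct hash values (<= s of them)."""

    values: np.ndarray
    params: BuildParams = field(default_factory=BuildParams)

    def __len__(self) -> int:
        return len(self.values)


def sequence_hashes(seq: str, k: int) -> tuple[np.ndarray, np.ndarray]:
    """Hash values of all canonical k-mers of ``seq`` plus a validity mask."""
    codes, valid = canonical_codes(encode_bases(seq), k)
    return h1_mix_array(codes), valid


def sketch_from_hashes(hashes: np.ndarray, valid: np.ndarray, s: int) -> np.ndarray:
    """The s smallest distinct hash values among the valid positions."""
    vals = np.unique(hashes[valid])
    return vals[:s]


def sketch_sequence(seq: str, params: BuildParams) -> Sketch:
    """Sketch a window or read: s smallest distinct hashes of its k-mers.

    Sequences shorter than k, or in which every k-mer is ambiguous, yield
    an empty sketch (downstream such a query is unclassified).
    """
    hashes, valid = sequence_hashes(seq, params.k)
    return Sketch(sketch_from_hashes(hashes, valid, params.sketch_size), params)


def sketch_batch(
    seqs: Sequence[str], params: BuildParams, chunk_size: int = 50_000
) -> list[np.ndarray]:
    """Sketch many sequences at once (vectorized; same result as per-sequence).

    Returns one ascending uint64 array per input sequence. Used on read sets
    where per-call overhead would dominate.
    """
    k = params.k
    s = params.sketch_size
    out: list[np.ndarray] = []
    for lo in range(0, len(seqs), chunk_size):
        block = seqs[lo : lo + chunk_size]
        n = len(block)
        lens = np.array([len(x) for x in block])
        lmax = int(lens.max()) if n else 0
        n_pos = lmax - k + 1
        if n_pos <= 0:
            out.extend(np.empty(0, dtype=np.uint64) for _ in block)
            continue
        mat = np.full((n, lmax), 255, dtype=np.uint8)
        for i, sq in enumerate(block):
            enc = encode_bases(sq)
            mat[i, : len(enc)] = enc
        b = mat.astype(np.uint64)
        three = np.uint64(3)
        fwd = np.zeros((n, n_pos), dtype=np.uint64)
        rc = np.zeros((n, n_pos), dtype=np.uint64)
        for j in range(k):
            col = b[:, j : j + n_pos] & three
            fwd = (fwd << np.uint64(2)) | col
            rc = rc | ((three - col) << np.uint64(2 * j))
        inv = np.zeros((n, lmax + 1), dtype=np.int32)
        np.cumsum(mat > 3, axis=1, out=inv[:, 1:])
        valid = (inv[:, k : k + n_pos] - inv[:, :n_pos]) == 0
        h = h1_mix_array(np.minimum(fwd, rc))
        h[~valid] = SENTINEL
        h.sort(axis=1)
        if n_pos > 1:
            dup = h[:, 1:] == h[:, :-1]
            h[:, 1:][dup] = SENTINEL
            h.sort(axis=1)
        head = h[:, :s]
        for row in head:
            out.append(row[row != SENTINEL].copy())
    return out


def subsampling_factor(params: BuildParams) -> float:
    """Data-reduction ratio S = (l - k + 1) / s of sketching vs. all k-mers."""
    return (params.window_len - params.k + 1) / params.sketch_size


def estimate_similarity(a: Sketch, b: Sketch) -> float:
    """Bottom-s minhash estimate of the Jaccard index of two sequences.

    Among the s smallest values of the union of both sketches, the fraction
    also present in both sketches estimates J(A, B) of the full k-mer sets.
    Empty sketches give 0.
    """
    if len(a) == 0 or len(b) == 0:
        return 0.0
    s = a.params.sketch_size
    union = np.union1d(a.values, b.values)[:s]
    inter = np.intersect1d(a.values, b.values, assume_unique=True)
    hits = int(np.isin(union, inter, assume_unique=True).sum())
    return hits / len(union)
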