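"""Canonical k-mer extraction.

k-mers are 2-bit packed into uint64 (supports k <= 31); a k-mer and its
reverse complement collapse to a single canonical key (the numerically
smaller encoding). Windows containing any non-ACGT character yield no k-mer,
so no k-mer ever spans an ambiguous base.
"""

from __future__ import annotations

import numpy as np

_CODE = np.full(256, 255, dtype=np.uint8)
for i, base in enumerate(b"ACGT"):
    _CODE[base] = i
    _CODE[base + 32] = i  # lowercase


def canonical_kmers(seq: str, k: int) -> np.ndarray:
    """All canonical k-mers of ``seq`` as a uint64 array (with duplicates).

    k must be odd so that no k-mer equals its own reverse complement,
    making canonicalization unambiguous.
    """
    if k < 1 or k > 31:
        raise ValueError(f"k must be in [1, 31], got {k}")
    if k % 2 == 0:
        raise ValueError("k must be odd for unambiguous canonicalization")
    n = len(seq)
    if n < k:
        return np.empty(0, dtype=np.uint64)
    codes = _CODE[np.frombuffer(seq.encode("ascii"), dtype=np.uint8)]
    valid = codes != 255
    codes64 = codes.astype(np.uint64)
    codes64[~valid] = 0
    m = n - k + 1
    fwd = np.zeros(m, dtype=np.uint64)
    rev = np.zeros(m, dtype=np.uint64)
    rc64 = np.uint64(3) - codes64  # complement under 2-bit encoding
    for i in range(k):
        fwd |= codes64[i : i + m] << np.uint64(2 * (k - 1 - i))
        rev |= rc64[i : i + m] << np.uint64(2 * i)
    canon = np.minimum(fwd, rev)
    # windows touching a non-ACGT base are dropped
    bad = np.cumsum(np.concatenate(([0], (~valid).astype(np.int64))))
    ok = (bad[k:] - bad[:-k]) == 0
    return canon[ok]


def kmer_set(seq: str, k: int) -> np.ndarray:
    """Unique canonical k-mers of a sequence."""
    return np.unique(canonical_kmers(seq, k))
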