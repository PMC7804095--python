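"""Exact edit distance via adaptive banding."""

from __future__ import annotations

import numpy as np

from ._kernels import banded_edit_kernel

_A_ORD = np.frombuffer(b"ACGT", dtype=np.uint8)


def _codes(seq: str) -> np.ndarray:
    return np.frombuffer(seq.upper().encode("ascii"), dtype=np.uint8)


def edit_ops(a: str, b: str) -> tuple[int, np.ndarray, np.ndarray]:
    """Unit-cost global alignment of b against a.

    Returns (distance, positions, kinds) with positions on ``a`` and kinds
    from ``_kernels`` (OP_SUB/OP_DEL/OP_INS).  The band is doubled until
    the computed distance fits inside it, which guarantees exactness.
    """
    ca, cb = _codes(a), _codes(b)
    if ca.size == 0:
        kinds = np.full(cb.size, 3, dtype=np.int8)
        return cb.size, np.zeros(cb.size, dtype=np.int32), kinds
    if cb.size == 0:
        kinds = np.full(ca.size, 2, dtype=np.int8)
        return ca.size, np.arange(ca.size, dtype=np.int32), kinds
    band = max(abs(ca.size - cb.size) + 16, 32)
    limit = max(ca.size, cb.size)
    while True:
        dist, pos, kind = banded_edit_kernel(ca, cb, band)
        if dist <= band or band >= limit:
            return int(dist), pos, kind
        band *= 2


def edit_distance(a: str, b: str) -> int:
    return edit_ops(a, b)[0]
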