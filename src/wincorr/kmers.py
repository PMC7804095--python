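"""Integer k-mer coding (2 bits per base, high-order base first)."""

from __future__ import annotations

import numpy as np
from numba import njit

_CODE = np.full(256, 0, dtype=np.uint8)
for _i, _b in enumerate(b"ACGT"):
    _CODE[_b] = _i


@njit(cache=True)
def _rolling_codes(codes, k):
    n = codes.size - k + 1
    out = np.empty(n, np.int64)
    mask = np.int64(4) ** k - 1
    c = np.int64(0)
    for i in range(codes.size):
        c = ((c << 2) | codes[i]) & mask
        if i >= k - 1:
            out[i - k + 1] = c
    return out


def kmer_codes(seq: str, k: int) -> np.ndarray:
    """Integer code of every k-mer of seq; empty array when |seq| < k."""
    raw = np.frombuffer(seq.encode("ascii"), dtype=np.uint8)
    if raw.size < k:
        return np.empty(0, dtype=np.int64)
    return _rolling_codes(_CODE[raw], k)


def encode_kmer(kmer: str) -> int:
    code = 0
    for ch in kmer:
        code = (code << 2) | int(_CODE[ord(ch)])
    return code


def decode_kmer(code: int, k: int) -> str:
    out = []
    for _ in range(k):
        out.append("ACGT"[code & 3])
        code >>= 2
    return "".join(reversed(out))
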