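"""Low-level nucleotide sequence helpers shared across the package.

Sequences are handled as Python strings at module boundaries and as
``numpy`` uint8 code arrays (A=0, C=1, G=2, T=3, N=4) internally.
"""

from __future__ import annotations

import numpy as np

NT_ORDER = "ACGTN"
_ENCODE = np.full(256, 4, dtype=np.uint8)
for _i, _c in enumerate("ACGT"):
    _ENCODE[ord(_c)] = _i
    _ENCODE[ord(_c.lower())] = _i
_DECODE = np.frombuffer(b"ACGTN", dtype=np.uint8)

_COMP = str.maketrans("ACGTNacgtn", "TGCANtgcan")

N_CODE = 4


def encode(seq: str) -> np.ndarray:
    """Encode a nucleotide string to a uint8 code array (non-ACGT -> N)."""
    raw = np.frombuffer(seq.encode("ascii"), dtype=np.uint8)
    return _ENCODE[raw]


def decode(arr: np.ndarray) -> str:
    return _DECODE[arr].tobytes().decode("ascii")


def revcomp(seq: str) -> str:
    return seq.translate(_COMP)[::-1]


def revcomp_arr(arr: np.ndarray) -> np.ndarray:
    out = arr[::-1].copy()
    acgt = out < 4
    out[acgt] = 3 - out[acgt]
    return out


def kmer_codes(arr: np.ndarray, k: int) -> tuple[np.ndarray, np.ndarray]:
    """Rolling k-mer integer codes over a code array.

    Returns ``(codes, valid)`` of length ``len(arr) - k + 1``; ``valid`` is
    False wherever the window contains an N. Codes use base-4 encoding.
    """
    n = len(arr) - k + 1
    if n <= 0:
        return np.empty(0, dtype=np.int64), np.empty(0, dtype=bool)
    codes = np.zeros(n, dtype=np.int64)
    bad = np.zeros(n, dtype=bool)
    a = arr.astype(np.int64)
    for j in range(k):
        codes = codes * 4 + np.minimum(a[j : j + n], 3)
        bad |= a[j : j + n] == N_CODE
    return codes, ~bad


class KmerIndex:
    """Bucketed k-mer position index of one code array (4**k buckets)."""

    def __init__(self, arr: np.ndarray, k: int):
        self.k = k
        codes, valid = kmer_codes(arr, k)
        pos = np.nonzero(valid)[0]
        codes = codes[pos]
        order = np.argsort(codes, kind="stable")
        self.positions = pos[order].astype(np.int64)
        self.offsets = np.zeros(4**k + 1, dtype=np.int64)
        counts = np.bincount(codes, minlength=4**k)
        np.cumsum(counts, out=self.offsets[1:])

    def lookup(self, code: int) -> np.ndarray:
        return self.positions[self.offsets[code] : self.offsets[code + 1]]

    def lookup_many(self, codes: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
        """Positions for an array of query codes.

        Returns ``(qidx, gpos)`` where ``qidx[i]`` indexes into ``codes`` and
        ``gpos[i]`` is a matching position in the indexed array.
        """
        starts = self.offsets[codes]
        ends = self.offsets[codes + 1]
        counts = (ends - starts).astype(np.int64)
        total = int(counts.sum())
        if total == 0:
            return np.empty(0, dtype=np.int64), np.empty(0, dtype=np.int64)
        qidx = np.repeat(np.arange(len(codes), dtype=np.int64), counts)
        # vectorized ragged-slice gather
        cum = np.concatenate(([0], np.cumsum(counts)))
        offs = np.arange(total, dtype=np.int64) - np.repeat(cum[:-1], counts)
        gpos = self.positions[np.repeat(starts, counts) + offs]
        return qidx, gpos
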