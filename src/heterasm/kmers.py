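"""Low-level canonical k-mer machinery shared by the spectrum, assembly,
purge and scaffolding stages.

Two representations are used.  For k <= 31 a k-mer fits in a 64-bit integer
(2 bits per base) and counting is vectorised with numpy; for larger k a
plain-Python path over byte strings is used.  Windows containing any
non-ACGT character (N, IUPAC ambiguity codes) never contribute a k-mer.
"""

from __future__ import annotations

from typing import Iterable, Sequence

import numpy as np

MAX_NUMPY_K = 31

# base encoding: A=0 C=1 G=2 T=3, everything else 255 (invalid)
_LUT = np.full(256, 255, dtype=np.uint8)
for _i, _b in enumerate(b"ACGT"):
    _LUT[_b] = _i
for _i, _b in enumerate(b"acgt"):
    _LUT[_b] = _i

_RC_TABLE = bytes.maketrans(b"ACGTacgtNn", b"TGCATGCANN")
_DECODE = np.frombuffer(b"ACGT", dtype=np.uint8)


def revcomp(seq: str | bytes) -> str | bytes:
    """Reverse complement; N maps to N."""
    if isinstance(seq, str):
        return seq.translate(str.maketrans("ACGTacgtNn", "TGCATGCANN"))[::-1]
    return seq.translate(_RC_TABLE)[::-1]


def encode_seq(seq: str | bytes) -> np.ndarray:
    """Encode a DNA string as uint8 codes (255 marks invalid characters)."""
    if isinstance(seq, str):
        seq = seq.encode()
    return _LUT[np.frombuffer(seq, dtype=np.uint8)]


def _concat_encoded(seqs: Iterable[str | bytes]) -> np.ndarray:
    """Concatenate encoded sequences with an invalid separator between them
    so that no window spans two sequences."""
    parts: list[np.ndarray] = []
    sep = np.array([255], dtype=np.uint8)
    for s in seqs:
        parts.append(encode_seq(s))
        parts.append(sep)
    if not parts:
        return np.empty(0, dtype=np.uint8)
    return np.concatenate(parts)


def window_codes(arr: np.ndarray, k: int) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    """Forward codes, reverse-complement codes and a validity mask for every
    length-k window of an encoded array.  Requires k <= MAX_NUMPY_K."""
    if k > MAX_NUMPY_K:
        raise ValueError(f"k={k} exceeds the integer-coding limit {MAX_NUMPY_K}")
    n = arr.size - k + 1
    if n <= 0:
        e = np.empty(0, dtype=np.uint64)
        return e, e.copy(), np.empty(0, dtype=bool)
    a = (arr & np.uint8(3)).astype(np.uint64)
    fwd = np.zeros(n, dtype=np.uint64)
    rev = np.zeros(n, dtype=np.uint64)
    for j in range(k):
        sl = a[j : j + n]
        fwd |= sl << np.uint64(2 * (k - 1 - j))
        rev |= (sl ^ np.uint64(3)) << np.uint64(2 * j)
    bad = (arr == 255).astype(np.int64)
    cs = np.concatenate(([0], np.cumsum(bad)))
    valid = (cs[k:] - cs[:-k]) == 0
    return fwd, rev, valid


def canonical_codes(arr: np.ndarray, k: int) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    """Canonical (min of strand pair) codes per window, plus a boolean array
    that is True where the forward orientation is the canonical one, plus the
    validity mask."""
    fwd, rev, valid = window_codes(arr, k)
    canon = np.minimum(fwd, rev)
    is_fwd = fwd <= rev
    return canon, is_fwd, valid


def decode_code(code: int, k: int) -> str:
    out = bytearray(k)
    for j in range(k - 1, -1, -1):
        out[j] = b"ACGT"[code & 3]
        code >>= 2
    return out.decode()


def decode_codes(codes: np.ndarray, k: int) -> list[bytes]:
    """Vectorised decoding of many codes to k-mer byte strings."""
    n = codes.size
    if n == 0:
        return []
    mat = np.empty((n, k), dtype=np.uint8)
    c = codes.copy()
    for j in range(k - 1, -1, -1):
        mat[:, j] = _DECODE[(c & np.uint64(3)).astype(np.intp)]
        c >>= np.uint64(2)
    flat = mat.tobytes()
    return [flat[i * k : (i + 1) * k] for i in range(n)]


class KmerTable:
    """Sorted table of distinct canonical k-mers with their instance counts.

    ``codes`` is a sorted uint64 array (k <= 31) and ``counts`` the matching
    multiplicities; lookups use binary search.  For k > 31 a dict of byte
    strings is used instead.
    """

    def __init__(self, k: int):
        if k % 2 == 0 or k < 3:
            raise ValueError(f"k must be odd and >= 3, got {k}")
        self.k = k
        self.codes: np.ndarray = np.empty(0, dtype=np.uint64)
        self.counts: np.ndarray = np.empty(0, dtype=np.int64)
        self._dict: dict[bytes, int] | None = None  # k > 31 fallback
        self.n_instances = 0

    # -- construction -------------------------------------------------
    @classmethod
    def from_seqs(cls, seqs: Iterable[str | bytes], k: int) -> "KmerTable":
        t = cls(k)
        if k <= MAX_NUMPY_K:
            arr = _concat_encoded(seqs)
            canon, _, valid = canonical_codes(arr, k)
            canon = canon[valid]
            t.n_instances = int(canon.size)
            if canon.size:
                t.codes, t.counts = np.unique(canon, return_counts=True)
        else:
            d: dict[bytes, int] = {}
            n = 0
            for s in seqs:
                b = s.encode() if isinstance(s, str) else bytes(s)
                b = b.upper()
                rc = revcomp(b)
                L = len(b)
                for i in range(L - k + 1):
                    km = b[i : i + k]
                    if km.strip(b"ACGT"):
                        continue
                    mate = rc[L - k - i : L - i]
                    key = km if km <= mate else mate
                    d[key] = d.get(key, 0) + 1
                    n += 1
            t._dict = d
            t.n_instances = n
        return t

    # -- queries ------------------------------------------------------
    @property
    def n_distinct(self) -> int:
        if self._dict is not None:
            return len(self._dict)
        return int(self.codes.size)

    def depth_histogram(self) -> np.ndarray:
        """hist[d] = number of distinct canonical k-mers seen exactly d times."""
        if self._dict is not None:
            counts = np.fromiter(self._dict.values(), dtype=np.int64)
        else:
            counts = self.counts
        if counts.size == 0:
            return np.zeros(1, dtype=np.int64)
        return np.bincount(counts)

    def lookup(self, canon: np.ndarray) -> np.ndarray:
        """Counts for an array of canonical codes (0 where absent)."""
        if self.codes.size == 0:
            return np.zeros(canon.size, dtype=np.int64)
        idx = np.searchsorted(self.codes, canon)
        idx_c = np.clip(idx, 0, self.codes.size - 1)
        hit = self.codes[idx_c] == canon
        out = np.zeros(canon.size, dtype=np.int64)
        out[hit] = self.counts[idx_c[hit]]
        return out

    def per_position_depth(self, seq: str | bytes) -> np.ndarray:
        """Depth of each position's canonical k-mer along a sequence
        (length L-k+1; -1 where the window is invalid)."""
        arr = encode_seq(seq)
        canon, _, valid = canonical_codes(arr, self.k)
        if self._dict is not None:
            raise NotImplementedError("per-position depth requires k <= 31")
        out = self.lookup(canon)
        out[~valid] = -1
        return out

    def items(self) -> Iterable[tuple[bytes, int]]:
        """(canonical k-mer bytes, count) pairs."""
        if self._dict is not None:
            return self._dict.items()
        kmers = decode_codes(self.codes, self.k)
        return zip(kmers, (int(c) for c in self.counts))


def distinct_canonical_set(seq: str | bytes, k: int) -> np.ndarray:
    """Sorted array of distinct canonical k-mer codes of one sequence."""
    arr = encode_seq(seq)
    canon, _, valid = canonical_codes(arr, k)
    return np.unique(canon[valid])


def seq_kmer_codes(seqs: Sequence[str | bytes], k: int) -> np.ndarray:
    """Distinct canonical codes over a collection of sequences."""
    arr = _concat_encoded(seqs)
    canon, _, valid = canonical_codes(arr, k)
    return np.unique(canon[valid])
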