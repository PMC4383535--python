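"""Exact-seed placement index shared by the QC mapper, the scaffolder and
the gap filler.

Reference sequences are indexed by canonical seed k-mers; a query is placed
where the best (reference, strand) pair collects at least ``vote_frac`` of
its seed votes.  Seeds occurring at more than ``max_hits`` reference
positions are treated as repeats and dropped from the index.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Sequence

import edlib
import numpy as np

from .kmers import canonical_codes, encode_seq, revcomp
from .seqio import SeqRecord


@dataclass
class Placement:
    ref_idx: int
    ref_name: str
    start: int  # inferred query start on the reference (may be negative)
    strand: str  # '+'/'-'
    votes: int
    total_votes: int


class SeedIndex:
    def __init__(self, refs: Sequence[SeqRecord], k: int = 21, max_hits: int = 4):
        if k % 2 == 0:
            raise ValueError("seed k must be odd")
        self.k = k
        self.refs = list(refs)
        self.names = [r.id for r in refs]
        index: dict[int, list[tuple[int, int, bool]] | None] = {}
        for ri, rec in enumerate(self.refs):
            arr = encode_seq(rec.seq)
            canon, is_fwd, valid = canonical_codes(arr, k)
            pos = np.nonzero(valid)[0]
            for p in pos:
                code = int(canon[p])
                slot = index.get(code)
                if slot is None and code in index:  # already ambiguous
                    continue
                if slot is None:
                    index[code] = [(ri, int(p), bool(is_fwd[p]))]
                elif len(slot) >= max_hits:
                    index[code] = None
                else:
                    slot.append((ri, int(p), bool(is_fwd[p])))
        self._index = index

    def place(
        self,
        seq: str,
        stride: int = 5,
        vote_frac: float = 0.8,
        min_votes: int = 2,
    ) -> Placement | None:
        """Place a query by seed votes; None when no (ref, strand) dominates."""
        k = self.k
        arr = encode_seq(seq)
        canon, is_fwd, valid = canonical_codes(arr, k)
        n = canon.size
        if n <= 0:
            return None
        qpos = list(range(0, n, stride))
        if qpos[-1] != n - 1:
            qpos.append(n - 1)
        L = len(seq)
        votes: dict[tuple[int, str], list[int]] = {}
        total = 0
        for q in qpos:
            if not valid[q]:
                continue
            slot = self._index.get(int(canon[q]))
            if not slot:
                continue
            for ri, p, fwd in slot:
                strand = "+" if fwd == bool(is_fwd[q]) else "-"
                start = p - q if strand == "+" else p - (L - k - q)
                votes.setdefault((ri, strand), []).append(start)
                total += 1
        if total == 0:
            return None
        (ri, strand), starts = max(votes.items(), key=lambda kv: (len(kv[1]), -kv[0][0]))
        if len(starts) < max(min_votes, vote_frac * total):
            return None
        start = int(np.median(starts))
        return Placement(ri, self.names[ri], start, strand, len(starts), total)

    def align(self, seq: str, placement: Placement, pad: int | None = None) -> tuple[float, int, int]:
        """Banded verification of a placement: identity of the query against
        the local reference window, plus the aligned window bounds."""
        ref = self.refs[placement.ref_idx].seq
        L = len(seq)
        if pad is None:
            pad = 10 + L // 20
        lo = max(0, placement.start - pad)
        hi = min(len(ref), placement.start + L + pad)
        if hi - lo < self.k:
            return 0.0, lo, hi
        query = seq if placement.strand == "+" else revcomp(seq)
        res = edlib.align(query, ref[lo:hi], mode="HW", task="locations")
        dist = res["editDistance"]
        if dist < 0:
            return 0.0, lo, hi
        s, e = res["locations"][0]
        return 1.0 - dist / L, lo + s, lo + e + 1
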