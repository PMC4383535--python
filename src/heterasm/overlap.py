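"""Overlap detection among unit assemblies and greedy merging into
super-contigs.

Shared exact seed k-mers nominate contig pairs and a strand/offset; the
implied overlap region is then verified by global (Needleman-Wunsch style)
alignment via edlib.  Overlaps are classified as containment (one contig
nearly fully covered), dovetail (alignment reaches the appropriate ends of
both contigs) or internal (mid-to-mid; likely repeat-induced and rejected
from merging).  Dovetails are joined greedily in decreasing identity, never
reusing a contig end and never closing a cycle.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Iterable, Sequence

import edlib
import numpy as np

from .kmers import canonical_codes, encode_seq, revcomp
from .seqio import PafRecord, SeqRecord


@dataclass
class OverlapRecord:
    """Pairwise local alignment in PAF convention (0-based half-open)."""

    qname: str
    tname: str
    qlen: int
    tlen: int
    qstart: int
    qend: int
    tstart: int
    tend: int
    strand: str
    matches: int
    aln_len: int

    @property
    def identity(self) -> float:
        return self.matches / self.aln_len

    def to_paf(self) -> PafRecord:
        return PafRecord(
            self.qname, self.qlen, self.qstart, self.qend, self.strand,
            self.tname, self.tlen, self.tstart, self.tend,
            self.matches, self.aln_len,
        )


def _cigar_stats(cigar: str) -> tuple[int, int]:
    """(matches, alignment length) from an extended cigar."""
    matches = 0
    aln = 0
    num = 0
    for ch in cigar:
        if ch.isdigit():
            num = num * 10 + int(ch)
        else:
            aln += num
            if ch == "=":
                matches += num
            num = 0
    return matches, aln


def _seed_occurrences(seq: str, k: int) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    arr = encode_seq(seq)
    canon, is_fwd, valid = canonical_codes(arr, k)
    pos = np.nonzero(valid)[0]
    return canon[pos], is_fwd[pos], pos


def find_overlaps(
    contigs: Sequence[SeqRecord],
    seed_k: int = 15,
    min_overlap: int = 200,
    min_identity: float = 0.95,
    max_seed_hits: int = 8,
    min_seeds: int = 4,
) -> list[OverlapRecord]:
    """Seed-chained, alignment-verified overlaps between contig pairs.

    Each (pair, relative strand) with enough shared seeds is tested once at
    the median seed offset; records pass when the aligned span is at least
    ``min_overlap`` bp at ``min_identity``.  Symmetric pairs are reported
    once with the lexicographically smaller name as query.
    """
    if len(contigs) < 2:
        return []
    order = sorted(range(len(contigs)), key=lambda i: contigs[i].id)
    seqs = [contigs[i] for i in order]

    index: dict[int, list[tuple[int, int, bool]] | None] = {}
    for ci, rec in enumerate(seqs):
        codes, fwd, pos = _seed_occurrences(rec.seq, seed_k)
        for code, f, p in zip(codes, fwd, pos):
            code = int(code)
            slot = index.get(code)
            if slot is None and code in index:
                continue
            if slot is None:
                index[code] = [(ci, int(p), bool(f))]
            elif len(slot) >= max_seed_hits:
                index[code] = None
            else:
                slot.append((ci, int(p), bool(f)))

    buckets: dict[tuple[int, int, str], list[tuple[int, int]]] = {}
    for slot in index.values():
        if not slot or len(slot) < 2:
            continue
        for a in range(len(slot)):
            for b in range(a + 1, len(slot)):
                (ci, pi, fi), (cj, pj, fj) = slot[a], slot[b]
                if ci == cj:
                    continue
                if ci > cj:
                    (ci, pi, fi), (cj, pj, fj) = (cj, pj, fj), (ci, pi, fi)
                strand = "+" if fi == fj else "-"
                if strand == "-":
                    pj = len(seqs[cj].seq) - seed_k - pj
                buckets.setdefault((ci, cj, strand), []).append((pi, pj))

    records = []
    for (ci, cj, strand), hits in sorted(buckets.items()):
        if len(hits) < min_seeds:
            continue
        rec = _verify_overlap(seqs[ci], seqs[cj], strand, hits, min_overlap, min_identity)
        if rec is not None:
            records.append(rec)
    return records


def _verify_overlap(
    q: SeqRecord,
    t: SeqRecord,
    strand: str,
    hits: list[tuple[int, int]],
    min_overlap: int,
    min_identity: float,
) -> OverlapRecord | None:
    qlen, tlen = len(q), len(t)
    offsets = sorted(pq - pt for pq, pt in hits)
    d = offsets[len(offsets) // 2]
    qs, ts = max(0, d), max(0, -d)
    span = min(qlen - qs, tlen - ts)
    if span < min_overlap * 0.8:
        return None
    tseq = t.seq if strand == "+" else revcomp(t.seq)
    res = edlib.align(q.seq[qs : qs + span], tseq[ts : ts + span], mode="NW", task="path")
    if res["editDistance"] < 0:
        return None
    matches, aln_len = _cigar_stats(res["cigar"])
    if aln_len < min_overlap or matches / aln_len < min_identity:
        return None
    qe, te = qs + span, ts + span
    if strand == "-":
        ts, te = tlen - te, tlen - ts
    return OverlapRecord(q.id, t.id, qlen, tlen, qs, qe, ts, te, strand, matches, aln_len)


# ------------------------------------------------------- classification

def classify_overlap(rec: OverlapRecord, end_slack: int = 50, containment_cov: float = 0.95) -> str:
    qcov = (rec.qend - rec.qstart) / rec.qlen
    tcov = (rec.tend - rec.tstart) / rec.tlen
    if qcov >= containment_cov or tcov >= containment_cov:
        return "containment"
    q_head = rec.qstart <= end_slack
    q_tail = rec.qend >= rec.qlen - end_slack
    t_head = rec.tstart <= end_slack
    t_tail = rec.tend >= rec.tlen - end_slack
    if rec.strand == "+":
        if (q_head and t_tail) or (t_head and q_tail):
            return "dovetail"
    else:
        if (q_head and t_head) or (q_tail and t_tail):
            return "dovetail"
    return "internal"


# -------------------------------------------------------------- merging

@dataclass
class ProvenanceRow:
    out_contig: str  # merged contig, container, or self
    source: str
    status: str  # kept | merged | contained
    start: int  # interval in out_contig (0-based half-open)
    end: int
    orientation: str


class _UnionFind:
    def __init__(self, n: int):
        self.parent = list(range(n))

    def find(self, i: int) -> int:
        while self.parent[i] != i:
            self.parent[i] = self.parent[self.parent[i]]
            i = self.parent[i]
        return i

    def union(self, i: int, j: int) -> None:
        self.parent[self.find(i)] = self.find(j)


def merge_assemblies(
    contigs: Sequence[SeqRecord],
    seed_k: int = 15,
    min_overlap: int = 200,
    min_identity: float = 0.95,
    end_slack: int = 50,
    prefix: str = "merge",
) -> tuple[list[SeqRecord], list[ProvenanceRow], list[OverlapRecord]]:
    """Merge unit contigs into super-contigs.

    Containment-absorbed contigs are dropped; dovetails are accepted
    greedily (identity desc, aligned length desc) when both contig ends are
    unused and no cycle would form.  Disagreeing overlap columns take the
    earlier (query-side) contig's base.
    """
    overlaps = find_overlaps(contigs, seed_k, min_overlap, min_identity)
    byname = {c.id: c for c in contigs}
    names = [c.id for c in contigs]
    idx = {n: i for i, n in enumerate(names)}

    contained: dict[str, OverlapRecord] = {}
    dovetails: list[OverlapRecord] = []
    for rec in overlaps:
        kind = classify_overlap(rec, end_slack)
        if kind == "containment":
            q_cov = (rec.qend - rec.qstart) / rec.qlen >= 0.95
            t_cov = (rec.tend - rec.tstart) / rec.tlen >= 0.95
            if q_cov and t_cov:  # near-identical pair: absorb the shorter
                victim = rec.qname if (rec.qlen, rec.tname) < (rec.tlen, rec.qname) else rec.tname
            elif q_cov:
                victim = rec.qname
            else:
                victim = rec.tname
            contained.setdefault(victim, rec)
        elif kind == "dovetail":
            dovetails.append(rec)

    alive = [n for n in names if n not in contained]
    alive_idx = {n: i for i, n in enumerate(alive)}

    uf = _UnionFind(len(alive))
    used_ends: set[tuple[str, str]] = set()
    joins: list[OverlapRecord] = []
    for rec in sorted(dovetails, key=lambda r: (-r.identity, -r.aln_len, r.qname, r.tname)):
        if rec.qname in contained or rec.tname in contained:
            continue
        ends = _join_ends(rec, end_slack)
        if ends is None:
            continue
        (qe_end, te_end) = ends
        a, b = (rec.qname, qe_end), (rec.tname, te_end)
        if a in used_ends or b in used_ends:
            continue
        ia, ib = alive_idx[rec.qname], alive_idx[rec.tname]
        if uf.find(ia) == uf.find(ib):
            continue
        uf.union(ia, ib)
        used_ends.add(a)
        used_ends.add(b)
        joins.append(rec)

    merged, provenance = _build_chains(alive, byname, joins, contained, prefix, end_slack)
    return merged, provenance, overlaps


def _join_ends(rec: OverlapRecord, end_slack: int) -> tuple[str, str] | None:
    """Which end of query and target the dovetail consumes."""
    q_head = rec.qstart <= end_slack
    q_tail = rec.qend >= rec.qlen - end_slack
    t_head = rec.tstart <= end_slack
    t_tail = rec.tend >= rec.tlen - end_slack
    if rec.strand == "+":
        if q_tail and t_head and not (q_head and t_tail):
            return ("tail", "head")
        if q_head and t_tail and not (q_tail and t_head):
            return ("head", "tail")
    else:
        if q_tail and t_tail and not (q_head and t_head):
            return ("tail", "tail")
        if q_head and t_head and not (q_tail and t_tail):
            return ("head", "head")
    return None  # ambiguous (both-end) or inconsistent overlap


def _build_chains(
    alive: list[str],
    byname: dict[str, SeqRecord],
    joins: list[OverlapRecord],
    contained: dict[str, OverlapRecord],
    prefix: str,
    end_slack: int,
):
    # adjacency: (name, end) -> (other name, other end, record)
    adj: dict[tuple[str, str], tuple[str, str, OverlapRecord]] = {}
    for rec in joins:
        qe, te = _join_ends(rec, end_slack)
        adj[(rec.qname, qe)] = (rec.tname, te, rec)
        adj[(rec.tname, te)] = (rec.qname, qe, rec)

    visited: set[str] = set()
    merged_records: list[SeqRecord] = []
    provenance: list[ProvenanceRow] = []
    serial = 0

    def _overlap_len_on(rec: OverlapRecord, name: str) -> int:
        return (rec.qend - rec.qstart) if name == rec.qname else (rec.tend - rec.tstart)

    for name in alive:
        if name in visited:
            continue
        # find a chain terminus: walk left as far as possible
        cur, cur_in_end = name, None
        seen_walk = {name}
        while True:
            # entering end: the end NOT already used to come in; pick any free link
            link = None
            for end in ("head", "tail"):
                if (cur, end) in adj and (cur_in_end is None or end != cur_in_end):
                    link = (end, adj[(cur, end)])
            if link is None:
                break
            end, (nxt, nxt_end, rec) = link
            if nxt in seen_walk:
                break
            seen_walk.add(nxt)
            cur, cur_in_end = nxt, nxt_end
        # cur is a terminus; orient it so the linked end (if any) is its right side
        chain: list[tuple[str, str, OverlapRecord | None]] = []  # (name, orient, record to next)
        node, in_end = cur, None
        while True:
            visited.add(node)
            out_link = None
            for end in ("head", "tail"):
                if end == in_end:
                    continue
                if (node, end) in adj:
                    nxt, nxt_end, rec = adj[(node, end)]
                    if nxt not in visited:
                        out_link = (end, nxt, nxt_end, rec)
            orient = "+"
            if out_link is not None:
                out_end = out_link[0]
                orient = "+" if out_end == "tail" else "-"
            elif in_end is not None:
                orient = "+" if in_end == "head" else "-"
            chain.append((node, orient, out_link[3] if out_link else None))
            if out_link is None:
                break
            _, node, in_end, _ = out_link

        if len(chain) == 1:
            rec0 = byname[chain[0][0]]
            provenance.append(ProvenanceRow(rec0.id, rec0.id, "kept", 0, len(rec0), "+"))
            merged_records.append(rec0)
            continue

        serial += 1
        out_name = f"{prefix}_{serial:04d}"
        parts: list[str] = []
        offset = 0
        for i, (node, orient, rec) in enumerate(chain):
            seq = byname[node].seq
            if orient == "-":
                seq = revcomp(seq)
            if i == 0:
                parts.append(seq)
                provenance.append(ProvenanceRow(out_name, node, "merged", 0, len(seq), orient))
                offset = len(seq)
            else:
                prev_rec = chain[i - 1][2]
                ovl = _overlap_len_on(prev_rec, node)
                parts.append(seq[ovl:])
                provenance.append(ProvenanceRow(out_name, node, "merged", offset - ovl, offset - ovl + len(seq), orient))
                offset += len(seq) - ovl
        merged_records.append(SeqRecord(out_name, "".join(parts)))

    for victim, rec in contained.items():
        container = rec.tname if victim == rec.qname else rec.qname
        if victim == rec.qname:
            s, e = rec.tstart, rec.tend
        else:
            s, e = rec.qstart, rec.qend
        provenance.append(ProvenanceRow(container, victim, "contained", s, e, rec.strand))

    merged_records.sort(key=lambda r: (-len(r), r.id))
    return merged_records, provenance
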