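"""Per-unit de Bruijn assembly with k-sweep selection.

Each sequencing unit (a clone insert's read set) is assembled independently
over a sweep of odd k values; the assembly with the longest N50 is kept
(ties: larger total length, then smaller k).  The graph stores every k-mer
in both orientations so that traversal never reports a sequence and its
reverse complement as two contigs.

Bubbles (two near-identical branch paths that reconverge) arise from
heterozygous sites and from sequencing errors.  When ``pop_bubbles`` is
set the weaker branch is discarded; when it is not, the weaker branch is
retained as an allelic variant and emitted as a second, haplotype-swapped
contig — the redundancy the purge stage later removes.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Iterable, Sequence

import edlib
import numpy as np

from .kmers import KmerTable, revcomp
from .seqio import SeqRecord
from .qc import nx

_BRANCH_WALK_LIMIT = 20000


class EmptyGraphError(RuntimeError):
    pass


class AssemblyError(RuntimeError):
    pass


@dataclass
class DeBruijnGraph:
    """Edge-centric de Bruijn graph: ``edges`` maps every k-mer (both
    orientations present) to its multiplicity."""

    k: int
    edges: dict[bytes, int]
    variants: list[tuple[bytes, bytes]] = field(default_factory=list)

    @property
    def n_edges(self) -> int:
        """Number of distinct canonical k-mers (strand pairs count once)."""
        return len(self.edges) // 2

    @property
    def nodes(self) -> set[bytes]:
        s: set[bytes] = set()
        for km in self.edges:
            s.add(km[:-1])
            s.add(km[1:])
        return s

    def __eq__(self, other: object) -> bool:
        return isinstance(other, DeBruijnGraph) and self.k == other.k and self.edges == other.edges

    def copy(self) -> "DeBruijnGraph":
        return DeBruijnGraph(self.k, dict(self.edges), list(self.variants))


def build_graph(reads: Iterable[SeqRecord | str], k: int) -> DeBruijnGraph:
    """One edge per read k-mer; both orientations stored."""
    if k % 2 == 0 or k < 3:
        raise ValueError(f"k must be odd and >= 3, got {k}")
    seqs = [r.seq if isinstance(r, SeqRecord) else r for r in reads]
    table = KmerTable.from_seqs(seqs, k)
    edges: dict[bytes, int] = {}
    for km, count in table.items():
        edges[km] = count
        edges[revcomp(km)] = count
    if not edges:
        raise EmptyGraphError(f"no k-mers at k={k} (all reads shorter than k?)")
    return DeBruijnGraph(k, edges)


# ------------------------------------------------------------- traversal

def _adjacency(edges: dict[bytes, int]) -> tuple[dict[bytes, list[bytes]], dict[bytes, int]]:
    out: dict[bytes, list[bytes]] = {}
    indeg: dict[bytes, int] = {}
    for km in edges:
        out.setdefault(km[:-1], []).append(km)
        indeg[km[1:]] = indeg.get(km[1:], 0) + 1
    for lst in out.values():
        lst.sort()
    return out, indeg


def _spell(path: Sequence[bytes]) -> bytes:
    return path[0] + b"".join(km[-1:] for km in path[1:])


def _unitigs(edges: dict[bytes, int]) -> list[list[bytes]]:
    """Maximal non-branching paths; each strand pair reported once."""
    out, indeg = _adjacency(edges)
    used: set[bytes] = set()
    unitigs: list[list[bytes]] = []

    def _walk(start: bytes) -> list[bytes]:
        path = [start]
        used.add(start)
        used.add(revcomp(start))
        cur = start
        while True:
            s = cur[1:]
            if indeg.get(s, 0) != 1 or len(out.get(s, ())) != 1:
                break
            nxt = out[s][0]
            if nxt in used:
                break
            path.append(nxt)
            used.add(nxt)
            used.add(revcomp(nxt))
            cur = nxt
        return path

    for km in sorted(edges):
        if km in used:
            continue
        p = km[:-1]
        if len(out.get(p, ())) != 1 or indeg.get(p, 0) != 1:
            unitigs.append(_walk(km))
    for km in sorted(edges):  # leftover cycles
        if km not in used:
            unitigs.append(_walk(km))
    return unitigs


# ------------------------------------------------------------ simplify

def _delete_path(edges: dict[bytes, int], path: Iterable[bytes]) -> None:
    for km in path:
        edges.pop(km, None)
        edges.pop(revcomp(km), None)


def _remove_tips(edges: dict[bytes, int], k: int, tip_len: int, median_mult: float) -> bool:
    out, indeg = _adjacency(edges)
    changed = False
    for path in _unitigs(edges):
        if any(km not in edges for km in path):
            continue
        start, end = path[0][:-1], path[-1][1:]
        dead_start = indeg.get(start, 0) == 0
        dead_end = len(out.get(end, ())) == 0
        if dead_start == dead_end:  # isolated contig or internal unitig
            continue
        bp = len(path) + k - 1
        mean_mult = sum(edges[e] for e in path) / len(path)
        if bp < tip_len and mean_mult < 0.5 * median_mult:
            _delete_path(edges, path)
            changed = True
    return changed


def _weighted_median_mult(edges: dict[bytes, int]) -> float:
    """Median edge multiplicity weighted by multiplicity (i.e. over k-mer
    instances).  Robust to error k-mers, which dominate the *distinct*
    k-mer count at realistic error rates but carry few instances."""
    vals = np.sort(np.fromiter(edges.values(), dtype=np.int64))
    cs = np.cumsum(vals)
    return float(vals[np.searchsorted(cs, cs[-1] / 2)])


def _drop_weak_edges(edges: dict[bytes, int], threshold: float) -> None:
    """Solid-k-mer filter: edges with multiplicity below ``threshold`` are
    treated as sequencing-error artifacts and removed."""
    if threshold <= 1:
        return
    for km in [km for km, m in edges.items() if m < threshold]:
        edges.pop(km, None)


def _branch_walk(edges: dict[bytes, int], out, indeg, start: bytes) -> tuple[list[bytes], bytes]:
    """Follow a linear path from a branch edge until a junction; return the
    path and its end node."""
    path = [start]
    cur = start
    while len(path) < _BRANCH_WALK_LIMIT:
        s = cur[1:]
        if indeg.get(s, 0) != 1 or len(out.get(s, ())) != 1:
            break
        cur = out[s][0]
        path.append(cur)
    return path, path[-1][1:]


def _branch_identity(a: bytes, b: bytes) -> float:
    res = edlib.align(a.decode(), b.decode(), task="distance")
    return 1.0 - res["editDistance"] / max(len(a), len(b))


def _pop_bubbles(
    edges: dict[bytes, int],
    k: int,
    identity_thr: float,
    keep_variants: bool,
    variants: list[tuple[bytes, bytes]],
) -> bool:
    out, indeg = _adjacency(edges)

    def _delete_and_update(path: list[bytes]) -> None:
        for km in path:
            for e in (km, revcomp(km)):
                if e not in edges:
                    continue
                del edges[e]
                lst = out.get(e[:-1])
                if lst is not None:
                    lst.remove(e)
                    if not lst:
                        del out[e[:-1]]
                indeg[e[1:]] -= 1
                if indeg[e[1:]] == 0:
                    del indeg[e[1:]]

    changed = False
    for u in sorted(out):
        branches = list(out.get(u, ()))
        if len(branches) != 2:
            continue
        if any(km not in edges for km in branches):
            continue
        (p0, end0) = _branch_walk(edges, out, indeg, branches[0])
        (p1, end1) = _branch_walk(edges, out, indeg, branches[1])
        if end0 != end1 or end0 == u:
            continue
        s0, s1 = _spell(p0), _spell(p1)
        if _branch_identity(s0, s1) < identity_thr:
            continue
        m0 = sum(edges[e] for e in p0) / len(p0)
        m1 = sum(edges[e] for e in p1) / len(p1)
        if (m0, s1) > (m1, s0):  # keep higher multiplicity; tie -> smaller spelling
            strong_path, weak_path, strong, weak = p0, p1, s0, s1
        else:
            strong_path, weak_path, strong, weak = p1, p0, s1, s0
        _delete_and_update(weak_path)
        if keep_variants:
            variants.append((strong, weak))
        changed = True
    return changed


def simplify(
    graph: DeBruijnGraph,
    tip_len: int | None = None,
    bubble_identity: float = 0.9,
    pop_bubbles: bool = True,
    max_rounds: int = 8,
    err_mult_frac: float = 0.1,
) -> DeBruijnGraph:
    """Clip weak tips and resolve near-identical bubbles.

    Edges with multiplicity below ``err_mult_frac`` x the instance-weighted
    median multiplicity are dropped first (sequencing-error k-mers).
    Dead-end paths shorter than ``tip_len`` (default 2k) with mean
    multiplicity below half that median are then removed.  Two-branch
    bubbles aligning at >= ``bubble_identity`` collapse to the stronger
    branch; with ``pop_bubbles=False`` the weaker branch is remembered and
    re-emitted as an allelic variant contig.  Idempotent on simple graphs.
    """
    g = graph.copy()
    if tip_len is None:
        tip_len = 2 * g.k
    if not g.edges:
        return g
    median_mult = _weighted_median_mult(g.edges)
    _drop_weak_edges(g.edges, err_mult_frac * median_mult)
    for _ in range(max_rounds):
        tips = _remove_tips(g.edges, g.k, tip_len, median_mult)
        bubbles = _pop_bubbles(g.edges, g.k, bubble_identity, not pop_bubbles, g.variants)
        if not tips and not bubbles:
            break
    return g


# -------------------------------------------------------------- contigs

def graph_contigs(graph: DeBruijnGraph, unit_id: str = "unit", min_len: int = 0) -> list[SeqRecord]:
    """Spell contigs from the simplified graph.

    Unitigs are deduplicated by canonical (strand-independent) form; every
    remembered allelic variant produces one additional contig with the
    weaker branch spliced in.
    """
    seen: set[bytes] = set()
    seqs: list[bytes] = []
    for path in _unitigs(graph.edges):
        s = _spell(path)
        canon = min(s, revcomp(s))
        if canon not in seen:
            seen.add(canon)
            seqs.append(s)
    alts: list[bytes] = []
    for s in seqs:
        alt = s
        for strong, weak in graph.variants:
            alt = alt.replace(strong, weak).replace(revcomp(strong), revcomp(weak))
        if alt != s:
            canon = min(alt, revcomp(alt))
            if canon not in seen:
                seen.add(canon)
                alts.append(alt)
    ordered = sorted((s for s in seqs + alts if len(s) >= min_len), key=lambda s: (-len(s), s))
    return [SeqRecord(f"{unit_id}.ctg{i:04d}", s.decode()) for i, s in enumerate(ordered, 1)]


# -------------------------------------------------------------- k-sweep

@dataclass
class UnitAssembly:
    unit_id: str
    k_used: int
    contigs: list[SeqRecord]
    n50: int

    @property
    def total_bp(self) -> int:
        return sum(len(c) for c in self.contigs)


def assemble_unit(
    reads: Sequence[SeqRecord | str],
    unit_id: str = "unit",
    k_min: int = 25,
    k_max: int = 63,
    k_step: int = 2,
    pop_bubbles: bool = True,
    bubble_identity: float = 0.9,
    tip_len: int | None = None,
    min_contig_len: int = 100,
) -> UnitAssembly:
    """Assemble one unit at every k in the sweep and keep the longest-N50
    assembly (ties: larger total length, then smaller k).

    The tip cutoff defaults to read length + k: an error near a read end
    spawns a dead-end branch of up to a full read length.
    """
    if k_min % 2 == 0 or k_max % 2 == 0:
        raise ValueError("k-sweep bounds must be odd")
    if k_step % 2 != 0 or k_step < 2:
        raise ValueError("k-sweep step must be even (odd k only)")
    if not reads:
        raise AssemblyError(f"{unit_id}: no reads")
    max_read = max(len(r.seq if isinstance(r, SeqRecord) else r) for r in reads)
    best: tuple[tuple[int, int, int], UnitAssembly] | None = None
    for k in range(k_min, k_max + 1, k_step):
        try:
            g = build_graph(reads, k)
        except EmptyGraphError:
            continue
        tl = tip_len if tip_len is not None else max(2 * k, max_read + k)
        g = simplify(g, tip_len=tl, bubble_identity=bubble_identity, pop_bubbles=pop_bubbles)
        contigs = graph_contigs(g, unit_id, min_len=min_contig_len)
        if not contigs:
            continue
        lengths = [len(c) for c in contigs]
        asm = UnitAssembly(unit_id, k, contigs, nx(lengths, 50))
        key = (asm.n50, asm.total_bp, -k)
        if best is None or key > best[0]:
            best = (key, asm)
    if best is None:
        raise AssemblyError(f"{unit_id}: every k in the sweep produced an empty assembly")
    return best[1]
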