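"""Scaffold gap closing with short-insert reads.

For each N run, reads seed-matching the flanking sequence (plus their
mates) are recruited into a tiny local de Bruijn graph; a unique path from
the last flank k-mer of the left flank to the first of the right flank
closes the gap.  When no path exists, the flanks are extended greedily
along unambiguous edges (at least one N always remains); when several
paths exist the gap is left untouched — ambiguity is refused.  Bases
outside the gap and its flank windows are never modified.
"""

from __future__ import annotations

import re
from dataclasses import dataclass, field
from typing import Sequence

from .kmers import revcomp
from .seqio import SeqRecord
from .seedindex import SeedIndex
from .scaffolder import Library

_GAP_RE = re.compile(r"N+")
_PATH_STATE_LIMIT = 50000


@dataclass
class GapContext:
    scaffold_id: str
    gap_index: int
    gap_start: int  # 0-based position of the N run
    gap_end: int
    left_flank: str
    right_flank: str
    gap_len_est: int
    reads: list[SeqRecord] = field(default_factory=list)
    insert_sd: float = 0.0


@dataclass
class GapFillResult:
    status: str  # closed | shortened | unchanged | skipped
    fill_seq: str | None = None
    left_ext: str = ""
    right_ext: str = ""
    support: int = 0


def find_gaps(scaffold: SeqRecord) -> list[tuple[int, int]]:
    """(start, end) of each N run, 0-based half-open."""
    return [(m.start(), m.end()) for m in _GAP_RE.finditer(scaffold.seq)]


def _gap_flanks(seq: str, gs: int, ge: int, flank_w: int, min_local_k: int) -> tuple[str, str] | None:
    left = seq[max(0, gs - flank_w) : gs]
    right = seq[ge : ge + flank_w]
    # flanks must be N-free: clip at the nearest interior N
    if "N" in left:
        left = left[left.rindex("N") + 1 :]
    if "N" in right:
        right = right[: right.index("N")]
    if len(left) < min_local_k or len(right) < min_local_k:
        return None
    return left, right


def recruit_reads(
    scaffold: SeqRecord,
    gap_index: int,
    libraries: Sequence[Library],
    flank_w: int = 500,
    seed_k: int = 21,
    min_local_k: int = 31,
) -> GapContext | None:
    """Build the context for one gap: flank windows plus recruited reads.

    Recruits reads with a seed match to either flank and their mates; a
    flank shorter than the local graph k skips the gap with a warning-level
    None return.  Recruitment radius never exceeds the flank window, which
    is itself far below insert_mean + 3 sd for short-insert libraries.
    """
    gaps = find_gaps(scaffold)
    gs, ge = gaps[gap_index]
    flanks_or_none = _gap_flanks(scaffold.seq, gs, ge, flank_w, min_local_k)
    if flanks_or_none is None:
        return None
    left, right = flanks_or_none
    ctx = GapContext(scaffold.id, gap_index, gs, ge, left, right, ge - gs)
    flanks = [SeqRecord("left", left), SeqRecord("right", right)]
    index = SeedIndex(flanks, k=seed_k)
    for lib in libraries:
        ctx.insert_sd = max(ctx.insert_sd, lib.insert_sd)
        for r1, r2 in lib.pairs:
            hit1 = index.place(r1.seq, min_votes=1, vote_frac=0.0) is not None
            hit2 = index.place(r2.seq, min_votes=1, vote_frac=0.0) is not None
            if hit1 or hit2:
                ctx.reads.append(r1)
                ctx.reads.append(r2)
    return ctx


def _local_graph(ctx: GapContext, k: int) -> dict[bytes, set[bytes]]:
    """Successor map over (k-1)-mers from recruited reads + flanks, both
    orientations."""
    succ: dict[bytes, set[bytes]] = {}
    seqs = [r.seq for r in ctx.reads] + [ctx.left_flank, ctx.right_flank]
    for s in seqs:
        for seq in (s, revcomp(s)):
            b = seq.encode()
            for i in range(len(b) - k + 1):
                km = b[i : i + k]
                if km.strip(b"ACGT"):
                    continue
                succ.setdefault(km[:-1], set()).add(km[1:])
    return succ


def fill_gap(ctx: GapContext, k_local: int = 31, max_len: int | None = None) -> GapFillResult:
    """Attempt to close one gap from its recruited reads.

    A unique left-anchor to right-anchor path of length <= max_len closes
    the gap; no path triggers unambiguous greedy flank extension; multiple
    paths leave the gap unchanged.
    """
    if max_len is None:
        max_len = ctx.gap_len_est + int(3 * ctx.insert_sd) + 2 * k_local
    if not ctx.reads:
        return GapFillResult("unchanged")
    succ = _local_graph(ctx, k_local)
    start = ctx.left_flank[-(k_local - 1) :].encode()
    target = ctx.right_flank[: k_local - 1].encode()
    if start not in succ:
        return GapFillResult("unchanged")

    # bounded DFS enumerating distinct node paths start -> target
    found: list[bytes] = []
    stack: list[tuple[bytes, bytes]] = [(start, b"")]  # (node, spelled extension)
    states = 0
    max_ext = max_len + 2 * (k_local - 1)
    while stack and len(found) < 2 and states < _PATH_STATE_LIMIT:
        node, ext = stack.pop()
        states += 1
        if node == target and ext:
            found.append(ext)
            continue
        if len(ext) > max_ext:
            continue
        for nxt in sorted(succ.get(node, ())):
            stack.append((nxt, ext + nxt[-1:]))
    if len(found) == 1:
        # ext spells nodes after start; strip the trailing target overlap
        fill = found[0][: -(k_local - 1)].decode() if len(found[0]) >= k_local - 1 else ""
        return GapFillResult("closed", fill_seq=fill, support=len(ctx.reads) // 2)
    if len(found) >= 2:
        return GapFillResult("unchanged", support=len(ctx.reads) // 2)

    # no path: extend each flank along unambiguous edges
    budget = max(0, ctx.gap_len_est - 1)
    left_ext = _extend_unique(succ, start, budget)
    rsucc = succ  # graph holds both strands; extend right flank leftward via rc
    right_start = revcomp(ctx.right_flank[: k_local - 1]).encode()
    right_ext_rc = _extend_unique(rsucc, right_start, budget - len(left_ext))
    right_ext = revcomp(right_ext_rc.decode()) if right_ext_rc else ""
    if not left_ext and not right_ext:
        return GapFillResult("unchanged", support=len(ctx.reads) // 2)
    return GapFillResult(
        "shortened",
        left_ext=left_ext.decode() if isinstance(left_ext, bytes) else left_ext,
        right_ext=right_ext,
        support=len(ctx.reads) // 2,
    )


def _extend_unique(succ: dict[bytes, set[bytes]], node: bytes, budget: int) -> bytes:
    out = bytearray()
    seen = {node}
    while len(out) < budget:
        nxts = succ.get(node)
        if not nxts or len(nxts) != 1:
            break
        (node,) = nxts
        if node in seen:
            break
        seen.add(node)
        out += node[-1:]
    return bytes(out)


def apply_fill(scaffold: SeqRecord, ctx: GapContext, result: GapFillResult) -> SeqRecord:
    """Splice a fill result into the scaffold; everything outside the gap
    is byte-identical to the input."""
    seq = scaffold.seq
    if result.status == "closed":
        new_gap = result.fill_seq or ""
    elif result.status == "shortened":
        remaining = ctx.gap_len_est - len(result.left_ext) - len(result.right_ext)
        new_gap = result.left_ext + "N" * max(1, remaining) + result.right_ext
    else:
        return scaffold
    new_seq = seq[: ctx.gap_start] + new_gap + seq[ctx.gap_end :]
    return SeqRecord(scaffold.id, new_seq)


def gapfill_scaffolds(
    scaffolds: Sequence[SeqRecord],
    libraries: Sequence[Library],
    k_local: int = 31,
    flank_w: int = 500,
    rounds: int = 2,
) -> tuple[list[SeqRecord], list[tuple[str, int, str, int]]]:
    """Run gap filling over every gap of every scaffold for a few rounds.

    Returns updated scaffolds and a per-gap report of
    (scaffold, gap index, status, filled length).
    """
    report: list[tuple[str, int, str, int]] = []
    out = list(scaffolds)
    seed_k = 21
    for rnd in range(rounds):
        # collect every gap's flank context, then recruit in one read pass
        contexts: list[GapContext] = []
        flank_recs: list[SeqRecord] = []
        for si, scaf in enumerate(out):
            for gi, (gs, ge) in enumerate(find_gaps(scaf)):
                flanks = _gap_flanks(scaf.seq, gs, ge, flank_w, k_local)
                if flanks is None:
                    if rnd == 0:
                        report.append((scaf.id, gi, "skipped", 0))
                    continue
                left, right = flanks
                ctx = GapContext(scaf.id, gi, gs, ge, left, right, ge - gs)
                ci = len(contexts)
                contexts.append(ctx)
                flank_recs.append(SeqRecord(f"{ci}|L", left))
                flank_recs.append(SeqRecord(f"{ci}|R", right))
        if not contexts:
            break
        index = SeedIndex(flank_recs, k=seed_k)
        for lib in libraries:
            for ctx in contexts:
                ctx.insert_sd = max(ctx.insert_sd, lib.insert_sd)
            for r1, r2 in lib.pairs:
                hits = set()
                for r in (r1, r2):
                    pl = index.place(r.seq, min_votes=1, vote_frac=0.0)
                    if pl is not None:
                        hits.add(int(pl.ref_name.split("|")[0]))
                for ci in hits:
                    contexts[ci].reads.append(r1)
                    contexts[ci].reads.append(r2)

        changed = False
        by_scaf: dict[str, list[tuple[GapContext, GapFillResult]]] = {}
        for ctx in contexts:
            res = fill_gap(ctx, k_local=k_local)
            by_scaf.setdefault(ctx.scaffold_id, []).append((ctx, res))
            if rnd == 0:
                filled = len(res.fill_seq or "") if res.status == "closed" else len(res.left_ext) + len(res.right_ext)
                report.append((ctx.scaffold_id, ctx.gap_index, res.status, filled))
        nxt: list[SeqRecord] = []
        for scaf in out:
            # apply right-to-left so earlier coordinates stay valid
            for ctx, res in sorted(by_scaf.get(scaf.id, []), key=lambda t: -t[0].gap_start):
                if res.status in ("closed", "shortened"):
                    scaf = apply_fill(scaf, ctx, res)
                    changed = True
            nxt.append(scaf)
        out = nxt
        if not changed:
            break
    return out, report
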