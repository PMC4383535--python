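"""Mate-pair scaffolding: order and orient purged contigs with read-pair
libraries applied hierarchically from the smallest insert to the largest.

Read pairs are anchored to contigs by unique seed votes; pairs whose mates
land on different contigs imply an (end, end) adjacency with a gap
estimate of insert_mean minus the two anchored flank lengths.  Links with
enough consistent support are accepted greedily (support descending) when
both contig ends are still free and no cycle would form; earlier (smaller
insert) rounds are never undone by later ones.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Sequence

import numpy as np

from .kmers import revcomp
from .seqio import AgpComponent, SeqRecord
from .seedindex import Placement, SeedIndex


@dataclass
class Library:
    """A read-pair group with declared insert geometry.

    ``orientation`` is FR for short-insert (inward-pointing) pairs and RF
    for mate-pair (outward-pointing) chemistry.
    """

    name: str
    insert_mean: float
    insert_sd: float
    orientation: str  # FR | RF
    pairs: list[tuple[SeqRecord, SeqRecord]] = field(default_factory=list)

    def __post_init__(self) -> None:
        if self.orientation not in ("FR", "RF"):
            raise ValueError(f"orientation must be FR or RF, got {self.orientation!r}")
        if self.insert_sd <= 0:
            raise ValueError("insert_sd must be positive")

    @property
    def n_pairs(self) -> int:
        return len(self.pairs)


@dataclass
class AnchoredPair:
    contig_a: str
    pos_a: int  # leftmost read coordinate on the contig
    strand_a: str
    len_a: int
    contig_b: str
    pos_b: int
    strand_b: str
    len_b: int


@dataclass
class LinkEvidence:
    contig_a: str
    end_a: str  # head | tail
    contig_b: str
    end_b: str
    support_count: int
    gap_estimates: list[int]
    insert_mean: float = 0.0
    insert_sd: float = 0.0
    read_len: float = 0.0

    @property
    def gap_median(self) -> int:
        return int(np.median(self.gap_estimates))

    def gap_estimate(self, insert_sd: float | None = None) -> int:
        """Outlier-trimmed, length-bias-corrected mean gap.

        The median anchors the trim (robust); the mean of the surviving
        estimates has the full sqrt(support) precision of the library's
        insert distribution.  Junction-spanning pairs are length-biased —
        a fragment spans a gap with probability proportional to its
        anchorable span — which deflates the naive estimate by about
        sd^2 / (insert_mean - 2 read_len - gap); that term is added back.
        """
        sd = self.insert_sd if insert_sd is None else insert_sd
        est = np.asarray(self.gap_estimates, dtype=float)
        if sd and est.size > 2:
            med = np.median(est)
            est = est[np.abs(est - med) <= 3 * sd]
        g = float(est.mean())
        if sd and self.insert_mean:
            denom = self.insert_mean - 2 * self.read_len - g
            if denom > 2 * sd:
                g += sd * sd / denom
        return int(round(g))


@dataclass
class ScaffoldPlan:
    """Ordered (contig, orientation, gap_after) components of one scaffold;
    the last component has gap_after 0."""

    name: str
    items: list[tuple[str, str, int]]


def anchor_pairs(
    library: Library,
    contigs: Sequence[SeqRecord],
    seed_k: int = 21,
    index: SeedIndex | None = None,
) -> tuple[list[AnchoredPair], list[tuple[str, int, int]]]:
    """Anchor both mates of every pair by unique seed votes.

    Returns pairs with mates on different contigs (linking evidence) and,
    separately, same-contig spans usable for insert-size re-estimation.
    """
    if index is None:
        index = SeedIndex(contigs, k=seed_k)
    cross: list[AnchoredPair] = []
    same: list[tuple[str, int, int]] = []
    for r1, r2 in library.pairs:
        p1 = index.place(r1.seq)
        p2 = index.place(r2.seq)
        if p1 is None or p2 is None:
            continue
        if p1.ref_idx == p2.ref_idx:
            same.append((p1.ref_name, min(p1.start, p2.start), max(p1.start + len(r1), p2.start + len(r2))))
            continue
        cross.append(
            AnchoredPair(
                p1.ref_name, p1.start, p1.strand, len(r1),
                p2.ref_name, p2.start, p2.strand, len(r2),
            )
        )
    return cross, same


def _mate_link(orientation: str, strand: str, pos: int, read_len: int, contig_len: int) -> tuple[str, int]:
    """(linked end, fragment bp anchored on this contig) for one mate."""
    inward = orientation == "FR"
    points_right = (strand == "+") == inward
    if points_right:
        return "tail", contig_len - pos
    return "head", pos + read_len


def build_links(
    anchored: Sequence[AnchoredPair],
    library: Library,
    contig_lengths: dict[str, int],
    min_links: int = 3,
) -> list[LinkEvidence]:
    """Aggregate anchored cross-contig pairs into end-to-end link evidence.

    Evidence needs ``min_links`` supporting pairs and a plausible median
    gap (|gap| <= insert_mean + 3 sd).  When several orientation classes
    exist for one contig pair, the majority class is kept only if it alone
    passes ``min_links``.
    """
    groups: dict[tuple[str, str, str, str], list[tuple[int, float]]] = {}
    for ap in anchored:
        end_a, flank_a = _mate_link(library.orientation, ap.strand_a, ap.pos_a, ap.len_a, contig_lengths[ap.contig_a])
        end_b, flank_b = _mate_link(library.orientation, ap.strand_b, ap.pos_b, ap.len_b, contig_lengths[ap.contig_b])
        gap = int(round(library.insert_mean - flank_a - flank_b))
        key = (ap.contig_a, end_a, ap.contig_b, end_b)
        if (ap.contig_b, ap.contig_a) < (ap.contig_a, ap.contig_b):
            key = (ap.contig_b, end_b, ap.contig_a, end_a)
        groups.setdefault(key, []).append((gap, (ap.len_a + ap.len_b) / 2))

    by_pair: dict[tuple[str, str], list] = {}
    for key, obs in groups.items():
        by_pair.setdefault((key[0], key[2]), []).append((key, obs))

    links: list[LinkEvidence] = []
    limit = library.insert_mean + 3 * library.insert_sd
    for pair, classes in sorted(by_pair.items()):
        passing = [
            (key, obs)
            for key, obs in classes
            if len(obs) >= min_links and abs(np.median([g for g, _ in obs])) <= limit
        ]
        if len(passing) != 1:
            continue  # no class passes, or orientation evidence is ambiguous
        (ca, ea, cb, eb), obs = passing[0]
        gaps = sorted(g for g, _ in obs)
        rl = float(np.mean([r for _, r in obs]))
        links.append(
            LinkEvidence(ca, ea, cb, eb, len(gaps), gaps,
                         insert_mean=library.insert_mean, insert_sd=library.insert_sd, read_len=rl)
        )
    return links


# ----------------------------------------------------------- scaffolding

class _Chain:
    """A growing scaffold: ordered (contig, orient) with gaps between."""

    __slots__ = ("items", "gaps")

    def __init__(self, name: str):
        self.items: list[tuple[str, str]] = [(name, "+")]
        self.gaps: list[int] = []

    def reverse(self) -> None:
        self.items = [(n, "-" if o == "+" else "+") for n, o in reversed(self.items)]
        self.gaps.reverse()

    def link_side(self, name: str, end: str) -> str | None:
        """Which chain boundary ('left'/'right') exposes native ``end`` of
        contig ``name``; None when that end is buried."""
        last_name, last_o = self.items[-1]
        if name == last_name and end == ("tail" if last_o == "+" else "head"):
            return "right"
        first_name, first_o = self.items[0]
        if name == first_name and end == ("head" if first_o == "+" else "tail"):
            return "left"
        return None


def scaffold(
    contigs: Sequence[SeqRecord],
    libraries: Sequence[Library],
    min_links: int = 3,
    seed_k: int = 21,
    min_contig_len: int = 500,
) -> tuple[list[ScaffoldPlan], list[SeqRecord], list[AgpComponent], list[LinkEvidence]]:
    """Hierarchical greedy scaffolding.

    Libraries are applied smallest insert first; per round links are
    accepted by descending support.  Negative gap estimates are clamped to
    a single N (overlap merging already happened upstream).  Contigs
    shorter than ``min_contig_len`` — mostly collapsed repeat cores, whose
    many loci would compete for the same two chain ends — are excluded
    from ordering and passed through as single-contig scaffolds.
    """
    active = [c for c in contigs if len(c) >= min_contig_len]
    if not active:
        active = list(contigs)
    passive = [c for c in contigs if c.id not in {a.id for a in active}]
    lengths = {c.id: len(c) for c in active}
    chain_of: dict[str, _Chain] = {c.id: _Chain(c.id) for c in active}

    all_links: list[LinkEvidence] = []
    index = SeedIndex(active, k=seed_k)
    for lib in sorted(libraries, key=lambda l: l.insert_mean):
        anchored, _ = anchor_pairs(lib, active, seed_k=seed_k, index=index)
        links = build_links(anchored, lib, lengths, min_links=min_links)
        all_links.extend(links)
        for link in sorted(links, key=lambda l: (-l.support_count, l.contig_a, l.contig_b)):
            ch_a = chain_of[link.contig_a]
            ch_b = chain_of[link.contig_b]
            if ch_a is ch_b:
                continue  # would close a cycle
            side_a = ch_a.link_side(link.contig_a, link.end_a)
            side_b = ch_b.link_side(link.contig_b, link.end_b)
            if side_a is None or side_b is None:
                continue  # end already used or buried inside a chain
            if side_a == "left":
                ch_a.reverse()
            if side_b == "right":
                ch_b.reverse()
            ch_a.gaps.append(max(1, link.gap_estimate(lib.insert_sd)))
            ch_a.items.extend(ch_b.items)
            ch_a.gaps.extend(ch_b.gaps)
            for n, _ in ch_b.items:
                chain_of[n] = ch_a

    seen: set[int] = set()
    plan_list: list[ScaffoldPlan] = []
    serial = 0
    for c in active:  # deterministic order by input contig order
        ch = chain_of[c.id]
        if id(ch) in seen:
            continue
        seen.add(id(ch))
        serial += 1
        name = f"scaffold_{serial:04d}"
        items = []
        for i, (n, o) in enumerate(ch.items):
            gap_after = ch.gaps[i] if i < len(ch.gaps) else 0
            items.append((n, o, gap_after))
        plan_list.append(ScaffoldPlan(name, items))
    for c in passive:
        serial += 1
        plan_list.append(ScaffoldPlan(f"scaffold_{serial:04d}", [(c.id, "+", 0)]))

    byname = {c.id: c for c in contigs}
    fasta, agp = plans_to_sequences(plan_list, byname)
    return plan_list, fasta, agp, all_links


def plans_to_sequences(
    plans: Sequence[ScaffoldPlan],
    contigs: dict[str, SeqRecord],
) -> tuple[list[SeqRecord], list[AgpComponent]]:
    """Materialise scaffold FASTA and AGP from plans (exact conservation:
    scaffold length = sum of contig lengths + sum of gaps)."""
    fasta: list[SeqRecord] = []
    agp: list[AgpComponent] = []
    for plan in plans:
        parts: list[str] = []
        pos = 0  # 0-based
        part_no = 0
        for i, (name, orient, gap_after) in enumerate(plan.items):
            seq = contigs[name].seq
            if orient == "-":
                seq = revcomp(seq)
            part_no += 1
            agp.append(
                AgpComponent(plan.name, pos + 1, pos + len(seq), part_no, "W",
                             comp_id=name, comp_start=1, comp_end=len(seq), orientation=orient)
            )
            parts.append(seq)
            pos += len(seq)
            if i < len(plan.items) - 1 and gap_after > 0:
                part_no += 1
                agp.append(AgpComponent(plan.name, pos + 1, pos + gap_after, part_no, "N", gap_len=gap_after))
                parts.append("N" * gap_after)
                pos += gap_after
        fasta.append(SeqRecord(plan.name, "".join(parts)))
    return fasta, agp
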