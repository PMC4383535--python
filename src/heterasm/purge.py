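"""Removal of allelic redundancy (haplotigs) from merged contigs by read
depth and shared k-mer percentage.

An allelic contig carries read depth near half the homozygous spectrum
peak (the reads it shares with its partner split between them) and shares
most of its k-mers with the already-kept partner.  A contig is removed iff
both signals agree: median k-mer depth <= t_depth x homozygous peak AND
shared k-mer fraction vs some kept contig >= t_shared.  The shared
fraction is asymmetric — the purge candidate's distinct k-mers are the
denominator — so a short haplotig contained in a long kept contig scores
high.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Sequence

import numpy as np

from .kmers import KmerTable, distinct_canonical_set
from .seqio import SeqRecord
from .spectrum import KmerSpectrum, detect_peaks


@dataclass
class DepthProfile:
    """Per-contig median k-mer depth plus the homozygous peak depth of the
    read set, all computed at the same k."""

    k: int
    median_depth: dict[str, float]
    homozygous_peak: float


@dataclass
class PurgeDecision:
    contig: str
    status: str  # kept | removed
    reason: str  # low_depth+shared | unique | high_depth | too_short
    partner: str | None
    shared_frac: float
    depth_ratio: float


def contig_depths(
    contigs: Sequence[SeqRecord],
    reads: Sequence[SeqRecord | str],
    k: int = 21,
    table: KmerTable | None = None,
) -> DepthProfile:
    """Median per-copy read depth of each contig, plus the homozygous peak
    of the same reads at the same k.

    Each position's read-k-mer count is divided by that k-mer's copy number
    across the contig set, so a k-mer shared by an allelic contig pair
    contributes its per-copy depth — this is what produces the half-peak
    signature of haplotigs (reads split between the two copies).  Contigs
    shorter than k get depth NaN and are auto-kept downstream.
    """
    if table is None:
        table = KmerTable.from_seqs((r.seq if isinstance(r, SeqRecord) else r for r in reads), k)
    spectrum = KmerSpectrum(k, table.depth_histogram())
    peaks = detect_peaks(spectrum)
    if peaks.heterozygous:
        hom_peak = float(peaks.peaks[-1][0])
    else:
        hom_peak = float(max(peaks.peaks, key=lambda p: p[1])[0])

    asm_table = KmerTable.from_seqs((c.seq for c in contigs), k)
    medians: dict[str, float] = {}
    for c in contigs:
        if len(c) < k:
            medians[c.id] = float("nan")
            continue
        depth = table.per_position_depth(c.seq).astype(float)
        mult = asm_table.per_position_depth(c.seq).astype(float)
        ok = (depth >= 0) & (mult >= 1)
        medians[c.id] = float(np.median(depth[ok] / mult[ok])) if ok.any() else float("nan")
    return DepthProfile(k, medians, hom_peak)


def shared_kmer_fraction(a: SeqRecord | str, b: SeqRecord | str, k: int = 21) -> float:
    """|distinct canonical k-mers of a and b| / |distinct of a|.

    Asymmetric: ``a`` is the purge candidate.
    """
    sa = a.seq if isinstance(a, SeqRecord) else a
    sb = b.seq if isinstance(b, SeqRecord) else b
    if len(sa) < k or len(sb) < k:
        raise ValueError(f"sequences must be at least k={k} long")
    ka = distinct_canonical_set(sa, k)
    kb = distinct_canonical_set(sb, k)
    if ka.size == 0:
        raise ValueError("candidate has no valid k-mers")
    shared = np.intersect1d(ka, kb, assume_unique=True).size
    return shared / ka.size


def purge_redundant(
    contigs: Sequence[SeqRecord],
    profile: DepthProfile,
    t_depth: float = 0.65,
    t_shared: float = 0.60,
) -> tuple[list[SeqRecord], list[PurgeDecision]]:
    """Greedy keep-longest purge.

    Contigs are processed in decreasing length (name ascending on ties); a
    contig is removed iff its depth ratio is at most ``t_depth`` and it
    shares at least ``t_shared`` of its k-mers with an already-kept contig.
    """
    k = profile.k
    order = sorted(contigs, key=lambda c: (-len(c), c.id))
    kept: list[SeqRecord] = []
    kept_sets: list[np.ndarray] = []
    decisions: list[PurgeDecision] = []
    for c in order:
        med = profile.median_depth.get(c.id, float("nan"))
        if np.isnan(med):
            kept.append(c)
            kept_sets.append(distinct_canonical_set(c.seq, k) if len(c) >= k else np.empty(0, np.uint64))
            decisions.append(PurgeDecision(c.id, "kept", "too_short", None, 0.0, float("nan")))
            continue
        ratio = med / profile.homozygous_peak
        if ratio > t_depth:
            kept.append(c)
            kept_sets.append(distinct_canonical_set(c.seq, k))
            decisions.append(PurgeDecision(c.id, "kept", "high_depth", None, 0.0, ratio))
            continue
        cand = distinct_canonical_set(c.seq, k)
        best_frac, best_partner = 0.0, None
        for rec, ks in zip(kept, kept_sets):
            if cand.size == 0 or ks.size == 0:
                continue
            frac = np.intersect1d(cand, ks, assume_unique=True).size / cand.size
            if frac > best_frac:
                best_frac, best_partner = frac, rec.id
        if best_frac >= t_shared:
            decisions.append(PurgeDecision(c.id, "removed", "low_depth+shared", best_partner, best_frac, ratio))
        else:
            kept.append(c)
            kept_sets.append(cand)
            decisions.append(PurgeDecision(c.id, "kept", "unique", best_partner, best_frac, ratio))
    name_order = {c.id: i for i, c in enumerate(contigs)}
    kept.sort(key=lambda c: name_order[c.id])
    return kept, decisions
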