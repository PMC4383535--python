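"""Assembly statistics and validation battery: Nx, fold coverage,
feature-track percentages, read-back mapping, per-base coverage, transcript
completeness and the cumulative scaffold coverage curve.

The read and transcript mappers are deliberately simple seed-vote + banded
extension stand-ins for a production aligner; their thresholds (90% of the
read at 90% identity; transcripts at 80% identity over half their length)
are documented defaults, not tuned values.
"""

from __future__ import annotations

import re
from dataclasses import dataclass
from decimal import ROUND_HALF_UP, Decimal
from typing import Iterable, Sequence

import numpy as np

from .seqio import SeqRecord
from .seedindex import SeedIndex

_GAP_RE = re.compile(r"N+")


def round2(x: float) -> float:
    """Round half-up to 2 decimals (report formatting)."""
    return float(Decimal(repr(float(x))).quantize(Decimal("0.01"), rounding=ROUND_HALF_UP))


# ----------------------------------------------------------------- Nx

def nx(lengths: Sequence[int], x: float = 50) -> int:
    """Length at which the descending cumulative sum first reaches x% of
    the total (N50 for x=50)."""
    if not lengths:
        raise ValueError("empty length list")
    if any(l <= 0 for l in lengths):
        raise ValueError("lengths must be positive")
    srt = sorted(lengths, reverse=True)
    threshold = sum(srt) * x / 100.0
    acc = 0
    for l in srt:
        acc += l
        if acc >= threshold:
            return l
    return srt[-1]


# --------------------------------------------------------------- stats

@dataclass
class AsmStats:
    n_contigs: int
    n_scaffolds: int
    contig_n50: int
    scaffold_n50: int
    longest: int
    total_size: int


def contig_lengths_of(scaffolds: Iterable[SeqRecord]) -> list[int]:
    """Contig lengths obtained by splitting scaffolds at N runs."""
    out = []
    for rec in scaffolds:
        for piece in _GAP_RE.split(rec.seq):
            if piece:
                out.append(len(piece))
    return out


def assembly_stats(scaffolds: Sequence[SeqRecord]) -> AsmStats:
    scaf_lengths = [len(r) for r in scaffolds]
    ctg_lengths = contig_lengths_of(scaffolds)
    return AsmStats(
        n_contigs=len(ctg_lengths),
        n_scaffolds=len(scaf_lengths),
        contig_n50=nx(ctg_lengths, 50),
        scaffold_n50=nx(scaf_lengths, 50),
        longest=max(scaf_lengths),
        total_size=sum(scaf_lengths),
    )


def fold_coverage(total_bases: float, genome_size: float) -> float:
    """Sequencing depth = total bases / genome size, to 2 decimals."""
    if genome_size <= 0:
        raise ValueError("genome size must be positive")
    return round2(total_bases / genome_size)


# ------------------------------------------------------ feature tracks

@dataclass
class FeatureCoverage:
    track: str
    covered_bp: int
    percent_of_assembly: float


def _union_length(intervals: Iterable[tuple[str, int, int]], seq_lengths: dict[str, int] | None) -> int:
    by_chrom: dict[str, list[tuple[int, int]]] = {}
    for chrom, start, end in intervals:
        if end <= start or start < 0:
            raise ValueError(f"invalid interval {chrom}:{start}-{end}")
        if seq_lengths is not None:
            if chrom not in seq_lengths or end > seq_lengths[chrom]:
                raise ValueError(f"interval {chrom}:{start}-{end} exceeds sequence bounds")
        by_chrom.setdefault(chrom, []).append((start, end))
    total = 0
    for ivs in by_chrom.values():
        ivs.sort()
        cur_s, cur_e = ivs[0]
        for s, e in ivs[1:]:
            if s > cur_e:
                total += cur_e - cur_s
                cur_s, cur_e = s, e
            else:
                cur_e = max(cur_e, e)
        total += cur_e - cur_s
    return total


def percent_of_assembly(
    track: int | Iterable[tuple[str, int, int]],
    assembly_size: int,
    name: str = "track",
    seq_lengths: dict[str, int] | None = None,
) -> FeatureCoverage:
    """Fraction of the assembly covered by a feature track.

    ``track`` is either a precomputed total length or a list of 0-based
    half-open intervals; overlapping intervals are unioned before summing.
    """
    if assembly_size <= 0:
        raise ValueError("assembly size must be positive")
    covered = track if isinstance(track, (int, np.integer)) else _union_length(track, seq_lengths)
    return FeatureCoverage(name, int(covered), round2(100.0 * covered / assembly_size))


# ----------------------------------------------------------- read-back

def read_mapping_rate(
    reads: Sequence[SeqRecord],
    assembly: Sequence[SeqRecord],
    seed_k: int = 21,
    min_identity: float = 0.90,
    min_read_frac: float = 0.90,
    index: SeedIndex | None = None,
) -> tuple[float, list[tuple[int, int, int]]]:
    """Fraction of reads whose best seed-vote placement aligns >= 90% of
    the read at >= 90% identity; also returns placements for pileup."""
    if index is None:
        index = SeedIndex(assembly, k=seed_k)
    mapped = 0
    placements: list[tuple[int, int, int]] = []
    for read in reads:
        pl = index.place(read.seq)
        if pl is None:
            continue
        ident, s, e = index.align(read.seq, pl)
        if ident >= min_identity and (e - s) >= min_read_frac * len(read.seq):
            mapped += 1
            placements.append((pl.ref_idx, s, e))
    return (mapped / len(reads) if reads else 0.0), placements


def base_coverage_fraction(
    assembly: Sequence[SeqRecord],
    placements: Iterable[tuple[int, int, int]],
    d: int = 5,
) -> float:
    """Fraction of assembly positions with pileup depth >= d."""
    diffs = [np.zeros(len(rec) + 1, dtype=np.int64) for rec in assembly]
    for ref_idx, s, e in placements:
        arr = diffs[ref_idx]
        arr[max(0, s)] += 1
        arr[min(len(arr) - 1, e)] -= 1
    covered = 0
    total = 0
    for arr in diffs:
        depth = np.cumsum(arr[:-1])
        covered += int((depth >= d).sum())
        total += depth.size
    return covered / total if total else 0.0


# --------------------------------------------------------- transcripts

def transcript_completeness(
    transcripts: Sequence[SeqRecord],
    assembly: Sequence[SeqRecord],
    min_len: int = 1000,
    min_identity: float = 0.80,
    chunk: int = 500,
    index: SeedIndex | None = None,
) -> float:
    """Fraction of long transcripts placed on the assembly.

    A transcript counts when chunks covering >= 50% of its length align at
    >= ``min_identity``, with placements allowed to split across at most
    two scaffolds (a proxy for spliced/split placement).
    """
    pool = [t for t in transcripts if len(t) > min_len]
    if not pool:
        return 0.0
    if index is None:
        index = SeedIndex(assembly, k=21)
    n_ok = 0
    for tr in pool:
        placed_bp: dict[int, int] = {}
        for i in range(0, len(tr.seq), chunk):
            piece = tr.seq[i : i + chunk]
            if len(piece) < index.k:
                continue
            pl = index.place(piece)
            if pl is None:
                continue
            ident, s, e = index.align(piece, pl)
            if ident >= min_identity:
                placed_bp[pl.ref_idx] = placed_bp.get(pl.ref_idx, 0) + len(piece)
        best2 = sorted(placed_bp.values(), reverse=True)[:2]
        if sum(best2) >= 0.5 * len(tr.seq):
            n_ok += 1
    return n_ok / len(pool)


# ------------------------------------------------- cumulative coverage

def cumulative_scaffold_coverage(lengths: Sequence[int]) -> tuple[list[tuple[int, float]], int]:
    """Descending cumulative assembly fraction per scaffold count, plus the
    smallest n of longest scaffolds reaching 90% of the assembly."""
    if not lengths:
        raise ValueError("empty length list")
    srt = sorted(lengths, reverse=True)
    total = sum(srt)
    curve = []
    acc = 0
    for i, l in enumerate(srt, 1):
        acc += l
        curve.append((i, acc / total))
    n90 = next(i for i, f in curve if f >= 0.90)
    return curve, n90
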