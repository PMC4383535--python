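"""End-to-end orchestration of the hierarchical assembly workflow on
simulated or user-supplied inputs:

    clones -> per-unit k-sweep assembly -> overlap merge -> haplotig purge
           -> mate-pair scaffolding -> short-insert gap filling -> QC
"""

from __future__ import annotations

import logging
import time
from dataclasses import dataclass, field
from typing import Sequence

from .config import PipelineConfig, sweep_ks
from .gapfill import gapfill_scaffolds
from .overlap import ProvenanceRow, merge_assemblies
from .purge import PurgeDecision, contig_depths, purge_redundant
from .qc import AsmStats, assembly_stats
from .scaffolder import Library, ScaffoldPlan, scaffold
from .seqio import SeqRecord
from .simgen import SimResult
from .spectrum import KmerSpectrum, SpectrumPeaks, count_canonical_kmers, detect_peaks, estimate_genome_size
from .unit_assembler import UnitAssembly, assemble_unit

log = logging.getLogger("heterasm")


@dataclass
class PipelineResult:
    spectrum: KmerSpectrum
    peaks: SpectrumPeaks
    genome_size_estimate: float
    unit_assemblies: list[UnitAssembly]
    merged: list[SeqRecord]
    provenance: list[ProvenanceRow]
    purged: list[SeqRecord]
    purge_decisions: list[PurgeDecision]
    plans: list[ScaffoldPlan]
    scaffolds: list[SeqRecord]
    filled: list[SeqRecord]
    gap_report: list[tuple[str, int, str, int]]
    stats: AsmStats
    timings: dict[str, float] = field(default_factory=dict)


def _flat_reads(libraries: Sequence[Library]) -> list[SeqRecord]:
    out: list[SeqRecord] = []
    for lib in libraries:
        for r1, r2 in lib.pairs:
            out.append(r1)
            out.append(r2)
    return out


def run_pipeline(sim: SimResult, cfg: PipelineConfig | None = None) -> PipelineResult:
    """Run every stage on a simulation result and return all intermediates."""
    cfg = cfg or PipelineConfig()
    t = {}

    def _tick(stage: str, t0: float) -> None:
        t[stage] = time.perf_counter() - t0
        log.info("stage %-10s %6.1fs", stage, t[stage])

    short_libs = [l for l in sim.libraries if l.orientation == "FR"]
    wgs_reads = _flat_reads(short_libs)

    t0 = time.perf_counter()
    spectrum = count_canonical_kmers(wgs_reads, cfg.spectrum_k)
    peaks = detect_peaks(spectrum, smooth_window=cfg.smooth_window, peak_min_frac=cfg.peak_min_frac)
    gsize = estimate_genome_size(spectrum, peaks, include_errors=cfg.kmer_include_errors)
    _tick("kmer", t0)

    t0 = time.perf_counter()
    units = []
    for clone in sim.clones:
        reads = [r for pair in clone.pairs for r in pair]
        units.append(
            assemble_unit(
                reads,
                unit_id=clone.truth.clone_id,
                k_min=cfg.ksweep_min,
                k_max=cfg.ksweep_max,
                k_step=cfg.ksweep_step,
                pop_bubbles=cfg.pop_bubbles,
                bubble_identity=cfg.bubble_identity,
            )
        )
    _tick("unit-asm", t0)

    t0 = time.perf_counter()
    all_contigs = [c for u in units for c in u.contigs]
    merged, provenance, _ = merge_assemblies(
        all_contigs,
        seed_k=cfg.overlap_seed_k,
        min_overlap=cfg.overlap_min_len,
        min_identity=cfg.overlap_min_identity,
        end_slack=cfg.end_slack,
    )
    _tick("merge", t0)

    t0 = time.perf_counter()
    profile = contig_depths(merged, wgs_reads, k=cfg.purge_k)
    purged, decisions = purge_redundant(
        merged, profile, t_depth=cfg.purge_depth_ratio, t_shared=cfg.purge_shared_frac
    )
    _tick("purge", t0)

    t0 = time.perf_counter()
    plans, scaffolds, _agp, _links = scaffold(
        purged, sim.libraries, min_links=cfg.scaffold_min_links, seed_k=cfg.scaffold_seed_k
    )
    _tick("scaffold", t0)

    t0 = time.perf_counter()
    filled, gap_report = gapfill_scaffolds(
        scaffolds, short_libs, k_local=cfg.gapfill_k, flank_w=cfg.gapfill_flank, rounds=cfg.gapfill_rounds
    )
    _tick("gapfill", t0)

    stats = assembly_stats(filled)
    return PipelineResult(
        spectrum, peaks, gsize, units, merged, provenance, purged, decisions,
        plans, scaffolds, filled, gap_report, stats, t,
    )
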