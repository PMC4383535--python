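"""Synthetic diploid data generator with exported truth.

Emulates the study inputs of a clone-based hierarchical assembly: a
haploid reference with planted near-identical repeats, a second haplotype
derived by SNPs and short indels, a tiling of ~120 kb clone inserts drawn
from either haplotype at ~4.3x coverage (the mechanism that creates
allelic redundancy across independently assembled clones), and
short-insert / mate-pair read libraries with substitution errors.

Every stochastic choice derives from one numpy Generator seeded from the
config, so identical seeds give byte-identical outputs; every read and
clone origin is recorded for oracle tests.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from typing import Sequence

import numpy as np

from .kmers import revcomp
from .scaffolder import Library
from .seqio import SeqRecord

_BASES = np.frombuffer(b"ACGT", dtype=np.uint8)


class SimConfigError(ValueError):
    pass


@dataclass
class LibrarySpec:
    name: str
    insert_mean: float
    insert_sd: float
    read_len: int = 100
    orientation: str = "FR"  # FR short-insert, RF mate-pair
    error_rate: float = 0.005
    depth: float = 30.0


@dataclass
class SimConfig:
    genome_len: int = 500_000
    repeat_frac: float = 0.05
    repeat_unit_len: int = 500
    repeat_divergence: float = 0.02  # copies stay >= 97% identical to the unit
    snp_rate: float = 0.01
    indel_rate: float = 0.001
    clone_len_mean: int = 120_000
    clone_len_sd: int = 10_000
    clone_coverage: float = 4.3
    clone_read_depth: float = 30.0
    clone_library: LibrarySpec = field(
        default_factory=lambda: LibrarySpec("clone_pe", 300, 30, 100, "FR", 0.005)
    )
    libraries: list[LibrarySpec] = field(
        default_factory=lambda: [
            LibrarySpec("pe300", 300, 30, 100, "FR", 0.005, depth=50.0),
            LibrarySpec("mp5000", 5000, 500, 100, "RF", 0.005, depth=10.0),
        ]
    )
    rng_seed: int = 0

    def __post_init__(self) -> None:
        for name in ("repeat_frac",):
            if not (0 <= getattr(self, name) <= 1):
                raise SimConfigError(f"{name} out of [0,1]")
        for name in ("snp_rate", "indel_rate", "repeat_divergence"):
            if not (0 <= getattr(self, name) <= 0.05):
                raise SimConfigError(f"{name} out of [0, 0.05]")
        if self.clone_coverage <= 0:
            raise SimConfigError("clone_coverage must be positive")


@dataclass
class Variant:
    pos: int  # hap1 coordinate
    ref: str  # "" for insertion
    alt: str  # "" for deletion
    kind: str  # snp | ins | del


@dataclass
class CloneTruth:
    clone_id: str
    hap: int  # 1 or 2
    start: int  # coordinates on that haplotype
    end: int


@dataclass
class PairOrigin:
    pair_id: str
    source: str  # e.g. "hap1", "hap2", clone id
    start: int  # fragment start on the source
    insert_len: int


@dataclass
class Clone:
    truth: CloneTruth
    pairs: list[tuple[SeqRecord, SeqRecord]]
    origins: list[PairOrigin]


@dataclass
class SimResult:
    config: SimConfig
    hap1: SeqRecord
    hap2: SeqRecord
    variants: list[Variant]
    repeat_bed: list[tuple[str, int, int]]
    clones: list[Clone]
    libraries: list[Library]
    origins: dict[str, list[PairOrigin]]


def _random_dna(rng: np.random.Generator, n: int) -> np.ndarray:
    return rng.integers(0, 4, n, dtype=np.uint8)


def _decode(codes: np.ndarray) -> str:
    return _BASES[codes].tobytes().decode()


# ------------------------------------------------------------ genome

def sim_genome(cfg: SimConfig, rng: np.random.Generator) -> tuple[SeqRecord, list[tuple[str, int, int]]]:
    """Uniform-random haploid reference with planted near-identical repeat
    copies; the BED records every copy."""
    L = cfg.genome_len
    codes = _random_dna(rng, L)
    bed: list[tuple[str, int, int]] = []
    if cfg.repeat_frac > 0:
        n_copies = int(round(cfg.repeat_frac * L / cfg.repeat_unit_len))
        if n_copies < 1:
            raise SimConfigError("repeat_frac * genome_len smaller than one repeat unit")
        unit = _random_dna(rng, cfg.repeat_unit_len)
        taken: list[tuple[int, int]] = []
        for _ in range(n_copies):
            for _try in range(200):
                start = int(rng.integers(0, L - cfg.repeat_unit_len))
                end = start + cfg.repeat_unit_len
                if all(end <= s or start >= e for s, e in taken):
                    break
            else:
                continue
            taken.append((start, end))
            copy = unit.copy()
            mut = rng.random(cfg.repeat_unit_len) < cfg.repeat_divergence
            copy[mut] = (copy[mut] + rng.integers(1, 4, int(mut.sum()), dtype=np.uint8)) % 4
            codes[start:end] = copy
        bed = [("hap1", s, e) for s, e in sorted(taken)]
    return SeqRecord("hap1", _decode(codes)), bed


# --------------------------------------------------------- diploidize

def diploidize(
    reference: SeqRecord | str,
    snp_rate: float,
    indel_rate: float,
    rng: np.random.Generator,
) -> tuple[SeqRecord, list[Variant]]:
    """Derive the second haplotype by SNPs and 1-5 bp geometric indels;
    the variant list reproduces it exactly via :func:`apply_variants`."""
    ref = reference.seq if isinstance(reference, SeqRecord) else reference
    L = len(ref)
    codes = np.frombuffer(ref.encode(), dtype=np.uint8)
    events: list[Variant] = []
    snp_pos = np.nonzero(rng.random(L) < snp_rate)[0]
    snp_shift = rng.integers(1, 4, snp_pos.size)
    indel_pos = np.nonzero(rng.random(L) < indel_rate)[0]
    indel_is_ins = rng.random(indel_pos.size) < 0.5
    indel_len = np.minimum(rng.geometric(0.5, indel_pos.size), 5)

    snp_lut = {65: "ACGT".index("A"), 67: 1, 71: 2, 84: 3}
    merged: list[Variant] = []
    si = ii = 0
    while si < snp_pos.size or ii < indel_pos.size:
        take_snp = ii >= indel_pos.size or (si < snp_pos.size and snp_pos[si] <= indel_pos[ii])
        if take_snp:
            p = int(snp_pos[si])
            base = snp_lut[codes[p]]
            alt = "ACGT"[(base + int(snp_shift[si])) % 4]
            merged.append(Variant(p, ref[p], alt, "snp"))
            si += 1
        else:
            p = int(indel_pos[ii])
            g = int(indel_len[ii])
            if indel_is_ins[ii]:
                ins = _decode(_random_dna(rng, g))
                merged.append(Variant(p, "", ins, "ins"))
            else:
                merged.append(Variant(p, ref[p : p + g], "", "del"))
            ii += 1
    # drop events overlapping an earlier deletion span or duplicated position
    last_end = -1
    for ev in merged:
        if ev.pos < last_end or ev.pos >= L:
            continue
        events.append(ev)
        last_end = ev.pos + max(1, len(ev.ref))
    hap2 = apply_variants(ref, events)
    return SeqRecord("hap2", hap2), events


def apply_variants(reference: str, variants: Sequence[Variant]) -> str:
    """Deterministically rebuild hap2 from hap1 and the variant list."""
    parts: list[str] = []
    cur = 0
    for v in sorted(variants, key=lambda v: v.pos):
        parts.append(reference[cur : v.pos])
        if v.kind == "snp":
            parts.append(v.alt)
            cur = v.pos + 1
        elif v.kind == "ins":
            parts.append(reference[v.pos] + v.alt)
            cur = v.pos + 1
        else:  # del
            cur = v.pos + len(v.ref)
    parts.append(reference[cur:])
    return "".join(parts)


# ------------------------------------------------------------- reads

def sim_paired_reads(
    source: SeqRecord | str,
    spec: LibrarySpec,
    depth: float,
    rng: np.random.Generator,
    prefix: str = "pair",
    source_name: str | None = None,
) -> tuple[list[tuple[SeqRecord, SeqRecord]], list[PairOrigin]]:
    """Paired reads from one source sequence.

    Insert lengths are Normal(mean, sd) truncated at [2 x read_len, source
    length]; FR pairs point inward, RF (mate-pair) pairs outward; errors
    are random substitutions at the spec's per-base rate.
    """
    seq = source.seq if isinstance(source, SeqRecord) else source
    sid = source_name or (source.id if isinstance(source, SeqRecord) else "seq")
    L = len(seq)
    rl = spec.read_len
    if spec.insert_mean >= L:
        raise SimConfigError(f"insert_mean {spec.insert_mean} >= source length {L}")
    n_pairs = int(round(depth * L / (2 * rl)))
    if n_pairs == 0:
        return [], []
    codes = np.frombuffer(seq.encode(), dtype=np.uint8)
    enc = np.full(256, 0, dtype=np.uint8)
    for i, b in enumerate(b"ACGT"):
        enc[b] = i
    codes = enc[codes]

    ins = np.clip(
        np.rint(rng.normal(spec.insert_mean, spec.insert_sd, n_pairs)),
        2 * rl,
        L,
    ).astype(np.int64)
    starts = (rng.random(n_pairs) * (L - ins + 1)).astype(np.int64)

    off = np.arange(rl)
    m1 = codes[starts[:, None] + off]
    m2 = codes[(starts + ins - rl)[:, None] + off]
    for m in (m1, m2):
        if spec.error_rate > 0:
            err = rng.random(m.shape) < spec.error_rate
            m[err] = (m[err] + rng.integers(1, 4, int(err.sum()), dtype=np.uint8)) % 4
    if spec.orientation == "FR":
        r1m, r2m = m1, (3 - m2)[:, ::-1]
    else:  # RF: outward-pointing
        r1m, r2m = (3 - m1)[:, ::-1], m2

    b1 = _BASES[r1m].tobytes()
    b2 = _BASES[r2m].tobytes()
    pairs: list[tuple[SeqRecord, SeqRecord]] = []
    origins: list[PairOrigin] = []
    for i in range(n_pairs):
        pid = f"{prefix}_{i:07d}"
        s1 = b1[i * rl : (i + 1) * rl].decode()
        s2 = b2[i * rl : (i + 1) * rl].decode()
        pairs.append((SeqRecord(pid + "/1", s1), SeqRecord(pid + "/2", s2)))
        origins.append(PairOrigin(pid, sid, int(starts[i]), int(ins[i])))
    return pairs, origins


# ------------------------------------------------------------- clones

def sim_clones(
    hap1: SeqRecord,
    hap2: SeqRecord,
    cfg: SimConfig,
    rng: np.random.Generator,
) -> list[Clone]:
    """Clone inserts drawn uniformly from a random haplotype each, with
    per-clone short-insert reads.  Expected total clone length is
    clone_coverage x genome_len.

    Placement is edge-clipped: a clone may run off either end of the
    simulated window (as a clone from a larger genome would) and is
    truncated at the window bounds, so coverage is uniform along the whole
    window instead of ramping down at the ends.  The clone count is scaled
    so the expected *clipped* total still matches the target coverage.
    """
    mean_clip = cfg.clone_len_mean * cfg.genome_len / (cfg.genome_len + cfg.clone_len_mean - 1)
    n_clones = int(round(cfg.clone_coverage * cfg.genome_len / mean_clip))
    min_len = max(2000, int(2 * cfg.clone_library.insert_mean))
    clones: list[Clone] = []
    for i in range(n_clones):
        length = int(np.clip(rng.normal(cfg.clone_len_mean, cfg.clone_len_sd),
                             cfg.clone_len_mean // 2, cfg.clone_len_mean * 2))
        hap = 1 + int(rng.integers(0, 2))
        src = hap1 if hap == 1 else hap2
        L = len(src)
        length = min(length, L)
        for _ in range(100):
            raw = int(rng.integers(-length + 1, L))
            start, end = max(0, raw), min(L, raw + length)
            if end - start >= min_len:
                break
        length = end - start
        cid = f"clone{i:04d}"
        insert = src.seq[start:end]
        pairs, origins = sim_paired_reads(
            insert, cfg.clone_library, cfg.clone_read_depth, rng, prefix=cid, source_name=cid
        )
        clones.append(Clone(CloneTruth(cid, hap, start, end), pairs, origins))
    return clones


# ---------------------------------------------------------- top level

def simulate(cfg: SimConfig) -> SimResult:
    """Full study-condition simulation: genome, second haplotype, clone
    tiling with per-clone reads, and whole-genome read libraries drawn
    evenly from both haplotypes."""
    rng = np.random.default_rng(cfg.rng_seed)
    hap1, bed = sim_genome(cfg, rng)
    hap2, variants = diploidize(hap1, cfg.snp_rate, cfg.indel_rate, rng)
    clones = sim_clones(hap1, hap2, cfg, rng)

    libraries: list[Library] = []
    origins: dict[str, list[PairOrigin]] = {}
    for spec in cfg.libraries:
        pairs: list[tuple[SeqRecord, SeqRecord]] = []
        orig: list[PairOrigin] = []
        for hap_rec in (hap1, hap2):
            p, o = sim_paired_reads(
                hap_rec, spec, spec.depth / 2, rng,
                prefix=f"{spec.name}_{hap_rec.id}", source_name=hap_rec.id,
            )
            pairs.extend(p)
            orig.extend(o)
        libraries.append(Library(spec.name, spec.insert_mean, spec.insert_sd, spec.orientation, pairs))
        origins[spec.name] = orig
    return SimResult(cfg, hap1, hap2, variants, bed, clones, libraries, origins)
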