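"""Readers and writers for the plain-text formats the pipeline touches:
FASTA, FASTQ (paired), PAF, AGP 2.1 and 3-column BED.

Coordinates are 0-based half-open everywhere except AGP, which is 1-based
inclusive per the format's own convention.
"""

from __future__ import annotations

import os
from dataclasses import dataclass, field
from typing import Iterable, Iterator, Sequence

from Bio.SeqIO.QualityIO import FastqGeneralIterator

from .kmers import revcomp

FASTA_WRAP = 60


class FormatError(ValueError):
    pass


@dataclass
class SeqRecord:
    """A named DNA sequence, optionally with FASTQ qualities."""

    id: str
    seq: str
    qual: str | None = None

    def __post_init__(self) -> None:
        if not self.id:
            raise FormatError("record id must be nonempty")
        if self.qual is not None and len(self.qual) != len(self.seq):
            raise FormatError(f"quality length mismatch for {self.id!r}")

    def __len__(self) -> int:
        return len(self.seq)

    def rc(self) -> "SeqRecord":
        return SeqRecord(self.id, revcomp(self.seq), None if self.qual is None else self.qual[::-1])


# ---------------------------------------------------------------- FASTA

def read_fasta(path: str | os.PathLike) -> list[SeqRecord]:
    """Parse a FASTA file.  Sequences are uppercased; order is preserved.

    Malformed headers and empty sequences raise :class:`FormatError` naming
    the offending line number.
    """
    records: list[SeqRecord] = []
    seen: set[str] = set()
    name: str | None = None
    chunks: list[str] = []
    header_line = 0

    def _flush(lineno: int) -> None:
        nonlocal name, chunks
        if name is None:
            return
        seq = "".join(chunks).upper()
        if not seq:
            raise FormatError(f"{path}: empty sequence for {name!r} (header at line {header_line})")
        if name in seen:
            raise FormatError(f"{path}: duplicate id {name!r} (line {header_line})")
        seen.add(name)
        records.append(SeqRecord(name, seq))
        name, chunks = None, []

    lineno = 0
    with open(path) as fh:
        for lineno, line in enumerate(fh, 1):
            line = line.rstrip("\n")
            if not line:
                continue
            if line.startswith(">"):
                _flush(lineno)
                name = line[1:].split()[0] if line[1:].split() else ""
                if not name:
                    raise FormatError(f"{path}: malformed header at line {lineno}")
                header_line = lineno
            else:
                if name is None:
                    raise FormatError(f"{path}: sequence before any header at line {lineno}")
                chunks.append(line)
        _flush(lineno)
    return records


def write_fasta(records: Iterable[SeqRecord], path: str | os.PathLike, wrap: int = FASTA_WRAP) -> None:
    with open(path, "w") as fh:
        for rec in records:
            fh.write(f">{rec.id}\n")
            for i in range(0, len(rec.seq), wrap):
                fh.write(rec.seq[i : i + wrap] + "\n")


# ---------------------------------------------------------------- FASTQ

def read_fastq(path: str | os.PathLike) -> list[SeqRecord]:
    out = []
    with open(path) as fh:
        for title, seq, qual in FastqGeneralIterator(fh):
            out.append(SeqRecord(title.split()[0], seq.upper(), qual))
    return out


def write_fastq(records: Iterable[SeqRecord], path: str | os.PathLike) -> None:
    with open(path, "w") as fh:
        for rec in records:
            qual = rec.qual if rec.qual is not None else "I" * len(rec.seq)
            fh.write(f"@{rec.id}\n{rec.seq}\n+\n{qual}\n")


def _pair_key(read_id: str) -> str:
    if read_id.endswith("/1") or read_id.endswith("/2"):
        return read_id[:-2]
    return read_id


def read_fastq_pairs(path1: str | os.PathLike, path2: str | os.PathLike) -> list[tuple[SeqRecord, SeqRecord]]:
    """Read two FASTQ files as mate pairs.

    Counts must match and ids must pair after stripping ``/1``/``/2``
    suffixes; a mismatch raises :class:`FormatError` naming the id.
    """
    r1 = read_fastq(path1)
    r2 = read_fastq(path2)
    if len(r1) != len(r2):
        raise FormatError(f"unequal read counts: {len(r1)} in {path1}, {len(r2)} in {path2}")
    pairs = []
    for a, b in zip(r1, r2):
        if _pair_key(a.id) != _pair_key(b.id):
            raise FormatError(f"unpaired read id {a.id!r} vs {b.id!r}")
        pairs.append((a, b))
    return pairs


# ---------------------------------------------------------------- PAF

@dataclass
class PafRecord:
    """One pairwise alignment in PAF convention (0-based half-open)."""

    qname: str
    qlen: int
    qstart: int
    qend: int
    strand: str
    tname: str
    tlen: int
    tstart: int
    tend: int
    matches: int
    aln_len: int
    mapq: int = 255

    def validate(self) -> None:
        for nm, s, e, ln in (("query", self.qstart, self.qend, self.qlen), ("target", self.tstart, self.tend, self.tlen)):
            if not (0 <= s < e <= ln):
                raise FormatError(f"invalid {nm} interval [{s},{e}) on length {ln} ({self.qname}/{self.tname})")
        if self.strand not in "+-":
            raise FormatError(f"invalid strand {self.strand!r}")
        if not (0 < self.matches <= self.aln_len):
            raise FormatError(f"invalid matches/aln_len {self.matches}/{self.aln_len}")


def write_paf(records: Iterable[PafRecord], path: str | os.PathLike) -> None:
    with open(path, "w") as fh:
        for r in records:
            r.validate()
            fh.write(
                "\t".join(
                    str(x)
                    for x in (
                        r.qname, r.qlen, r.qstart, r.qend, r.strand,
                        r.tname, r.tlen, r.tstart, r.tend,
                        r.matches, r.aln_len, r.mapq,
                    )
                )
                + "\n"
            )


def read_paf(path: str | os.PathLike) -> list[PafRecord]:
    out = []
    with open(path) as fh:
        for lineno, line in enumerate(fh, 1):
            f = line.rstrip("\n").split("\t")
            if len(f) < 12:
                raise FormatError(f"{path}: PAF line {lineno} has {len(f)} columns")
            out.append(
                PafRecord(
                    f[0], int(f[1]), int(f[2]), int(f[3]), f[4],
                    f[5], int(f[6]), int(f[7]), int(f[8]),
                    int(f[9]), int(f[10]), int(f[11]),
                )
            )
    return out


# ---------------------------------------------------------------- AGP 2.1

@dataclass
class AgpComponent:
    """One AGP line: either a contig placement (W) or a gap (N)."""

    obj: str
    obj_start: int  # 1-based inclusive
    obj_end: int
    part: int
    kind: str  # "W" or "N"
    comp_id: str | None = None
    comp_start: int | None = None  # 1-based, W lines
    comp_end: int | None = None
    orientation: str | None = None  # +/-
    gap_len: int | None = None


def write_agp(components: Iterable[AgpComponent], path: str | os.PathLike) -> None:
    with open(path, "w") as fh:
        fh.write("##agp-version\t2.1\n")
        for c in components:
            if c.obj_end - c.obj_start + 1 <= 0:
                raise FormatError(f"AGP object interval empty for {c.obj} part {c.part}")
            if c.kind == "W":
                span = c.comp_end - c.comp_start + 1
                if span != c.obj_end - c.obj_start + 1:
                    raise FormatError(f"AGP component span mismatch for {c.comp_id}")
                fh.write(
                    f"{c.obj}\t{c.obj_start}\t{c.obj_end}\t{c.part}\tW\t"
                    f"{c.comp_id}\t{c.comp_start}\t{c.comp_end}\t{c.orientation}\n"
                )
            elif c.kind == "N":
                if c.gap_len != c.obj_end - c.obj_start + 1:
                    raise FormatError(f"AGP gap span mismatch in {c.obj} part {c.part}")
                fh.write(
                    f"{c.obj}\t{c.obj_start}\t{c.obj_end}\t{c.part}\tN\t"
                    f"{c.gap_len}\tscaffold\tyes\tpaired-ends\n"
                )
            else:
                raise FormatError(f"unknown AGP component kind {c.kind!r}")


def read_agp(path: str | os.PathLike) -> list[AgpComponent]:
    out = []
    with open(path) as fh:
        for line in fh:
            if line.startswith("#"):
                continue
            f = line.rstrip("\n").split("\t")
            if len(f) < 9:
                raise FormatError(f"{path}: short AGP line: {line!r}")
            base = dict(obj=f[0], obj_start=int(f[1]), obj_end=int(f[2]), part=int(f[3]), kind=f[4])
            if f[4] == "W":
                out.append(AgpComponent(**base, comp_id=f[5], comp_start=int(f[6]), comp_end=int(f[7]), orientation=f[8]))
            else:
                out.append(AgpComponent(**base, gap_len=int(f[5])))
    return out


def scaffold_fasta_from_agp(components: Sequence[AgpComponent], contigs: dict[str, str]) -> list[SeqRecord]:
    """Rebuild scaffold sequences from an AGP and its component contigs."""
    by_obj: dict[str, list[AgpComponent]] = {}
    for c in components:
        by_obj.setdefault(c.obj, []).append(c)
    out = []
    for obj, comps in by_obj.items():
        comps.sort(key=lambda c: c.part)
        parts = []
        for c in comps:
            if c.kind == "N":
                parts.append("N" * c.gap_len)
            else:
                s = contigs[c.comp_id][c.comp_start - 1 : c.comp_end]
                parts.append(revcomp(s) if c.orientation == "-" else s)
        out.append(SeqRecord(obj, "".join(parts)))
    return out


# ---------------------------------------------------------------- BED

def read_bed(path: str | os.PathLike) -> list[tuple[str, int, int]]:
    out = []
    with open(path) as fh:
        for lineno, line in enumerate(fh, 1):
            line = line.rstrip("\n")
            if not line or line.startswith(("#", "track")):
                continue
            f = line.split("\t")
            if len(f) < 3:
                raise FormatError(f"{path}: BED line {lineno} has fewer than 3 columns")
            out.append((f[0], int(f[1]), int(f[2])))
    return out


def write_bed(intervals: Iterable[tuple[str, int, int]], path: str | os.PathLike) -> None:
    with open(path, "w") as fh:
        for chrom, start, end in intervals:
            if end <= start:
                raise FormatError(f"empty BED interval {chrom}:{start}-{end}")
            fh.write(f"{chrom}\t{start}\t{end}\n")


# ---------------------------------------------------------------- TSV helper

def write_tsv(rows: Iterable[Sequence], path: str | os.PathLike, header: Sequence[str] | None = None) -> None:
    with open(path, "w") as fh:
        if header:
            fh.write("\t".join(header) + "\n")
        for row in rows:
            fh.write("\t".join(str(x) for x in row) + "\n")
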