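"""Shared helpers for the test suite."""

from __future__ import annotations

import numpy as np

_BASES = np.array(list("ACGT"))


def dna(rng: np.random.Generator, n: int) -> str:
    """Uniform random DNA string."""
    return "".join(_BASES[rng.integers(0, 4, n)])


def mutate_snps(seq: str, rate: float, rng: np.random.Generator) -> str:
    """Independent substitutions at the given per-base rate."""
    out = list(seq)
    for p in np.nonzero(rng.random(len(seq)) < rate)[0]:
        out[p] = "ACGT"[("ACGT".index(out[p]) + int(rng.integers(1, 4))) % 4]
    return "".join(out)


def tile_reads(seq: str, read_len: int = 100, stride: int = 10) -> list[str]:
    """Error-free reads tiling a sequence end to end."""
    reads = [seq[i : i + read_len] for i in range(0, len(seq) - read_len + 1, stride)]
    if (len(seq) - read_len) % stride:
        reads.append(seq[-read_len:])
    return reads


def brute_force_canonical_kmers(seqs: list[str], k: int) -> dict[str, int]:
    """Independent canonical k-mer counting oracle (plain string scan)."""
    comp = str.maketrans("ACGT", "TGCA")
    counts: dict[str, int] = {}
    for s in seqs:
        for i in range(len(s) - k + 1):
            km = s[i : i + k]
            if set(km) - set("ACGT"):
                continue
            rc = km.translate(comp)[::-1]
            key = min(km, rc)
            counts[key] = counts.get(key, 0) + 1
    return counts


def brute_force_nx(lengths: list[int], x: float = 50) -> int:
    """Independent Nx oracle: linear scan over descending lengths."""
    srt = sorted(lengths, reverse=True)
    need = sum(srt) * x / 100.0
    run = 0
    for l in srt:
        run += l
        if run >= need:
            return l
    raise AssertionError("unreachable for nonempty input")
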