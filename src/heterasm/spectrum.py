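"""k-mer depth spectrum analysis and genome-size estimation.

A read of length L contributes L-k+1 k-mer instances (fewer when windows
contain N).  The histogram of per-k-mer depths is bimodal for a
heterozygous diploid: allelic k-mers pile up at half the depth of the
homozygous peak.  Genome size is estimated as

    G = K_num / K_depth

where K_num is the total number of counted k-mer instances (error k-mers
excluded by default) and K_depth the depth of the homozygous peak.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Iterable

import numpy as np
from scipy.signal import find_peaks

from .kmers import KmerTable
from .seqio import SeqRecord

# adjacent peak-depth ratio range that flags an allelic half-depth peak
HET_RATIO_RANGE = (0.4, 0.6)


class NoPeakError(RuntimeError):
    """Raised when no usable peak exists above the error trough
    (typically: coverage too low or error-dominated input)."""


@dataclass
class KmerSpectrum:
    """Depth histogram of distinct canonical k-mers.

    ``hist[d]`` is the number of distinct canonical k-mers observed exactly
    d times; ``hist[0]`` is always 0.
    """

    k: int
    hist: np.ndarray

    def __post_init__(self) -> None:
        self.hist = np.asarray(self.hist, dtype=np.int64)
        if self.hist.size == 0:
            self.hist = np.zeros(1, dtype=np.int64)
        if (self.hist < 0).any():
            raise ValueError("negative histogram counts")

    @classmethod
    def from_dict(cls, k: int, d: dict[int, int]) -> "KmerSpectrum":
        if not d:
            return cls(k, np.zeros(1, dtype=np.int64))
        hist = np.zeros(max(d) + 1, dtype=np.int64)
        for depth, count in d.items():
            if depth < 1:
                raise ValueError("histogram depths must be >= 1")
            hist[depth] = count
        return cls(k, hist)

    @property
    def k_num(self) -> int:
        """Total counted k-mer instances: sum over d of d * hist[d]."""
        d = np.arange(self.hist.size, dtype=np.int64)
        return int((d * self.hist).sum())

    def k_num_above(self, trough: int) -> int:
        """Instance count restricted to depths above the error trough."""
        d = np.arange(self.hist.size, dtype=np.int64)
        mask = d > trough
        return int((d[mask] * self.hist[mask]).sum())


@dataclass
class SpectrumPeaks:
    peaks: list[tuple[int, int]]  # (depth, height) ascending depth
    error_trough: int
    heterozygous: bool

    def __post_init__(self) -> None:
        depths = [d for d, _ in self.peaks]
        if depths != sorted(set(depths)):
            raise ValueError("peak depths must be strictly increasing")
        if self.peaks and self.error_trough >= self.peaks[0][0]:
            raise ValueError("error trough must sit below the first peak")


def count_canonical_kmers(seqs: Iterable[SeqRecord | str], k: int) -> KmerSpectrum:
    """Count canonical k-mers over reads and build the depth spectrum.

    Every A/C/G/T-only window of length k contributes one instance of
    min(kmer, revcomp(kmer)); windows with N are skipped.
    """
    if k % 2 == 0 or not (11 <= k <= 31):
        raise ValueError(f"spectrum k must be odd and in [11, 31], got {k}")
    table = KmerTable.from_seqs((s.seq if isinstance(s, SeqRecord) else s for s in seqs), k)
    return KmerSpectrum(k, table.depth_histogram())


def _smooth(hist: np.ndarray, window: int) -> np.ndarray:
    if window <= 1:
        return hist.astype(float)
    kernel = np.ones(window) / window
    # centred moving average; depths outside the histogram hold zero k-mers
    padded = np.pad(hist.astype(float), window // 2, mode="constant")
    return np.convolve(padded, kernel, mode="valid")


def detect_peaks(
    spectrum: KmerSpectrum,
    min_depth: int = 2,
    smooth_window: int = 3,
    peak_min_frac: float = 0.10,
) -> SpectrumPeaks:
    """Locate the error trough and the coverage peaks of a spectrum.

    The histogram is smoothed with a centred moving average; the error
    trough is the first local minimum at depth >= ``min_depth``; peaks are
    local maxima above the trough, kept when at least ``peak_min_frac`` of
    the tallest.  The half-depth (allelic) signature sets ``heterozygous``
    when some adjacent peak pair has a depth ratio in [0.4, 0.6].
    """
    hist = spectrum.hist
    if hist.sum() == 0:
        raise NoPeakError("empty spectrum")
    s = _smooth(hist, smooth_window)

    trough = None
    for d in range(max(1, min_depth), s.size - 1):
        if s[d] <= s[d - 1] and s[d] <= s[d + 1]:
            trough = d
            break
    if trough is None:
        raise NoPeakError("no error trough / peak structure found (monotone spectrum)")

    region = s[trough:]
    # pad so maxima at the array boundary are still reported
    idx, _props = find_peaks(np.concatenate(([-1.0], region, [-1.0])))
    peak_depths = [int(trough + i - 1) for i in idx]
    # snap each smoothed maximum to the raw-histogram mode within +-1 and
    # deduplicate (smoothing can split a sharp mode into twin shoulders)
    snapped: list[int] = []
    for d in peak_depths:
        lo = max(0, d - 1)
        d2 = int(lo + np.argmax(hist[lo : d + 2]))
        if d2 > trough and d2 not in snapped:
            snapped.append(d2)
    peak_depths = sorted(snapped)
    if not peak_depths:
        raise NoPeakError("no peak above the error trough")
    heights = {d: int(hist[d]) for d in peak_depths}
    tallest = max(s[d] for d in peak_depths)
    kept = [d for d in peak_depths if s[d] >= peak_min_frac * tallest]

    het = any(
        HET_RATIO_RANGE[0] <= kept[i] / kept[i + 1] <= HET_RATIO_RANGE[1]
        for i in range(len(kept) - 1)
    )
    return SpectrumPeaks([(d, heights[d]) for d in kept], trough, het)


def estimate_genome_size(
    spectrum: KmerSpectrum,
    peaks: SpectrumPeaks,
    include_errors: bool = False,
) -> float:
    """Genome size G = K_num / K_depth.

    K_depth is the homozygous peak depth: the deepest retained peak when the
    spectrum is heterozygous (the shallower peak is allelic), otherwise the
    tallest peak.  K_num excludes depths at or below the error trough unless
    ``include_errors`` is set.
    """
    if not peaks.peaks:
        raise NoPeakError("no peaks available for genome-size estimation")
    if peaks.heterozygous:
        k_depth = peaks.peaks[-1][0]
    else:
        k_depth = max(peaks.peaks, key=lambda p: p[1])[0]
    k_num = spectrum.k_num if include_errors else spectrum.k_num_above(peaks.error_trough)
    return k_num / k_depth
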