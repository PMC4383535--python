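"""Haplotig purging: per-copy depth, shared k-mer fraction, decisions."""

import numpy as np
import pytest

from helpers import dna, mutate_snps, tile_reads
from heterasm.purge import contig_depths, purge_redundant, shared_kmer_fraction
from heterasm.seqio import SeqRecord
from heterasm.simgen import LibrarySpec, SimConfig, diploidize, sim_genome, sim_paired_reads


class TestContigDepths:
    def test_ten_exact_copies_give_median_ten(self, rng):
        c = SeqRecord("c", dna(rng, 2000))
        profile = contig_depths([c], [c.seq] * 10, k=21)
        assert profile.median_depth["c"] == 10.0

    def test_absent_contig_has_zero_depth(self, rng):
        present = SeqRecord("p", dna(rng, 2000))
        absent = SeqRecord("a", dna(rng, 2000))
        profile = contig_depths([present, absent], [present.seq] * 10, k=21)
        assert profile.median_depth["a"] == 0.0

    def test_short_contig_auto_kept(self, rng):
        c = SeqRecord("c", dna(rng, 2000))
        tiny = SeqRecord("t", "ACGTACGT")
        profile = contig_depths([c, tiny], [c.seq] * 10, k=21)
        assert np.isnan(profile.median_depth["t"])
        kept, decisions = purge_redundant([c, tiny], profile)
        assert {x.id for x in kept} == {"c", "t"}

    def test_allelic_pair_sits_at_half_peak(self):
        """Read-back depth of a haplotig pair shows the half-peak signature."""
        cfg = SimConfig(genome_len=60_000, repeat_frac=0, snp_rate=0.01, indel_rate=0, rng_seed=6)
        rng = np.random.default_rng(6)
        hap1, _ = sim_genome(cfg, rng)
        hap2, _ = diploidize(hap1, 0.01, 0.0, rng)
        lib = LibrarySpec("pe", 300, 30, 100, "FR", 0.0)
        reads = []
        for hap in (hap1, hap2):
            pairs, _ = sim_paired_reads(hap, lib, 25.0, rng)
            reads.extend(r for p in pairs for r in p)
        contigs = [
            SeqRecord("h1", hap1.seq[10_000:40_000]),
            SeqRecord("h2", hap2.seq[10_000:40_000]),
        ]
        profile = contig_depths(contigs, reads, k=21)
        for cid in ("h1", "h2"):
            ratio = profile.median_depth[cid] / profile.homozygous_peak
            assert 0.35 <= ratio <= 0.6


class TestSharedKmerFraction:
    def test_identical_contigs(self, rng):
        s = dna(rng, 5000)
        assert shared_kmer_fraction(s, s, 21) == 1.0

    def test_binomial_expectation_at_1pct(self):
        """Haplotig pairs with independent SNPs at p=0.01 share about
        (1-p)^k of their k-mers."""
        expected = 0.99 ** 21
        for seed in range(5):
            rng = np.random.default_rng(seed)
            a = dna(rng, 20_000)
            b = mutate_snps(a, 0.01, rng)
            assert shared_kmer_fraction(a, b, 21) == pytest.approx(expected, abs=0.05)

    def test_unrelated_near_zero(self, rng):
        assert shared_kmer_fraction(dna(rng, 5000), dna(rng, 5000), 21) < 0.01

    def test_too_short_rejected(self):
        with pytest.raises(ValueError):
            shared_kmer_fraction("ACGT", "ACGTACGTACGTACGTACGTACGTA", 21)


class TestPurge:
    def _diploid_scene(self, seed, snp_rate):
        cfg = SimConfig(genome_len=60_000, repeat_frac=0, snp_rate=snp_rate, indel_rate=0, rng_seed=seed)
        rng = np.random.default_rng(seed)
        hap1, _ = sim_genome(cfg, rng)
        if snp_rate > 0:
            hap2, _ = diploidize(hap1, snp_rate, 0.0, rng)
        else:
            hap2 = SeqRecord("hap2", hap1.seq)
        lib = LibrarySpec("pe", 300, 30, 100, "FR", 0.0)
        reads = []
        for hap in (hap1, hap2):
            pairs, _ = sim_paired_reads(hap, lib, 25.0, rng)
            reads.extend(r for p in pairs for r in p)
        contigs = []
        for i in range(3):
            contigs.append(SeqRecord(f"h1c{i}", hap1.seq[i * 20_000 : (i + 1) * 20_000]))
            contigs.append(SeqRecord(f"h2c{i}", hap2.seq[i * 20_000 + 3 : (i + 1) * 20_000]))
        return contigs, reads

    def _score(self, contigs, decisions):
        removed = {d.contig for d in decisions if d.status == "removed"}
        true_haplotigs = set()
        for i in range(3):
            pair = {f"h1c{i}", f"h2c{i}"}
            # exactly one member of each allelic pair should go
            true_haplotigs |= pair
        tp = len(removed)  # every removal should hit an allelic pair member
        correct_pairs = sum(
            1 for i in range(3) if len({f"h1c{i}", f"h2c{i}"} & removed) == 1
        )
        return removed, correct_pairs

    def test_exact_duplicates_perfect_precision_recall(self):
        contigs, reads = self._diploid_scene(seed=11, snp_rate=0.0)
        profile = contig_depths(contigs, reads, k=21)
        kept, decisions = purge_redundant(contigs, profile)
        removed, correct_pairs = self._score(contigs, decisions)
        assert len(removed) == 3 and correct_pairs == 3  # precision = recall = 1
        assert len(kept) == 3

    def test_1pct_divergence_high_accuracy(self):
        contigs, reads = self._diploid_scene(seed=12, snp_rate=0.01)
        profile = contig_depths(contigs, reads, k=21)
        kept, decisions = purge_redundant(contigs, profile)
        removed, correct_pairs = self._score(contigs, decisions)
        assert correct_pairs >= 3 * 0.9
        assert len(removed) <= 3  # no unique contig sacrificed

    def test_collapsed_repeat_kept_despite_full_sharing(self, rng):
        """A contig at full per-copy peak depth sharing 100% of its k-mers
        (a collapsed repeat) fails the depth condition and stays."""
        u = dna(rng, 30_000)
        r = dna(rng, 2000)
        big = SeqRecord("big", u + r)
        rep = SeqRecord("rep", r)
        # reads: 20x over big's locus plus 20x over an extra copy of r
        reads = tile_reads(u + r, 100, 5) + tile_reads(r, 100, 5)
        profile = contig_depths([big, rep], reads, k=21)
        kept, decisions = purge_redundant([big, rep], profile)
        d = next(x for x in decisions if x.contig == "rep")
        assert d.status == "kept" and d.reason == "high_depth"

    def test_length_conservation(self):
        contigs, reads = self._diploid_scene(seed=13, snp_rate=0.01)
        profile = contig_depths(contigs, reads, k=21)
        kept, decisions = purge_redundant(contigs, profile)
        removed = {d.contig for d in decisions if d.status == "removed"}
        total = sum(len(c) for c in contigs)
        kept_len = sum(len(c) for c in kept)
        removed_len = sum(len(c) for c in contigs if c.id in removed)
        assert kept_len + removed_len == total

    def test_deterministic(self):
        contigs, reads = self._diploid_scene(seed=14, snp_rate=0.01)
        profile = contig_depths(contigs, reads, k=21)
        a = purge_redundant(contigs, profile)
        b = purge_redundant(list(reversed(contigs)), profile)
        assert [c.id for c in a[0]] == sorted((c.id for c in b[0]), key=[c.id for c in a[0]].index)
        assert {d.contig: d.status for d in a[1]} == {d.contig: d.status for d in b[1]}
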