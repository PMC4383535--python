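"""FASTA/FASTQ/PAF/AGP/BED readers and writers, and the flat config."""

import warnings

import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from heterasm.config import PipelineConfig, read_config, sweep_ks, write_config
from heterasm.seqio import (
    AgpComponent,
    FormatError,
    PafRecord,
    SeqRecord,
    read_agp,
    read_bed,
    read_fasta,
    read_fastq_pairs,
    read_paf,
    scaffold_fasta_from_agp,
    write_agp,
    write_bed,
    write_fasta,
    write_fastq,
    write_paf,
)


class TestFasta:
    def test_single_record(self, tmp_path):
        p = tmp_path / "a.fa"
        p.write_text(">a\nACGT\n")
        assert read_fasta(p) == [SeqRecord("a", "ACGT")]

    def test_lowercase_uppercased(self, tmp_path):
        p = tmp_path / "a.fa"
        p.write_text(">a\nacgtn\n")
        assert read_fasta(p)[0].seq == "ACGTN"

    def test_order_preserved(self, tmp_path):
        p = tmp_path / "a.fa"
        p.write_text(">z\nAC\n>a\nGT\n")
        assert [r.id for r in read_fasta(p)] == ["z", "a"]

    @given(
        st.lists(
            st.tuples(
                st.text(alphabet="abcdefgh", min_size=1, max_size=8),
                st.text(alphabet="ACGTN", min_size=1, max_size=200),
            ),
            min_size=0,
            max_size=8,
            unique_by=lambda t: t[0],
        )
    )
    @settings(max_examples=50, deadline=None)
    def test_round_trip_byte_identical(self, tmp_path_factory, records):
        tmp = tmp_path_factory.mktemp("fa")
        recs = [SeqRecord(i, s) for i, s in records]
        p1, p2 = tmp / "x.fa", tmp / "y.fa"
        write_fasta(recs, p1)
        back = read_fasta(p1) if recs else []
        assert back == recs
        write_fasta(back, p2)
        assert p1.read_bytes() == p2.read_bytes()

    def test_empty_sequence_names_line(self, tmp_path):
        p = tmp_path / "bad.fa"
        p.write_text(">a\n>b\nACGT\n")
        with pytest.raises(FormatError, match="line 1"):
            read_fasta(p)

    def test_malformed_header_names_line(self, tmp_path):
        p = tmp_path / "bad.fa"
        p.write_text(">\nACGT\n")
        with pytest.raises(FormatError, match="line 1"):
            read_fasta(p)


class TestFastqPairs:
    def _write(self, path, recs):
        write_fastq(recs, path)

    def test_pairing(self, tmp_path):
        self._write(tmp_path / "r1.fq", [SeqRecord("r1/1", "ACGT"), SeqRecord("r2/1", "GGTT")])
        self._write(tmp_path / "r2.fq", [SeqRecord("r1/2", "TTAA"), SeqRecord("r2/2", "CCAA")])
        pairs = read_fastq_pairs(tmp_path / "r1.fq", tmp_path / "r2.fq")
        assert len(pairs) == 2
        assert pairs[0][0].id == "r1/1" and pairs[0][1].id == "r1/2"

    def test_mismatched_counts(self, tmp_path):
        self._write(tmp_path / "r1.fq", [SeqRecord("a/1", "ACGT")])
        self._write(tmp_path / "r2.fq", [])
        with pytest.raises(FormatError, match="unequal"):
            read_fastq_pairs(tmp_path / "r1.fq", tmp_path / "r2.fq")

    def test_unpaired_id_named(self, tmp_path):
        self._write(tmp_path / "r1.fq", [SeqRecord("a/1", "ACGT")])
        self._write(tmp_path / "r2.fq", [SeqRecord("b/2", "ACGT")])
        with pytest.raises(FormatError, match="a/1"):
            read_fastq_pairs(tmp_path / "r1.fq", tmp_path / "r2.fq")


class TestPaf:
    def test_write_read_round_trip(self, tmp_path):
        rec = PafRecord("q", 1000, 500, 1000, "+", "t", 2000, 0, 500, 498, 500)
        p = tmp_path / "o.paf"
        write_paf([rec], p)
        line = p.read_text().strip().split("\t")
        assert len(line) == 12
        assert int(line[3]) - int(line[2]) == 500  # qend - qstart = span
        assert read_paf(p) == [rec]

    def test_invalid_coordinates_refused(self, tmp_path):
        rec = PafRecord("q", 1000, 900, 800, "+", "t", 2000, 0, 500, 100, 100)
        with pytest.raises(FormatError):
            write_paf([rec], tmp_path / "o.paf")

    def test_empty_record_list(self, tmp_path):
        p = tmp_path / "o.paf"
        write_paf([], p)
        assert p.read_text() == ""


class TestAgp:
    def test_two_contigs_one_gap(self, tmp_path):
        comps = [
            AgpComponent("s1", 1, 300, 1, "W", comp_id="c1", comp_start=1, comp_end=300, orientation="+"),
            AgpComponent("s1", 301, 400, 2, "N", gap_len=100),
            AgpComponent("s1", 401, 600, 3, "W", comp_id="c2", comp_start=1, comp_end=200, orientation="-"),
        ]
        p = tmp_path / "s.agp"
        write_agp(comps, p)
        back = read_agp(p)
        assert len(back) == 3
        assert back == comps
        assert back[-1].obj_end == 600  # scaffold length

    def test_fasta_rebuild_matches(self, tmp_path, rng):
        from helpers import dna
        from heterasm.kmers import revcomp

        c1, c2 = dna(rng, 300), dna(rng, 200)
        comps = [
            AgpComponent("s1", 1, 300, 1, "W", comp_id="c1", comp_start=1, comp_end=300, orientation="+"),
            AgpComponent("s1", 301, 400, 2, "N", gap_len=100),
            AgpComponent("s1", 401, 600, 3, "W", comp_id="c2", comp_start=1, comp_end=200, orientation="-"),
        ]
        out = scaffold_fasta_from_agp(comps, {"c1": c1, "c2": c2})
        assert out[0].seq == c1 + "N" * 100 + revcomp(c2)

    def test_span_mismatch_refused(self, tmp_path):
        bad = AgpComponent("s1", 1, 300, 1, "W", comp_id="c1", comp_start=1, comp_end=200, orientation="+")
        with pytest.raises(FormatError):
            write_agp([bad], tmp_path / "s.agp")


class TestBed:
    def test_round_trip(self, tmp_path):
        ivs = [("c1", 0, 100), ("c2", 50, 80)]
        p = tmp_path / "t.bed"
        write_bed(ivs, p)
        assert read_bed(p) == ivs

    def test_empty_interval_refused(self, tmp_path):
        with pytest.raises(FormatError):
            write_bed([("c1", 10, 10)], tmp_path / "t.bed")


class TestConfig:
    def test_round_trip(self, tmp_path):
        cfg = PipelineConfig(spectrum_k=19, purge_depth_ratio=0.5)
        p = tmp_path / "cfg.txt"
        write_config(cfg, p)
        assert read_config(p) == cfg

    def test_unknown_key_warns(self, tmp_path):
        p = tmp_path / "cfg.txt"
        p.write_text("no_such_knob = 3\nspectrum_k = 19\n")
        with warnings.catch_warnings(record=True) as w:
            warnings.simplefilter("always")
            cfg = read_config(p)
        assert any("no_such_knob" in str(x.message) for x in w)
        assert cfg.spectrum_k == 19
        assert cfg.purge_k == PipelineConfig().purge_k  # missing -> default

    @pytest.mark.parametrize(
        "kw",
        [
            {"spectrum_k": 16},  # even
            {"spectrum_k": 9},  # too small
            {"overlap_min_identity": 1.5},
            {"purge_shared_frac": 0.0},
            {"ksweep_min": 24},
            {"ksweep_step": 3},
        ],
    )
    def test_invalid_values_rejected(self, kw):
        with pytest.raises(ValueError):
            PipelineConfig(**kw)

    def test_sweep_visits_default_odd_range(self):
        assert sweep_ks(PipelineConfig()) == list(range(25, 64, 2))
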