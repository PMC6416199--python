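"""Tests for FASTA I/O, shuffled controls, and synthetic fixtures."""

import gzip
import itertools

import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from strandsym.kmer_core import count_kmers, reverse_complement
from strandsym.sequence_io import (
    FastaParseError,
    GenomeAssembly,
    SequenceRecord,
    generate_mixture,
    generate_symmetric,
    make_control_set,
    read_fasta,
    shuffle_control,
    write_fasta,
)

dna = st.text(alphabet="ACGT", min_size=1, max_size=40)


class TestReadFasta:
    def test_single_record(self, tmp_path):
        p = tmp_path / "x.fasta"
        p.write_text(">x\nacgt\n")
        asm = read_fasta(p)
        assert len(asm.records) == 1
        assert asm.records[0].residues == "ACGT"
        assert asm.gc_content == 0.5

    def test_all_gc(self, tmp_path):
        p = tmp_path / "x.fasta"
        p.write_text(">x\nGGCC\n")
        assert read_fasta(p).gc_content == 1.0

    def test_multi_record_base_counts(self, tmp_path):
        p = tmp_path / "m.fasta"
        p.write_text(">a\nAAA\n>b\nTTT\n")
        asm = read_fasta(p)
        assert len(asm.records) == 2
        counts = asm.base_counts
        assert counts["A"] == 3 and counts["T"] == 3
        assert counts["C"] == counts["G"] == counts["other"] == 0

    def test_gzip_accepted(self, tmp_path):
        p = tmp_path / "x.fasta.gz"
        with gzip.open(p, "wt") as fh:
            fh.write(">x\nACGTN\n")
        asm = read_fasta(p)
        assert asm.records[0].residues == "ACGTN"

    def test_empty_file_rejected(self, tmp_path):
        p = tmp_path / "empty.fasta"
        p.write_text("")
        with pytest.raises(FastaParseError, match="empty"):
            read_fasta(p)

    def test_sequence_before_header_names_line(self, tmp_path):
        p = tmp_path / "bad.fasta"
        p.write_text("ACGT\n>x\nACGT\n")
        with pytest.raises(FastaParseError, match="line 1"):
            read_fasta(p)

    def test_non_iupac_residue_named(self, tmp_path):
        p = tmp_path / "bad.fasta"
        p.write_text(">x\nACGJ\n")
        with pytest.raises(FastaParseError, match="J"):
            read_fasta(p)

    def test_roundtrip(self, tmp_path):
        asm = GenomeAssembly(
            genome_id="g",
            records=[SequenceRecord("a", "ACGT" * 30), SequenceRecord("b", "TTTTN")],
        )
        path = tmp_path / "g.fasta"
        write_fasta(asm, path)
        back = read_fasta(path)
        assert [r.residues for r in back.records] == [r.residues for r in asm.records]


class TestShuffleControl:
    def _asm(self, *seqs):
        return GenomeAssembly(
            genome_id="g",
            records=[SequenceRecord(f"r{i}", s) for i, s in enumerate(seqs)],
        )

    @given(dna, st.integers(0, 2**31 - 1))
    @settings(derandomize=True, max_examples=100)
    def test_multiset_and_length_preserved(self, seq, seed):
        asm = self._asm(seq)
        ctrl = shuffle_control(asm, seed)
        assert len(ctrl.records[0]) == len(seq)
        assert sorted(ctrl.records[0].residues) == sorted(seq)

    def test_determinism(self):
        asm = self._asm("ACGTACGTAAACCCGGGTTT")
        a = shuffle_control(asm, 42)
        b = shuffle_control(asm, 42)
        assert a.records[0].residues == b.records[0].residues

    def test_single_symbol_fixed_point(self):
        asm = self._asm("AAAA")
        assert shuffle_control(asm, 7).records[0].residues == "AAAA"

    def test_per_record_shuffling_keeps_each_chromosome_composition(self):
        asm = self._asm("AAAA", "CCCC")
        ctrl = shuffle_control(asm, 3)
        assert ctrl.records[0].residues == "AAAA"
        assert ctrl.records[1].residues == "CCCC"

    def test_ambiguity_letters_kept(self):
        asm = self._asm("ACGTNNN")
        ctrl = shuffle_control(asm, 5)
        assert sorted(ctrl.records[0].residues) == sorted("ACGTNNN")


class TestMakeControlSet:
    def test_sizes_and_distinctness(self):
        seq = "".join("ACGT"[i % 4] for i in range(400))
        asm = GenomeAssembly(genome_id="g", records=[SequenceRecord("r", seq)])
        cs1 = make_control_set(asm, 1, 0)
        assert cs1.n_controls == 1
        cs30 = make_control_set(asm, 30, 0)
        assert cs30.n_controls == 30
        seqs = {c.records[0].residues for c in cs30.controls}
        assert len(seqs) == 30  # distinct permutations for long sequences

    def test_n_zero_rejected(self):
        asm = GenomeAssembly(genome_id="g", records=[SequenceRecord("r", "ACGT")])
        with pytest.raises(ValueError):
            make_control_set(asm, 0, 0)

    def test_seed_regeneration_identical(self):
        asm = GenomeAssembly(genome_id="g", records=[SequenceRecord("r", "ACGT" * 50)])
        a = make_control_set(asm, 3, 9)
        b = make_control_set(asm, 3, 9)
        for ca, cb in zip(a.controls, b.controls):
            assert ca.records[0].residues == cb.records[0].residues


class TestGenerateSymmetric:
    @pytest.mark.parametrize("core,expected", [("AC", "ACGT"), ("A", "AT")])
    def test_examples(self, core, expected):
        assert generate_symmetric(core).residues == expected

    @given(dna)
    @settings(derandomize=True)
    def test_output_is_its_own_reverse_complement(self, core):
        out = generate_symmetric(core).residues
        assert reverse_complement(out) == out

    def test_every_kmer_matches_its_reverse_complement(self):
        out = generate_symmetric("ACGGTAC").residues
        for k in range(1, min(4, len(out)) + 1):
            t = count_kmers(out, k)
            for w in ["".join(p) for p in itertools.product("ACGT", repeat=k)]:
                assert t.counts.get(w, 0) == t.counts.get(reverse_complement(w), 0)

    def test_ambiguity_rejected(self):
        with pytest.raises(ValueError):
            generate_symmetric("ACN")


class TestGenerateMixture:
    def test_full_symmetry_is_self_reverse_complement(self):
        rec = generate_mixture(1000, 1.0, 0.5, seed=1)
        assert reverse_complement(rec.residues) == rec.residues

    def test_zero_fraction_gc_close_to_target(self):
        rec = generate_mixture(20000, 0.0, 0.7, seed=2)
        gc = sum(rec.residues.count(b) for b in "GC") / len(rec.residues)
        assert abs(gc - 0.7) < 0.02

    def test_determinism_and_length(self):
        a = generate_mixture(500, 0.5, 0.4, seed=3)
        b = generate_mixture(500, 0.5, 0.4, seed=3)
        assert a.residues == b.residues
        assert len(a) == 500

    @pytest.mark.parametrize(
        "kwargs",
        [
            dict(length=1, symmetric_fraction=0.5, gc=0.5, seed=0),
            dict(length=10, symmetric_fraction=1.5, gc=0.5, seed=0),
            dict(length=10, symmetric_fraction=0.5, gc=-0.1, seed=0),
        ],
    )
    def test_invalid_arguments(self, kwargs):
        with pytest.raises(ValueError):
            generate_mixture(**kwargs)
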