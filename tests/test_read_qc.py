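import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from phagescreen.library_design import construct_dna, reverse_complement
from phagescreen.read_qc import (
    Fate,
    QCConfig,
    ReadRecord,
    TranslationError,
    frame_and_constant_check,
    orient_read,
    qc_read,
    quality_filter,
    run_qc,
    translate_variable_region,
)
from phagescreen.synthetic_data import write_fastq


def perfect_read(template, codon_design, variable, read_id="r0", qual=35):
    dna = construct_dna(template, codon_design, variable)
    return ReadRecord(read_id, dna, (qual,) * len(dna))


class TestOrient:
    def test_sense_unchanged(self, loop_template, codon_design):
        read = perfect_read(loop_template, codon_design, "YLTIRLM")
        out = orient_read(read, loop_template)
        assert out.orientation == "sense"
        assert out.bases == read.bases

    def test_antisense_recovered(self, loop_template, codon_design):
        read = perfect_read(loop_template, codon_design, "YLTIRLM")
        flipped = ReadRecord(
            "r1", reverse_complement(read.bases), tuple(reversed(read.quals))
        )
        out = orient_read(flipped, loop_template)
        assert out.orientation == "antisense"
        assert out.bases == read.bases
        assert out.quals == read.quals

    def test_unrelated_sequence_unoriented(self, loop_template):
        read = ReadRecord("r2", "ACGT" * 30, (30,) * 120)
        out = orient_read(read, loop_template)
        assert out.fate is Fate.UNORIENTED

    def test_orientation_idempotent_under_rc(self, side_template, codon_design):
        read = perfect_read(side_template, codon_design, "VIWIDD")
        rc = ReadRecord(
            "r3", reverse_complement(read.bases), tuple(reversed(read.quals))
        )
        assert orient_read(read, side_template).bases == orient_read(
            rc, side_template
        ).bases


class TestQualityFilter:
    def test_clean_read_passes(self):
        assert quality_filter(ReadRecord("r", "ACGT", (30,) * 4)) is Fate.PASSED

    def test_single_low_qual_fails(self):
        read = ReadRecord("r", "ACGTACGT", (40, 40, 20, 40, 40, 40, 40, 40))
        assert quality_filter(read) is Fate.LOW_QUALITY

    def test_boundary_q21_passes(self):
        assert quality_filter(ReadRecord("r", "ACGT", (21,) * 4)) is Fate.PASSED

    def test_n_base_fails_even_at_high_quality(self):
        read = ReadRecord("r", "ACNT", (40,) * 4)
        assert quality_filter(read) is Fate.CONTAINS_N

    def test_negative_threshold_rejected(self):
        with pytest.raises(ValueError):
            quality_filter(ReadRecord("r", "A", (30,)), min_phred=-1)


class TestFrameAndConstant:
    def test_perfect_loop_read(self, loop_template, codon_design):
        read = perfect_read(loop_template, codon_design, "YLTIRLM")
        fate, codons = frame_and_constant_check(read, loop_template)
        assert fate is Fate.PASSED
        assert translate_variable_region(codons) == "YLTIRLM"

    def test_flank_substitution_fails(self, loop_template, codon_design):
        read = perfect_read(loop_template, codon_design, "YLTIRLM")
        i = read.bases.find(loop_template.dna_flank_5p)
        bad = read.bases[:i] + ("C" if read.bases[i] != "C" else "G") + read.bases[i + 1 :]
        fate, _ = frame_and_constant_check(
            ReadRecord("r", bad, read.quals), loop_template
        )
        assert fate is Fate.FLANK_MISMATCH

    def test_truncated_before_3p_flank(self, loop_template, codon_design):
        read = perfect_read(loop_template, codon_design, "YLTIRLM")
        i = read.bases.find(loop_template.dna_flank_5p)
        cut = i + len(loop_template.dna_flank_5p) + 10
        fate, _ = frame_and_constant_check(
            ReadRecord("r", read.bases[:cut], read.quals[:cut]), loop_template
        )
        assert fate is Fate.FLANK_MISMATCH

    def test_side_constant_substitution(self, side_template, codon_design):
        read = perfect_read(side_template, codon_design, "VIWIDD")
        # mutate a constant-region base far from the variable block
        pos = 10
        base = "C" if read.bases[pos] != "C" else "G"
        bad = read.bases[:pos] + base + read.bases[pos + 1 :]
        fate, _ = frame_and_constant_check(
            ReadRecord("r", bad, read.quals), side_template
        )
        assert fate is Fate.CONSTANT_MISMATCH

    def test_side_codons_concatenated(self, side_template, codon_design):
        read = perfect_read(side_template, codon_design, "VIWIDD")
        fate, codons = frame_and_constant_check(read, side_template)
        assert fate is Fate.PASSED
        assert len(codons) == 18
        assert translate_variable_region(codons) == "VIWIDD"

    def test_variable_region_mimicking_flank_still_passes(
        self, loop_template, codon_design
    ):
        # peptide ending in M recreates the ATG+GGT... 5' flank motif
        read = perfect_read(loop_template, codon_design, "SLDGNRM")
        fate, codons = frame_and_constant_check(read, loop_template)
        assert fate is Fate.PASSED
        assert translate_variable_region(codons) == "SLDGNRM"


class TestTranslate:
    def test_standard_code(self):
        assert translate_variable_region("TATCTGACCATTCGTCTGATG") == "YLTIRLM"

    def test_amber_reads_as_gln(self):
        assert translate_variable_region("TAGCTGACCATTCGTCTGATG") == "QLTIRLM"

    def test_hard_stop_fails(self):
        with pytest.raises(TranslationError) as exc:
            translate_variable_region("TAACTGACCATTCGTCTGATG")
        assert exc.value.fate is Fate.IN_FRAME_STOP
        with pytest.raises(TranslationError):
            translate_variable_region("TGACTGACCATTCGTCTGATG")

    def test_frame_error(self):
        with pytest.raises(TranslationError) as exc:
            translate_variable_region("TATCTGACCATTCGTCTGAT")
        assert exc.value.fate is Fate.FRAME_ERROR


class TestRunQC:
    def _write(self, tmp_path, reads, name="reads.fastq"):
        path = tmp_path / name
        write_fastq(reads, path)
        return path

    def test_perfect_reads_full_retention(
        self, tmp_path, loop_template, codon_design
    ):
        reads = [
            perfect_read(loop_template, codon_design, "YLTIRLM", read_id=f"r{i}")
            for i in range(100)
        ]
        path = self._write(tmp_path, reads)
        passed, report = run_qc(path, loop_template)
        assert report.total == 100
        assert report.retention_fraction == 1.0
        assert all(p == "YLTIRLM" for _, p in passed)

    def test_constructed_failure_attribution(
        self, tmp_path, loop_template, codon_design
    ):
        # 80 perfect, 10 with one q20 base, 10 with an in-frame TAA codon
        reads = []
        for i in range(80):
            reads.append(
                perfect_read(loop_template, codon_design, "YLTIRLM", f"ok{i}")
            )
        for i in range(10):
            r = perfect_read(loop_template, codon_design, "YLTIRLM", f"lowq{i}")
            quals = list(r.quals)
            quals[50] = 20
            reads.append(ReadRecord(r.read_id, r.bases, tuple(quals)))
        spans_start = 3 * loop_template.randomized_positions[0]
        for i in range(10):
            r = perfect_read(loop_template, codon_design, "YLTIRLM", f"stop{i}")
            bad = r.bases[:spans_start] + "TAA" + r.bases[spans_start + 3 :]
            reads.append(ReadRecord(r.read_id, bad, r.quals))
        path = self._write(tmp_path, reads)
        passed, report = run_qc(path, loop_template)
        assert report.total == 100
        assert report.retained == 80
        assert report.counts[Fate.LOW_QUALITY.value] == 10
        assert report.counts[Fate.IN_FRAME_STOP.value] == 10

    def test_empty_fastq(self, tmp_path, loop_template):
        path = tmp_path / "empty.fastq"
        path.write_text("")
        passed, report = run_qc(path, loop_template)
        assert passed == []
        assert report.total == 0
        assert report.retention_fraction == 0.0

    def test_gzip_input(self, tmp_path, loop_template, codon_design):
        reads = [perfect_read(loop_template, codon_design, "YLTIRLM")]
        path = tmp_path / "reads.fastq.gz"
        write_fastq(reads, path)
        passed, report = run_qc(path, loop_template)
        assert report.retained == 1

    def test_permutation_stability(self, tmp_path, loop_template, codon_design, rng):
        variables = ["YLTIRLM", "SLDGNRM", "AAAAAAA", "QWERTYD"]
        reads = [
            perfect_read(loop_template, codon_design, v, f"r{i}")
            for i, v in enumerate(variables)
        ]
        p1 = self._write(tmp_path, reads, "a.fastq")
        perm = [reads[i] for i in rng.permutation(len(reads))]
        p2 = self._write(tmp_path, perm, "b.fastq")
        out1, _ = run_qc(p1, loop_template)
        out2, _ = run_qc(p2, loop_template)
        assert dict(out1) == dict(out2)
        assert [r.read_id for r in perm] == [rid for rid, _ in out2]

    def test_malformed_fastq_raises(self, tmp_path, loop_template):
        path = tmp_path / "bad.fastq"
        path.write_text("@r1\nACGT\n+\nII\n")  # qual length mismatch
        with pytest.raises(ValueError):
            run_qc(path, loop_template)


class TestCascadeProperties:
    @given(seed=st.integers(min_value=0, max_value=10_000))
    @settings(max_examples=10, deadline=None)
    def test_zero_error_retention_is_total(self, seed):
        from phagescreen.library_design import builtin_template
        from phagescreen.synthetic_data import SimulationConfig, simulate_naive_library

        tmpl = builtin_template("loop")
        cfg = SimulationConfig(
            n_reads=30, error_rate=0.0, antisense_fraction=0.5, seed=seed
        )
        reads, peptides = simulate_naive_library(tmpl, 30, None, cfg)
        results = [qc_read(r, tmpl) for r in reads]
        assert all(f.fate is Fate.PASSED for f, _ in results)
        assert [p for _, p in results] == peptides
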