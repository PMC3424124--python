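import sys
import textwrap

import numpy as np
import pytest

from metashot.align import (
    AlignmentRecord,
    ReferenceIndex,
    builtin_align,
    invoke_external_aligner,
    read_alignments,
    write_sam,
)
from metashot.simulate import PlainRead


def _revcomp(seq):
    return seq.translate(str.maketrans("ACGT", "TGCA"))[::-1]


def oracle_align(read_seq, catalog, k):
    """Exhaustive mismatch scan over every offset of every record, both strands.

    Independent of the package's seed-table path: returns the best placement
    under the documented tie-break (fewest mismatches, earlier record,
    leftmost position, forward strand first) or None.
    """
    best = None  # (mm, rec_i, pos, strand_flag)
    for rec_i, rec in enumerate(catalog):
        g = np.frombuffer(rec.sequence.encode(), dtype=np.uint8)
        L = len(read_seq)
        if L > len(g) or L == 0:
            continue
        windows = np.lib.stride_tricks.sliding_window_view(g, L)
        for strand_flag, seq in ((0, read_seq), (1, _revcomp(read_seq))):
            r = np.frombuffer(seq.encode(), dtype=np.uint8)
            mm = (windows != r).sum(axis=1)
            # lexicographic min of (mm, pos, strand) within this record/strand
            for pos in np.flatnonzero(mm == mm.min()):
                cand = (int(mm[pos]), rec_i, int(pos), strand_flag)
                if best is None or cand < best:
                    best = cand
                break  # positions ascending: first min position suffices
    if best is None or best[0] > k:
        return None
    return best


def _mutate(seq, positions, rng):
    out = list(seq)
    for p in positions:
        out[p] = rng.choice([b for b in "ACGT" if b != out[p]])
    return "".join(out)


class TestBuiltinAgainstOracle:
    @pytest.mark.parametrize("k", [0, 1, 2, 3])
    def test_planted_and_random_reads(self, tiny_catalog, k):
        rng = np.random.default_rng(100 + k)
        reads = []
        for i in range(60):
            rec = tiny_catalog.records[rng.integers(0, 2)]
            length = 30
            start = int(rng.integers(0, rec.length - length + 1))
            seq = rec.sequence[start : start + length]
            n_mut = int(rng.integers(0, k + 2))  # sometimes exceeds k
            seq = _mutate(seq, rng.choice(length, size=n_mut, replace=False), rng)
            if rng.random() < 0.5:
                seq = _revcomp(seq)
            reads.append(PlainRead(f"p{i}", seq))
        for i in range(20):  # random reads, usually unmappable
            seq = "".join(rng.choice(list("ACGT"), size=30))
            reads.append(PlainRead(f"r{i}", seq))

        got = builtin_align(reads, tiny_catalog, max_mismatches=k)
        for read, aln in zip(reads, got):
            expected = oracle_align(read.sequence, tiny_catalog, k)
            if expected is None:
                assert not aln.mapped, read.read_id
            else:
                mm, rec_i, pos, strand_flag = expected
                assert aln.mapped, read.read_id
                assert aln.record_id == tiny_catalog.records[rec_i].record_id
                assert aln.start == pos
                assert aln.mismatches == mm
                assert aln.strand == ("-" if strand_flag else "+")

    def test_exact_unique_substring_k0(self, tiny_catalog):
        rec = tiny_catalog.records[1]
        read = PlainRead("x", rec.sequence[1000:1040])
        (aln,) = builtin_align([read], tiny_catalog, max_mismatches=0)
        assert aln.mapped and aln.record_id == rec.record_id
        assert aln.start == 1000 and aln.mismatches == 0 and aln.strand == "+"

    def test_single_substitution_found_with_k2(self, tiny_catalog):
        rng = np.random.default_rng(3)
        rec = tiny_catalog.records[0]
        seq = _mutate(rec.sequence[200:240], [17], rng)
        (aln,) = builtin_align([PlainRead("m", seq)], tiny_catalog, max_mismatches=2)
        expected = oracle_align(seq, tiny_catalog, 2)
        assert aln.mapped and aln.mismatches == 1
        assert (aln.start, aln.mismatches) == (expected[2], expected[0])

    def test_absent_read_unmapped_k0(self, tiny_catalog):
        rng = np.random.default_rng(4)
        while True:
            seq = "".join(rng.choice(list("ACGT"), size=40))
            if oracle_align(seq, tiny_catalog, 0) is None:
                break
        (aln,) = builtin_align([PlainRead("z", seq)], tiny_catalog, max_mismatches=0)
        assert not aln.mapped

    def test_reverse_strand_position(self, tiny_catalog):
        rec = tiny_catalog.records[0]
        read = PlainRead("rc", _revcomp(rec.sequence[500:550]))
        (aln,) = builtin_align([read], tiny_catalog, max_mismatches=0)
        assert aln.mapped and aln.strand == "-" and aln.start == 500

    def test_prebuilt_index_reused(self, tiny_catalog):
        idx = ReferenceIndex(tiny_catalog, seed_length=10)
        rec = tiny_catalog.records[0]
        read = PlainRead("i", rec.sequence[100:140])
        (aln,) = builtin_align([read], tiny_catalog, max_mismatches=1, index=idx)
        assert aln.mapped and aln.start == 100

    def test_cardinality(self, tiny_catalog, clean_reads):
        got = builtin_align(clean_reads[:20], tiny_catalog, max_mismatches=1)
        assert len(got) == 20
        assert sum(a.is_primary for a in got) <= 20


class TestSamRoundTrip:
    def test_write_then_read_reproduces_records(self, tiny_catalog, tmp_path):
        rng = np.random.default_rng(8)
        reads = []
        for i in range(30):
            rec = tiny_catalog.records[rng.integers(0, 2)]
            start = int(rng.integers(0, rec.length - 40 + 1))
            seq = rec.sequence[start : start + 40]
            if i % 3 == 0:
                seq = _revcomp(seq)
            reads.append(PlainRead(f"s{i}", seq))
        reads.append(PlainRead("junk", "".join(rng.choice(list("ACGT"), size=40))))
        alignments = builtin_align(reads, tiny_catalog, max_mismatches=0)
        sam = tmp_path / "out.sam"
        write_sam(alignments, reads, tiny_catalog, sam)
        loaded = list(read_alignments(sam))
        assert loaded == alignments


class TestReadAlignments:
    HEADER = "@HD\tVN:1.6\n@SQ\tSN:chr1\tLN:1000\n"

    def _parse(self, tmp_path, body):
        path = tmp_path / "t.sam"
        path.write_text(self.HEADER + textwrap.dedent(body))
        return list(read_alignments(path))

    def test_unmapped_flag(self, tmp_path):
        (rec,) = self._parse(tmp_path, "r1\t4\t*\t0\t0\t*\t*\t0\t0\tACGT\t*\n")
        assert rec.mapped is False and rec.record_id is None

    def test_pos_converted_to_zero_based(self, tmp_path):
        (rec,) = self._parse(tmp_path, "r1\t0\tchr1\t1\t255\t4M\t*\t0\t0\tACGT\t*\tNM:i:2\n")
        assert rec.start == 0 and rec.mismatches == 2 and rec.strand == "+"

    def test_reverse_flag(self, tmp_path):
        (rec,) = self._parse(tmp_path, "r1\t16\tchr1\t11\t255\t4M\t*\t0\t0\tACGT\t*\n")
        assert rec.strand == "-" and rec.start == 10 and rec.mismatches is None

    def test_secondary_excluded(self, tmp_path):
        body = (
            "r1\t0\tchr1\t1\t255\t4M\t*\t0\t0\tACGT\t*\n"
            "r1\t256\tchr1\t51\t255\t4M\t*\t0\t0\tACGT\t*\n"
            "r1\t2048\tchr1\t71\t255\t4M\t*\t0\t0\tACGT\t*\n"
        )
        records = self._parse(tmp_path, body)
        assert len(records) == 1 and records[0].start == 0

    def test_malformed_record_raises(self, tmp_path):
        path = tmp_path / "bad.sam"
        path.write_text(self.HEADER + "r1\tnotaflag\tchr1\tX\t255\n")
        with pytest.raises(ValueError, match="bad.sam"):
            list(read_alignments(path))

    def test_unmapped_record_cannot_carry_position(self):
        with pytest.raises(ValueError):
            AlignmentRecord("r", mapped=False, record_id="chr1", start=5)


class TestExternalAligner:
    def _stub(self, tmp_path, exit_code=0):
        stub = tmp_path / "fake_aligner.py"
        stub.write_text(
            "import sys\n"
            "args = sys.argv[1:]\n"
            f"exit_code = {exit_code}\n"
            "if exit_code:\n"
            "    sys.stderr.write('boom')\n"
            "    sys.exit(exit_code)\n"
            "out = args[2]\n"
            "with open(out, 'w') as fh:\n"
            "    fh.write('@HD\\tVN:1.6\\n@SQ\\tSN:chr1\\tLN:100\\n')\n"
            "    fh.write('r1\\t0\\tchr1\\t1\\t255\\t4M\\t*\\t0\\t0\\tACGT\\t*\\n')\n"
        )
        return stub

    def test_stub_aligner_output_parseable(self, tmp_path):
        stub = self._stub(tmp_path)
        reads = tmp_path / "reads.fa"
        reads.write_text(">r1\nACGT\n")
        out = invoke_external_aligner(
            reads, "idx", tmp_path / "out.sam",
            command_template=f"{sys.executable} {stub} {{index}} {{reads}} {{out}}",
        )
        records = list(read_alignments(out))
        assert records[0].mapped and records[0].record_id == "chr1"

    def test_extra_params_passed_verbatim_and_logged(self, tmp_path, caplog):
        stub = self._stub(tmp_path)
        reads = tmp_path / "reads.fa"
        reads.write_text(">r1\nACGT\n")
        with caplog.at_level("INFO", logger="metashot.align"):
            invoke_external_aligner(
                reads, "idx", tmp_path / "out.sam",
                command_template=f"{sys.executable} {stub} {{index}} {{reads}} {{out}} {{extra}}",
                extra_params="--very-sensitive -p 1",
            )
        assert any("--very-sensitive -p 1" in rec.message for rec in caplog.records)

    def test_missing_executable_actionable_error(self, tmp_path):
        with pytest.raises(RuntimeError, match="no_such_aligner_xyz"):
            invoke_external_aligner(
                tmp_path / "r.fa", "idx", tmp_path / "o.sam",
                command_template="no_such_aligner_xyz {index} {reads} {out}",
            )

    def test_nonzero_exit_propagates_stderr(self, tmp_path):
        stub = self._stub(tmp_path, exit_code=3)
        with pytest.raises(RuntimeError, match="boom"):
            invoke_external_aligner(
                tmp_path / "r.fa", "idx", tmp_path / "o.sam",
                command_template=f"{sys.executable} {stub} {{index}} {{reads}} {{out}}",
            )
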