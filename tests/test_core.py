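import json

import pytest

from virextend import (
    Contig,
    EditEvent,
    ReadSet,
    Region,
    read_fasta,
    read_fastq,
    replay_history,
    revcomp,
    write_fasta,
    write_fastq,
    write_outputs,
)
from virextend.core import SequenceAlphabetError
from virextend.pipeline import IterationLog, Round


class TestFasta:
    def test_minimal_record(self, tmp_path):
        p = tmp_path / "a.fasta"
        p.write_text(">s\nACGT\n")
        assert read_fasta(p) == [Contig("s", "ACGT")]

    def test_lowercase_normalized(self, tmp_path):
        p = tmp_path / "a.fasta"
        p.write_text(">s\nacgt\n")
        assert read_fasta(p)[0].seq == "ACGT"

    def test_wrapped_lines_preserve_length(self, tmp_path):
        # long record wrapped at 70 columns round-trips with exact length
        n = 193_112
        seq = ("ACGT" * (n // 4 + 1))[:n]
        p = tmp_path / "long.fasta"
        p.write_text(">long\n" + "\n".join(seq[i : i + 70] for i in range(0, n, 70)) + "\n")
        (c,) = read_fasta(p)
        assert len(c) == n and c.seq == seq

    def test_roundtrip_byte_identical(self, tmp_path, lin10):
        _, genome, _ = lin10
        p = tmp_path / "g.fasta"
        write_fasta(p, [genome])
        assert read_fasta(p)[0].seq == genome.seq

    def test_empty_file(self, tmp_path):
        p = tmp_path / "e.fasta"
        p.write_text("")
        assert read_fasta(p) == []

    def test_invalid_alphabet_rejected(self):
        with pytest.raises(SequenceAlphabetError):
            Contig("x", "ACGU")


class TestFastq:
    def _write(self, path, records):
        path.write_text("".join(f"@{i}\n{s}\n+\n{'I' * len(s)}\n" for i, s in records))

    def test_single(self, tmp_path):
        p = tmp_path / "r.fastq"
        self._write(p, [("r1", "A" * 150), ("r2", "C" * 150)])
        rs = read_fastq(p)
        assert len(rs) == 2 and rs.read_length == 150

    def test_paired_positional(self, tmp_path):
        p1, p2 = tmp_path / "1.fastq", tmp_path / "2.fastq"
        self._write(p1, [(f"r{i}", "ACGT" * 30) for i in range(10)])
        self._write(p2, [(f"r{i}", "TTTT" * 30) for i in range(10)])
        rs = read_fastq(p1, p2)
        assert len(rs) == 20 and len(rs.mates) == 20
        assert rs.mates["r0/1"] == "r0/2" and rs.mates["r0/2"] == "r0/1"

    def test_pair_count_mismatch(self, tmp_path):
        p1, p2 = tmp_path / "1.fastq", tmp_path / "2.fastq"
        self._write(p1, [("a", "ACGT")])
        self._write(p2, [("a", "ACGT"), ("b", "ACGT")])
        with pytest.raises(ValueError, match="mismatch"):
            read_fastq(p1, p2)

    def test_modal_read_length(self, tmp_path):
        p = tmp_path / "r.fastq"
        self._write(p, [(f"r{i}", "A" * 150) for i in range(9)] + [("r9", "A" * 75)])
        assert read_fastq(p).read_length == 150

    def test_roundtrip(self, tmp_path, lin10):
        _, _, reads = lin10
        p = tmp_path / "rt.fastq.gz"
        write_fastq(p, reads)
        back = read_fastq(p)
        assert back.seqs == reads.seqs and back.ids == reads.ids


class TestReadSetInvariants:
    def test_duplicate_ids_rejected(self):
        with pytest.raises(ValueError, match="unique"):
            ReadSet(["a", "a"], ["ACGT", "ACGT"], [None, None])

    def test_qual_length_mismatch_rejected(self):
        with pytest.raises(ValueError, match="quality"):
            ReadSet(["a"], ["ACGT"], ["II"])


class TestOutputs:
    def test_bed_convention_and_log(self, tmp_path):
        contig = Contig("s", "ACGTACGTAC")
        log = IterationLog()
        for i in range(1, 4):
            log.append(Round(i, "extend", 10, 10, "no_growth_after_trim" if i == 3 else None))
        paths = write_outputs(contig, [Region("s", 2, 5, "suspicious")], log, tmp_path)
        bed = paths["bed"].read_text().splitlines()
        assert bed[1] == "s\t2\t5\tsuspicious"
        parsed = json.loads(paths["log"].read_text())
        assert parsed["schema"] == 1 and len(parsed["rounds"]) == 3

    def test_empty_regions_header_only(self, tmp_path):
        paths = write_outputs(Contig("s", "ACGT"), [], IterationLog([Round(1, "x", 4, 4, "circular")]), tmp_path)
        lines = paths["bed"].read_text().splitlines()
        assert len(lines) == 1 and lines[0].startswith("track")


class TestRegionsAndHistory:
    def test_one_based_report_convention(self):
        # 0-based [25566, 152989) is 1-based inclusive 25567..152989, length 127423
        r = Region("s", 25566, 152989)
        assert r.to_1based() == (25567, 152989)
        assert len(r) == 127_423 == 152_989 - 25_567 + 1

    def test_replay_handcrafted_events(self):
        original = "AAAACCCCGGGGTTTT"
        events = [
            EditEvent("suspicious_split", Region("s", 2, 14), -4, 1),
            EditEvent("extension", None, 4, 2, {"left": "TT", "right": "GG"}),
            EditEvent("end_trim", None, -2, 3, {"trim_bp": 1}),
            EditEvent(
                "base_correction", None, 0, 4,
                {"ops": [{"op": "sub", "pos": 0, "new": "G"}]},
            ),
        ]
        # split -> AACCCCGGGGTT; extend -> TTAACCCCGGGGTTGG;
        # trim 1 each end -> TAACCCCGGGGTTG; sub pos0->G -> GAACCCCGGGGTTG
        assert replay_history(original, events) == "GAACCCCGGGGTTG"

    def test_with_edit_checks_delta(self):
        c = Contig("s", "ACGT")
        with pytest.raises(ValueError, match="delta_bp"):
            c.with_edit("ACG", EditEvent("end_trim", None, -2, 1, {"trim_bp": 1}))

    def test_revcomp(self):
        assert revcomp("ACGTN") == "NACGT"
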