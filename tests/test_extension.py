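import numpy as np
import pytest

from virextend import (
    Contig,
    ExtensionParams,
    ReadSet,
    SimConfig,
    extract_edges,
    local_assemble,
    make_genome,
    merge_extension,
    recruit_reads,
    revcomp,
    simulate_reads,
    trim_and_retry,
)
from virextend.extension import extend_once
from virextend.mapping import ReadMapper


class TestExtractEdges:
    def test_default_edge_arithmetic(self):
        # edge length = read_length * 1.5
        c = Contig("c", "A" * 10000)
        left, right = extract_edges(c, 150)
        assert (left.start, left.end) == (0, 225)
        assert (right.start, right.end) == (9775, 10000)

    def test_short_contig_split_in_halves(self):
        c = Contig("c", "A" * 300)
        left, right = extract_edges(c, 150)
        assert (left.start, left.end) == (0, 150)
        assert (right.start, right.end) == (150, 300)

    def test_unit_edge_factor(self):
        c = Contig("c", "A" * 1000)
        left, right = extract_edges(c, 100, ExtensionParams(edge_factor=1.0))
        assert len(left) == len(right) == 100


class TestRecruit:
    def test_interior_reads_not_recruited(self, lin10):
        _, genome, _ = lin10
        # reads tiling only the unique interior, none within an edge
        interior = [genome.seq[p : p + 150] for p in range(3000, 6000, 50)]
        reads = ReadSet([f"i{k}" for k in range(len(interior))], interior, [None] * len(interior))
        got = recruit_reads(reads, extract_edges(genome, 150), genome)
        assert len(got) == 0

    def test_edge_overlapping_read_and_its_revcomp(self, lin10):
        _, genome, _ = lin10
        read = genome.seq[9800:9950]  # overlaps the right edge
        reads = ReadSet(["fwd", "rev"], [read, revcomp(read)], [None, None])
        got = recruit_reads(reads, extract_edges(genome, 150), genome)
        assert set(got.ids) == {"fwd", "rev"}

    def test_mate_rescued_regardless_of_own_match(self, lin10):
        _, genome, _ = lin10
        edge_read = genome.seq[9800:9950]
        far = "ACGT" * 38  # unrelated mate sequence, no k-mer match
        reads = ReadSet(["a/1", "a/2"], [edge_read, far[:150]], [None, None], {"a/1": "a/2", "a/2": "a/1"})
        got = recruit_reads(reads, extract_edges(genome, 150), genome)
        assert set(got.ids) == {"a/1", "a/2"}


class TestLocalAssemble:
    def test_empty_recruitment_is_identity(self):
        edge = "ACGTACGTACGTACGTACGTACGTACGTACGTACGT"
        assert local_assemble(edge, ReadSet([], [], [])) == [edge]

    def test_error_free_tiling_reads_recover_truth_exactly(self, lin10):
        _, genome, reads = lin10
        # recruit reads near [1000, 3000) and extend the edge rightward
        mapper = ReadMapper(reads)
        idx = mapper.recruit([genome.seq[1000:3000]], min_shared=3)
        recruited = reads.subset(idx)
        edge = genome.seq[1000:1225]
        (ext,) = local_assemble(edge, recruited)
        assert len(ext) > 2000  # reached well beyond the recruitment window
        assert genome.seq[1000 : 1000 + len(ext)] == ext  # exact truth prefix

    def test_noisy_reads_stay_near_truth(self):
        cfg = SimConfig(genome_length=8000, seed=23, error_rate=0.01)
        genome = make_genome(cfg)
        reads = simulate_reads(genome, cfg)
        mapper = ReadMapper(reads)
        recruited = reads.subset(mapper.recruit([genome.seq[2000:4000]], min_shared=3))
        edge = genome.seq[2000:2225]
        (ext,) = local_assemble(edge, recruited)
        import edlib

        d = edlib.align(ext, genome.seq, mode="HW")["editDistance"]
        assert len(ext) > 1000
        assert d / len(ext) <= 0.01  # >= 99% identity vs simulated truth


class TestMerge:
    def test_no_overhangs_no_growth(self, lin10):
        _, genome, _ = lin10
        left, right = extract_edges(genome, 150)
        merged, out = merge_extension(
            genome, genome.seq[left.start : left.end], genome.seq[right.start : right.end], 150
        )
        assert not out.grew and merged.seq == genome.seq

    def test_one_sided_growth_additivity(self, lin10):
        _, genome, _ = lin10
        left, right = extract_edges(genome, 150)
        left_ext = "A" * 500 + genome.seq[left.start : left.end]
        merged, out = merge_extension(genome, left_ext, genome.seq[right.start : right.end], 150)
        assert out.grew and out.left_added_bp == 500 and out.right_added_bp == 0
        assert len(merged) == len(genome) + 500
        assert merged.seq[500:] == genome.seq

    def test_broken_anchor_discarded(self, lin10):
        _, genome, _ = lin10
        left, right = extract_edges(genome, 150)
        bogus = "G" * 300  # does not contain the left edge
        merged, out = merge_extension(genome, bogus, genome.seq[right.start : right.end], 150)
        assert not out.grew and merged.seq == genome.seq


class TestTrimAndRetry:
    def test_scrambled_end_cleared_by_trimming(self):
        # a simulated misjoin at the right end blocks extension; trimming
        # 300 bp clears it and both ends then regrow past the trim cost
        cfg = SimConfig(genome_length=12000, seed=31, error_rate=0.0)
        genome = make_genome(cfg)
        reads = simulate_reads(genome, cfg)
        rng = np.random.default_rng(5)
        junk = "".join("ACGT"[i] for i in rng.integers(0, 4, 250))
        contig = Contig("misjoin", genome.seq[3000:8750] + junk)
        plain, out0 = extend_once(contig, reads, 150)
        assert not out0.grew or out0.right_added_bp == 0  # right side is blocked
        fixed, out = trim_and_retry(contig, reads, 150)
        assert out.grew and out.trimmed_bp_applied >= 300
        assert len(fixed) > len(contig)

    def test_complete_genome_cannot_repay_trim(self, lin10):
        _, genome, reads = lin10
        result, out = trim_and_retry(genome, reads, 150)
        assert not out.grew and result.seq == genome.seq

    def test_empty_schedule_fails_immediately(self, lin10):
        _, genome, reads = lin10
        _, out = trim_and_retry(genome, reads, 150, ExtensionParams(trim_schedule=()))
        assert not out.grew


class TestInvariants:
    def test_interior_preserved_and_deterministic(self, lin10):
        _, genome, reads = lin10
        frag = Contig("frag", genome.seq[2000:7000])
        a, out_a = extend_once(frag, reads, 150)
        b, out_b = extend_once(frag, reads, 150)
        assert out_a.grew
        assert a.seq == b.seq  # identical inputs -> identical outputs
        assert frag.seq in a.seq  # original interior untouched
        # growth matches the simulated truth on both sides
        start = a.seq.find(frag.seq)
        assert genome.seq[2000 - start : 2000 - start + len(a)] == a.seq
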