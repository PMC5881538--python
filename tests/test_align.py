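"""The k-mer index, linear aligner (with a brute-force oracle), SAM ingestion
and the region/chromosome tallies."""

import dataclasses

import numpy as np
import pytest

import circprofiler as cp
from circprofiler import align, qc
from circprofiler.sim import revcomp


def record(seq, rid="r1"):
    return qc.ReadRecord(rid, seq, [35] * len(seq))


class TestKmerIndex:
    def test_self_lookup(self, small_bundle, small_index):
        seq = small_bundle.chroms["chr1"]
        k = small_index.k
        for pos in (0, 100, 5000):
            hits = small_index.lookup(seq[pos : pos + k])
            assert ("chr1", pos, "+") in hits

    def test_absent_kmer_empty(self, small_index):
        assert small_index.lookup("Q" * small_index.k) == []

    def test_palindromic_kmer_hits_both_strands(self):
        # reverse-complement-equal 8-mer embedded in a toy genome
        pal = "ACGTACGT"
        assert revcomp(pal) == pal
        bundle = cp.GenomeBundle(chroms={"c": "TTTT" + pal + "TTTT"}, genes=[])
        index = align.build_index(bundle, k=8)
        hits = index.lookup(pal)
        assert ("c", 4, "+") in hits and ("c", 4, "-") in hits

    def test_k_too_small_rejected(self):
        with pytest.raises(ValueError, match="k"):
            align.KmerIndex(k=4)


class TestAlignLinear:
    def test_exact_exonic_read_single_block(self, small_bundle, small_index):
        gene = next(g for g in small_bundle.genes if g.strand == "+")
        s, e = gene.exons[0]
        seq = small_bundle.chroms[gene.chrom][s : s + 50]
        mapped, unmapped = align.align_linear([record(seq)], small_index, small_bundle)
        assert unmapped == []
        aln = mapped[0]
        assert aln.blocks == [(s, s + 50)] and aln.mismatches == 0
        assert aln.strand == "+" and aln.chrom == gene.chrom

    def test_junction_read_two_blocks_abut_intron(self, small_bundle, small_index):
        gene = next(g for g in small_bundle.genes if g.strand == "+" and len(g.exons) >= 2)
        (s1, e1), (s2, e2) = gene.exons[0], gene.exons[1]
        chrom = small_bundle.chroms[gene.chrom]
        seq = chrom[e1 - 30 : e1] + chrom[s2 : s2 + 30]
        mapped, unmapped = align.align_linear([record(seq)], small_index, small_bundle)
        assert unmapped == []
        assert mapped[0].blocks == [(e1 - 30, e1), (s2, s2 + 30)]

    def test_minus_strand_read_maps_reverse(self, small_bundle, small_index):
        gene = next(g for g in small_bundle.genes if g.strand == "-")
        s, e = gene.exons[0]
        seq = revcomp(small_bundle.chroms[gene.chrom][s : s + 50])
        mapped, _ = align.align_linear([record(seq)], small_index, small_bundle)
        assert mapped[0].strand == "-"
        assert mapped[0].blocks == [(s, s + 50)]

    def test_backsplice_read_lands_unmapped(self, standard_run):
        """Junction-spanning reads have their halves in reversed genomic order
        and therefore admit no monotone full-length alignment."""
        junction_ids = {
            rid for rid, _, _ in standard_run["sim_reads"].reads if ":circ:" in rid
        }
        unmapped_ids = {r.read_id for r in standard_run["unmapped"]}
        assert junction_ids <= unmapped_ids
        mapped_ids = {a.read_id for a in standard_run["mapped"]}
        assert not (junction_ids & mapped_ids)

    def test_partition_every_read_mapped_or_unmapped(self, standard_run):
        n = len(standard_run["kept"])
        assert len(standard_run["mapped"]) + len(standard_run["unmapped"]) == n
        assert not (
            {a.read_id for a in standard_run["mapped"]}
            & {r.read_id for r in standard_run["unmapped"]}
        )


def brute_force_mapped(seq, bundle, max_mm):
    """Oracle: scan every genomic placement (both strands), contiguous or
    split at one annotated intron."""
    L = len(seq)
    introns = set()
    for g in bundle.genes:
        for iv in g.introns():
            introns.add((g.chrom, iv))
    for query in (seq, revcomp(seq)):
        for chrom, genome in bundle.chroms.items():
            for gstart in range(len(genome) - L + 1):
                if sum(a != b for a, b in zip(query, genome[gstart : gstart + L])) <= max_mm:
                    return True
            for (c, (istart, iend)) in introns:
                if c != chrom:
                    continue
                for b in range(1, L):
                    gstart = istart - b
                    if gstart < 0 or iend + L - b > len(genome):
                        continue
                    mm = sum(a != x for a, x in zip(query[:b], genome[gstart:istart]))
                    mm += sum(a != x for a, x in zip(query[b:], genome[iend : iend + L - b]))
                    if mm <= max_mm:
                        return True
    return False


class TestOracleEquivalence:
    def test_verdicts_match_brute_force_on_tiny_genome(self):
        cfg = dataclasses.replace(
            cp.SimConfig(), n_genes=3, n_chromosomes=1, chrom_length=18_000,
            exons_per_gene=(3, 4), intron_length=(200, 400), circ_fraction=1.0,
            linear_depth=15, n_noise_reads=10, read_length=60,
        )
        bundle = cp.generate_genome(cfg)
        circles = cp.simulate_circles(bundle, cfg)
        reads = [
            qc.ReadRecord(rid, s, [35] * len(s))
            for rid, s, _ in cp.simulate_reads(bundle, circles, cfg).reads
        ][:150]
        index = align.build_index(bundle)
        mapped, unmapped = align.align_linear(reads, index, bundle, max_mismatches=0)
        verdict = {a.read_id: True for a in mapped}
        verdict.update({r.read_id: False for r in unmapped})
        for r in reads:
            assert verdict[r.read_id] == brute_force_mapped(r.sequence, bundle, 0), r.read_id


SAM_TEXT = """\
@HD\tVN:1.6
@SQ\tSN:chr1\tLN:10000
full\t0\tchr1\t101\t60\t100M\t*\t0\t0\t{full_seq}\t*\tNM:i:0
split\t0\tchr1\t201\t60\t50M50S\t*\t0\t0\t{split_seq}\t*\tNM:i:0
split\t2048\tchr1\t501\t60\t50S50M\t*\t0\t0\t{split_seq}\t*\tNM:i:0
lost\t4\t*\t0\t0\t*\t*\t0\t0\t{lost_seq}\t*
"""


class TestIngestSam:
    def test_cigar_routing(self, tmp_path):
        sam = tmp_path / "toy.sam"
        sam.write_text(
            SAM_TEXT.format(full_seq="A" * 100, split_seq="C" * 100, lost_seq="G" * 80)
        )
        linear, segments, unmapped, report = align.ingest_sam(sam)
        # 100M primary -> one LinearAlignment with a single 100-nt block
        assert len(linear) == 1
        assert linear[0].blocks == [(100, 200)] and linear[0].aligned_length == 100
        # 50M50S primary + 50S50M supplementary -> two SegmentMatches
        segs = segments["split"]
        assert len(segs) == 2
        assert (segs[0].read_start, segs[0].read_end, segs[0].g_start) == (0, 50, 200)
        assert (segs[1].read_start, segs[1].read_end, segs[1].g_start) == (50, 100, 500)
        # flag-4 record -> unmapped pool
        assert [r.read_id for r in unmapped] == ["lost"]
        assert report.n_linear == 1 and report.n_segments == 2 and report.n_unmapped == 1

    def test_agrees_with_builtin_segments_on_simulated_reads(
        self, standard_run, tmp_path
    ):
        """A SAM file encoding the simulator's truth yields the same segment
        read intervals as the built-in discovery."""
        run = standard_run
        junc = [r for r in run["unmapped"] if ":circ:" in r.read_id][:20]
        internal = align.segments_by_read(junc, run["index"], run["bundle"])
        lines = ["@HD\tVN:1.6"]
        for chrom, seq in run["bundle"].chroms.items():
            lines.append(f"@SQ\tSN:{chrom}\tLN:{len(seq)}")
        for r in junc:
            for seg in internal[r.read_id]:
                n_m = seg.read_end - seg.read_start
                if seg.strand == "+":
                    pre, post = seg.read_start, len(r.sequence) - seg.read_end
                    seq_out = r.sequence
                    flag = 0
                else:
                    pre = len(r.sequence) - seg.read_end
                    post = seg.read_start
                    seq_out = revcomp(r.sequence)
                    flag = 16
                cigar = (f"{pre}S" if pre else "") + f"{n_m}M" + (f"{post}S" if post else "")
                lines.append(
                    f"{r.read_id}\t{flag}\t{seg.chrom}\t{seg.g_start + 1}\t60\t{cigar}"
                    f"\t*\t0\t0\t{seq_out}\t*\tNM:i:0"
                )
        sam = tmp_path / "segs.sam"
        sam.write_text("\n".join(lines) + "\n")
        _, ingested, _, _ = align.ingest_sam(sam)
        for r in junc:
            got = {
                (s.read_start, s.read_end, s.chrom, s.strand, s.g_start, s.g_end)
                for s in ingested[r.read_id]
            }
            want = {
                (s.read_start, s.read_end, s.chrom, s.strand, s.g_start, s.g_end)
                for s in internal[r.read_id]
            }
            assert got == want


class TestRegionAndChromosomeTallies:
    def test_internal_exon_read_far_from_ends_is_exon(self, small_bundle):
        window = 1000
        for gene in small_bundle.genes:
            for s, e in gene.exons[1:-1]:
                if e - s < 40:
                    continue
                if min(abs(s - gene.tx_start), abs(s - gene.tx_end)) <= window + 50:
                    continue
                aln = align.LinearAlignment(
                    "r", gene.chrom, gene.strand, [(s + 5, s + 35)], 0
                )
                tally = align.annotate_regions([aln], small_bundle)
                assert tally["exon"] == 1
                return
        pytest.skip("no internal exon far from transcript ends in this genome")

    def test_tss_window_priority(self, small_bundle):
        gene = next(g for g in small_bundle.genes if g.strand == "+")
        t = gene.tx_start
        aln = align.LinearAlignment("r", gene.chrom, "+", [(t, t + 30)], 0)
        tally = align.annotate_regions([aln], small_bundle)
        assert tally["TSS"] == 1

    def test_partition_sums_to_alignment_count(self, standard_run):
        tally = align.annotate_regions(standard_run["mapped"], standard_run["bundle"])
        assert sum(tally.values()) == len(standard_run["mapped"])

    def test_chromosome_tally_conservation_and_order_invariance(self):
        rng = np.random.default_rng(1)
        alns = [
            align.LinearAlignment(f"r{i}", f"chr{rng.integers(1, 4)}", "+", [(0, 10)], 0)
            for i in range(30)
        ]
        t1 = align.chromosome_tally(alns)
        t2 = align.chromosome_tally(alns[::-1])
        assert t1 == t2 and sum(t1.values()) == 30
        assert align.chromosome_tally([]) == {}

    def test_all_on_one_chromosome(self):
        alns = [align.LinearAlignment(f"r{i}", "chr1", "+", [(0, 5)], 0) for i in range(10)]
        assert align.chromosome_tally(alns) == {"chr1": 10}
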