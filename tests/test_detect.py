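"""Backsplice detection: the reverse-order pairing rules (with a brute-force
oracle), splice-site scoring, junction refinement, calling thresholds and the
known/novel comparison."""

import dataclasses

import numpy as np
import pytest

import circprofiler as cp
from circprofiler import align, detect, qc
from circprofiler.align import SegmentMatch


def seg(rid, rs, re, chrom, strand, gs, ge):
    return SegmentMatch(
        read_id=rid, read_start=rs, read_end=re, chrom=chrom, strand=strand,
        g_start=gs, g_end=ge, score=re - rs,
    )


class TestFindSegmentPairs:
    READ = {"r": "A" * 100}

    def pairs(self, segments, **kw):
        return detect.find_segment_pairs({"r": segments}, self.READ, **kw)

    def test_reverse_order_pair_is_candidate(self):
        out = self.pairs(
            [seg("r", 0, 50, "chr1", "+", 5000, 5050),
             seg("r", 50, 100, "chr1", "+", 1000, 1050)]
        )
        assert len(out) == 1
        cand = out[0]
        assert (cand.acceptor_pos, cand.donor_end) == (1000, 5050)
        assert cand.strand == "+" and cand.supporting_read_ids == {"r"}

    def test_different_chromosomes_rejected(self):
        out = self.pairs(
            [seg("r", 0, 50, "chr1", "+", 5000, 5050),
             seg("r", 50, 100, "chr2", "+", 1000, 1050)]
        )
        assert out == []

    def test_span_over_one_megabase_rejected(self):
        out = self.pairs(
            [seg("r", 0, 50, "chr1", "+", 2_000_000, 2_000_050),
             seg("r", 50, 100, "chr1", "+", 0, 50)]
        )
        assert out == []

    def test_forward_order_is_ordinary_splice_not_candidate(self):
        out = self.pairs(
            [seg("r", 0, 50, "chr1", "+", 1000, 1050),
             seg("r", 50, 100, "chr1", "+", 5000, 5050)]
        )
        assert out == []

    def test_opposite_strands_rejected(self):
        out = self.pairs(
            [seg("r", 0, 50, "chr1", "+", 5000, 5050),
             seg("r", 50, 100, "chr1", "-", 1000, 1050)]
        )
        assert out == []

    def test_minus_strand_mirrored_geometry(self):
        # read-earlier segment genomically upstream on '-' means reverse order
        out = self.pairs(
            [seg("r", 0, 50, "chr1", "-", 1000, 1050),
             seg("r", 50, 100, "chr1", "-", 5000, 5050)]
        )
        assert len(out) == 1
        assert (out[0].acceptor_pos, out[0].donor_end) == (1000, 5050)
        assert out[0].strand == "-"

    def test_matches_brute_force_on_random_configurations(self):
        """1000 random two-segment configurations against a direct encoding
        of the rules: same chromosome, same strand, reverse order, <= 1 Mb."""
        rng = np.random.default_rng(42)
        n_agree = 0
        for _ in range(1000):
            chrom_a = f"chr{rng.integers(1, 3)}"
            chrom_b = f"chr{rng.integers(1, 3)}"
            strand_a = "+-"[rng.integers(2)]
            strand_b = "+-"[rng.integers(2)]
            split = int(rng.integers(20, 81))
            ga = int(rng.integers(0, 2_000_000))
            gb = int(rng.integers(0, 2_000_000))
            a = seg("r", 0, split, chrom_a, strand_a, ga, ga + split)
            b = seg("r", split, 100, chrom_b, strand_b, gb, gb + (100 - split))
            got = detect.find_segment_pairs({"r": [a, b]}, self.READ)
            # oracle
            expect = None
            if chrom_a == chrom_b and strand_a == strand_b:
                if strand_a == "+" and b.g_end <= a.g_start and a.g_end - b.g_start <= 1_000_000:
                    expect = (b.g_start, a.g_end)
                if strand_a == "-" and a.g_end <= b.g_start and b.g_end - a.g_start <= 1_000_000:
                    expect = (a.g_start, b.g_end)
            if expect is None:
                n_agree += got == []
            else:
                n_agree += (
                    len(got) == 1
                    and (got[0].acceptor_pos, got[0].donor_end) == expect
                )
        assert n_agree == 1000

    def test_overlap_trimmed_onto_later_segment(self):
        # 4-base read-interval overlap: acceptor advances by 4
        out = self.pairs(
            [seg("r", 0, 54, "chr1", "+", 4996, 5050),
             seg("r", 50, 100, "chr1", "+", 1000, 1050)]
        )
        assert (out[0].acceptor_pos, out[0].donor_end) == (1004, 5050)


class TestSpliceScorer:
    def make_scorer(self, donor_col0=None):
        donor = np.full((9, 4), 0.25)
        acceptor = np.full((23, 4), 0.25)
        if donor_col0 is not None:
            donor[0] = donor_col0
        return detect.SpliceScorer(donor, acceptor)

    def test_background_window_scores_zero(self):
        scorer = self.make_scorer()
        assert scorer.donor_score("ACGTACGTA") == pytest.approx(0.0)
        assert scorer.acceptor_score("ACGT" * 5 + "ACG") == pytest.approx(0.0)

    def test_hand_computed_log_odds(self):
        # P(A at pos 1) = 0.5 against uniform background: log2(0.5/0.25) = 1
        scorer = self.make_scorer(donor_col0=[0.5, 1 / 6, 1 / 6, 1 / 6])
        assert scorer.donor_score("ACGTACGTA") == pytest.approx(1.0)
        # a non-consensus base at that position: log2((1/6)/(1/4)) = -0.585
        assert scorer.donor_score("CCGTACGTA") == pytest.approx(
            np.log2((1 / 6) / 0.25)
        )

    def test_n_in_window_scores_minus_infinity(self):
        scorer = self.make_scorer()
        d, a = detect.score_splice_sites(scorer, "ACGNACGTA", "A" * 23)
        assert d == float("-inf") and a == pytest.approx(0.0)

    def test_wrong_window_length_rejected(self):
        scorer = self.make_scorer()
        with pytest.raises(ValueError, match="length"):
            scorer.donor_score("ACGT")

    def test_canonical_gt_beats_mutated_aa(self, standard_run):
        """Under the annotation-trained model, a true donor window scores
        strictly higher than the same window with GT mutated to AA."""
        scorer = standard_run["scorer"]
        bundle = standard_run["bundle"]
        gene = next(g for g in bundle.genes if g.strand == "+" and len(g.exons) > 1)
        istart, _ = gene.introns()[0]
        window = bundle.chroms[gene.chrom][istart - 3 : istart + 6]
        assert window[3:5] == "GT"
        mutated = window[:3] + "AA" + window[5:]
        assert scorer.donor_score(window) > scorer.donor_score(mutated)

    def test_column_normalization_enforced(self):
        bad = np.full((9, 4), 0.3)
        with pytest.raises(ValueError, match="sum"):
            detect.SpliceScorer(bad, np.full((23, 4), 0.25))

    def test_tsv_round_trip(self, standard_run, tmp_path):
        scorer = standard_run["scorer"]
        scorer.to_tsv(tmp_path / "pwm.tsv")
        again = detect.SpliceScorer.from_tsv(tmp_path / "pwm.tsv")
        win = "CAGGTAAGT"
        assert again.donor_score(win) == pytest.approx(
            scorer.donor_score(win), abs=1e-6
        )


class TestRefineJunction:
    def test_true_junction_unchanged_at_shift_zero(self, standard_run):
        bundle, scorer = standard_run["bundle"], standard_run["scorer"]
        circ = standard_run["circles"][0]
        cand = detect.JunctionCandidate(
            chrom=circ.chrom, strand=circ.strand,
            acceptor_pos=circ.start, donor_end=circ.end,
        )
        refined = detect.refine_junction(cand, bundle, scorer)
        assert (refined.acceptor_pos, refined.donor_end) == (circ.start, circ.end)
        assert refined.splice_score >= 10

    def test_offset_candidate_recentered_on_true_site(self, standard_run):
        bundle, scorer = standard_run["bundle"], standard_run["scorer"]
        circ = standard_run["circles"][0]
        cand = detect.JunctionCandidate(
            chrom=circ.chrom, strand=circ.strand,
            acceptor_pos=circ.start + 3, donor_end=circ.end + 3,
        )
        refined = detect.refine_junction(cand, bundle, scorer)
        assert (refined.acceptor_pos, refined.donor_end) == (circ.start, circ.end)

    def test_tie_goes_to_smaller_acceptor(self):
        # a uniform scorer makes every shift score 0: the smallest consistent
        # acceptor position must win
        bundle = cp.GenomeBundle(chroms={"c": "ACGT" * 300}, genes=[])
        scorer = detect.SpliceScorer(np.full((9, 4), 0.25), np.full((23, 4), 0.25))
        cand = detect.JunctionCandidate(
            chrom="c", strand="+", acceptor_pos=100, donor_end=500
        )
        refined = detect.refine_junction(cand, bundle, scorer, shift_window=10)
        assert refined.acceptor_pos == 90
        assert refined.splice_score == pytest.approx(0.0)


class TestCallThresholds:
    def make_refined(self, bundle, rid, score, start=1000, end=2000):
        return detect.JunctionCandidate(
            chrom="chr1", strand="+", acceptor_pos=start, donor_end=end,
            supporting_read_ids={rid}, splice_score=score,
        )

    def test_single_read_never_called(self, small_bundle):
        refined = [self.make_refined(small_bundle, "r1", 15.0)]
        assert detect.call_circRNAs(refined, small_bundle) == []

    def test_two_reads_at_score_threshold_called(self, small_bundle):
        refined = [self.make_refined(small_bundle, r, 10.0) for r in ("r1", "r2")]
        calls = detect.call_circRNAs(refined, small_bundle, min_score=10.0)
        assert len(calls) == 1 and calls[0].n_backspliced_reads == 2

    def test_score_below_threshold_never_called(self, small_bundle):
        refined = [self.make_refined(small_bundle, f"r{i}", 9.9) for i in range(5)]
        assert detect.call_circRNAs(refined, small_bundle, min_score=10.0) == []

    def test_randomized_threshold_behaviour(self, small_bundle):
        """Over 100 random junctions: one supporting read is never enough;
        two reads with the score exactly at threshold always call."""
        rng = np.random.default_rng(7)
        chrom_len = len(small_bundle.chroms["chr1"])
        for _ in range(100):
            start = int(rng.integers(100, chrom_len - 5000))
            end = start + int(rng.integers(200, 4000))
            score = float(rng.uniform(10, 40))
            one = [self.make_refined(small_bundle, "a", score, start, end)]
            assert detect.call_circRNAs(one, small_bundle, min_score=10.0) == []
            two = one + [self.make_refined(small_bundle, "b", score, start, end)]
            at_threshold = [
                dataclasses.replace(c, splice_score=10.0, supporting_read_ids=set(c.supporting_read_ids))
                for c in two
            ]
            calls = detect.call_circRNAs(at_threshold, small_bundle, min_score=10.0)
            assert len(calls) == 1

    def test_monotone_in_min_reads_and_min_score(self, standard_run):
        run = standard_run
        segs = align.segments_by_read(run["unmapped"], run["index"], run["bundle"])
        read_seqs = {r.read_id: r.sequence for r in run["unmapped"]}
        raw = detect.find_segment_pairs(segs, read_seqs)
        raw += detect.rescue_short_overhangs(segs, read_seqs, run["bundle"])
        refined = [
            r for r in (
                detect.refine_junction(c, run["bundle"], run["scorer"]) for c in raw
            ) if r is not None
        ]
        last = None
        for min_reads in (2, 5, 10, 20):
            n = len(detect.call_circRNAs(refined, run["bundle"], min_reads=min_reads))
            if last is not None:
                assert n <= last
            last = n
        last = None
        for min_score in (0.0, 10.0, 25.0, 40.0):
            n = len(
                detect.call_circRNAs(refined, run["bundle"], min_score=min_score)
            )
            if last is not None:
                assert n <= last
            last = n


class TestRecoveryAndSpecificity:
    def test_truth_junctions_recovered_exactly(self, standard_run):
        truth = {
            (c.chrom, c.strand, c.start, c.end) for c in standard_run["circles"]
        }
        called = {
            (c.chrom, c.strand, c.start, c.end) for c in standard_run["calls"]
        }
        assert called == truth

    def test_zero_circles_zero_calls_small(self):
        cfg = dataclasses.replace(
            cp.SimConfig(), n_genes=12, n_chromosomes=2, chrom_length=60_000,
            circ_fraction=0.0, linear_depth=40, n_noise_reads=200,
        )
        bundle = cp.generate_genome(cfg)
        reads = [
            qc.ReadRecord(rid, s, [ord(c) - 33 for c in q])
            for rid, s, q in cp.simulate_reads(bundle, [], cfg).reads
        ]
        kept, _ = qc.filter_reads(reads, qc.QcParams())
        index = align.build_index(bundle)
        _, unmapped = align.align_linear(kept, index, bundle, max_mismatches=0)
        assert detect.detect_circRNAs(unmapped, index, bundle) == []


class TestCompareToKnown:
    def bed(self, tmp_path, lines):
        p = tmp_path / "known.bed"
        p.write_text("".join(lines))
        return p

    def call(self, start, end):
        return detect.CircCall(
            circ_id="c", chrom="chr1", strand="+", start=start, end=end,
            n_backspliced_reads=3, splice_score=20.0, host_genes=[],
            exonic_length=end - start,
        )

    def test_exact_match_is_known(self, tmp_path):
        bed = self.bed(tmp_path, ["chr1\t100\t900\tk1\t0\t+\n"])
        calls = [self.call(100, 900)]
        summary = detect.compare_to_known(calls, bed)
        assert calls[0].novelty == "known" and summary == {"known": 1, "novel": 0}

    def test_off_by_one_is_novel(self, tmp_path):
        bed = self.bed(tmp_path, ["chr1\t100\t900\tk1\t0\t+\n"])
        calls = [self.call(101, 900)]
        detect.compare_to_known(calls, bed)
        assert calls[0].novelty == "novel"

    def test_empty_known_set_all_novel(self):
        calls = [self.call(1, 2), self.call(5, 9)]
        summary = detect.compare_to_known(calls, set())
        assert summary == {"known": 0, "novel": 2}

    def test_malformed_bed_reports_line_number(self, tmp_path):
        bed = self.bed(tmp_path, ["chr1\t100\t900\tk1\t0\t+\n", "chr1\tbroken\n"])
        with pytest.raises(ValueError, match="line 2"):
            detect.read_bed_junctions(bed)
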