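"""Backsplice (head-to-tail) junction detection and circRNA calling.

Unmapped reads are decomposed into local segment matches; a pair of segments
from one read that maps to the same chromosome and strand, no more than 1 Mb
apart, but in *reverse* genomic order is a candidate head-to-tail junction.
Candidate coordinates are refined by sliding the junction jointly over the
repeat-induced ambiguity window and picking the placement with the strongest
splice-site score (donor + acceptor, log2-odds under a position-weight-matrix
model).  Junctions supported by at least two distinct reads with a splicing
score >= 10 are reported as circRNA calls.

Coordinate convention: ``acceptor_pos`` is the 0-based genomic start of the
circle and ``donor_end`` its exclusive genomic end, for either strand; on '-'
the biological donor site sits at the genomic start and the acceptor at the
genomic end, and splice windows are extracted reverse-complemented.
"""

from __future__ import annotations

from collections import defaultdict
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Mapping, Sequence

import numpy as np

from .align import MIN_SEGMENT_LENGTH, SegmentMatch
from .sim import (
    ACCEPTOR_EXONIC,
    ACCEPTOR_INTRONIC,
    BASES,
    DONOR_EXONIC,
    DONOR_INTRONIC,
    GenomeBundle,
    revcomp,
)

MAX_SPAN = 1_000_000
DEFAULT_MIN_READS = 2
DEFAULT_MIN_SCORE = 10.0
NEG_INF = float("-inf")


# ---------------------------------------------------------------------------
# Splice-site scoring
# ---------------------------------------------------------------------------


class SpliceScorer:
    """Position-weight-matrix splice-site scorer.

    Donor model: 9-nt window (3 exonic + 6 intronic bases, gene-strand
    orientation); acceptor model: 23-nt window (20 intronic + 3 exonic).
    A window scores the sum over positions of log2(P_model / P_background);
    a window distributed like the background scores 0.  Windows containing N
    score -inf (site unusable).

    The default matrices are estimated from an annotation's own splice sites
    with add-one smoothing (``SpliceScorer.from_annotation``); matrices can
    also be loaded from a TSV (``from_tsv``).  The score scale is therefore a
    calibrated operating point of this scorer, not a claim of equivalence
    with any external maximum-entropy model.
    """

    DONOR_WIDTH = DONOR_EXONIC + DONOR_INTRONIC      # 9
    ACCEPTOR_WIDTH = ACCEPTOR_INTRONIC + ACCEPTOR_EXONIC  # 23

    def __init__(
        self,
        donor_pwm: np.ndarray,
        acceptor_pwm: np.ndarray,
        background: Mapping[str, float] | None = None,
    ):
        if donor_pwm.shape != (self.DONOR_WIDTH, 4):
            raise ValueError(f"donor PWM must be {self.DONOR_WIDTH} x 4")
        if acceptor_pwm.shape != (self.ACCEPTOR_WIDTH, 4):
            raise ValueError(f"acceptor PWM must be {self.ACCEPTOR_WIDTH} x 4")
        for name, pwm in (("donor", donor_pwm), ("acceptor", acceptor_pwm)):
            if not np.allclose(pwm.sum(axis=1), 1.0):
                raise ValueError(f"{name} PWM columns must sum to 1")
        bg = background or dict.fromkeys(BASES, 0.25)
        self._bg = np.array([bg[b] for b in BASES])
        self._donor = np.log2(donor_pwm / self._bg)
        self._acceptor = np.log2(acceptor_pwm / self._bg)
        self._base_idx = {b: i for i, b in enumerate(BASES)}

    # -- construction ------------------------------------------------------

    @classmethod
    def from_annotation(cls, bundle: GenomeBundle, pseudocount: float = 1.0) -> "SpliceScorer":
        """Estimate PWMs from every annotated intron's donor/acceptor windows."""
        donor_counts = np.full((cls.DONOR_WIDTH, 4), pseudocount)
        acceptor_counts = np.full((cls.ACCEPTOR_WIDTH, 4), pseudocount)
        idx = {b: i for i, b in enumerate(BASES)}
        n_sites = 0
        for gene in bundle.genes:
            for istart, iend in gene.introns():
                # an intron's donor sits at its genomic start (on '+'), the
                # mirror of backsplice geometry: swap the coordinates
                d, a = splice_windows(bundle, gene.chrom, gene.strand, iend, istart)
                if d is None or a is None or "N" in d or "N" in a:
                    continue
                n_sites += 1
                for i, b in enumerate(d):
                    donor_counts[i, idx[b]] += 1
                for i, b in enumerate(a):
                    acceptor_counts[i, idx[b]] += 1
        if n_sites == 0:
            raise ValueError("annotation contains no usable splice sites")
        # background from genome base composition
        comp = np.zeros(4)
        for seq in bundle.chroms.values():
            for i, b in enumerate(BASES):
                comp[i] += seq.count(b)
        comp = comp / comp.sum()
        bg = dict(zip(BASES, comp))
        return cls(
            donor_counts / donor_counts.sum(axis=1, keepdims=True),
            acceptor_counts / acceptor_counts.sum(axis=1, keepdims=True),
            background=bg,
        )

    @classmethod
    def from_tsv(cls, path: str | Path) -> "SpliceScorer":
        """Load matrices from a TSV with columns model, position, A, C, G, T."""
        import pandas as pd

        df = pd.read_csv(path, sep="\t")
        mats = {}
        for model, width in (("donor", cls.DONOR_WIDTH), ("acceptor", cls.ACCEPTOR_WIDTH)):
            sub = df[df["model"] == model].sort_values("position")
            if len(sub) != width:
                raise ValueError(f"{model} model needs {width} rows, got {len(sub)}")
            mats[model] = sub[list(BASES)].to_numpy(dtype=float)
        bg = None
        bg_rows = df[df["model"] == "background"]
        if len(bg_rows) == 1:
            bg = dict(zip(BASES, bg_rows[list(BASES)].to_numpy(dtype=float)[0]))
        return cls(mats["donor"], mats["acceptor"], background=bg)

    def to_tsv(self, path: str | Path) -> None:
        import pandas as pd

        rows = []
        for model, mat in (("donor", self._donor), ("acceptor", self._acceptor)):
            probs = (2.0 ** mat) * self._bg
            for i in range(mat.shape[0]):
                rows.append({"model": model, "position": i, **dict(zip(BASES, probs[i]))})
        rows.append({"model": "background", "position": 0, **dict(zip(BASES, self._bg))})
        pd.DataFrame(rows).to_csv(path, sep="\t", index=False)

    # -- scoring -----------------------------------------------------------

    def _score(self, seq: str, logodds: np.ndarray) -> float:
        if len(seq) != logodds.shape[0]:
            raise ValueError(
                f"window length {len(seq)} does not match model width {logodds.shape[0]}"
            )
        total = 0.0
        for i, b in enumerate(seq):
            j = self._base_idx.get(b)
            if j is None:
                return NEG_INF
            total += logodds[i, j]
        return total

    def donor_score(self, window: str) -> float:
        return self._score(window, self._donor)

    def acceptor_score(self, window: str) -> float:
        return self._score(window, self._acceptor)


def score_splice_sites(
    scorer: SpliceScorer, donor_window: str, acceptor_window: str
) -> tuple[float, float]:
    """(donor, acceptor) log2-odds scores; -inf for windows containing N."""
    return scorer.donor_score(donor_window), scorer.acceptor_score(acceptor_window)


def splice_windows(
    bundle: GenomeBundle, chrom: str, strand: str, start: int, end: int
) -> tuple[str | None, str | None]:
    """Donor and acceptor windows, gene-strand orientation, for a junction
    whose genomic span is [start, end).

    For a backsplice candidate the donor window flanks the circle's genomic
    end on '+' (its genomic start on '-') and the acceptor window flanks the
    opposite boundary; the same geometry scores an annotated intron when
    called with the intron's coordinates swapped appropriately by the caller.
    Returns None for a window that would run off the chromosome.
    """
    seq = bundle.chroms[chrom]
    n = len(seq)
    if strand == "+":
        d_lo, d_hi = end - DONOR_EXONIC, end + DONOR_INTRONIC
        a_lo, a_hi = start - ACCEPTOR_INTRONIC, start + ACCEPTOR_EXONIC
        donor = seq[d_lo:d_hi] if 0 <= d_lo and d_hi <= n else None
        acceptor = seq[a_lo:a_hi] if 0 <= a_lo and a_hi <= n else None
    else:
        d_lo, d_hi = start - DONOR_INTRONIC, start + DONOR_EXONIC
        a_lo, a_hi = end - ACCEPTOR_EXONIC, end + ACCEPTOR_INTRONIC
        donor = revcomp(seq[d_lo:d_hi]) if 0 <= d_lo and d_hi <= n else None
        acceptor = revcomp(seq[a_lo:a_hi]) if 0 <= a_lo and a_hi <= n else None
    return donor, acceptor


def default_scorer(bundle: GenomeBundle) -> SpliceScorer:
    return SpliceScorer.from_annotation(bundle)


# ---------------------------------------------------------------------------
# Candidates
# ---------------------------------------------------------------------------


@dataclass
class JunctionCandidate:
    """A candidate backsplice junction (possibly raw, one read; or refined)."""

    chrom: str
    strand: str
    acceptor_pos: int   # genomic start of the circle
    donor_end: int      # exclusive genomic end
    supporting_read_ids: set[str] = field(default_factory=set)
    splice_score: float = NEG_INF
    # internal evidence for refinement: query sequence (genome-forward
    # orientation) and the query offset of the junction
    query: str | None = None
    split: int | None = None

    def __post_init__(self) -> None:
        if not self.acceptor_pos < self.donor_end:
            raise ValueError("acceptor_pos must precede donor_end")
        if self.donor_end - self.acceptor_pos > MAX_SPAN:
            raise ValueError("junction span exceeds 1 Mb")


def _query_interval(seg: SegmentMatch, read_len: int) -> tuple[int, int]:
    """Segment interval in genome-forward query coordinates."""
    if seg.strand == "+":
        return seg.read_start, seg.read_end
    return read_len - seg.read_end, read_len - seg.read_start


def find_segment_pairs(
    segments_by_read: Mapping[str, Sequence[SegmentMatch]],
    read_seqs: Mapping[str, str],
    max_span: int = MAX_SPAN,
    max_overlap: int = 10,
    max_gap: int = 3,
) -> list[JunctionCandidate]:
    """Raw head-to-tail candidates from reverse-ordered segment pairs.

    For each read, every segment pair on (a) the same chromosome, (b) the
    same strand, (c) in reverse genomic order relative to read order, with a
    genomic span of at most ``max_span``, yields one raw candidate:
    the acceptor at the genomically-upstream segment's start and the donor at
    the downstream segment's end.  Small read-interval overlaps (repeat
    slippage during extension, up to ``max_overlap``) are trimmed onto the
    later segment; small gaps (sequencing errors, up to ``max_gap``) are
    bridged.  One candidate is emitted per qualifying pair, carrying its read
    as evidence for refinement.
    """
    out: list[JunctionCandidate] = []
    for read_id, segs in segments_by_read.items():
        seq = read_seqs[read_id]
        L = len(seq)
        for a in segs:
            for b in segs:
                if b is a or a.chrom != b.chrom or a.strand != b.strand:
                    continue
                if not (a.read_start < b.read_start or
                        (a.read_start == b.read_start and a.read_end < b.read_end)):
                    continue  # a must come first in the read
                strand = a.strand
                # work in genome-forward query space: the earlier query
                # segment must map downstream of the later one
                query = seq if strand == "+" else revcomp(seq)
                aq = _query_interval(a, L)
                bq = _query_interval(b, L)
                if strand == "+":
                    first, second = (a, aq), (b, bq)
                else:
                    first, second = (b, bq), (a, aq)
                (f_seg, (fqs, fqe)), (s_seg, (sqs, sqe)) = first, second
                # reverse order: the query-later segment lies genomically upstream
                if not s_seg.g_end <= f_seg.g_start:
                    continue
                span = f_seg.g_end - s_seg.g_start
                if span <= 0 or span > max_span:
                    continue
                delta = sqs - fqe  # gap (>0) or overlap (<0) in query space
                if delta < -max_overlap or delta > max_gap:
                    continue
                # the junction sits at the first segment's query end; trimming
                # an overlap advances the acceptor, bridging a gap pulls it back
                split = fqe
                acceptor = s_seg.g_start - delta
                donor_end = f_seg.g_end
                if donor_end - acceptor > max_span or acceptor >= donor_end:
                    continue
                out.append(
                    JunctionCandidate(
                        chrom=a.chrom, strand=strand,
                        acceptor_pos=acceptor, donor_end=donor_end,
                        supporting_read_ids={read_id},
                        query=query, split=split,
                    )
                )
    return out


def rescue_short_overhangs(
    segments_by_read: Mapping[str, Sequence[SegmentMatch]],
    read_seqs: Mapping[str, str],
    bundle: GenomeBundle,
    min_overhang: int = 6,
    min_segment_length: int = MIN_SEGMENT_LENGTH,
    max_span: int = MAX_SPAN,
) -> list[JunctionCandidate]:
    """Anchor-and-search candidates for reads whose junction overhang on one
    side is shorter than the minimum segment length.

    A junction read with, say, an 8-nt overhang produces only one long
    segment; the unaligned remainder is searched for exactly (forward strand
    of the anchor's locus) within ``max_span`` of the anchor, on the side
    reverse order requires.  Each exact occurrence yields a raw candidate;
    implausible ones are eliminated later by the splice score.

    Remainders explainable by ordinary forward splicing — the read simply
    continues across an annotated intron flanking the anchor — are not
    rescued: such reads are linear, not backspliced.
    """
    donors_at: dict[tuple[str, int], list[int]] = defaultdict(list)
    acceptors_at: dict[tuple[str, int], list[int]] = defaultdict(list)
    for gene in bundle.genes:
        for istart, iend in gene.introns():
            donors_at[(gene.chrom, istart)].append(iend)
            acceptors_at[(gene.chrom, iend)].append(istart)

    def forward_explained(query: str, chrom: str, qpos0: int, gpos0: int) -> bool:
        """Can the whole query be walked left and right from the anchor point
        exactly, jumping forward over annotated introns?  Such reads are
        ordinary (multi-)spliced linear reads, not backsplices."""
        seq = bundle.chroms[chrom]
        L = len(query)

        def fwd(qpos: int, gpos: int) -> bool:
            while qpos < L:
                for iend in donors_at.get((chrom, gpos), ()):
                    if fwd(qpos, iend):
                        return True
                if gpos < len(seq) and seq[gpos] == query[qpos]:
                    qpos += 1
                    gpos += 1
                else:
                    return False
            return True

        def bwd(qpos: int, gpos: int) -> bool:
            while qpos > 0:
                for istart in acceptors_at.get((chrom, gpos), ()):
                    if bwd(qpos, istart):
                        return True
                if gpos > 0 and seq[gpos - 1] == query[qpos - 1]:
                    qpos -= 1
                    gpos -= 1
                else:
                    return False
            return True

        return fwd(qpos0, gpos0) and bwd(qpos0, gpos0)

    out: list[JunctionCandidate] = []
    for read_id, segs in segments_by_read.items():
        seq = read_seqs[read_id]
        L = len(seq)
        for seg in segs:
            if seg.score < min_segment_length:
                continue
            query = seq if seg.strand == "+" else revcomp(seq)
            qs, qe = _query_interval(seg, L)
            chrom_seq = bundle.chroms[seg.chrom]
            # anchor the walk inside the segment: its edges may have slipped
            # past an exon boundary by chance matches
            qmid = (qs + qe) // 2
            if forward_explained(query, seg.chrom, qmid, seg.g_start + (qmid - qs)):
                continue
            # unaligned query suffix: anchor is the tail side (ends at donor)
            rem = query[qe:]
            if min_overhang <= len(rem) < min_segment_length:
                lo = max(0, seg.g_start - max_span)
                for g in _occurrences(chrom_seq, rem, lo, seg.g_start):
                    if seg.g_end - g <= max_span and g < seg.g_start:
                        out.append(
                            JunctionCandidate(
                                chrom=seg.chrom, strand=seg.strand,
                                acceptor_pos=g, donor_end=seg.g_end,
                                supporting_read_ids={read_id},
                                query=query, split=qe,
                            )
                        )
            # unaligned query prefix: anchor is the head side (starts at acceptor)
            rem = query[:qs]
            if min_overhang <= len(rem) < min_segment_length:
                hi = min(len(chrom_seq), seg.g_end + max_span)
                for g in _occurrences(chrom_seq, rem, seg.g_end, hi):
                    donor_end = g + len(rem)
                    if donor_end - seg.g_start <= max_span and donor_end > seg.g_start:
                        out.append(
                            JunctionCandidate(
                                chrom=seg.chrom, strand=seg.strand,
                                acceptor_pos=seg.g_start, donor_end=donor_end,
                                supporting_read_ids={read_id},
                                query=query, split=qs,
                            )
                        )
    return out


def _occurrences(haystack: str, needle: str, lo: int, hi: int) -> list[int]:
    out = []
    if not needle:
        return out
    i = haystack.find(needle, lo)
    while 0 <= i and i + len(needle) <= hi:
        out.append(i)
        i = haystack.find(needle, i + 1)
    return out


# ---------------------------------------------------------------------------
# Junction refinement
# ---------------------------------------------------------------------------


def refine_junction(
    candidate: JunctionCandidate,
    bundle: GenomeBundle,
    scorer: SpliceScorer,
    shift_window: int = 10,
    max_mismatches: int = 2,
    min_overhang: int = 6,
) -> JunctionCandidate | None:
    """Slide the junction jointly over [-shift_window, +shift_window] and keep
    the consistent placement with the highest donor + acceptor score.

    A shift is consistent when the supporting read still matches the genome on
    both sides of the shifted junction with at most ``max_mismatches`` total.
    Ties go to the smallest acceptor position.  Returns None when no shift is
    consistent.
    """
    chrom_seq = bundle.chroms[candidate.chrom]
    n = len(chrom_seq)
    best: tuple[float, int] | None = None  # (score, acceptor)
    for s in range(-shift_window, shift_window + 1):
        acc = candidate.acceptor_pos + s
        don = candidate.donor_end + s
        if acc < 0 or don > n or acc >= don:
            continue
        if candidate.query is not None and candidate.split is not None:
            if not _consistent(
                candidate.query, candidate.split + s, chrom_seq, acc, don,
                max_mismatches, min_overhang,
            ):
                continue
        d_win, a_win = splice_windows(
            bundle, candidate.chrom, candidate.strand, acc, don
        )
        if d_win is None or a_win is None:
            continue
        d, a = score_splice_sites(scorer, d_win, a_win)
        score = d + a
        key = (score, -acc)
        if best is None or key > (best[0], -best[1]):
            best = (score, acc)
    if best is None:
        return None
    score, acc = best
    shift = acc - candidate.acceptor_pos
    return JunctionCandidate(
        chrom=candidate.chrom, strand=candidate.strand,
        acceptor_pos=acc, donor_end=candidate.donor_end + shift,
        supporting_read_ids=set(candidate.supporting_read_ids),
        splice_score=score,
        query=candidate.query,
        split=None if candidate.split is None else candidate.split + shift,
    )


def _consistent(
    query: str, split: int, chrom_seq: str, acceptor: int, donor_end: int,
    max_mismatches: int, min_overhang: int,
) -> bool:
    """Does query[:split] end at the donor and query[split:] start at the
    acceptor, within the mismatch budget?"""
    L = len(query)
    if not (min_overhang <= split <= L - min_overhang):
        return False
    left_lo = donor_end - split
    right_hi = acceptor + (L - split)
    if left_lo < 0 or right_hi > len(chrom_seq):
        return False
    mm = _mm(query[:split], chrom_seq[left_lo:donor_end], max_mismatches)
    if mm > max_mismatches:
        return False
    mm += _mm(query[split:], chrom_seq[acceptor:right_hi], max_mismatches - mm)
    return mm <= max_mismatches


def _mm(a: str, b: str, limit: int) -> int:
    if a == b:
        return 0
    mm = 0
    for x, y in zip(a, b):
        if x != y:
            mm += 1
            if mm > limit:
                break
    return mm


# ---------------------------------------------------------------------------
# Calling
# ---------------------------------------------------------------------------


@dataclass
class CircCall:
    """A called circRNA junction."""

    circ_id: str
    chrom: str
    strand: str
    start: int
    end: int
    n_backspliced_reads: int
    splice_score: float
    host_genes: list[str]
    exonic_length: int
    novelty: str = "unassessed"


def call_circRNAs(
    refined: Iterable[JunctionCandidate],
    bundle: GenomeBundle,
    min_reads: int = DEFAULT_MIN_READS,
    min_score: float = DEFAULT_MIN_SCORE,
) -> list[CircCall]:
    """Aggregate refined candidates into circRNA calls.

    Candidates are grouped by (chrom, strand, acceptor, donor_end); a read
    supporting several refined junctions counts only toward the one with the
    highest splice score (ties: smallest coordinates).  A junction is emitted
    iff it is supported by at least ``min_reads`` distinct reads and its
    splice score is >= ``min_score`` (both inclusive thresholds per their
    definitions: >= min_reads, >= min_score).
    """
    groups: dict[tuple, list[JunctionCandidate]] = defaultdict(list)
    for cand in refined:
        groups[(cand.chrom, cand.strand, cand.acceptor_pos, cand.donor_end)].append(cand)

    # junction-level score: all members share coordinates; take the max
    # (members differ only through read-specific window truncation)
    score_of = {
        key: max(c.splice_score for c in members) for key, members in groups.items()
    }
    # assign each read to its best junction
    read_best: dict[str, tuple] = {}
    for key, members in groups.items():
        for cand in members:
            for rid in cand.supporting_read_ids:
                rank = (score_of[key], -key[2], -key[3])
                prev = read_best.get(rid)
                if prev is None or rank > prev[0]:
                    read_best[rid] = (rank, key)
    support: dict[tuple, set[str]] = defaultdict(set)
    for rid, (_, key) in read_best.items():
        support[key].add(rid)

    calls: list[CircCall] = []
    for key in sorted(groups):
        chrom, strand, start, end = key
        n = len(support.get(key, ()))
        score = score_of[key]
        if n < min_reads or score < min_score:
            continue
        hosts = host_genes(bundle, chrom, strand, start, end)
        exonic = exonic_length(bundle, hosts[0], start, end) if hosts else end - start
        calls.append(
            CircCall(
                circ_id="", chrom=chrom, strand=strand, start=start, end=end,
                n_backspliced_reads=n, splice_score=score,
                host_genes=hosts, exonic_length=exonic,
            )
        )
    for i, call in enumerate(calls):
        call.circ_id = f"circ_call_{i + 1:04d}"
    return calls


def host_genes(
    bundle: GenomeBundle, chrom: str, strand: str, start: int, end: int
) -> list[str]:
    """Same-strand genes whose span contains the junction, coordinate order."""
    hits = [
        g for g in bundle.genes
        if g.chrom == chrom and g.strand == strand
        and g.start <= start and end <= g.end
    ]
    hits.sort(key=lambda g: (g.start, g.end))
    return [g.gene_id for g in hits]


def exonic_length(bundle: GenomeBundle, gene_id: str, start: int, end: int) -> int:
    gene = bundle.gene(gene_id)
    total = sum(
        min(e, end) - max(s, start)
        for s, e in gene.exons
        if max(s, start) < min(e, end)
    )
    return total if total > 0 else end - start


def detect_circRNAs(
    unmapped_reads,
    index,
    bundle: GenomeBundle,
    scorer: SpliceScorer | None = None,
    min_reads: int = DEFAULT_MIN_READS,
    min_score: float = DEFAULT_MIN_SCORE,
    min_overhang: int = 6,
    max_span: int = MAX_SPAN,
    shift_window: int = 10,
    max_mismatches: int = 2,
    segments: Mapping[str, Sequence[SegmentMatch]] | None = None,
) -> list[CircCall]:
    """Full detection pass: segments -> pairs (+ short-overhang rescue) ->
    refinement -> calls.  ``segments`` may be supplied (e.g. from SAM
    ingestion) to skip the built-in segment discovery."""
    from .align import segments_by_read as _segments

    if scorer is None:
        scorer = default_scorer(bundle)
    read_seqs = {r.read_id: r.sequence for r in unmapped_reads}
    if segments is None:
        segments = _segments(unmapped_reads, index, bundle)
    raw = find_segment_pairs(segments, read_seqs, max_span=max_span)
    raw += rescue_short_overhangs(
        segments, read_seqs, bundle, min_overhang=min_overhang, max_span=max_span
    )
    refined = []
    for cand in raw:
        r = refine_junction(
            cand, bundle, scorer, shift_window=shift_window,
            max_mismatches=max_mismatches, min_overhang=min_overhang,
        )
        if r is not None:
            refined.append(r)
    return call_circRNAs(refined, bundle, min_reads=min_reads, min_score=min_score)


# ---------------------------------------------------------------------------
# Known-circRNA comparison and output
# ---------------------------------------------------------------------------


def read_bed_junctions(path: str | Path) -> set[tuple[str, str, int, int]]:
    """Known junctions from a BED6 file as (chrom, strand, start, end)."""
    known = set()
    with open(path) as fh:
        for lineno, line in enumerate(fh, start=1):
            if not line.strip() or line.startswith(("#", "track", "browser")):
                continue
            f = line.rstrip("\n").split("\t")
            if len(f) < 6:
                raise ValueError(f"{path}: line {lineno}: expected >= 6 BED columns")
            try:
                start, end = int(f[1]), int(f[2])
            except ValueError as exc:
                raise ValueError(f"{path}: line {lineno}: non-integer coordinates") from exc
            if f[5] not in "+-":
                raise ValueError(f"{path}: line {lineno}: bad strand {f[5]!r}")
            known.add((f[0], f[5], start, end))
    return known


def compare_to_known(
    calls: Sequence[CircCall], known: set[tuple[str, str, int, int]] | str | Path
) -> dict[str, int]:
    """Label calls known/novel by exact (chrom, strand, start, end) match."""
    if not isinstance(known, set):
        known = read_bed_junctions(known)
    n_known = 0
    for call in calls:
        if (call.chrom, call.strand, call.start, call.end) in known:
            call.novelty = "known"
            n_known += 1
        else:
            call.novelty = "novel"
    return {"known": n_known, "novel": len(calls) - n_known}


def write_calls_bed(calls: Sequence[CircCall], path: str | Path) -> None:
    """BED6+3: name = circ_id, score = read support, extras: splice_score,
    host_genes, novelty."""
    with open(path, "w") as fh:
        for c in calls:
            hosts = ",".join(c.host_genes) if c.host_genes else "."
            fh.write(
                f"{c.chrom}\t{c.start}\t{c.end}\t{c.circ_id}\t{c.n_backspliced_reads}\t"
                f"{c.strand}\t{c.splice_score:.4f}\t{hosts}\t{c.novelty}\n"
            )
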