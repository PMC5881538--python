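"""Desk-scale linear read alignment and mapping summaries.

A k-mer seed-and-extend aligner stands in for a production spliced aligner:
it reports, for each clean read, either a full-length linear alignment
(contiguous, or split across one annotated intron) or routes the read to the
unmapped pool that feeds backsplice detection.  Local segment matches of
unmapped reads — the atoms of backsplice discovery — are found with the same
index.  Alignments can alternatively be ingested from a SAM file produced by
an external aligner.

Coordinates are 0-based half-open throughout; strand '-' means the read
matches the reverse complement of the forward genome.
"""

from __future__ import annotations

from collections import Counter, defaultdict
from dataclasses import dataclass
from pathlib import Path
from typing import Iterable, Sequence

from .qc import ReadRecord
from .sim import GenomeBundle, GeneModel, revcomp

DEFAULT_K = 15
MIN_SEGMENT_LENGTH = 18


# ---------------------------------------------------------------------------
# Types
# ---------------------------------------------------------------------------


@dataclass
class LinearAlignment:
    """A full-length linear alignment; blocks are genomic intervals in read order."""

    read_id: str
    chrom: str
    strand: str
    blocks: list[tuple[int, int]]
    mismatches: int

    @property
    def start(self) -> int:
        return min(s for s, _ in self.blocks)

    @property
    def end(self) -> int:
        return max(e for _, e in self.blocks)

    @property
    def aligned_length(self) -> int:
        return sum(e - s for s, e in self.blocks)


@dataclass(frozen=True)
class SegmentMatch:
    """A local alignment of a read substring to the genome.

    ``read_start``/``read_end`` are offsets in the original read orientation;
    for strand '-' the read substring matches the reverse complement of
    ``[g_start, g_end)``.  score = matched length - mismatches.
    """

    read_id: str
    read_start: int
    read_end: int
    chrom: str
    strand: str
    g_start: int
    g_end: int
    score: int

    def __post_init__(self) -> None:
        if self.read_end - self.read_start != self.g_end - self.g_start:
            raise ValueError("segment read span and genomic span differ")


class KmerIndex:
    """Exact k-mer index over both strands of a genome.

    Minus-strand occurrences are stored under the reverse complement of the
    forward k-mer, so looking up a read k-mer directly yields every locus the
    k-mer matches on either strand.  k-mers containing N are skipped.
    """

    def __init__(self, k: int = DEFAULT_K):
        if k < 8:
            raise ValueError("k must be >= 8")
        self.k = k
        self._table: dict[str, list[tuple[str, int, str]]] = defaultdict(list)

    def add_genome(self, bundle: GenomeBundle) -> None:
        k = self.k
        for chrom in bundle.chroms:
            seq = bundle.chroms[chrom]
            rc = revcomp(seq)
            n = len(seq)
            for pos in range(n - k + 1):
                kmer = seq[pos : pos + k]
                if "N" in kmer:
                    continue
                self._table[kmer].append((chrom, pos, "+"))
                # the same locus seen on the minus strand
                self._table[rc[n - pos - k : n - pos]].append((chrom, pos, "-"))

    def lookup(self, kmer: str) -> list[tuple[str, int, str]]:
        return self._table.get(kmer, [])

    def forward_hits(self, kmer: str) -> list[tuple[str, int]]:
        """Loci where ``kmer`` matches the forward strand."""
        return [(c, p) for c, p, s in self._table.get(kmer, []) if s == "+"]


def build_index(genome: GenomeBundle, k: int = DEFAULT_K) -> KmerIndex:
    index = KmerIndex(k=k)
    index.add_genome(genome)
    return index


# ---------------------------------------------------------------------------
# Mismatch-limited comparison helpers
# ---------------------------------------------------------------------------


def count_mismatches(a: str, b: str, limit: int) -> int:
    """Mismatches between equal-length strings, stopping past ``limit``
    (returns limit + 1 to signal failure)."""
    if a == b:
        return 0
    mm = 0
    for x, y in zip(a, b):
        if x != y:
            mm += 1
            if mm > limit:
                return mm
    return mm


# ---------------------------------------------------------------------------
# Linear alignment
# ---------------------------------------------------------------------------


def _intron_table(genes: Sequence[GeneModel]) -> dict[str, list[tuple[int, int]]]:
    table: dict[str, set[tuple[int, int]]] = defaultdict(set)
    for g in genes:
        for intron in g.introns():
            table[g.chrom].add(intron)
    return {c: sorted(v) for c, v in table.items()}


def _verify_candidate(
    query: str,
    chrom_seq: str,
    gstart: int,
    introns: Sequence[tuple[int, int]],
    max_mismatches: int,
) -> list[tuple[int, list[tuple[int, int]]]]:
    """All full-length placements of ``query`` at diagonal ``gstart``:
    contiguous, or split at one annotated intron."""
    L = len(query)
    out = []
    if 0 <= gstart and gstart + L <= len(chrom_seq):
        mm = count_mismatches(query, chrom_seq[gstart : gstart + L], max_mismatches)
        if mm <= max_mismatches:
            out.append((mm, [(gstart, gstart + L)]))
    # left-anchored across an intron: first block [gstart, istart)
    for istart, iend in introns:
        b = istart - gstart
        if 1 <= b <= L - 1 and iend + (L - b) <= len(chrom_seq):
            mm = count_mismatches(query[:b], chrom_seq[gstart:istart], max_mismatches)
            if mm <= max_mismatches:
                mm += count_mismatches(
                    query[b:], chrom_seq[iend : iend + L - b], max_mismatches - mm
                )
                if mm <= max_mismatches:
                    out.append((mm, [(gstart, istart), (iend, iend + L - b)]))
    return out


def align_linear(
    reads: Iterable[ReadRecord],
    index: KmerIndex,
    bundle: GenomeBundle,
    max_mismatches: int = 0,
) -> tuple[list[LinearAlignment], list[ReadRecord]]:
    """Map each read full-length (contiguous or across one annotated intron).

    A read is mapped iff some placement with <= ``max_mismatches`` exists;
    the best placement has fewest mismatches, ties broken by lowest
    (chrom, position, strand).  Everything else lands in the unmapped pool,
    preserved verbatim for backsplice detection.
    """
    introns = _intron_table(bundle.genes)
    k = index.k
    mapped: list[LinearAlignment] = []
    unmapped: list[ReadRecord] = []
    for read in reads:
        L = len(read.sequence)
        best: tuple | None = None
        for orientation in ("+", "-"):
            query = read.sequence if orientation == "+" else revcomp(read.sequence)
            if L < k:
                continue
            chrom_introns_cache: dict[str, list] = {}
            seen_diag: set[tuple[str, int]] = set()
            offsets = list(range(0, L - k + 1, k))
            if offsets[-1] != L - k:
                offsets.append(L - k)
            for o in offsets:
                kmer = query[o : o + k]
                if "N" in kmer:
                    continue
                for chrom, pos in index.forward_hits(kmer):
                    chrom_seq = bundle.chroms[chrom]
                    cin = chrom_introns_cache.setdefault(chrom, introns.get(chrom, []))
                    gstart = pos - o
                    if (chrom, gstart) not in seen_diag:
                        seen_diag.add((chrom, gstart))
                        for mm, blocks in _verify_candidate(
                            query, chrom_seq, gstart, cin, max_mismatches
                        ):
                            key = (mm, chrom, blocks[0][0], orientation, tuple(blocks))
                            if best is None or key < best:
                                best = key
                    # right-anchored intron split: seed may sit in the 2nd block
                    gend = pos + (L - o)
                    for istart, iend in cin:
                        b = L - (gend - iend)
                        if 1 <= b <= L - 1 and o >= b and istart - b >= 0:
                            mm = count_mismatches(
                                query[:b], chrom_seq[istart - b : istart], max_mismatches
                            )
                            if mm <= max_mismatches:
                                mm += count_mismatches(
                                    query[b:], chrom_seq[iend:gend], max_mismatches - mm
                                )
                                if mm <= max_mismatches:
                                    blocks = [(istart - b, istart), (iend, gend)]
                                    key = (mm, chrom, blocks[0][0], orientation, tuple(blocks))
                                    if best is None or key < best:
                                        best = key
        if best is None:
            unmapped.append(read)
        else:
            mm, chrom, _, orientation, blocks = best
            blocks = list(blocks)
            if orientation == "-":
                blocks = blocks[::-1]  # read order runs genomically downwards
            mapped.append(
                LinearAlignment(
                    read_id=read.read_id, chrom=chrom, strand=orientation,
                    blocks=blocks, mismatches=mm,
                )
            )
    return mapped, unmapped


# ---------------------------------------------------------------------------
# Segment discovery for unmapped reads
# ---------------------------------------------------------------------------


def discover_segments(
    read: ReadRecord,
    index: KmerIndex,
    bundle: GenomeBundle,
    min_length: int = MIN_SEGMENT_LENGTH,
) -> list[SegmentMatch]:
    """Maximal near-exact local matches of a read, both strands.

    Seeds from the k-mer index are merged per diagonal and extended in both
    directions; a mismatch may be crossed as long as the running total stays
    within one mismatch per 25 aligned bases.  Segments scoring
    (length - mismatches) below ``min_length`` are discarded.
    """
    k = index.k
    L = len(read.sequence)
    out: list[SegmentMatch] = []
    for orientation in ("+", "-"):
        query = read.sequence if orientation == "+" else revcomp(read.sequence)
        diags: dict[tuple[str, int], list[int]] = defaultdict(list)
        for o in range(0, L - k + 1):
            kmer = query[o : o + k]
            if "N" in kmer:
                continue
            for chrom, pos in index.forward_hits(kmer):
                diags[(chrom, pos - o)].append(o)
        for (chrom, diag), offs in diags.items():
            chrom_seq = bundle.chroms[chrom]
            qs, qe = min(offs), max(offs) + k
            qs, qe, mm = _extend(query, chrom_seq, diag, qs, qe)
            if (qe - qs) - mm < min_length:
                continue
            gs, ge = diag + qs, diag + qe
            if orientation == "+":
                rs, re = qs, qe
            else:
                rs, re = L - qe, L - qs
            out.append(
                SegmentMatch(
                    read_id=read.read_id, read_start=rs, read_end=re,
                    chrom=chrom, strand=orientation, g_start=gs, g_end=ge,
                    score=(qe - qs) - mm,
                )
            )
    out.sort(key=lambda s: (s.read_start, s.read_end, s.chrom, s.g_start, s.strand))
    return out


def _extend(
    query: str, chrom_seq: str, diag: int, qs: int, qe: int
) -> tuple[int, int, int]:
    """Extend [qs, qe) along a diagonal, crossing mismatches while the total
    stays within 1 per 25 aligned bases."""
    mm = 0
    # rightwards
    while True:
        j = qe
        while j < len(query) and 0 <= diag + j < len(chrom_seq) and query[j] == chrom_seq[diag + j]:
            j += 1
        qe = j
        if j < len(query) and 0 <= diag + j < len(chrom_seq) and (mm + 1) * 25 <= (qe - qs) + 1:
            mm += 1
            qe = j + 1
        else:
            break
    # leftwards
    while True:
        i = qs
        while i > 0 and diag + i - 1 >= 0 and query[i - 1] == chrom_seq[diag + i - 1]:
            i -= 1
        qs = i
        if i > 0 and diag + i - 1 >= 0 and (mm + 1) * 25 <= (qe - qs) + 1:
            mm += 1
            qs = i - 1
        else:
            break
    # trim flanking mismatches introduced by the last failed crossings
    while qs < qe and query[qs] != chrom_seq[diag + qs]:
        qs += 1
        mm -= 1
    while qe > qs and query[qe - 1] != chrom_seq[diag + qe - 1]:
        qe -= 1
        mm -= 1
    return qs, qe, max(mm, 0)


def segments_by_read(
    reads: Iterable[ReadRecord],
    index: KmerIndex,
    bundle: GenomeBundle,
    min_length: int = MIN_SEGMENT_LENGTH,
) -> dict[str, list[SegmentMatch]]:
    """Segment sets keyed by read id, segments ordered by read offset."""
    out: dict[str, list[SegmentMatch]] = {}
    for read in reads:
        segs = discover_segments(read, index, bundle, min_length=min_length)
        if segs:
            out[read.read_id] = sorted(segs, key=lambda s: (s.read_start, s.read_end))
    return out


# ---------------------------------------------------------------------------
# SAM ingestion (external-aligner path)
# ---------------------------------------------------------------------------


@dataclass
class SamIngestReport:
    n_records: int = 0
    n_linear: int = 0
    n_segments: int = 0
    n_unmapped: int = 0
    n_skipped: int = 0


def ingest_sam(
    path: str | Path,
    min_segment_length: int = MIN_SEGMENT_LENGTH,
) -> tuple[list[LinearAlignment], dict[str, list[SegmentMatch]], list[ReadRecord], SamIngestReport]:
    """Read alignments from a SAM file.

    Primary full-length records (no clipping; N operations allowed for splices)
    become LinearAlignments; records with soft clips of at least
    ``min_segment_length`` aligned bases, and supplementary records, become
    SegmentMatch sets keyed by read id.  Flag-4 records are routed to the
    unmapped pool.  Unparseable records are skipped and counted.
    """
    import pysam

    report = SamIngestReport()
    linear: list[LinearAlignment] = []
    segments: dict[str, list[SegmentMatch]] = defaultdict(list)
    unmapped: list[ReadRecord] = []
    with pysam.AlignmentFile(str(path), "r", check_sq=False) as fh:
        for rec in fh:
            report.n_records += 1
            try:
                if rec.is_unmapped:
                    report.n_unmapped += 1
                    seq = rec.query_sequence or ""
                    quals = list(rec.query_qualities) if rec.query_qualities is not None else [30] * len(seq)
                    unmapped.append(ReadRecord(rec.query_name, seq, quals))
                    continue
                cigar = rec.cigartuples or []
                has_clip = any(op in (4, 5) for op, _ in cigar)
                if not has_clip and not rec.is_supplementary and not rec.is_secondary:
                    blocks = [(s, e) for s, e in rec.get_blocks()]
                    if rec.is_reverse:
                        blocks = blocks[::-1]
                    nm = rec.get_tag("NM") if rec.has_tag("NM") else 0
                    linear.append(
                        LinearAlignment(
                            read_id=rec.query_name,
                            chrom=rec.reference_name,
                            strand="-" if rec.is_reverse else "+",
                            blocks=blocks,
                            mismatches=int(nm),
                        )
                    )
                    report.n_linear += 1
                else:
                    seg = _segment_from_record(rec, min_segment_length)
                    if seg is not None:
                        segments[rec.query_name].append(seg)
                        report.n_segments += 1
            except (ValueError, TypeError, KeyError):
                report.n_skipped += 1
    for rid in segments:
        segments[rid].sort(key=lambda s: (s.read_start, s.read_end))
    return linear, dict(segments), unmapped, report


def _segment_from_record(rec, min_segment_length: int):
    cigar = rec.cigartuples or []
    aligned = sum(n for op, n in cigar if op in (0, 7, 8))
    if aligned < min_segment_length:
        return None
    left_clip = cigar[0][1] if cigar and cigar[0][0] in (4, 5) else 0
    # total read length including hard-clipped parts
    read_len = rec.infer_read_length() or (left_clip + aligned + (
        cigar[-1][1] if cigar and cigar[-1][0] in (4, 5) else 0))
    q_start = left_clip
    q_end = left_clip + sum(n for op, n in cigar if op in (0, 1, 7, 8))
    if rec.is_reverse:
        rs, re = read_len - q_end, read_len - q_start
    else:
        rs, re = q_start, q_end
    nm = int(rec.get_tag("NM")) if rec.has_tag("NM") else 0
    g_start, g_end = rec.reference_start, rec.reference_end
    if (re - rs) != (g_end - g_start):
        # indel-containing segment: fall back to the reference span
        re = rs + (g_end - g_start)
    return SegmentMatch(
        read_id=rec.query_name, read_start=rs, read_end=re,
        chrom=rec.reference_name, strand="-" if rec.is_reverse else "+",
        g_start=g_start, g_end=g_end, score=aligned - nm,
    )


# ---------------------------------------------------------------------------
# Region and chromosome tallies
# ---------------------------------------------------------------------------

REGION_PRIORITY = ("TSS", "TES", "5UTR", "3UTR", "exon", "intron", "intergenic")


def _overlaps(a_start: int, a_end: int, b_start: int, b_end: int) -> bool:
    return a_start < b_end and b_start < a_end


def _utr_intervals(gene: GeneModel) -> tuple[list[tuple[int, int]], list[tuple[int, int]]]:
    """(5'UTR, 3'UTR) genomic intervals for an mRNA gene with a CDS."""
    if gene.cds_start is None or gene.cds_end is None:
        return [], []
    left = [
        (max(s, gene.start), min(e, gene.cds_start))
        for s, e in gene.exons
        if s < gene.cds_start
    ]
    right = [
        (max(s, gene.cds_end), min(e, gene.end))
        for s, e in gene.exons
        if e > gene.cds_end
    ]
    left = [(s, e) for s, e in left if s < e]
    right = [(s, e) for s, e in right if s < e]
    return (left, right) if gene.strand == "+" else (right, left)


def annotate_regions(
    alignments: Iterable[LinearAlignment],
    bundle: GenomeBundle,
    tss_window: int = 1000,
    tes_window: int = 1000,
) -> dict[str, int]:
    """Assign each alignment exactly one genomic-region category.

    Fixed priority: TSS > TES > 5'UTR > 3'UTR > exon > intron > intergenic,
    with TSS/TES as +-window intervals around annotated transcript start/end.
    """
    by_chrom: dict[str, list[GeneModel]] = defaultdict(list)
    for g in bundle.genes:
        by_chrom[g.chrom].append(g)
    utrs = {g.gene_id: _utr_intervals(g) for g in bundle.genes}
    tally = dict.fromkeys(REGION_PRIORITY, 0)
    for aln in alignments:
        a_start, a_end = aln.start, aln.end
        category = "intergenic"
        rank = REGION_PRIORITY.index(category)
        for g in by_chrom.get(aln.chrom, []):
            if not _overlaps(a_start, a_end, g.start - tss_window, g.end + tes_window):
                continue
            cand: list[str] = []
            if _overlaps(a_start, a_end, g.tx_start - tss_window, g.tx_start + tss_window + 1):
                cand.append("TSS")
            if _overlaps(a_start, a_end, g.tx_end - tes_window, g.tx_end + tes_window + 1):
                cand.append("TES")
            utr5, utr3 = utrs[g.gene_id]
            if any(_overlaps(a_start, a_end, s, e) for s, e in utr5):
                cand.append("5UTR")
            if any(_overlaps(a_start, a_end, s, e) for s, e in utr3):
                cand.append("3UTR")
            if any(_overlaps(a_start, a_end, s, e) for s, e in g.exons):
                cand.append("exon")
            if _overlaps(a_start, a_end, g.start, g.end):
                cand.append("intron")
            for c in cand:
                r = REGION_PRIORITY.index(c)
                if r < rank:
                    rank, category = r, c
        tally[category] += 1
    return tally


def chromosome_tally(alignments: Iterable[LinearAlignment]) -> dict[str, int]:
    """Read counts per chromosome; the sum equals the number of alignments."""
    return dict(Counter(aln.chrom for aln in alignments))


def write_tally(tally: dict[str, int], path: str | Path, key: str = "category") -> None:
    with open(path, "w") as fh:
        fh.write(f"{key}\tcount\n")
        for k in tally:
            fh.write(f"{k}\t{tally[k]}\n")
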