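"""Synthetic genomes, annotations, circRNA truth sets and reads.

This module generates the desk-scale inputs the rest of the pipeline consumes:
a small multi-chromosome genome with multi-exon genes whose introns carry
canonical (GT..AG) splice sites drawn from a strong consensus, a circRNA truth
set with exon-bounded backsplice junctions, single-end Phred+33 FASTQ reads
(linear transcript reads, junction-spanning reads with controlled overhangs,
and QC contaminants), and negative-binomial count matrices with spiked fold
changes for differential-expression calibration.

Everything is a pure function of the configuration, seed included: the same
``SimConfig`` always yields byte-identical FASTA/GTF/FASTQ output.
"""

from __future__ import annotations

import dataclasses
import json
from dataclasses import dataclass, field
from pathlib import Path
from typing import Mapping, Sequence

import numpy as np
import pandas as pd

# ---------------------------------------------------------------------------
# Basic sequence helpers
# ---------------------------------------------------------------------------

_COMPLEMENT = str.maketrans("ACGTNacgtn", "TGCANtgcan")

BASES = ("A", "C", "G", "T")


def revcomp(seq: str) -> str:
    """Reverse complement of a DNA string (N-safe)."""
    return seq.translate(_COMPLEMENT)[::-1]


# ---------------------------------------------------------------------------
# Canonical splice-site consensus
#
# Donor window: 3 exonic + 6 intronic positions (the intron starts GT).
# Acceptor window: 20 intronic + 3 exonic positions (the intron ends AG),
# with a pyrimidine-rich tract upstream of the AG.  Simulated genes carry
# splice sites sampled from these tables, so a position-weight-matrix scorer
# trained on the annotation separates true sites from background sharply.
# ---------------------------------------------------------------------------

DONOR_EXONIC = 3
DONOR_INTRONIC = 6
ACCEPTOR_INTRONIC = 20
ACCEPTOR_EXONIC = 3

# per-position base probabilities, gene-strand orientation
DONOR_CONSENSUS: list[dict[str, float]] = [
    {"C": 0.5, "A": 0.5},            # exon -3
    {"A": 0.6, "G": 0.4},            # exon -2
    {"G": 1.0},                      # exon -1
    {"G": 1.0},                      # intron +1
    {"T": 1.0},                      # intron +2
    {"A": 0.6, "G": 0.4},            # intron +3
    {"A": 1.0},                      # intron +4
    {"G": 0.7, "A": 0.3},            # intron +5
    {"T": 1.0},                      # intron +6
]

_PYRIMIDINE = {"C": 0.5, "T": 0.5}
ACCEPTOR_CONSENSUS: list[dict[str, float]] = (
    [_PYRIMIDINE] * 17               # intron -20..-4: polypyrimidine tract
    + [{"C": 0.7, "T": 0.3}]         # intron -3
    + [{"A": 1.0}]                   # intron -2
    + [{"G": 1.0}]                   # intron -1
    + [{"G": 0.5, "A": 0.5}]         # exon +1
    + [dict.fromkeys(BASES, 0.25)]   # exon +2
    + [dict.fromkeys(BASES, 0.25)]   # exon +3
)


def _sample_motif(consensus: Sequence[Mapping[str, float]], rng: np.random.Generator) -> str:
    out = []
    for col in consensus:
        bases = sorted(col)
        probs = np.array([col[b] for b in bases])
        out.append(bases[rng.choice(len(bases), p=probs / probs.sum())])
    return "".join(out)


# ---------------------------------------------------------------------------
# Configuration
# ---------------------------------------------------------------------------


@dataclass(frozen=True)
class DeDesign:
    """Count-matrix design: samples per condition and spiked fold changes."""

    n_per_condition: int = 3
    spike_fold_changes: tuple[float, ...] = (8.0, 0.125)


@dataclass(frozen=True)
class SimConfig:
    """All knobs of the simulator; the seed makes every output reproducible.

    Defaults describe the standard synthetic study: 3 chromosomes of 100 kb,
    40 multi-exon genes, 20 canonical exon-bounded circles carrying 2-30
    junction-spanning reads each, error-free reads of 100 nt, and a 3-vs-3
    differential design with 8-fold spikes.
    """

    seed: int = 42
    n_chromosomes: int = 3
    chrom_length: int = 100_000
    n_genes: int = 40
    exons_per_gene: tuple[int, int] = (3, 6)
    exon_length: tuple[int, int] = (80, 300)
    intron_length: tuple[int, int] = (200, 1500)
    read_length: int = 100
    base_error_rate: float = 0.0
    n_fraction: float = 0.0
    linear_depth: float = 50.0
    total_linear_reads: int | None = None
    n_noise_reads: int = 0
    circ_fraction: float = 0.5
    circ_read_range: tuple[int, int] = (2, 30)
    min_overhang: int = 6
    mrna_fraction: float = 0.7
    non_canonical: bool = False
    de_design: DeDesign = field(default_factory=DeDesign)

    def __post_init__(self) -> None:
        for name in ("exons_per_gene", "exon_length", "intron_length", "circ_read_range"):
            lo, hi = getattr(self, name)
            if lo > hi:
                raise ValueError(f"{name} range ({lo}, {hi}) is empty")
        if self.read_length < 2 * self.min_overhang:
            raise ValueError(
                f"read_length {self.read_length} < 2 x min_overhang {self.min_overhang}"
            )
        if not (0.0 <= self.base_error_rate <= 1.0 and 0.0 <= self.n_fraction <= 1.0):
            raise ValueError("error rates must be probabilities")

    @classmethod
    def from_json(cls, path: str | Path) -> "SimConfig":
        raw = json.loads(Path(path).read_text())
        if "de_design" in raw:
            dd = raw["de_design"]
            raw["de_design"] = DeDesign(
                n_per_condition=dd.get("n_per_condition", 3),
                spike_fold_changes=tuple(dd.get("spike_fold_changes", (8.0, 0.125))),
            )
        for name in ("exons_per_gene", "exon_length", "intron_length", "circ_read_range"):
            if name in raw:
                raw[name] = tuple(raw[name])
        return cls(**raw)


# ---------------------------------------------------------------------------
# Gene models and the genome bundle
# ---------------------------------------------------------------------------


@dataclass
class GeneModel:
    """One gene, one transcript; exons in ascending genomic order (0-based, half-open)."""

    gene_id: str
    chrom: str
    strand: str
    exons: list[tuple[int, int]]
    biotype: str  # "mRNA" | "lncRNA"
    cds_start: int | None = None  # genomic, 0-based; mRNA only
    cds_end: int | None = None

    @property
    def start(self) -> int:
        return self.exons[0][0]

    @property
    def end(self) -> int:
        return self.exons[-1][1]

    @property
    def tx_start(self) -> int:
        """Genomic position of the transcription start site."""
        return self.start if self.strand == "+" else self.end - 1

    @property
    def tx_end(self) -> int:
        """Genomic position of the transcription end site."""
        return self.end - 1 if self.strand == "+" else self.start

    def introns(self) -> list[tuple[int, int]]:
        return [
            (self.exons[i][1], self.exons[i + 1][0]) for i in range(len(self.exons) - 1)
        ]

    def spliced_length(self) -> int:
        return sum(e - s for s, e in self.exons)


@dataclass
class GenomeBundle:
    """Chromosome sequences plus gene models: the shared coordinate authority."""

    chroms: dict[str, str]
    genes: list[GeneModel]

    def gene(self, gene_id: str) -> GeneModel:
        for g in self.genes:
            if g.gene_id == gene_id:
                return g
        raise KeyError(gene_id)

    def fetch(self, chrom: str, start: int, end: int) -> str:
        seq = self.chroms[chrom]
        if start < 0 or end > len(seq):
            raise IndexError(f"{chrom}:{start}-{end} outside chromosome bounds")
        return seq[start:end]

    def transcript_sequence(self, gene: GeneModel) -> str:
        """Spliced transcript sequence in gene orientation (5'->3')."""
        seq = "".join(self.fetch(gene.chrom, s, e) for s, e in gene.exons)
        return seq if gene.strand == "+" else revcomp(seq)

    # ---- file output -----------------------------------------------------

    def write_fasta(self, path: str | Path, width: int = 70) -> None:
        with open(path, "w") as fh:
            for name in self.chroms:
                fh.write(f">{name}\n")
                seq = self.chroms[name]
                for i in range(0, len(seq), width):
                    fh.write(seq[i : i + width] + "\n")

    def write_gtf(self, path: str | Path) -> None:
        """GTF output, 1-based inclusive, one transcript per gene."""
        with open(path, "w") as fh:
            for g in self.genes:
                attrs = (
                    f'gene_id "{g.gene_id}"; transcript_id "{g.gene_id}.t1"; '
                    f'transcript_biotype "{g.biotype}";'
                )
                rows = [("gene", g.start, g.end), ("transcript", g.start, g.end)]
                rows += [("exon", s, e) for s, e in g.exons]
                if g.biotype == "mRNA" and g.cds_start is not None:
                    rows.append(("CDS", g.cds_start, g.cds_end))
                for feature, s, e in rows:
                    fh.write(
                        f"{g.chrom}\tcircprofiler\t{feature}\t{s + 1}\t{e}\t.\t"
                        f"{g.strand}\t.\t{attrs}\n"
                    )

    # ---- file input ------------------------------------------------------

    @classmethod
    def from_files(cls, fasta: str | Path, gtf: str | Path) -> "GenomeBundle":
        """Load a bundle from a genome FASTA and a GTF annotation
        (1-based inclusive, converted to 0-based half-open internally)."""
        import gffutils
        from Bio import SeqIO

        chroms = {rec.id: str(rec.seq).upper() for rec in SeqIO.parse(str(fasta), "fasta")}
        db = gffutils.create_db(
            str(gtf), ":memory:",
            disable_infer_genes=True, disable_infer_transcripts=True,
        )
        genes: dict[str, GeneModel] = {}
        cds: dict[str, tuple[int, int]] = {}
        for feat in db.all_features():
            gid_attr = feat.attributes.get("gene_id")
            if not gid_attr:
                continue
            gid = gid_attr[0]
            s, e = feat.start - 1, feat.end
            if feat.featuretype == "exon":
                g = genes.get(gid)
                if g is None:
                    biotype = (feat.attributes.get("transcript_biotype") or ["mRNA"])[0]
                    g = GeneModel(
                        gene_id=gid, chrom=feat.seqid, strand=feat.strand,
                        exons=[], biotype=biotype,
                    )
                    genes[gid] = g
                g.exons.append((s, e))
            elif feat.featuretype == "CDS":
                lo, hi = cds.get(gid, (s, e))
                cds[gid] = (min(lo, s), max(hi, e))
        for gid, g in genes.items():
            g.exons.sort()
            if gid in cds:
                g.cds_start, g.cds_end = cds[gid]
        return cls(chroms=chroms, genes=sorted(genes.values(), key=lambda g: g.gene_id))


# ---------------------------------------------------------------------------
# Genome generation
# ---------------------------------------------------------------------------


def generate_genome(config: SimConfig) -> GenomeBundle:
    """Generate chromosome sequences and gene models.

    Genes are laid out left to right with random intergenic gaps; every
    annotated intron begins GT and ends AG on the gene strand, with full
    donor/acceptor consensus windows written into the sequence so that a
    splice-site scorer trained on the annotation is informative.
    """
    rng = np.random.default_rng(config.seed)
    chrom_names = [f"chr{i + 1}" for i in range(config.n_chromosomes)]
    seqs = {
        name: bytearray(
            rng.choice(np.frombuffer(b"ACGT", dtype=np.uint8), size=config.chrom_length)
            .tobytes()
        )
        for name in chrom_names
    }

    margin = 1200  # clearance at chromosome ends for TSS/TES windows
    gap_range = (500, 3000)
    cursors = dict.fromkeys(chrom_names, margin)
    genes: list[GeneModel] = []
    for i in range(config.n_genes):
        chrom = chrom_names[i % config.n_chromosomes]
        n_ex = int(rng.integers(config.exons_per_gene[0], config.exons_per_gene[1] + 1))
        ex_lens = rng.integers(config.exon_length[0], config.exon_length[1] + 1, n_ex)
        in_lens = rng.integers(
            config.intron_length[0], config.intron_length[1] + 1, max(n_ex - 1, 0)
        )
        span = int(ex_lens.sum() + in_lens.sum())
        start = cursors[chrom] + int(rng.integers(*gap_range))
        if start + span + margin > config.chrom_length:
            raise ValueError(
                f"chrom_length {config.chrom_length} too small to place gene {i + 1} "
                f"of {config.n_genes} on {chrom} (needs {start + span + margin} nt); "
                "increase chrom_length or reduce n_genes/exon/intron sizes"
            )
        exons = []
        pos = start
        for j in range(n_ex):
            exons.append((pos, pos + int(ex_lens[j])))
            pos += int(ex_lens[j])
            if j < n_ex - 1:
                pos += int(in_lens[j])
        cursors[chrom] = pos
        strand = "+" if rng.random() < 0.5 else "-"
        biotype = "mRNA" if rng.random() < config.mrna_fraction else "lncRNA"
        gene = GeneModel(
            gene_id=f"gene_{i + 1:04d}", chrom=chrom, strand=strand, exons=exons,
            biotype=biotype,
        )
        if biotype == "mRNA":
            _assign_cds(gene, rng)
        genes.append(gene)
        _write_splice_sites(seqs[chrom], gene, rng)

    chroms = {name: bytes(seqs[name]).decode() for name in chrom_names}
    return GenomeBundle(chroms=chroms, genes=genes)


def _assign_cds(gene: GeneModel, rng: np.random.Generator) -> None:
    first_len = gene.exons[0][1] - gene.exons[0][0]
    last_len = gene.exons[-1][1] - gene.exons[-1][0]
    utr5 = int(rng.integers(15, max(16, min(60, first_len - 20))))
    utr3 = int(rng.integers(15, max(16, min(60, last_len - 20))))
    if gene.strand == "+":
        gene.cds_start = gene.exons[0][0] + utr5
        gene.cds_end = gene.exons[-1][1] - utr3
    else:
        gene.cds_start = gene.exons[0][0] + utr3
        gene.cds_end = gene.exons[-1][1] - utr5


def _write_splice_sites(seq: bytearray, gene: GeneModel, rng: np.random.Generator) -> None:
    """Overwrite genome sequence with sampled donor/acceptor windows, strand-aware."""
    for istart, iend in gene.introns():
        donor = _sample_motif(DONOR_CONSENSUS, rng)
        acceptor = _sample_motif(ACCEPTOR_CONSENSUS, rng)
        if gene.strand == "+":
            seq[istart - DONOR_EXONIC : istart + DONOR_INTRONIC] = donor.encode()
            seq[iend - ACCEPTOR_INTRONIC : iend + ACCEPTOR_EXONIC] = acceptor.encode()
        else:
            # transcript reads right to left: donor at intron's genomic end
            seq[iend - DONOR_INTRONIC : iend + DONOR_EXONIC] = revcomp(donor).encode()
            seq[istart - ACCEPTOR_EXONIC : istart + ACCEPTOR_INTRONIC] = (
                revcomp(acceptor).encode()
            )


# ---------------------------------------------------------------------------
# circRNA truth
# ---------------------------------------------------------------------------


@dataclass
class CircTruth:
    """Ground-truth backsplice circle: exon-bounded on its host gene."""

    circ_id: str
    host_gene: str
    chrom: str
    strand: str
    start: int  # 0-based acceptor-side position (genomic)
    end: int    # exclusive donor-side end (genomic)
    exon_indices: list[int]
    true_junction_reads: int

    def __post_init__(self) -> None:
        if not self.start < self.end:
            raise ValueError("circle start must precede end")
        if self.end - self.start > 1_000_000:
            raise ValueError("circle span exceeds 1 Mb")


def circle_sequence(bundle: GenomeBundle, circ: CircTruth) -> str:
    """Spliced circle sequence in transcript orientation (head-to-tail open form)."""
    gene = bundle.gene(circ.host_gene)
    exons = [gene.exons[i] for i in circ.exon_indices]
    seq = "".join(bundle.fetch(gene.chrom, s, e) for s, e in exons)
    return seq if gene.strand == "+" else revcomp(seq)


def simulate_circles(bundle: GenomeBundle, config: SimConfig) -> list[CircTruth]:
    """Draw exon-bounded circles over internal exon runs of multi-exon genes.

    The number of circles is round(circ_fraction * n_genes); when two or more
    circles are requested, the first host gene carries two distinct circles so
    per-gene multiplicity is exercised.  Only runs whose spliced length is at
    least the read length are eligible (junction reads must fit the circle).
    """
    rng = np.random.default_rng(config.seed + 1)
    n_total = int(round(config.circ_fraction * config.n_genes))
    if n_total == 0:
        return []
    eligible = [g for g in bundle.genes if len(g.exons) >= 3]
    if not eligible:
        raise ValueError("no gene with >=3 exons available to host circles")

    def runs(gene: GeneModel) -> list[tuple[int, int]]:
        n = len(gene.exons)
        out = []
        for i in range(1, n - 1):
            for j in range(i, n - 1):
                length = sum(e - s for s, e in gene.exons[i : j + 1])
                if length >= config.read_length:
                    out.append((i, j))
        return out

    eligible = [g for g in eligible if runs(g)]
    if not eligible:
        raise ValueError("no eligible internal exon run long enough for a circle")
    n_hosts = max(1, n_total - 1) if n_total >= 2 else 1
    n_hosts = min(n_hosts, len(eligible))
    host_idx = rng.choice(len(eligible), size=n_hosts, replace=False)
    hosts = [eligible[i] for i in sorted(host_idx)]
    # the double-circle host must actually offer two distinct exon runs
    for i, g in enumerate(hosts):
        if len(runs(g)) >= 2:
            hosts[0], hosts[i] = hosts[i], hosts[0]
            break
    else:
        rich = [g for g in eligible if len(runs(g)) >= 2 and g not in hosts]
        if rich and n_total >= 2:
            hosts[0] = rich[0]

    circles: list[CircTruth] = []
    for h, gene in enumerate(hosts):
        n_here = 2 if (h == 0 and n_total >= 2) else 1
        gene_runs = runs(gene)
        if n_here > len(gene_runs):
            n_here = len(gene_runs)
        picked = rng.choice(len(gene_runs), size=n_here, replace=False)
        for idx in sorted(picked):
            i, j = gene_runs[idx]
            circles.append(
                CircTruth(
                    circ_id=f"circ_{len(circles) + 1:04d}",
                    host_gene=gene.gene_id,
                    chrom=gene.chrom,
                    strand=gene.strand,
                    start=gene.exons[i][0],
                    end=gene.exons[j][1],
                    exon_indices=list(range(i, j + 1)),
                    true_junction_reads=int(
                        rng.integers(config.circ_read_range[0], config.circ_read_range[1] + 1)
                    ),
                )
            )
    # pad with extra single-circle hosts if multiplicity trimming left us short
    while len(circles) < n_total:
        gene = eligible[int(rng.integers(len(eligible)))]
        gene_runs = runs(gene)
        i, j = gene_runs[int(rng.integers(len(gene_runs)))]
        key = (gene.chrom, gene.exons[i][0], gene.exons[j][1])
        if any((c.chrom, c.start, c.end) == key for c in circles):
            continue
        circles.append(
            CircTruth(
                circ_id=f"circ_{len(circles) + 1:04d}",
                host_gene=gene.gene_id,
                chrom=gene.chrom,
                strand=gene.strand,
                start=gene.exons[i][0],
                end=gene.exons[j][1],
                exon_indices=list(range(i, j + 1)),
                true_junction_reads=int(
                    rng.integers(config.circ_read_range[0], config.circ_read_range[1] + 1)
                ),
            )
        )
    return circles


def write_circle_truth(circles: Sequence[CircTruth], path: str | Path) -> None:
    df = pd.DataFrame(
        [
            {
                "circ_id": c.circ_id,
                "host_gene": c.host_gene,
                "chrom": c.chrom,
                "strand": c.strand,
                "start": c.start,
                "end": c.end,
                "exon_indices": ",".join(map(str, c.exon_indices)),
                "true_junction_reads": c.true_junction_reads,
            }
            for c in circles
        ]
    )
    df.to_csv(path, sep="\t", index=False)


def write_known_bed(circles: Sequence[CircTruth], path: str | Path) -> None:
    """Write circles as a BED6 known-circRNA set (0-based half-open)."""
    with open(path, "w") as fh:
        for c in circles:
            fh.write(f"{c.chrom}\t{c.start}\t{c.end}\t{c.circ_id}\t0\t{c.strand}\n")


# ---------------------------------------------------------------------------
# Read simulation
# ---------------------------------------------------------------------------


@dataclass
class SimReads:
    """Simulated read set with origin bookkeeping."""

    reads: list[tuple[str, str, str]]  # (read_id, sequence, quality string)
    n_linear: int
    n_junction: int
    n_noise: int


def _apply_errors(seq: str, rng: np.random.Generator, error_rate: float, n_frac: float) -> str:
    if error_rate <= 0 and n_frac <= 0:
        return seq
    arr = np.frombuffer(seq.encode(), dtype=np.uint8).copy()
    if error_rate > 0:
        hits = np.nonzero(rng.random(arr.size) < error_rate)[0]
        for i in hits:
            alt = [b for b in b"ACGT" if b != arr[i]]
            arr[i] = alt[int(rng.integers(3))]
    if n_frac > 0:
        arr[rng.random(arr.size) < n_frac] = ord("N")
    return arr.tobytes().decode()


def simulate_reads(
    bundle: GenomeBundle,
    circles: Sequence[CircTruth],
    config: SimConfig,
    out_fastq: str | Path | None = None,
    sample_id: str = "s1",
    rng: np.random.Generator | None = None,
    depth_scale: Mapping[str, float] | None = None,
) -> SimReads:
    """Simulate one sample's single-end reads.

    Emits (a) linear transcript reads uniform over each spliced transcript,
    (b) for each circle exactly ``true_junction_reads`` reads spanning the
    backsplice with >= ``min_overhang`` nt on both sides, drawn from the
    circular (wrap-around) sequence, and (c) optional noise reads that carry
    N runs or low-quality tails to exercise QC.  Read names encode origin as
    ``{sample}:{serial}:origin:{lin|circ|noise}:{source}:{pos}``.

    ``depth_scale`` multiplies a gene's expected linear read count (used for
    read-level fold-change spikes in multi-sample designs).
    """
    if rng is None:
        rng = np.random.default_rng(config.seed + 2)
    L = config.read_length
    q35 = chr(35 + 33) * L
    reads: list[tuple[str, str, str]] = []
    serial = 0

    # --- linear reads
    transcripts = [(g, bundle.transcript_sequence(g)) for g in bundle.genes]
    transcripts = [(g, t) for g, t in transcripts if len(t) >= L]
    scale = depth_scale or {}
    if config.total_linear_reads is not None and transcripts:
        weights = np.array([scale.get(g.gene_id, 1.0) for g, _ in transcripts], float)
        counts = rng.multinomial(config.total_linear_reads, weights / weights.sum())
    else:
        counts = np.array(
            [
                rng.poisson(config.linear_depth * scale.get(g.gene_id, 1.0))
                for g, _ in transcripts
            ]
        )
    n_linear = int(counts.sum())
    for (gene, tseq), n in zip(transcripts, counts):
        if n == 0:
            continue
        starts = rng.integers(0, len(tseq) - L + 1, size=int(n))
        for pos in starts:
            serial += 1
            seq = _apply_errors(
                tseq[pos : pos + L], rng, config.base_error_rate, config.n_fraction
            )
            rid = f"{sample_id}:{serial}:origin:lin:{gene.gene_id}:{int(pos)}"
            reads.append((rid, seq, q35))

    # --- backsplice junction reads
    mo = config.min_overhang
    n_junction = 0
    for circ in circles:
        cseq = circle_sequence(bundle, circ)
        if L > len(cseq):
            raise ValueError(
                f"read_length {L} exceeds circumference {len(cseq)} of {circ.circ_id}"
            )
        doubled = cseq + cseq
        C = len(cseq)
        for _ in range(circ.true_junction_reads):
            serial += 1
            n_junction += 1
            a = int(rng.integers(mo, L - mo + 1))  # bases from the circle tail
            seq = doubled[C - a : C - a + L]
            seq = _apply_errors(seq, rng, config.base_error_rate, config.n_fraction)
            rid = f"{sample_id}:{serial}:origin:circ:{circ.circ_id}:{a}"
            reads.append((rid, seq, q35))

    # --- noise reads: half clean random, a quarter N-laced, a quarter low-quality
    acgt = np.frombuffer(b"ACGT", dtype=np.uint8)
    for i in range(config.n_noise_reads):
        serial += 1
        seq = rng.choice(acgt, size=L).tobytes().decode()
        qual = q35
        kind = ("random", "nlaced", "lowq")[0 if i % 4 < 2 else (1 if i % 4 == 2 else 2)]
        if kind == "nlaced":  # 10% N > the 5% QC cutoff
            arr = bytearray(seq.encode())
            for p in rng.choice(L, size=max(1, L // 10), replace=False):
                arr[p] = ord("N")
            seq = bytes(arr).decode()
        elif kind == "lowq":  # 25% of bases below Q13 > the 20% cutoff
            n_low = L // 4
            qual = chr(35 + 33) * (L - n_low) + chr(10 + 33) * n_low
        rid = f"{sample_id}:{serial}:origin:noise:{kind}:{i}"
        reads.append((rid, seq, qual))

    if out_fastq is not None:
        with open(out_fastq, "w") as fh:
            for rid, seq, qual in reads:
                fh.write(f"@{rid}\n{seq}\n+\n{qual}\n")
    return SimReads(
        reads=reads, n_linear=n_linear, n_junction=n_junction,
        n_noise=config.n_noise_reads,
    )


def simulate_samples(
    bundle: GenomeBundle,
    circles: Sequence[CircTruth],
    config: SimConfig,
    outdir: str | Path,
    spiked_genes: Mapping[str, float] | None = None,
) -> pd.DataFrame:
    """Simulate a full multi-sample design (tumor vs normal) as FASTQ files.

    ``spiked_genes`` maps gene ids to the fold change applied to their linear
    read depth in the tumor condition.  Returns a sample sheet DataFrame with
    columns sample, condition, fastq.
    """
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    spiked = dict(spiked_genes or {})
    rows = []
    idx = 0
    for condition in ("normal", "tumor"):
        for k in range(config.de_design.n_per_condition):
            idx += 1
            sample = f"{condition}{k + 1}"
            rng = np.random.default_rng(config.seed + 100 + idx)
            scale = spiked if condition == "tumor" else None
            path = outdir / f"{sample}.fastq"
            simulate_reads(
                bundle, circles, config, out_fastq=path, sample_id=sample,
                rng=rng, depth_scale=scale,
            )
            rows.append({"sample": sample, "condition": condition, "fastq": str(path)})
    sheet = pd.DataFrame(rows)
    sheet.to_csv(outdir / "samples.tsv", sep="\t", index=False)
    return sheet


# ---------------------------------------------------------------------------
# Count-matrix simulation (negative binomial with spiked fold changes)
# ---------------------------------------------------------------------------


def simulate_counts(
    n_features: int = 1000,
    n_per_condition: int = 3,
    dispersion: float = 0.1,
    spike_fold_changes: Sequence[float] | Mapping[str, float] = (),
    seed: int = 0,
    base_mean_range: tuple[float, float] = (100.0, 500.0),
    biotype: str = "mRNA",
) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Simulate an NB count matrix for a two-condition design plus spike truth.

    Feature means are log-normal (median ~150); spiked features get a base
    mean drawn from ``base_mean_range`` and their condition-2 (tumor) mean is
    multiplied by the stated fold change.  Counts are NB with variance
    mu + dispersion * mu^2 (Poisson when dispersion == 0).

    Returns (counts DataFrame with tumor/normal sample columns, spike truth
    DataFrame with columns feature, fold_change).
    """
    if n_per_condition < 2:
        raise ValueError("need >=2 samples per condition")
    if dispersion < 0:
        raise ValueError("dispersion must be non-negative")
    rng = np.random.default_rng(seed)
    features = [f"{biotype}_{i + 1:05d}" for i in range(n_features)]
    means = rng.lognormal(mean=np.log(150.0), sigma=1.0, size=n_features)
    means = np.clip(means, 0.5, 1e5)
    if isinstance(spike_fold_changes, Mapping):
        spikes = dict(spike_fold_changes)
    else:
        spikes = {features[i]: float(fc) for i, fc in enumerate(spike_fold_changes)}
    unknown = set(spikes) - set(features)
    if unknown:
        raise ValueError(f"spiked features not in matrix: {sorted(unknown)}")
    fc = np.ones(n_features)
    for i, f in enumerate(features):
        if f in spikes:
            means[i] = rng.uniform(*base_mean_range)
            fc[i] = spikes[f]
    if np.any(means <= 0):
        raise ValueError("feature means must be positive")

    samples = [f"normal{k + 1}" for k in range(n_per_condition)] + [
        f"tumor{k + 1}" for k in range(n_per_condition)
    ]
    cols = {}
    for j, s in enumerate(samples):
        mu = means * np.where(np.array([s.startswith("tumor")] * n_features), fc, 1.0)
        if dispersion == 0:
            cols[s] = rng.poisson(mu)
        else:
            r = 1.0 / dispersion
            cols[s] = rng.negative_binomial(r, r / (r + mu))
    counts = pd.DataFrame(cols, index=pd.Index(features, name="feature"))
    truth = pd.DataFrame(
        {"feature": list(spikes), "fold_change": [spikes[f] for f in spikes]}
    )
    return counts, truth
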