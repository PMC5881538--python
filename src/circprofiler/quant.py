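"""circRNA quantification against pseudo-circular junction references.

For every called circRNA a junction construct is assembled by concatenating
the circle's 3'-terminal bases to its 5'-initial bases (using annotated exons
of the host gene when known, else the genomic span), and all unmapped reads
are realigned to these constructs.  A read counts for a circle iff it matches
the construct with a limited number of mismatches and covers at least
``min_overhang`` bases on both sides of the junction midpoint; each read
counts for at most one circle.
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd

from .detect import CircCall
from .qc import ReadRecord
from .sim import GenomeBundle, revcomp

DEFAULT_MIN_OVERHANG = 6
DEFAULT_MAX_MISMATCHES = 2


@dataclass
class PseudoReference:
    """Junction construct of length 2*(L - min_overhang), midpoint = junction."""

    circ_id: str
    junction_sequence: str

    @property
    def midpoint(self) -> int:
        return len(self.junction_sequence) // 2


@dataclass
class CircExpression:
    circ_id: str
    junction_reads: dict[str, int]  # per sample
    exonic_length: int


def circle_sequence_for_call(call: CircCall, bundle: GenomeBundle) -> str:
    """Spliced circle sequence, transcript orientation.

    Uses the same-strand annotated exons of the first host gene intersected
    with [start, end); falls back to the genomic span when no host is known.
    """
    if call.host_genes:
        gene = bundle.gene(call.host_genes[0])
        parts = [
            (max(s, call.start), min(e, call.end))
            for s, e in gene.exons
            if max(s, call.start) < min(e, call.end)
        ]
        if parts:
            seq = "".join(bundle.fetch(call.chrom, s, e) for s, e in parts)
            return seq if call.strand == "+" else revcomp(seq)
    seq = bundle.fetch(call.chrom, call.start, call.end)
    return seq if call.strand == "+" else revcomp(seq)


def build_pseudo_reference(
    call: CircCall,
    bundle: GenomeBundle,
    read_length: int,
    min_overhang: int = DEFAULT_MIN_OVERHANG,
) -> PseudoReference:
    """Concatenate the circle's last (L - min_overhang) bases to its first
    (L - min_overhang) bases; circles shorter than one arm wrap around."""
    circ = circle_sequence_for_call(call, bundle)
    if not circ:
        raise ValueError(f"{call.circ_id}: zero-length circle sequence")
    arm = read_length - min_overhang
    reps = -(-arm // len(circ)) + 1  # enough copies to take either arm
    tiled = circ * reps
    left = tiled[-arm:] if arm <= len(tiled) else tiled
    right = tiled[:arm]
    return PseudoReference(circ_id=call.circ_id, junction_sequence=left + right)


def _best_placement(
    read: str, construct: str, midpoint: int, min_overhang: int, max_mm: int
) -> int | None:
    """Fewest mismatches over placements covering the midpoint with
    >= min_overhang on both sides (either read orientation); None if none."""
    best: int | None = None
    n, L = len(construct), len(read)
    lo = max(0, midpoint + min_overhang - L)
    hi = min(n - L, midpoint - min_overhang)
    for seq in (read, revcomp(read)):
        for o in range(lo, hi + 1):
            mm = _mm(seq, construct[o : o + L], max_mm)
            if mm <= max_mm and (best is None or mm < best):
                best = mm
                if best == 0:
                    return 0
    return best


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


def count_junction_reads(
    pseudo_refs: Sequence[PseudoReference],
    unmapped_reads: Iterable[ReadRecord],
    min_overhang: int = DEFAULT_MIN_OVERHANG,
    max_mismatches: int = DEFAULT_MAX_MISMATCHES,
) -> dict[str, int]:
    """Junction-spanning read counts per circle for one read pool.

    A read counts for the single best-matching construct (fewest mismatches,
    ties to the lexicographically smallest circ_id) iff it covers the
    midpoint with at least ``min_overhang`` bases on both sides.
    """
    refs = sorted(pseudo_refs, key=lambda r: r.circ_id)
    counts = {r.circ_id: 0 for r in refs}
    for read in unmapped_reads:
        best_id = None
        best_mm: int | None = None
        for ref in refs:
            mm = _best_placement(
                read.sequence, ref.junction_sequence, ref.midpoint,
                min_overhang, max_mismatches,
            )
            if mm is not None and (best_mm is None or mm < best_mm):
                best_id, best_mm = ref.circ_id, mm
                if mm == 0:
                    break  # refs sorted: first zero-mismatch wins ties
        if best_id is not None:
            counts[best_id] += 1
    return counts


def quantify(
    calls: Sequence[CircCall],
    bundle: GenomeBundle,
    unmapped_by_sample: Mapping[str, Iterable[ReadRecord]],
    read_length: int,
    min_overhang: int = DEFAULT_MIN_OVERHANG,
    max_mismatches: int = DEFAULT_MAX_MISMATCHES,
) -> pd.DataFrame:
    """circ x sample junction-read count table over per-sample unmapped pools."""
    refs = [
        build_pseudo_reference(c, bundle, read_length, min_overhang) for c in calls
    ]
    cols = {}
    for sample in unmapped_by_sample:
        counts = count_junction_reads(
            refs, unmapped_by_sample[sample], min_overhang, max_mismatches
        )
        cols[sample] = pd.Series(counts)
    df = pd.DataFrame(cols)
    df.index.name = "circ_id"
    return df.fillna(0).astype(int)


# ---------------------------------------------------------------------------
# Summaries
# ---------------------------------------------------------------------------


@dataclass
class SummaryStats:
    n_circ: int
    median_length: float
    lengths: list[int]
    read_count_histogram: dict[int, int]
    fraction_under_10_reads: float
    per_gene_counts: dict[str, int]
    n_single_circ_genes: int
    max_multiplicity_gene: tuple[str, int] | None
    total_backspliced_reads: int

    def to_json_dict(self) -> dict:
        return {
            "n_circ": self.n_circ,
            "median_length": self.median_length,
            "fraction_under_10_reads": self.fraction_under_10_reads,
            "n_single_circ_genes": self.n_single_circ_genes,
            "max_multiplicity_gene": list(self.max_multiplicity_gene)
            if self.max_multiplicity_gene
            else None,
            "total_backspliced_reads": self.total_backspliced_reads,
        }


def summarize_circ(
    calls: Sequence[CircCall], expression: pd.DataFrame | Mapping[str, int] | None = None
) -> SummaryStats:
    """Length, abundance and per-gene multiplicity summaries.

    ``expression`` may be a circ x sample DataFrame (reads summed over
    samples) or a circ -> count mapping; when None, detection support counts
    are used.
    """
    lengths = [c.exonic_length for c in calls]
    if expression is None:
        reads = {c.circ_id: c.n_backspliced_reads for c in calls}
    elif isinstance(expression, pd.DataFrame):
        reads = expression.sum(axis=1).to_dict()
    else:
        reads = dict(expression)
    per_gene: dict[str, int] = {}
    for c in calls:
        if c.host_genes:
            g = c.host_genes[0]  # multiplicity statistics use the first host
            per_gene[g] = per_gene.get(g, 0) + 1
    hist: dict[int, int] = {}
    for c in calls:
        n = int(reads.get(c.circ_id, 0))
        hist[n] = hist.get(n, 0) + 1
    n_under_10 = sum(v for k, v in hist.items() if k < 10)
    max_gene = max(per_gene.items(), key=lambda kv: (kv[1], kv[0])) if per_gene else None
    return SummaryStats(
        n_circ=len(calls),
        median_length=float(np.median(lengths)) if lengths else float("nan"),
        lengths=sorted(lengths),
        read_count_histogram=dict(sorted(hist.items())),
        fraction_under_10_reads=n_under_10 / len(calls) if calls else float("nan"),
        per_gene_counts=dict(sorted(per_gene.items())),
        n_single_circ_genes=sum(1 for v in per_gene.values() if v == 1),
        max_multiplicity_gene=max_gene,
        total_backspliced_reads=int(sum(reads.get(c.circ_id, 0) for c in calls)),
    )


def write_summary(stats: SummaryStats, path: str | Path) -> None:
    import json

    Path(path).write_text(json.dumps(stats.to_json_dict(), indent=2, sort_keys=True) + "\n")
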