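"""Read quality control: adaptor trimming and clean-read filters.

Raw single-end reads become "clean reads" by three rules applied in order:
3' adaptor removal, a minimum post-trim length floor, removal of reads with
more than 5% ambiguous bases (N), and removal of low-quality reads in which
more than 20% of bases fall below Phred 13.  Both fraction filters use strict
inequality (a read at exactly the threshold is retained) and are evaluated on
the trimmed read.
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path
from typing import Iterable, Iterator

# ---------------------------------------------------------------------------
# Records and parameters
# ---------------------------------------------------------------------------


@dataclass
class ReadRecord:
    """A single read: sequence over {A,C,G,T,N} plus per-base Phred scores."""

    read_id: str
    sequence: str
    qualities: list[int]

    def __post_init__(self) -> None:
        if len(self.sequence) != len(self.qualities):
            raise ValueError(
                f"read {self.read_id}: sequence length {len(self.sequence)} != "
                f"quality length {len(self.qualities)}"
            )


@dataclass(frozen=True)
class QcParams:
    adaptor: str = ""
    min_adaptor_overlap: int = 5
    max_adaptor_mismatches: int = 0
    max_n_fraction: float = 0.05
    low_q_threshold: int = 13
    max_low_q_fraction: float = 0.20
    min_length_after_trim: int = 20

    def __post_init__(self) -> None:
        if not (0 <= self.max_n_fraction <= 1 and 0 <= self.max_low_q_fraction <= 1):
            raise ValueError("fraction thresholds must lie in [0, 1]")


@dataclass
class QcReport:
    """Per-rule removal tallies; kept + removed sums to the input count."""

    n_input: int = 0
    n_kept: int = 0
    n_trimmed: int = 0          # reads that had an adaptor removed (not dropped)
    removed_short: int = 0
    removed_n_fraction: int = 0
    removed_low_quality: int = 0

    @property
    def n_removed(self) -> int:
        return self.removed_short + self.removed_n_fraction + self.removed_low_quality

    def to_tsv(self, path: str | Path) -> None:
        with open(path, "w") as fh:
            fh.write("metric\tcount\n")
            for k in (
                "n_input", "n_kept", "n_trimmed", "removed_short",
                "removed_n_fraction", "removed_low_quality",
            ):
                fh.write(f"{k}\t{getattr(self, k)}\n")


# ---------------------------------------------------------------------------
# FASTQ I/O (Phred+33)
# ---------------------------------------------------------------------------


def read_fastq(path: str | Path) -> Iterator[ReadRecord]:
    """Parse a Phred+33 FASTQ file into ReadRecords (pysam-backed)."""
    import pysam

    with pysam.FastxFile(str(path)) as fh:
        for rec in fh:
            seq = rec.sequence or ""
            qual = rec.quality or ""
            if len(seq) != len(qual):
                raise ValueError(
                    f"read {rec.name}: sequence/quality length mismatch "
                    f"({len(seq)} vs {len(qual)})"
                )
            yield ReadRecord(rec.name, seq.upper(), [ord(c) - 33 for c in qual])


def write_fastq(reads: Iterable[ReadRecord], path: str | Path) -> None:
    with open(path, "w") as fh:
        for r in reads:
            qual = "".join(chr(q + 33) for q in r.qualities)
            fh.write(f"@{r.read_id}\n{r.sequence}\n+\n{qual}\n")


# ---------------------------------------------------------------------------
# Filtering
# ---------------------------------------------------------------------------


def trim_adaptor(read: ReadRecord, params: QcParams) -> ReadRecord:
    """Remove a 3' adaptor: the leftmost suffix of the read matching a prefix
    of the adaptor with at least ``min_adaptor_overlap`` bases and at most
    ``max_adaptor_mismatches`` mismatches."""
    ad = params.adaptor.upper()
    if not ad:
        return read
    seq = read.sequence
    n = len(seq)
    for p in range(0, n - params.min_adaptor_overlap + 1):
        m = min(n - p, len(ad))
        mism = 0
        ok = True
        for i in range(m):
            if seq[p + i] != ad[i]:
                mism += 1
                if mism > params.max_adaptor_mismatches:
                    ok = False
                    break
        if ok:
            return ReadRecord(read.read_id, seq[:p], read.qualities[:p])
    return read


def filter_reads(
    reads: Iterable[ReadRecord], params: QcParams
) -> tuple[list[ReadRecord], QcReport]:
    """Apply trim -> length -> N-fraction -> quality-fraction, in that order.

    A read is removed iff its N fraction exceeds ``max_n_fraction`` or the
    fraction of bases with Phred < ``low_q_threshold`` exceeds
    ``max_low_q_fraction`` (both strict), or it is shorter than
    ``min_length_after_trim`` after adaptor removal.
    """
    report = QcReport()
    kept: list[ReadRecord] = []
    for read in reads:
        report.n_input += 1
        trimmed = trim_adaptor(read, params)
        if len(trimmed.sequence) < len(read.sequence):
            report.n_trimmed += 1
        n = len(trimmed.sequence)
        if n < params.min_length_after_trim:
            report.removed_short += 1
            continue
        if trimmed.sequence.count("N") / n > params.max_n_fraction:
            report.removed_n_fraction += 1
            continue
        n_low = sum(1 for q in trimmed.qualities if q < params.low_q_threshold)
        if n_low / n > params.max_low_q_fraction:
            report.removed_low_quality += 1
            continue
        report.n_kept += 1
        kept.append(trimmed)
    return kept, report
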