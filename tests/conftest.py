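"""Shared fixtures: synthetic study data generated once per session."""

from __future__ import annotations

import dataclasses

import pytest

import circprofiler as cp
from circprofiler import align, detect, qc


def to_read_records(sim_reads):
    return [
        qc.ReadRecord(rid, seq, [ord(c) - 33 for c in qual])
        for rid, seq, qual in sim_reads.reads
    ]


@pytest.fixture(scope="session")
def small_config():
    # compact two-chromosome genome for unit tests
    return dataclasses.replace(
        cp.SimConfig(), n_genes=12, n_chromosomes=2, chrom_length=60_000,
        circ_fraction=0.5, linear_depth=25,
    )


@pytest.fixture(scope="session")
def small_bundle(small_config):
    return cp.generate_genome(small_config)


@pytest.fixture(scope="session")
def small_index(small_bundle):
    return align.build_index(small_bundle)


@pytest.fixture(scope="session")
def simulated_study(tmp_path_factory):
    """A compact 3-vs-3 study with spiked genes, written to disk."""
    from circprofiler import sim

    root = tmp_path_factory.mktemp("study")
    cfg = dataclasses.replace(
        cp.SimConfig(), n_genes=16, n_chromosomes=2, chrom_length=80_000,
        circ_fraction=0.5, linear_depth=30, n_noise_reads=50,
    )
    bundle = cp.generate_genome(cfg)
    bundle.write_fasta(root / "genome.fa")
    bundle.write_gtf(root / "annotation.gtf")
    circles = cp.simulate_circles(bundle, cfg)
    sim.write_circle_truth(circles, root / "circ_truth.tsv")
    sim.write_known_bed(circles, root / "known.bed")
    spiked = {
        g.gene_id: fc
        for g, fc in zip(bundle.genes[:4], (8.0, 8.0, 0.125, 0.125))
    }
    sheet = sim.simulate_samples(bundle, circles, cfg, root / "reads", spiked_genes=spiked)
    return {
        "root": root, "config": cfg, "bundle": bundle, "circles": circles,
        "sheet": sheet, "spiked": spiked,
    }


@pytest.fixture(scope="session")
def standard_run():
    """The standard synthetic study: default config (seed 42, 3 x 100 kb,
    40 genes, 20 canonical circles with 2-30 junction reads, error-free),
    taken through QC, alignment and circRNA detection."""
    cfg = cp.SimConfig()
    bundle = cp.generate_genome(cfg)
    circles = cp.simulate_circles(bundle, cfg)
    sim_reads = cp.simulate_reads(bundle, circles, cfg)
    reads = to_read_records(sim_reads)
    kept, qc_report = qc.filter_reads(reads, qc.QcParams())
    index = align.build_index(bundle)
    mapped, unmapped = align.align_linear(kept, index, bundle, max_mismatches=0)
    scorer = detect.default_scorer(bundle)
    calls = detect.detect_circRNAs(unmapped, index, bundle, scorer=scorer)
    return {
        "config": cfg,
        "bundle": bundle,
        "circles": circles,
        "sim_reads": sim_reads,
        "reads": reads,
        "kept": kept,
        "qc_report": qc_report,
        "index": index,
        "mapped": mapped,
        "unmapped": unmapped,
        "scorer": scorer,
        "calls": calls,
    }
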