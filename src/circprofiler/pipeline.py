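"""End-to-end pipeline orchestration with a single JSON-configurable entry.

``run_all`` mirrors the analysis workflow: QC -> linear alignment ->
backsplice detection -> pseudo-circular quantification -> gene counting ->
differential expression (mRNA, lncRNA, circRNA separately) -> enrichment ->
condition co-expression networks.  All interchange is via files in the
output directory; a machine-readable run report records counts in and out of
every stage plus the seed, so two runs of the same config are byte-identical.
"""

from __future__ import annotations

import dataclasses
import json
from dataclasses import dataclass
from pathlib import Path
from typing import Any

import pandas as pd

from . import align as al
from . import de as de_mod
from . import detect as dt
from . import networks as nw
from . import qc as qc_mod
from . import quant as qt
from .sim import GenomeBundle


@dataclass
class PipelineConfig:
    """Paths and parameters for a full run; defaults are the standard
    operating points (min 2 reads, score >= 10, span <= 1 Mb, overhang >= 6,
    FC > 2 or < 0.5, FDR < 0.05, GO tree P < 0.01)."""

    genome_fasta: str
    gtf: str
    samples: list[dict[str, str]]  # {"sample":, "condition":, "fastq":}
    outdir: str
    known_bed: str | None = None
    gene_term_tsv: str | None = None
    dag_tsv: str | None = None
    seed: int = 0

    adaptor: str = ""
    max_mismatches: int = 0
    kmer_size: int = al.DEFAULT_K
    min_reads: int = dt.DEFAULT_MIN_READS
    min_score: float = dt.DEFAULT_MIN_SCORE
    max_span: int = dt.MAX_SPAN
    min_overhang: int = qt.DEFAULT_MIN_OVERHANG
    quant_max_mismatches: int = qt.DEFAULT_MAX_MISMATCHES
    fc_up: float = de_mod.FC_UP
    fc_down: float = de_mod.FC_DOWN
    max_fdr: float = de_mod.MAX_FDR
    go_p_cut: float = nw.GO_TREE_P_CUT
    coexp_r_cut: float = nw.COEXP_R_CUT
    coexp_p_cut: float = nw.COEXP_P_CUT

    @classmethod
    def from_json(cls, path: str | Path) -> "PipelineConfig":
        return cls(**json.loads(Path(path).read_text()))

    def validate(self) -> None:
        missing = [
            p for p in [self.genome_fasta, self.gtf, self.known_bed,
                        self.gene_term_tsv, self.dag_tsv]
            + [s["fastq"] for s in self.samples]
            if p is not None and not Path(p).exists()
        ]
        if missing:
            raise FileNotFoundError(f"missing input paths: {missing}")
        if not self.samples:
            raise ValueError("config lists no samples")
        if self.min_reads < 1 or self.min_overhang < 1 or self.kmer_size < 8:
            raise ValueError("parameter out of domain")


class StageError(RuntimeError):
    def __init__(self, stage: str, cause: Exception):
        super().__init__(f"stage {stage!r} failed: {cause}")
        self.stage = stage
        self.cause = cause


def run_all(config: PipelineConfig) -> dict[str, Any]:
    """Execute the whole pipeline; returns (and writes) the run report."""
    config.validate()
    outdir = Path(config.outdir)
    for sub in ("qc", "align", "circ", "de", "network"):
        (outdir / sub).mkdir(parents=True, exist_ok=True)
    report: dict[str, Any] = {"seed": config.seed, "stages": {}}

    def stage(name):
        def wrap(fn):
            try:
                return fn()
            except Exception as exc:  # partial outputs are retained
                raise StageError(name, exc) from exc
        return wrap

    # --- load reference
    bundle = stage("load_reference")(
        lambda: GenomeBundle.from_files(config.genome_fasta, config.gtf)
    )

    # --- QC
    clean_by_sample: dict[str, list[qc_mod.ReadRecord]] = {}
    qc_stats = {}
    params = qc_mod.QcParams(adaptor=config.adaptor)

    def _qc():
        for s in config.samples:
            reads = qc_mod.read_fastq(s["fastq"])
            kept, rep = qc_mod.filter_reads(reads, params)
            clean_by_sample[s["sample"]] = kept
            qc_mod.write_fastq(kept, outdir / "qc" / f"{s['sample']}.clean.fastq")
            rep.to_tsv(outdir / "qc" / f"{s['sample']}.qc_report.tsv")
            qc_stats[s["sample"]] = {"in": rep.n_input, "kept": rep.n_kept}
    stage("qc")(_qc)
    report["stages"]["qc"] = qc_stats

    # --- alignment
    index = stage("index")(lambda: al.build_index(bundle, k=config.kmer_size))
    mapped_by_sample: dict[str, list[al.LinearAlignment]] = {}
    unmapped_by_sample: dict[str, list[qc_mod.ReadRecord]] = {}

    def _align():
        for sample, reads in clean_by_sample.items():
            mapped, unmapped = al.align_linear(
                reads, index, bundle, max_mismatches=config.max_mismatches
            )
            mapped_by_sample[sample] = mapped
            unmapped_by_sample[sample] = unmapped
    stage("align")(_align)
    all_mapped = [a for m in mapped_by_sample.values() for a in m]
    region = al.annotate_regions(all_mapped, bundle)
    chrom = al.chromosome_tally(all_mapped)
    al.write_tally(region, outdir / "align" / "region_tally.tsv", key="region")
    al.write_tally(
        dict(sorted(chrom.items())), outdir / "align" / "chromosome_tally.tsv",
        key="chrom",
    )
    report["stages"]["align"] = {
        s: {"in": qc_stats[s]["kept"], "mapped": len(mapped_by_sample[s]),
            "unmapped": len(unmapped_by_sample[s])}
        for s in mapped_by_sample
    }

    # --- backsplice detection on the pooled unmapped reads
    pooled_unmapped = [r for u in unmapped_by_sample.values() for r in u]
    scorer = stage("splice_model")(lambda: dt.default_scorer(bundle))
    calls = stage("circ_detect")(
        lambda: dt.detect_circRNAs(
            pooled_unmapped, index, bundle, scorer=scorer,
            min_reads=config.min_reads, min_score=config.min_score,
            min_overhang=config.min_overhang, max_span=config.max_span,
        )
    )
    if config.known_bed:
        novelty = dt.compare_to_known(calls, config.known_bed)
    else:
        novelty = {"known": 0, "novel": len(calls)}
    dt.write_calls_bed(calls, outdir / "circ" / "calls.bed")
    report["stages"]["circ_detect"] = {
        "unmapped_in": len(pooled_unmapped), "calls": len(calls), **novelty
    }

    # --- quantification
    read_length = max(
        (len(r.sequence) for reads in clean_by_sample.values() for r in reads),
        default=100,
    )
    circ_counts = stage("circ_quant")(
        lambda: qt.quantify(
            calls, bundle, unmapped_by_sample, read_length,
            min_overhang=config.min_overhang,
            max_mismatches=config.quant_max_mismatches,
        )
    )
    circ_counts.to_csv(outdir / "circ" / "circ_counts.tsv", sep="\t")
    summary = qt.summarize_circ(calls, circ_counts)
    qt.write_summary(summary, outdir / "circ" / "summary.json")
    report["stages"]["circ_quant"] = {
        "circ": len(calls),
        "junction_reads": int(circ_counts.to_numpy().sum()) if len(calls) else 0,
    }

    # --- gene counting and differential expression
    conditions = {s["sample"]: s["condition"] for s in config.samples}
    gene_counts = {}
    for sample, alignments in mapped_by_sample.items():
        counts, _ = de_mod.count_features(alignments, bundle)
        gene_counts[sample] = counts
    biotypes = {g.gene_id: g.biotype for g in bundle.genes}
    matrix = de_mod.count_matrix(gene_counts, biotypes)
    matrix.to_csv(outdir / "de" / "gene_counts.tsv", sep="\t")

    cond_levels = sorted(set(conditions.values()))
    de_tables: dict[str, pd.DataFrame] = {}
    can_de = (
        len(cond_levels) == 2
        and all(sum(1 for c in conditions.values() if c == lv) >= 2 for lv in cond_levels)
    )
    if can_de:
        pair = ("tumor", "normal") if set(cond_levels) == {"tumor", "normal"} else (
            cond_levels[1], cond_levels[0]
        )

        def _de():
            for biotype in ("mRNA", "lncRNA"):
                feats = [f for f in matrix.index if biotypes.get(f) == biotype]
                sub = matrix.loc[feats]
                sub = sub[sub.sum(axis=1) > 0]
                if len(sub) == 0:
                    continue
                table = _run_de(sub, conditions, config, pair)
                table.to_csv(outdir / "de" / f"{biotype.lower()}_de.tsv", sep="\t")
                de_tables[biotype] = table
            if len(calls) and circ_counts.to_numpy().sum() > 0:
                sub = circ_counts[circ_counts.sum(axis=1) > 0]
                if len(sub):
                    table = _run_de(sub, conditions, config, pair)
                    table.to_csv(outdir / "de" / "circrna_de.tsv", sep="\t")
                    de_tables["circRNA"] = table
        stage("de")(_de)
    report["stages"]["de"] = {
        bt: {"tested": len(t), "up": int((t["status"] == "up").sum()),
             "down": int((t["status"] == "down").sum())}
        for bt, t in de_tables.items()
    }

    # --- enrichment
    if config.gene_term_tsv and "mRNA" in de_tables:
        def _enrich():
            coll = nw.GeneSetCollection.from_tsv(config.gene_term_tsv, config.dag_tsv)
            table = de_tables["mRNA"]
            background = [g for g in matrix.index if biotypes.get(g) == "mRNA"]
            rows = []
            for direction in ("up", "down"):
                query = [
                    g for g in table.index[table["status"] == direction]
                    if g in set(background)
                ]
                if query:
                    rows += nw.fisher_enrichment(query, coll, background, direction)
            nw.enrichment_table(rows).to_csv(
                outdir / "de" / "enrichment.tsv", sep="\t", index=False
            )
            if coll.dag_parents:
                tree = nw.go_tree(rows, coll, p_cut=config.go_p_cut)
                nw.write_edge_list(tree.to_undirected(), outdir / "network" / "go_tree.tsv")
            report["stages"]["enrichment"] = {"terms_tested": len(rows)}
        stage("enrichment")(_enrich)

    # --- co-expression networks
    if can_de and "mRNA" in de_tables:
        def _network():
            de_feats = sorted(
                f for bt, t in de_tables.items() if bt != "circRNA"
                for f in t.index[t["status"].isin(["up", "down"])]
            )
            if len(de_feats) < 2:
                report["stages"]["network"] = {"note": "fewer than 2 DE features"}
                return
            factors = de_mod.size_factors(matrix, pseudocount=0.5)
            normed = nw.normalize_for_network(matrix.loc[de_feats], factors)
            nets = {}
            for level in cond_levels:
                samples = [s for s, c in conditions.items() if c == level]
                if len(samples) < 3:
                    continue
                net = nw.coexpnet_build(
                    normed, samples, condition=level,
                    r_cut=config.coexp_r_cut, p_cut=config.coexp_p_cut,
                )
                nets[level] = net
                nw.write_edge_list(net.graph, outdir / "network" / f"coexp_{level}.tsv")
            if len(nets) == 2:
                a, b = (nets[lv] for lv in cond_levels)
                regulators = nw.core_regulators(a, b, top_k=10)
                with open(outdir / "network" / "core_regulators.tsv", "w") as fh:
                    fh.write("gene\tdegree_" + cond_levels[0] + "\tdegree_" + cond_levels[1] + "\n")
                    for g, d_a, d_b in regulators:
                        fh.write(f"{g}\t{d_a}\t{d_b}\n")
                report["stages"]["network"] = {
                    lv: {"nodes": nets[lv].graph.number_of_nodes(),
                         "edges": nets[lv].graph.number_of_edges()}
                    for lv in nets
                }
        stage("network")(_network)

    report_path = outdir / "report.json"
    report_path.write_text(json.dumps(report, indent=2, sort_keys=True) + "\n")
    return report


def _run_de(matrix, conditions, config: PipelineConfig, pair) -> pd.DataFrame:
    factors = de_mod.size_factors(matrix, pseudocount=0.0) if (
        (matrix.to_numpy() > 0).all(axis=1).any()
    ) else de_mod.size_factors(matrix, pseudocount=0.5)
    disp = de_mod.estimate_dispersion(matrix, factors, conditions)
    results = de_mod.nb_test(matrix, factors, disp, conditions, condition_pair=pair)
    return de_mod.de_table(
        de_mod.filter_de(
            results, fc_up=config.fc_up, fc_down=config.fc_down, max_fdr=config.max_fdr
        )
    )
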