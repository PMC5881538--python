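"""Functional enrichment, GO trees, pathway networks and co-expression cores.

Enrichment is a one-sided Fisher (hypergeometric upper-tail) test of a query
gene list against term gene sets drawn from a user-supplied flat TSV mapping,
BH-corrected across terms.  Significant GO terms (P < 0.01) plus their
ancestors induce a GO tree over the supplied DAG.  Enriched pathways form a
network with shared-DE-gene Jaccard edge weights.  Per-condition Pearson
co-expression networks support degree centrality, W-core extraction (the
k-core with k = W) and differential core-regulator ranking by between-
condition degree differences.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Mapping, Sequence

import networkx as nx
import numpy as np
import pandas as pd
from scipy import stats

from .de import bh_fdr

GO_TREE_P_CUT = 0.01
COEXP_R_CUT = 0.9
COEXP_P_CUT = 0.05


# ---------------------------------------------------------------------------
# Gene sets
# ---------------------------------------------------------------------------


@dataclass
class GeneSetCollection:
    """Term gene sets plus optional DAG (GO) or relation (pathway) edges."""

    terms: dict[str, set[str]]
    names: dict[str, str] = field(default_factory=dict)
    dag_parents: dict[str, set[str]] = field(default_factory=dict)

    def __post_init__(self) -> None:
        dag = nx.DiGraph()
        for child, parents in self.dag_parents.items():
            for p in parents:
                dag.add_edge(child, p)
        if dag.number_of_edges() and not nx.is_directed_acyclic_graph(dag):
            raise ValueError("term hierarchy contains a cycle")

    @classmethod
    def from_tsv(
        cls, gene_term_tsv: str | Path, dag_tsv: str | Path | None = None
    ) -> "GeneSetCollection":
        """gene_term_tsv: columns gene, term[, name]; dag_tsv: child, parent."""
        df = pd.read_csv(gene_term_tsv, sep="\t")
        terms: dict[str, set[str]] = {}
        names: dict[str, str] = {}
        for row in df.itertuples(index=False):
            terms.setdefault(str(row.term), set()).add(str(row.gene))
            if hasattr(row, "name"):
                names[str(row.term)] = str(row.name)
        parents: dict[str, set[str]] = {}
        if dag_tsv is not None:
            dd = pd.read_csv(dag_tsv, sep="\t")
            for row in dd.itertuples(index=False):
                parents.setdefault(str(row.child), set()).add(str(row.parent))
        return cls(terms=terms, names=names, dag_parents=parents)


# ---------------------------------------------------------------------------
# Fisher enrichment
# ---------------------------------------------------------------------------


@dataclass
class EnrichmentRow:
    term: str
    overlap: int       # k
    term_size: int     # K
    query_size: int    # n
    background_size: int  # N
    p_value: float
    fdr: float = float("nan")
    direction: str = ""


def fisher_enrichment(
    query: Iterable[str],
    collection: GeneSetCollection,
    background: Iterable[str],
    direction: str = "",
) -> list[EnrichmentRow]:
    """One-sided over-representation test per term with BH correction.

    p = P[X >= k] for X ~ Hypergeom(N, K, n), i.e. the Fisher exact test of
    the 2x2 query/term table.  Terms with no background annotation (K = 0)
    are skipped; query genes missing from the background raise.
    """
    query = set(query)
    background = set(background)
    missing = sorted(query - background)
    if missing:
        raise ValueError(f"query genes absent from background: {missing[:10]}")
    n = len(query)
    N = len(background)
    rows: list[EnrichmentRow] = []
    for term in sorted(collection.terms):
        genes = collection.terms[term] & background
        K = len(genes)
        if K == 0:
            continue
        k = len(genes & query)
        p = float(stats.hypergeom.sf(k - 1, N, K, n)) if k > 0 else 1.0
        rows.append(
            EnrichmentRow(
                term=term, overlap=k, term_size=K, query_size=n,
                background_size=N, p_value=min(p, 1.0), direction=direction,
            )
        )
    if rows:
        for row, q in zip(rows, bh_fdr([r.p_value for r in rows])):
            row.fdr = float(q)
    return rows


def enrichment_table(rows: Sequence[EnrichmentRow]) -> pd.DataFrame:
    return pd.DataFrame(
        [
            {
                "term": r.term, "overlap": r.overlap, "term_size": r.term_size,
                "query_size": r.query_size, "background_size": r.background_size,
                "p_value": r.p_value, "fdr": r.fdr, "direction": r.direction,
            }
            for r in rows
        ]
    )


# ---------------------------------------------------------------------------
# GO tree
# ---------------------------------------------------------------------------


def go_tree(
    enrichment: Sequence[EnrichmentRow],
    collection: GeneSetCollection,
    p_cut: float = GO_TREE_P_CUT,
) -> nx.DiGraph:
    """Induced DAG over significant terms (p < p_cut) and all their ancestors.

    Node attributes: ``significant`` (bool) and ``direction`` (comma-joined
    directions of the significant enrichment rows hitting the node, for
    direction-partitioned queries).  Edges point child -> parent.
    """
    dag = nx.DiGraph()
    for child, parents in collection.dag_parents.items():
        for p in parents:
            dag.add_edge(child, p)
    if dag.number_of_edges() and not nx.is_directed_acyclic_graph(dag):
        raise ValueError("term hierarchy contains a cycle")
    significant: dict[str, set[str]] = {}
    for row in enrichment:
        if row.p_value < p_cut:
            significant.setdefault(row.term, set())
            if row.direction:
                significant[row.term].add(row.direction)
    keep: set[str] = set(significant)
    for term in significant:
        if term in dag:
            keep |= nx.descendants(dag, term)  # ancestors: edges run child->parent
    tree = dag.subgraph(keep).copy()
    tree.add_nodes_from(keep - set(tree.nodes))
    for node in tree.nodes:
        tree.nodes[node]["significant"] = node in significant
        tree.nodes[node]["direction"] = ",".join(sorted(significant.get(node, ())))
    return tree


# ---------------------------------------------------------------------------
# Pathway network
# ---------------------------------------------------------------------------


def pathway_network(
    enriched: Sequence[EnrichmentRow],
    collection: GeneSetCollection,
    de_status: Mapping[str, str],
    top_k: int = 4,
) -> tuple[nx.Graph, list[str]]:
    """Network of enriched pathways linked by shared DE genes.

    Node direction is the majority up/down status of the pathway's DE genes;
    an edge joins two pathways iff they share at least one DE gene, weighted
    by the Jaccard index of their DE-gene sets.  Returns (graph, core
    pathways = the ``top_k`` highest-degree nodes).
    """
    de_genes = {g for g, s in de_status.items() if s in ("up", "down")}
    graph = nx.Graph()
    sets: dict[str, set[str]] = {}
    for row in enriched:
        genes = collection.terms.get(row.term, set()) & de_genes
        sets[row.term] = genes
        ups = sum(1 for g in genes if de_status.get(g) == "up")
        downs = sum(1 for g in genes if de_status.get(g) == "down")
        graph.add_node(row.term, direction="up" if ups >= downs else "down",
                       n_de_genes=len(genes))
    terms = sorted(sets)
    for i, t1 in enumerate(terms):
        for t2 in terms[i + 1:]:
            shared = sets[t1] & sets[t2]
            if shared:
                union = sets[t1] | sets[t2]
                graph.add_edge(t1, t2, weight=len(shared) / len(union),
                               shared=len(shared))
    degree = dict(graph.degree)
    core = sorted(degree, key=lambda t: (-degree[t], t))[:top_k]
    return graph, core


# ---------------------------------------------------------------------------
# Co-expression networks
# ---------------------------------------------------------------------------


@dataclass
class ConditionNetwork:
    condition: str
    graph: nx.Graph

    @property
    def nodes(self) -> list[str]:
        return sorted(self.graph.nodes)


def normalize_for_network(counts: pd.DataFrame, factors: pd.Series) -> pd.DataFrame:
    """Size-factor-normalized log2(x + 1) counts (Pearson-stabilizing)."""
    return np.log2(counts.div(factors, axis=1) + 1.0)


def coexpnet_build(
    matrix: pd.DataFrame,
    samples: Sequence[str],
    condition: str = "",
    r_cut: float = COEXP_R_CUT,
    p_cut: float = COEXP_P_CUT,
) -> ConditionNetwork:
    """Pearson co-expression network over one condition's samples.

    Every feature pair is scored by Pearson r across the condition's samples;
    an edge is kept iff |r| >= r_cut and its BH-adjusted t-distribution
    p-value (df = n - 2) is <= p_cut.  Zero-variance features are excluded
    with a warning.  Requires >= 3 samples (df > 0).
    """
    samples = list(samples)
    if len(samples) < 3:
        raise ValueError("correlation significance needs >= 3 samples (df = n - 2 > 0)")
    sub = matrix[samples]
    var = sub.var(axis=1)
    dropped = var[var == 0].index
    if len(dropped):
        warnings.warn(
            f"excluding {len(dropped)} zero-variance features from the "
            f"{condition or 'condition'} network"
        )
    sub = sub.loc[var > 0]
    features = list(sub.index)
    graph = nx.Graph()
    graph.add_nodes_from(features)
    if len(features) >= 2:
        n = len(samples)
        r = np.corrcoef(sub.to_numpy())
        iu = np.triu_indices(len(features), k=1)
        rv = np.clip(r[iu], -1.0, 1.0)
        with np.errstate(divide="ignore"):
            t = rv * np.sqrt((n - 2) / np.maximum(1.0 - rv**2, 1e-300))
        p = 2.0 * stats.t.sf(np.abs(t), df=n - 2)
        q = bh_fdr(np.minimum(p, 1.0))
        for (i, j, rij, qij, pij) in zip(iu[0], iu[1], rv, q, p):
            if abs(rij) >= r_cut and qij <= p_cut:
                graph.add_edge(features[i], features[j],
                               r=float(rij), p_value=float(pij), q=float(qij))
    return ConditionNetwork(condition=condition, graph=graph)


def degree_centrality(network: ConditionNetwork | nx.Graph) -> dict[str, int]:
    """Degree = number of incident edges, per node."""
    g = network.graph if isinstance(network, ConditionNetwork) else network
    return {n: int(d) for n, d in g.degree}


def w_core(network: ConditionNetwork | nx.Graph, w: int) -> nx.Graph:
    """Maximal subgraph in which every node has >= w neighbours inside it
    (the k-core with k = w), via networkx's iterative pruning."""
    if w < 0:
        raise ValueError("W must be >= 0")
    g = network.graph if isinstance(network, ConditionNetwork) else network
    g = nx.Graph(g)  # k_core rejects graphs with self-loops; ours have none
    return nx.k_core(g, k=w)


def core_regulators(
    network_a: ConditionNetwork | nx.Graph,
    network_b: ConditionNetwork | nx.Graph,
    top_k: int = 10,
) -> list[tuple[str, int, int]]:
    """Nodes ranked by |degree_A - degree_B| over the shared node universe.

    Missing nodes count as degree 0; ties break by the larger of the two
    degrees, then lexicographic id.  Returns (node, degree_A, degree_B)."""
    da = degree_centrality(network_a)
    db = degree_centrality(network_b)
    universe = set(da) | set(db)
    ranked = sorted(
        universe,
        key=lambda n: (
            -abs(da.get(n, 0) - db.get(n, 0)),
            -max(da.get(n, 0), db.get(n, 0)),
            n,
        ),
    )
    return [(n, da.get(n, 0), db.get(n, 0)) for n in ranked[:top_k]]


def write_edge_list(graph: nx.Graph, path: str | Path) -> None:
    with open(path, "w") as fh:
        fh.write("source\ttarget\tweight\n")
        for u, v, data in sorted(graph.edges(data=True)):
            w = data.get("weight", data.get("r", 1.0))
            fh.write(f"{u}\t{v}\t{w:.6f}\n")
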