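"""Gene-gene co-occurrence: Jaccard distance, HMI, dendrograms, communities.

Two genes that keep appearing in the same published lists may be functionally
related or may simply ride the same waves of attention; the *historical
mutual information* (HMI) between their presence/absence patterns captures
both without distinguishing them. Genes are linked when the HMI distance
(1 - HMI) is at or below a threshold and grouped with the Girvan-Newman
algorithm, returning the maximum-modularity partition along the removal
sequence.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from typing import Iterable, Literal, Mapping, Sequence

import networkx as nx
import numpy as np
import pandas as pd
from scipy.cluster.hierarchy import linkage, to_tree
from scipy.spatial.distance import squareform

from metascreen.occurrence import OccurrenceMatrix

HmiNorm = Literal["sum", "sqrt"]


def jaccard_distance(a: np.ndarray, b: np.ndarray) -> float:
    """1 - intersection/union of the list-index sets of two presence vectors."""
    a = np.asarray(a, dtype=bool)
    b = np.asarray(b, dtype=bool)
    if a.shape != b.shape:
        raise ValueError("presence vectors must have equal length")
    if not a.any() or not b.any():
        raise ValueError("Jaccard distance undefined for all-zero vectors")
    union = np.logical_or(a, b).sum()
    inter = np.logical_and(a, b).sum()
    return 1.0 - inter / union


def _entropy(p: np.ndarray) -> float:
    p = p[p > 0]
    return float(-(p * np.log(p)).sum())


def hmi(a: np.ndarray, b: np.ndarray, *, norm: HmiNorm = "sum") -> float:
    """Symmetric normalized mutual information of two binary vectors.

    From the 2x2 contingency over lists: I(A;B) normalized by
    2I/(H_A + H_B) (``sum``, default) or I/sqrt(H_A * H_B) (``sqrt``).
    Returns 0 when the chosen denominator vanishes (constant vectors).
    """
    a = np.asarray(a, dtype=bool)
    b = np.asarray(b, dtype=bool)
    if a.shape != b.shape:
        raise ValueError("presence vectors must have equal length")
    n = a.size
    if n == 0:
        raise ValueError("empty vectors")
    counts = np.array(
        [
            [np.sum(~a & ~b), np.sum(~a & b)],
            [np.sum(a & ~b), np.sum(a & b)],
        ],
        dtype=float,
    )
    joint = counts / n
    pa = joint.sum(axis=1)
    pb = joint.sum(axis=0)
    ha, hb = _entropy(pa), _entropy(pb)
    info = 0.0
    for i in range(2):
        for j in range(2):
            if joint[i, j] > 0:
                info += joint[i, j] * np.log(joint[i, j] / (pa[i] * pb[j]))
    info = max(info, 0.0)
    if norm == "sum":
        denom = ha + hb
        value = 2.0 * info / denom if denom > 0 else 0.0
    elif norm == "sqrt":
        denom = np.sqrt(ha * hb)
        value = info / denom if denom > 0 else 0.0
    else:
        raise ValueError(f"unknown HMI normalization {norm!r}")
    return float(min(value, 1.0))


@dataclass
class Dendrogram:
    """Average-linkage tree over labeled items, serializable to Newick."""

    labels: list[str]
    linkage_matrix: np.ndarray  # scipy linkage format

    def merge_heights(self) -> np.ndarray:
        return self.linkage_matrix[:, 2].copy()

    def to_newick(self) -> str:
        tree = to_tree(self.linkage_matrix)

        def _fmt(node, parent_height: float) -> str:
            length = parent_height - node.dist
            if node.is_leaf():
                return f"{self.labels[node.id]}:{length:.6g}"
            left = _fmt(node.left, node.dist)
            right = _fmt(node.right, node.dist)
            return f"({left},{right}):{length:.6g}"

        left = _fmt(tree.left, tree.dist)
        right = _fmt(tree.right, tree.dist)
        return f"({left},{right});"


def average_linkage_tree(
    d: np.ndarray, labels: Sequence[str] | None = None
) -> Dendrogram:
    """UPGMA agglomeration of a symmetric zero-diagonal distance matrix."""
    d = np.asarray(d, dtype=float)
    if d.ndim != 2 or d.shape[0] != d.shape[1]:
        raise ValueError("distance matrix must be square")
    if not np.allclose(d, d.T, atol=1e-12):
        raise ValueError("distance matrix must be symmetric")
    if not np.allclose(np.diag(d), 0.0, atol=1e-12):
        raise ValueError("distance matrix must have a zero diagonal")
    if labels is None:
        labels = [str(i) for i in range(d.shape[0])]
    if len(labels) != d.shape[0]:
        raise ValueError("label count does not match matrix size")
    z = linkage(squareform(d, checks=False), method="average")
    return Dendrogram(labels=list(labels), linkage_matrix=z)


@dataclass
class CooccurrenceGraph:
    """HMI-weighted gene graph with an optional community partition."""

    graph: nx.Graph
    threshold: float
    communities: list[frozenset[str]] = field(default_factory=list)

    @property
    def nodes(self) -> list[str]:
        return sorted(self.graph.nodes)

    def community_sizes(self) -> list[int]:
        return sorted((len(c) for c in self.communities), reverse=True)


def build_hmi_graph(
    m: OccurrenceMatrix,
    genes: Iterable[str] | None = None,
    threshold: float = 0.9,
    *,
    norm: HmiNorm = "sum",
) -> CooccurrenceGraph:
    """Link gene pairs whose HMI distance (1 - HMI) is <= *threshold*."""
    if not (0.0 < threshold <= 1.0):
        raise ValueError(f"threshold must be in (0, 1], got {threshold}")
    gene_list = sorted(genes) if genes is not None else list(m.gene_ids)
    idx = m.gene_index(gene_list)
    graph = nx.Graph()
    graph.add_nodes_from(gene_list)
    rows = m.incidence[idx]
    for i in range(len(gene_list)):
        for j in range(i + 1, len(gene_list)):
            w = hmi(rows[i], rows[j], norm=norm)
            if 1.0 - w <= threshold:
                graph.add_edge(gene_list[i], gene_list[j], weight=w)
    return CooccurrenceGraph(graph=graph, threshold=threshold)


def _max_betweenness_edge(graph: nx.Graph) -> tuple:
    eb = nx.edge_betweenness_centrality(graph)
    best = max(eb.values())
    candidates = [tuple(sorted(e)) for e, v in eb.items() if v >= best - 1e-12]
    return min(candidates)


def girvan_newman(cg: CooccurrenceGraph | nx.Graph) -> list[frozenset[str]]:
    """Max-modularity partition over the Girvan-Newman removal sequence.

    Edges of highest betweenness (recomputed after each removal, unweighted
    topology, lexicographic tie-break) are removed one by one; the connected
    components at each step form candidate partitions, and the one maximizing
    weighted modularity on the original graph wins. Isolated nodes end up as
    singletons; an empty graph yields an empty partition.
    """
    graph = cg.graph if isinstance(cg, CooccurrenceGraph) else cg
    if graph.number_of_nodes() == 0:
        return []
    if graph.number_of_edges() == 0:
        return [frozenset([node]) for node in sorted(graph.nodes)]
    work = graph.copy()
    best_partition = [frozenset(c) for c in nx.connected_components(graph)]
    best_q = nx.community.modularity(graph, best_partition, weight="weight")
    while work.number_of_edges() > 0:
        work.remove_edge(*_max_betweenness_edge(work))
        parts = [frozenset(c) for c in nx.connected_components(work)]
        q = nx.community.modularity(graph, parts, weight="weight")
        if q > best_q + 1e-12:
            best_q = q
            best_partition = parts
    return sorted(best_partition, key=lambda c: (-len(c), min(c)))


def annotate_communities(
    partition: Sequence[frozenset[str]],
    metadata: pd.DataFrame | Mapping[str, Mapping] | None = None,
) -> pd.DataFrame:
    """Join community labels with per-gene metadata flags.

    Metadata may be a mapping keyed by gene id or a DataFrame with a ``gene``
    column. Genes in the metadata but not in the partition trigger a warning;
    duplicate metadata rows keep the last occurrence (with a warning).
    """
    rows = []
    for cid, comm in enumerate(partition):
        for gene in sorted(comm):
            rows.append({"gene": gene, "community": cid})
    table = pd.DataFrame(rows, columns=["gene", "community"])
    if metadata is None:
        return table
    if isinstance(metadata, pd.DataFrame):
        if "gene" not in metadata.columns:
            raise ValueError("metadata DataFrame needs a 'gene' column")
        if metadata["gene"].duplicated().any():
            warnings.warn("duplicate metadata keys; keeping the last occurrence")
            metadata = metadata.drop_duplicates("gene", keep="last")
        meta = {str(r["gene"]): {k: r[k] for k in metadata.columns if k != "gene"}
                for _, r in metadata.iterrows()}
    else:
        meta = {str(k): dict(v) for k, v in metadata.items()}
    known = set(table["gene"])
    unknown = sorted(set(meta) - known)
    if unknown:
        warnings.warn(f"metadata for genes absent from the partition: {unknown}")
    for key in sorted({k for v in meta.values() for k in v}):
        table[key] = [meta.get(g, {}).get(key) for g in table["gene"]]
    return table


def export_partition(table: pd.DataFrame, path: str) -> None:
    table.to_csv(path, sep="\t", index=False)


def export_graph(cg: CooccurrenceGraph, graphml_path: str, tsv_path: str) -> None:
    nx.write_graphml(cg.graph, graphml_path)
    records = [
        {"gene_a": u, "gene_b": v, "hmi": d.get("weight", 1.0)}
        for u, v, d in sorted(cg.graph.edges(data=True))
    ]
    pd.DataFrame(records, columns=["gene_a", "gene_b", "hmi"]).to_csv(
        tsv_path, sep="\t", index=False
    )
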