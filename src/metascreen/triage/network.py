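"""Aggregate interaction calls into an exportable network."""

from __future__ import annotations

from pathlib import Path
from typing import Mapping, Sequence

import networkx as nx
import pandas as pd

from metascreen.triage.models import InteractionCall


def build_network(
    calls: Sequence[InteractionCall],
    evidence: Mapping[tuple[str, str], Mapping] | None = None,
) -> nx.Graph:
    """Nodes are proteins (role: regulator/candidate/both); edges carry calls.

    ``evidence`` may attach extra per-pair attributes (e.g. experimental
    support flag or a concordance verdict). Duplicate pairs are an error.
    """
    evidence = evidence or {}
    graph = nx.Graph()
    seen = set()
    for call in calls:
        bait, prey = call.pair_id
        key = (bait, prey)
        if key in seen or (prey, bait) in seen:
            raise ValueError(f"duplicate interaction pair {key}")
        seen.add(key)
        for node, role in ((bait, "regulator"), (prey, "candidate")):
            if node in graph and graph.nodes[node]["role"] != role:
                graph.nodes[node]["role"] = "both"
            elif node not in graph:
                graph.add_node(node, role=role)
        attrs = {
            "ranking": float(call.ranking),
            "area_norm": float(call.area_norm),
            "n_bait": int(call.n_bait),
            "n_prey": int(call.n_prey),
            "passes_v1": bool(call.passes_v1),
            "passes_v2": bool(call.passes_v2),
        }
        extra = evidence.get(key) or evidence.get((prey, bait)) or {}
        attrs.update({k: v for k, v in extra.items()})
        graph.add_edge(bait, prey, **attrs)
    return graph


def export_network(
    calls: Sequence[InteractionCall],
    graphml_path: str | Path,
    tsv_path: str | Path,
    evidence: Mapping[tuple[str, str], Mapping] | None = None,
) -> nx.Graph:
    """Write GraphML and an edge-list TSV; returns the graph."""
    graph = build_network(calls, evidence)
    nx.write_graphml(graph, str(graphml_path))
    records = []
    for u, v, data in sorted(graph.edges(data=True)):
        row = {"bait": u, "prey": v}
        row.update(data)
        records.append(row)
    columns = ["bait", "prey", "ranking", "area_norm", "n_bait", "n_prey",
               "passes_v1", "passes_v2"]
    df = pd.DataFrame(records)
    if not df.empty:
        ordered = [c for c in columns if c in df.columns]
        ordered += [c for c in df.columns if c not in ordered]
        df = df[ordered]
    else:
        df = pd.DataFrame(columns=columns)
    df.to_csv(tsv_path, sep="\t", index=False)
    return graph
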