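"""Pathway over-representation and the gene-tissue-metabolite network.

ORA is the one-sided hypergeometric upper-tail test of a selected feature
set against annotated pathway sets, BH-corrected across pathways (the
standard computation behind web enrichment services).  The association
network is tripartite: gene nodes link to the tissue(s) they mark, tissue
nodes link to their marker metabolites/lipids; edge weight defaults to
|log2 fold change| and a node's connection degree is its incident weight
sum.
"""

from __future__ import annotations

import json
from pathlib import Path

import networkx as nx
import numpy as np
import pandas as pd
from scipy.stats import hypergeom

from .markers import adjust_bh

__all__ = [
    "ora_hypergeom",
    "build_association_network",
    "export_sankey",
    "load_sankey",
]

ENRICHMENT_COLUMNS = ["pathway_id", "N", "K", "n", "overlap", "p_value", "q_value"]


def ora_hypergeom(
    selected_set,
    universe,
    pathway_sets: dict,
) -> pd.DataFrame:
    """Hypergeometric over-representation of ``selected_set`` per pathway.

    p = P(X >= x) with X ~ Hypergeom(N = |universe|, K = |pathway ∩
    universe|, n = |selected|); pathways with no universe members are
    skipped (recorded in ``DataFrame.attrs['skipped']``); q is BH across
    the tested pathways; rows sorted by p (ties by pathway id).
    """
    uni = set(universe)
    if not uni:
        raise ValueError("invalid-argument: empty universe")
    selected = set(selected_set) & uni
    if not set(selected_set) <= uni:
        raise ValueError("selected set must be a subset of the universe")
    N, n = len(uni), len(selected)
    rows, skipped = [], []
    for pid in sorted(pathway_sets, key=str):
        members = set(pathway_sets[pid]) & uni
        K = len(members)
        if K == 0:
            skipped.append(pid)
            continue
        x = len(selected & members)
        p = float(hypergeom.sf(x - 1, N, K, n)) if x > 0 else 1.0
        rows.append((pid, N, K, n, x, min(p, 1.0)))
    out = pd.DataFrame(rows, columns=ENRICHMENT_COLUMNS[:-1])
    out["q_value"] = adjust_bh(out["p_value"].to_numpy()) if len(out) else []
    out = out.sort_values(["p_value", "pathway_id"], ignore_index=True)
    out.attrs["skipped"] = skipped
    return out


def build_association_network(
    gene_markers: pd.DataFrame,
    met_markers: pd.DataFrame,
    weight: str = "abs_log2fc",
) -> nx.Graph:
    """Tripartite gene-tissue-metabolite association network.

    Both marker tables must already be screened (genes: FC >= 2 and
    p < 0.05; metabolites/lipids: FC >= 1.5) and carry ``feature_id``,
    ``group`` (the tissue) and ``log2_fc``.  One tissue node per group with
    at least one marker on either side; an edge per marker, weighted by
    |log2FC| (or 1.0 with ``weight="unit"``).  Node attribute ``degree``
    is the incident weight sum.
    """
    if weight not in ("abs_log2fc", "unit"):
        raise ValueError(f"unknown weight scheme {weight!r}")
    g = nx.Graph()

    def add_edges(table: pd.DataFrame, kind: str) -> None:
        for _, row in table.iterrows():
            w = abs(float(row["log2_fc"])) if weight == "abs_log2fc" else 1.0
            if w <= 0:
                continue
            tissue = str(row["group"])
            feat = str(row["feature_id"])
            g.add_node(tissue, kind="tissue")
            g.add_node(feat, kind=kind)
            g.add_edge(feat, tissue, weight=w)

    add_edges(gene_markers, "gene")
    add_edges(met_markers, "metabolite_or_lipid")
    degrees = dict(g.degree(weight="weight"))
    nx.set_node_attributes(g, degrees, "degree")
    return g


def export_sankey(network: nx.Graph, path: str | Path) -> dict[str, Path]:
    """Write node/link TSV tables and a Sankey-ready JSON document.

    Nodes: ``id, type, degree``; links: ``source, target, weight`` with
    gene->tissue and tissue->metabolite orientation.  Deterministic row
    order (type, then id).
    """
    path = Path(path)
    path.mkdir(parents=True, exist_ok=True)
    type_rank = {"gene": 0, "tissue": 1, "metabolite_or_lipid": 2}
    nodes = sorted(
        network.nodes(data=True),
        key=lambda kv: (type_rank.get(kv[1].get("kind", ""), 9), str(kv[0])),
    )
    node_rows = [
        {"id": str(n), "type": d.get("kind", ""), "degree": float(d.get("degree", 0.0))}
        for n, d in nodes
    ]
    links = []
    for u, v, d in network.edges(data=True):
        # orient away from the tissue layer: gene -> tissue -> metabolite
        u_kind = network.nodes[u].get("kind")
        if u_kind == "tissue":
            src, dst = (v, u) if network.nodes[v].get("kind") == "gene" else (u, v)
        else:
            src, dst = (u, v) if u_kind == "gene" else (v, u)
        links.append({"source": str(src), "target": str(dst),
                      "weight": float(d.get("weight", 1.0))})
    links.sort(key=lambda l: (l["source"], l["target"]))
    nodes_df = pd.DataFrame(node_rows, columns=["id", "type", "degree"])
    links_df = pd.DataFrame(links, columns=["source", "target", "weight"])
    nodes_path = path / "sankey_nodes.tsv"
    links_path = path / "sankey_links.tsv"
    json_path = path / "sankey.json"
    nodes_df.to_csv(nodes_path, sep="\t", index=False, float_format="%.10g")
    links_df.to_csv(links_path, sep="\t", index=False, float_format="%.10g")
    with open(json_path, "w") as fh:
        json.dump({"nodes": node_rows, "links": links}, fh, indent=1, sort_keys=True)
        fh.write("\n")
    return {"nodes": nodes_path, "links": links_path, "json": json_path}


def load_sankey(path: str | Path) -> nx.Graph:
    """Rebuild the association network from an exported Sankey directory."""
    path = Path(path)
    with open(path / "sankey.json") as fh:
        doc = json.load(fh)
    g = nx.Graph()
    for node in doc["nodes"]:
        g.add_node(node["id"], kind=node["type"], degree=node["degree"])
    for link in doc["links"]:
        g.add_edge(link["source"], link["target"], weight=link["weight"])
    return g
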