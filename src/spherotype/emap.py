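"""Enrichment maps: Jaccard-linked pathway graphs and cluster concordance.

Each significantly enriched pathway becomes a node whose gene subset is
its leading edge (or its full membership restricted to the expressed
universe). Two nodes are linked when the Jaccard index of their subsets
strictly exceeds the link threshold (default 0.4); connected components
form "collections" that summarize a shared biological process, labeled
by their three most frequent name tokens. The same Jaccard statistic, at
a higher bar (default 0.7, non-strict), scores the concordance of
cluster-wise enriched-pathway sets across clustering methods.
"""

from __future__ import annotations

import json
from collections import Counter
from dataclasses import dataclass, field
from pathlib import Path

import networkx as nx
import pandas as pd

from .enrich import EnrichmentResult
from .io_formats import GeneSetCollection

__all__ = [
    "EnrichmentMapGraph",
    "jaccard",
    "build_enrichment_map",
    "name_collections",
    "cluster_concordance",
    "export_graph",
    "DEFAULT_STOPWORDS",
    "SOURCE_PREFIXES",
]

DEFAULT_STOPWORDS = (
    "OF", "THE", "AND", "IN", "TO", "VIA", "BY", "A", "AN", "WITH", "FOR",
    "ON", "AT", "FROM", "UP", "DN", "PATHWAY", "PATHWAYS",
)

#: database prefixes stripped from pathway names before word counting
SOURCE_PREFIXES = ("REACTOME", "KEGG", "HALLMARK", "GO", "PID", "BIOCARTA")


def jaccard(a: set, b: set) -> float:
    """|a & b| / |a | b|; 0 when both sets are empty."""
    union = len(a | b)
    return len(a & b) / union if union else 0.0


@dataclass
class EnrichmentMapGraph:
    """Pathway graph plus its connected-component collections."""

    graph: nx.Graph
    collections: dict[int, dict] = field(default_factory=dict)
    # each collection: {"members": [names], "words": (w1, w2, w3) | None,
    #                   "fallback": bool}

    @property
    def n_nodes(self) -> int:
        return self.graph.number_of_nodes()

    @property
    def n_edges(self) -> int:
        return self.graph.number_of_edges()


def build_enrichment_map(
    enriched: list[EnrichmentResult],
    universe: set[str],
    threshold: float = 0.4,
    subset_mode: str = "leading_edge",
    collection: GeneSetCollection | None = None,
) -> EnrichmentMapGraph:
    """Build the pathway graph from significant enrichment results.

    Node gene subsets are leading edges by default; with
    ``subset_mode="expressed_set"`` they are the full set membership
    restricted to the expressed universe (requires ``collection``).
    Edges require Jaccard strictly above ``threshold``.
    """
    if not enriched:
        raise ValueError("no enriched pathways to map")
    if subset_mode not in ("leading_edge", "expressed_set"):
        raise ValueError(f"unknown subset_mode {subset_mode!r}")
    if subset_mode == "expressed_set" and collection is None:
        raise ValueError("expressed_set mode needs the gene-set collection")

    g = nx.Graph()
    subsets: dict[str, frozenset[str]] = {}
    for r in enriched:
        if subset_mode == "leading_edge":
            subset = frozenset(r.leading_edge)
        else:
            subset = frozenset(collection[r.set_name].genes & universe)
        subsets[r.set_name] = subset
        g.add_node(r.set_name, size=len(subset),
                   gene_subset=";".join(sorted(subset)), NES=r.NES)
    names = [r.set_name for r in enriched]
    for i, a in enumerate(names):
        for b in names[i + 1:]:
            w = jaccard(set(subsets[a]), set(subsets[b]))
            if w > threshold:
                g.add_edge(a, b, weight=w)

    collections = {}
    for cid, comp in enumerate(sorted(nx.connected_components(g),
                                      key=lambda c: sorted(c)[0])):
        collections[cid] = {"members": sorted(comp), "words": None,
                            "fallback": False}
        for n in comp:
            g.nodes[n]["collection"] = cid
    return EnrichmentMapGraph(g, collections)


def _tokens(pathway_name: str, stopwords: set[str]) -> list[str]:
    raw = [t for t in "".join(
        ch if ch.isalnum() else " " for ch in pathway_name.upper()
    ).split() if t]
    return [t for t in raw
            if t not in SOURCE_PREFIXES and t not in stopwords]


def name_collections(
    g: EnrichmentMapGraph, stopwords: tuple[str, ...] = DEFAULT_STOPWORDS
) -> EnrichmentMapGraph:
    """Label every collection with its 3 most frequent name tokens.

    Ties break alphabetically. If stopwording removes every token, the
    label falls back to the first member's pathway name and is flagged.
    """
    sw = {w.upper() for w in stopwords}
    for info in g.collections.values():
        counts: Counter[str] = Counter()
        for member in info["members"]:
            counts.update(_tokens(member, sw))
        if counts:
            top = sorted(counts.items(), key=lambda kv: (-kv[1], kv[0]))[:3]
            info["words"] = tuple(w for w, _ in top)
            info["fallback"] = False
        else:
            info["words"] = (info["members"][0],)
            info["fallback"] = True
    return g


def cluster_concordance(
    pathway_sets_by_method: dict[str, dict[str, set[str]]],
    threshold: float = 0.7,
) -> pd.DataFrame:
    """Cross-method cluster matching by Jaccard of enriched-pathway names.

    Every cluster pair across every pair of methods is scored; a pair is
    matched when the Jaccard index is >= threshold (many-to-one matches
    allowed). Clusters with no enriched pathway get Jaccard 0 and the
    note "undefined function".
    """
    methods = list(pathway_sets_by_method)  # caller's order is kept
    if len(methods) < 2:
        raise ValueError("concordance needs at least 2 methods")
    rows = []
    for i, ma in enumerate(methods):
        for mb in methods[i + 1:]:
            for ca, sa in sorted(pathway_sets_by_method[ma].items()):
                for cb, sb in sorted(pathway_sets_by_method[mb].items()):
                    note = ""
                    if not sa or not sb:
                        j = 0.0
                        note = "undefined function"
                    else:
                        j = jaccard(sa, sb)
                    rows.append({
                        "method_a": ma, "cluster_a": ca,
                        "method_b": mb, "cluster_b": cb,
                        "jaccard": j, "matched": j >= threshold,
                        "note": note,
                    })
    return pd.DataFrame(rows)


def export_graph(
    g: EnrichmentMapGraph, path: str | Path, format: str = "graphml"
) -> None:
    """Write the map as GraphML (lossless), SIF (topology) or JSON."""
    path = Path(path)
    if format == "graphml":
        nx.write_graphml(g.graph, path)
    elif format == "sif":
        with open(path, "w") as fh:
            seen = set()
            for a, b in sorted(g.graph.edges()):
                fh.write(f"{a}\tshares_genes\t{b}\n")
                seen.update((a, b))
            for n in sorted(g.graph.nodes()):
                if n not in seen:
                    fh.write(f"{n}\n")
    elif format == "json":
        data = nx.node_link_data(g.graph, edges="edges")
        data["collections"] = {
            str(cid): {"members": info["members"],
                       "words": list(info["words"]) if info["words"] else None,
                       "fallback": info["fallback"]}
            for cid, info in g.collections.items()
        }
        path.write_text(json.dumps(data, indent=1))
    else:
        raise ValueError(f"unknown format {format!r}")
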