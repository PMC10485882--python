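"""Cross-class interaction networks among SNV-associated DE RNAs.

Nodes are the SNV-associated differentially expressed features, typed
DEG (mRNA), DEC (circRNA), DEL (lncRNA) or DEM (miRNA).  An edge joins
two features whose normalized expression profiles are strongly
co-expressed (|Pearson r| >= threshold, p < threshold) across a common
sample set.  This co-expression rule is this package's own edge
definition — the network is a co-expression network, and the tallies
(DEC–DEG, DEL–DEG, DEL–DEC pairs and DEL–DEC–DEG triangles) are counted
from it.  DEM nodes are carried in the graph but excluded from the
three tallied pair types.
"""

from __future__ import annotations

from dataclasses import dataclass
from itertools import combinations
from typing import Mapping, Sequence

import networkx as nx
import numpy as np
import pandas as pd

from .stats import bh_adjust, hypergeom_upper_tail, pearson_test

NODE_CLASSES = ("DEG", "DEC", "DEL", "DEM")
RNA_TO_NODE_CLASS = {"mRNA": "DEG", "circRNA": "DEC", "lncRNA": "DEL", "miRNA": "DEM"}
#: the three tallied cross-class pair types; DEM edges are kept in the
#: graph but not tallied
PAIR_NAMES = {
    frozenset({"DEC", "DEG"}): "DEC-DEG",
    frozenset({"DEL", "DEG"}): "DEL-DEG",
    frozenset({"DEL", "DEC"}): "DEL-DEC",
}
TRIAD_NAME = "DEL-DEC-DEG"


def tally_graph(graph: nx.Graph) -> dict[str, int]:
    """Class-pair edge counts plus the DEL–DEC–DEG triangle count,
    recomputed directly from the edge list (order-independent)."""
    tallies = {name: 0 for name in PAIR_NAMES.values()}
    for u, v in graph.edges():
        cu, cv = graph.nodes[u]["node_class"], graph.nodes[v]["node_class"]
        name = PAIR_NAMES.get(frozenset({cu, cv}))
        if name is not None:
            tallies[name] += 1
    triads = 0
    for u, v, w in combinations(graph.nodes, 3):
        classes = sorted(graph.nodes[n]["node_class"] for n in (u, v, w))
        if classes != ["DEC", "DEG", "DEL"]:
            continue
        if graph.has_edge(u, v) and graph.has_edge(v, w) and graph.has_edge(u, w):
            triads += 1
    tallies[TRIAD_NAME] = triads
    return tallies


def build_network(
    node_features: Mapping[str, Sequence[str]],
    expression: Mapping[str, pd.DataFrame],
    r_threshold: float = 0.9,
    p_threshold: float = 0.05,
) -> nx.Graph:
    """Co-expression graph over typed nodes.

    node_features maps RNA class -> associated-DE feature ids; expression
    maps RNA class -> log2 normalized expression (features x samples).
    All classes must share at least three common samples.
    """
    profiles: dict[str, np.ndarray] = {}
    graph = nx.Graph()
    frames = [expression[c] for c in node_features if node_features[c]]
    if not frames:
        return graph
    common = sorted(set.intersection(*(set(f.columns) for f in frames)))
    if len(common) < 3:
        raise ValueError(f"need >=3 common samples across classes, got {len(common)}")
    for rna_class, features in sorted(node_features.items()):
        node_class = RNA_TO_NODE_CLASS[rna_class]
        for fid in sorted(features):
            if fid not in expression[rna_class].index:
                continue
            node = f"{node_class}:{fid}"
            graph.add_node(node, node_class=node_class, feature_id=fid, rna_class=rna_class)
            profiles[node] = expression[rna_class].loc[fid, common].to_numpy(dtype=float)
    for u, v in combinations(sorted(graph.nodes), 2):
        if graph.nodes[u]["rna_class"] == graph.nodes[v]["rna_class"] and graph.nodes[u][
            "feature_id"
        ] == graph.nodes[v]["feature_id"]:
            continue
        r, p = pearson_test(profiles[u], profiles[v])
        if np.isfinite(p) and abs(r) >= r_threshold and p < p_threshold:
            graph.add_edge(u, v, r=float(r), p=float(p))
    return graph


def edge_frame(graph: nx.Graph) -> pd.DataFrame:
    rows = [
        {
            "node_a": u,
            "class_a": graph.nodes[u]["node_class"],
            "node_b": v,
            "class_b": graph.nodes[v]["node_class"],
            "r": d["r"],
            "p": d["p"],
        }
        for u, v, d in sorted(graph.edges(data=True))
    ]
    return pd.DataFrame(rows, columns=["node_a", "class_a", "node_b", "class_b", "r", "p"])


def chord_matrix(graph: nx.Graph) -> pd.DataFrame:
    """Class x class edge-count matrix, chord-diagram ready."""
    mat = pd.DataFrame(0, index=list(NODE_CLASSES), columns=list(NODE_CLASSES))
    for u, v in graph.edges():
        cu, cv = graph.nodes[u]["node_class"], graph.nodes[v]["node_class"]
        mat.loc[cu, cv] += 1
        if cu != cv:
            mat.loc[cv, cu] += 1
    return mat


@dataclass(frozen=True)
class EnrichmentResult:
    set_name: str
    overlap: int
    set_size: int
    study_size: int
    universe_size: int
    p_value: float
    q_value: float


def enrich(
    study: set[str], gene_sets: Mapping[str, set[str]], universe: set[str]
) -> list[EnrichmentResult]:
    """Hypergeometric over-representation of a study list in each set.

    Sets are intersected with the universe first; the study list must be
    a subset of the universe.
    """
    if not universe:
        raise ValueError("empty universe")
    stray = study - universe
    if stray:
        raise ValueError(f"study genes outside the universe: {sorted(stray)[:5]}")
    rows = []
    for name in sorted(gene_sets):
        members = gene_sets[name] & universe
        overlap = len(members & study)
        p = hypergeom_upper_tail(overlap, len(members), len(study), len(universe))
        rows.append((name, overlap, len(members), p))
    qs = bh_adjust([p for _, _, _, p in rows]) if rows else []
    return [
        EnrichmentResult(
            set_name=name,
            overlap=overlap,
            set_size=set_size,
            study_size=len(study),
            universe_size=len(universe),
            p_value=float(p),
            q_value=float(q),
        )
        for (name, overlap, set_size, p), q in zip(rows, qs)
    ]


def enrichment_frame(results: Sequence[EnrichmentResult]) -> pd.DataFrame:
    return pd.DataFrame(
        [
            {
                "set_name": r.set_name,
                "overlap": r.overlap,
                "set_size": r.set_size,
                "study_size": r.study_size,
                "universe_size": r.universe_size,
                "p_value": r.p_value,
                "q_value": r.q_value,
            }
            for r in results
        ]
    )
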