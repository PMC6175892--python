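"""PPI subnetwork topology and gene-set over-representation.

The DEG union is mapped onto a confidence-thresholded protein-protein
interaction network (STRING-style combined scores, default threshold
800 inclusive).  The induced subgraph keeps every query gene — genes
with no qualifying interaction appear as isolated, degree-0 nodes — and
per-node degree and betweenness centrality identify topological
bottlenecks.  Betweenness is reported unnormalized with endpoints
excluded, each unordered pair counted once (Brandes' algorithm via
networkx).

Over-representation analysis tests each gene set for excess overlap with
a query list by the one-sided hypergeometric upper tail
P(overlap >= observed), with Benjamini-Hochberg adjustment across sets.
"""

from __future__ import annotations

import networkx as nx
import numpy as np
import pandas as pd
from scipy import stats

from cdscreen.dge import bh_adjust
from cdscreen.io_formats import EdgeList, GeneSetCollection


def build_graph(genes, edges: EdgeList) -> nx.Graph:
    """Induced subgraph of the scored edge list on a gene set.

    Every input gene becomes a node; edges are kept only when both
    endpoints are in the gene set.  Assumes the edge list was already
    score-filtered at load time.
    """
    gene_set = set(genes)
    if not gene_set:
        raise ValueError("empty gene set")
    g = nx.Graph()
    g.add_nodes_from(sorted(gene_set))
    df = edges.edges
    mask = df["node_a"].isin(gene_set) & df["node_b"].isin(gene_set)
    for a, b, s in df[mask].itertuples(index=False):
        g.add_edge(a, b, combined_score=int(s))
    return g


def centrality(graph: nx.Graph) -> pd.DataFrame:
    """Degree and unnormalized betweenness per node.

    Betweenness excludes endpoints and counts each unordered pair once;
    disconnected pairs contribute nothing.  Returns a node-indexed
    DataFrame with columns degree, betweenness, sorted by degree
    descending then node id ascending.
    """
    nodes = sorted(graph.nodes)
    deg = dict(graph.degree())
    btw = nx.betweenness_centrality(graph, normalized=False, endpoints=False)
    df = pd.DataFrame(
        {
            "gene": nodes,
            "degree": [int(deg[n]) for n in nodes],
            "betweenness": [float(btw[n]) for n in nodes],
        }
    ).set_index("gene")
    return df.sort_values(
        ["degree", "betweenness"], ascending=[False, False], kind="mergesort"
    )


def overrepresentation(
    query, sets: GeneSetCollection, universe
) -> pd.DataFrame:
    """Hypergeometric over-representation of a query list in each gene set.

    Every set is intersected with the universe before testing; the query
    must be a subset of the universe.  Returns a set-indexed DataFrame
    with columns overlap, set_size, query_size, universe_size, p, adj_p,
    sorted by p ascending then set name.
    """
    universe = set(universe)
    query = set(query)
    if not universe or not query:
        raise ValueError("query and universe must be non-empty")
    if not query <= universe:
        extra = sorted(query - universe)[:3]
        raise ValueError(f"query genes outside the universe, e.g. {extra}")
    m = len(universe)
    n_query = len(query)
    records = []
    for name in sets.names():
        members = set(sets.members(name)) & universe
        k = len(members & query)
        n_set = len(members)
        # P(X >= k), X ~ Hypergeom(M=m, n=n_set, N=n_query)
        p = float(stats.hypergeom.sf(k - 1, m, n_set, n_query)) if n_set else 1.0
        records.append((name, k, n_set, n_query, m, min(p, 1.0)))
    df = pd.DataFrame(
        records,
        columns=["set", "overlap", "set_size", "query_size", "universe_size", "p"],
    ).set_index("set")
    df["adj_p"] = bh_adjust(df["p"].to_numpy()) if len(df) else []
    return df.sort_values(["p", "set"], kind="mergesort")
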