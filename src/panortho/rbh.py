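"""Reciprocal-best-hit graph construction.

Two ORFs x (genome i) and y (genome j) are connected iff y is x's top hit
in genome j AND x is y's top hit in genome i — the classic operational
ortholog criterion.  Only cross-genome edges exist; each node therefore has
at most one edge per other genome.  Edge weight is the arithmetic mean of
the two directed scores (clustering uses it only when explicitly asked to).
"""

from __future__ import annotations

from pathlib import Path

import networkx as nx

from .search import TopHitTable


def build_rbh_graph(top_hits: TopHitTable) -> nx.Graph:
    """Undirected RBH graph over all ORFs; isolated ORFs are kept as nodes.

    Isolated nodes become singleton orthogroups downstream, so every ORF is
    accounted for in the final tables.
    """
    g = nx.Graph()
    g.add_nodes_from(top_hits.genome_of)
    for (q, _tg), ps in top_hits.hits.items():
        t = ps.target_orf_id
        back = top_hits.top_hit(t, top_hits.genome_of[q])
        if back is not None and back.target_orf_id == q:
            weight = (ps.score + back.score) / 2.0
            g.add_edge(q, t, weight=weight)
    for n in g.nodes:
        g.nodes[n]["genome"] = top_hits.genome_of[n]
    return g


def write_edge_list(graph: nx.Graph, path: str | Path) -> None:
    """ABC edge-list format (orf_a, orf_b, weight), as consumed by MCL tooling."""
    with Path(path).open("w") as fh:
        for a, b, data in sorted(graph.edges(data=True), key=lambda e: (min(e[0], e[1]), max(e[0], e[1]))):
            a, b = sorted((a, b))
            fh.write(f"{a}\t{b}\t{data.get('weight', 1.0):g}\n")
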