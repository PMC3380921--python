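"""Normalized Similarity Index (NSI) edge weighting.

The efficiency with which a signal crosses an edge is estimated purely from
topology: two connected proteins that share many interaction partners sit in
the same densely wired module, where transmission is efficient.  For an edge
between nodes *i* and *j*,

    NSI_ij = (M_ij + C_ij) / (D_ij + C_ij)

where ``M`` is the number of matching connections (third nodes adjacent to
both *i* and *j*), ``D`` the number of distinct neighbors of the pair
(union, excluding *i* and *j* themselves), and ``C`` the number of directed
edges between *i* and *j* (1, or 2 when a reciprocal edge exists).
Neighborhoods ignore edge direction and sign: signs encode regulation, not
connectivity.  The weight always lies in (0, 1] and is symmetric in *i*, *j*.
"""

from __future__ import annotations

from pathlib import Path

from .errors import NetworkLookupError
from .graph_io import SignedDigraph

EdgeWeightMap = dict[tuple[str, str], float]


def neighbor_counts(g: SignedDigraph, i: str, j: str) -> tuple[int, int, int]:
    """Matching connections M, distinct neighbors D, direct connections C.

    Raises a domain error for ``i == j``: self-similarity is fixed at 0 by
    convention and has no neighbor decomposition.
    """
    if i == j:
        raise ValueError("self-similarity is undefined (fixed at 0); need i != j")
    for n in (i, j):
        if not g.has_node(n):
            raise NetworkLookupError(f"unknown node {n!r}")
    ni = g.neighbors_undirected(i) - {j}
    nj = g.neighbors_undirected(j) - {i}
    m = len(ni & nj)
    d = len(ni | nj)
    c = int(g.has_edge(i, j)) + int(g.has_edge(j, i))
    return m, d, c


def edge_nsi(g: SignedDigraph, i: str, j: str) -> float:
    """NSI weight of the edge (i, j); requires the edge to exist.

    A self-loop gets weight 1.0 (neutral efficiency); an isolated pair with
    no other neighbors gets (0+1)/(0+1) = 1.0.
    """
    if not (g.has_edge(i, j) or g.has_edge(j, i)):
        raise NetworkLookupError(f"no edge between {i!r} and {j!r}")
    if i == j:
        return 1.0
    m, d, c = neighbor_counts(g, i, j)
    return (m + c) / (d + c)


def weight_all_edges(g: SignedDigraph) -> EdgeWeightMap:
    """NSI weight for every edge of the network; deterministic, symmetric."""
    return {(u, v): edge_nsi(g, u, v) for u, v, _ in g.edges()}


def export_similarity(g: SignedDigraph, weights: EdgeWeightMap, destination) -> None:
    """Write weights.tsv (source, target, sign, nsi_weight) for layout tools.

    ``destination`` is a path or an open text handle; weights are rendered
    with 6 decimals.
    """
    lines = ["source\ttarget\tsign\tnsi_weight"]
    for u, v, s in sorted(g.edges()):
        lines.append(f"{u}\t{v}\t{s:+d}\t{weights[(u, v)]:.6f}")
    text = "\n".join(lines) + "\n"
    if hasattr(destination, "write"):
        destination.write(text)
    else:
        Path(destination).write_text(text)
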