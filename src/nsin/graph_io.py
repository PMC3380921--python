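"""Signed directed signaling networks: parsing, writing and topological annotation.

A signaling network is a directed graph whose nodes are molecules (ligands,
receptors, kinases, transcription factors) and whose edges carry a sign:
``+1`` for activation, ``-1`` for inhibition.  Source nodes (in-degree 0)
are ligands or receptors; sink nodes (out-degree 0) are effectors such as
transcription factors or cellular responses.

The canonical on-disk dialect is a 3-column TSV ``source  target  sign``
(``#`` comments allowed, header auto-detected); Cytoscape-style SIF lines
``A activates B`` / ``A inhibits B`` are accepted as well.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from pathlib import Path
from typing import Iterable, Iterator, Mapping

import networkx as nx

from .errors import ConsistencyError, FormatError, NetworkLookupError

logger = logging.getLogger(__name__)

ACTIVATION = +1
INHIBITION = -1

#: total degree at or above which a node's half-life class becomes ambiguous
HALF_LIFE_DEGREE_THRESHOLD = 6

_SIGN_TOKENS = {
    "1": ACTIVATION,
    "+1": ACTIVATION,
    "-1": INHIBITION,
    "−1": INHIBITION,  # unicode minus
    "activate": ACTIVATION,
    "activates": ACTIVATION,
    "activation": ACTIVATION,
    "inhibit": INHIBITION,
    "inhibits": INHIBITION,
    "inhibition": INHIBITION,
}


class SignedDigraph:
    """Directed graph with a ``+1``/``-1`` sign on every edge.

    Thin wrapper around :class:`networkx.DiGraph` that enforces the model's
    invariants: at most one edge per ordered pair, signs restricted to
    ``{+1, -1}``, and endpoints always declared as nodes.  Node identifiers
    are case-sensitive strings (protein symbols are case-meaningful).
    """

    def __init__(self) -> None:
        self._g = nx.DiGraph()

    # -- construction -------------------------------------------------

    def add_node(self, node: str, **labels: str) -> None:
        self._g.add_node(str(node).strip(), **labels)

    def add_edge(self, src: str, tgt: str, sign: int) -> None:
        if sign not in (ACTIVATION, INHIBITION):
            raise ValueError(f"edge sign must be +1 or -1, got {sign!r}")
        src, tgt = str(src).strip(), str(tgt).strip()
        if self._g.has_edge(src, tgt):
            old = self._g.edges[src, tgt]["sign"]
            if old != sign:
                raise ConsistencyError(
                    f"conflicting signs for edge {src}->{tgt}: {old:+d} vs {sign:+d}"
                )
            logger.warning("duplicate edge %s->%s collapsed", src, tgt)
            return
        if src == tgt:
            logger.warning("self-loop on %s accepted; excluded from BFS layering", src)
        self._g.add_edge(src, tgt, sign=sign)

    def copy(self) -> "SignedDigraph":
        out = SignedDigraph()
        out._g = self._g.copy()
        return out

    # -- queries ------------------------------------------------------

    @property
    def nodes(self) -> set[str]:
        return set(self._g.nodes)

    def edges(self) -> Iterator[tuple[str, str, int]]:
        for u, v, d in self._g.edges(data="sign"):
            yield u, v, d

    @property
    def n_nodes(self) -> int:
        return self._g.number_of_nodes()

    @property
    def n_edges(self) -> int:
        return self._g.number_of_edges()

    def has_node(self, node: str) -> bool:
        return self._g.has_node(node)

    def has_edge(self, src: str, tgt: str) -> bool:
        return self._g.has_edge(src, tgt)

    def sign(self, src: str, tgt: str) -> int:
        try:
            return self._g.edges[src, tgt]["sign"]
        except KeyError:
            raise NetworkLookupError(f"no edge {src}->{tgt}") from None

    def predecessors(self, node: str) -> list[str]:
        return list(self._g.predecessors(node))

    def successors(self, node: str) -> list[str]:
        return list(self._g.successors(node))

    def in_degree(self, node: str) -> int:
        return self._g.in_degree(node)

    def out_degree(self, node: str) -> int:
        return self._g.out_degree(node)

    def neighbors_undirected(self, node: str) -> set[str]:
        """All nodes adjacent to *node* ignoring direction and sign (and self)."""
        nbrs = set(self._g.predecessors(node)) | set(self._g.successors(node))
        nbrs.discard(node)
        return nbrs

    def to_networkx(self) -> nx.DiGraph:
        """The underlying directed graph (a live view; copy before mutating)."""
        return self._g

    def __eq__(self, other: object) -> bool:
        if not isinstance(other, SignedDigraph):
            return NotImplemented
        return self.nodes == other.nodes and set(self.edges()) == set(other.edges())

    def __repr__(self) -> str:
        return f"SignedDigraph(n_nodes={self.n_nodes}, n_edges={self.n_edges})"


@dataclass(frozen=True)
class DegreeRecord:
    node: str
    in_degree: int
    out_degree: int

    @property
    def total_degree(self) -> int:
        return self.in_degree + self.out_degree


@dataclass(frozen=True)
class HalfLifeClass:
    """Half-life classification of a node, derived from topology.

    ``category`` is ``"ambiguous"`` when the node's half-life cannot be
    predicted from topology alone (hub with total degree >= 6, or a source
    or sink node): such nodes are simulated under both a short- and a
    long-half-life stability regime.  A user ``override`` of ``"short"`` or
    ``"long"`` pins the regime and removes the ambiguity.
    """

    node: str
    category: str  # "default" | "ambiguous"
    override: str | None = None  # None | "short" | "long"

    @property
    def effective(self) -> str:
        """Regime label used by the simulator: override, else category."""
        return self.override if self.override is not None else self.category


# ---------------------------------------------------------------------------
# parsing


def _parse_sign(token: str, lineno: int) -> int:
    try:
        return _SIGN_TOKENS[token.strip().lower()]
    except KeyError:
        raise FormatError(f"line {lineno}: cannot parse edge sign {token!r}") from None


_HEADER_WORDS = {"sign", "interaction", "type", "relation", "effect", "regulation"}


def _looks_like_header(fields: list[str]) -> bool:
    # a first row whose third column is a column name, not a sign value
    return len(fields) >= 3 and fields[2].strip().lower() in _HEADER_WORDS


def read_network(
    edge_lines: Iterable[str],
    node_lines: Iterable[str] | None = None,
) -> SignedDigraph:
    """Parse a signed edge list (and optional node list) into a network.

    Edge lines are whitespace- or tab-separated triples ``src tgt sign``;
    SIF-style ``src activates tgt`` / ``src inhibits tgt`` is recognised by
    the relation word in the middle column.  ``#`` lines are comments; a
    header row is skipped when its third column is not a sign token.
    Duplicate identical edges collapse with a warning; conflicting signs for
    the same ordered pair raise :class:`ConsistencyError`.
    """
    g = SignedDigraph()
    if node_lines is not None:
        for raw in node_lines:
            name = raw.split("#", 1)[0].strip()
            if name:
                g.add_node(name)
    first_data_line = True
    for lineno, raw in enumerate(edge_lines, start=1):
        line = raw.split("#", 1)[0].strip()
        if not line:
            continue
        fields = line.split("\t") if "\t" in line else line.split()
        fields = [f.strip() for f in fields if f.strip()]
        if first_data_line and _looks_like_header(fields) and not _is_sif(fields):
            first_data_line = False
            continue
        first_data_line = False
        if _is_sif(fields):
            src, rel, tgt = fields[0], fields[1], fields[2]
            sign = _parse_sign(rel, lineno)
        elif len(fields) == 3:
            src, tgt = fields[0], fields[1]
            sign = _parse_sign(fields[2], lineno)
        else:
            raise FormatError(
                f"line {lineno}: expected 3 columns (src, tgt, sign), got {len(fields)}"
            )
        g.add_node(src)
        g.add_node(tgt)
        g.add_edge(src, tgt, sign)
    return g


def _is_sif(fields: list[str]) -> bool:
    return len(fields) == 3 and fields[1].strip().lower() in (
        "activates",
        "activate",
        "activation",
        "inhibits",
        "inhibit",
        "inhibition",
    )


def read_network_files(edge_path: str | Path, node_path: str | Path | None = None) -> SignedDigraph:
    edge_lines = Path(edge_path).read_text().splitlines()
    node_lines = Path(node_path).read_text().splitlines() if node_path else None
    return read_network(edge_lines, node_lines)


def write_network(g: SignedDigraph, edge_path: str | Path, node_path: str | Path | None = None) -> None:
    """Write the canonical TSV dialect; round-trips through :func:`read_network`."""
    lines = ["source\ttarget\tsign"]
    for u, v, s in sorted(g.edges()):
        lines.append(f"{u}\t{v}\t{s:+d}")
    Path(edge_path).write_text("\n".join(lines) + "\n")
    if node_path is not None:
        Path(node_path).write_text("\n".join(sorted(g.nodes)) + "\n")


# ---------------------------------------------------------------------------
# topological annotation


def reachable_subnetwork(g: SignedDigraph, sources: Iterable[str]) -> SignedDigraph:
    """Induced subgraph on nodes reachable from any source by directed paths.

    Nodes the signal can never reach play no role in the dynamics and are
    dropped (sources themselves are kept).
    """
    sources = list(sources)
    if not sources:
        raise NetworkLookupError("at least one source node is required")
    for s in sources:
        if not g.has_node(s):
            raise NetworkLookupError(f"unknown source node {s!r}")
    keep: set[str] = set(sources)
    for s in sources:
        keep |= nx.descendants(g.to_networkx(), s)
    sub = SignedDigraph()
    for n in keep:
        sub.add_node(n)
    for u, v, s in g.edges():
        if u in keep and v in keep:
            sub.add_edge(u, v, s)
    return sub


def degree_table(g: SignedDigraph) -> list[DegreeRecord]:
    """In/out/total degree per node, counting directed edges regardless of sign."""
    return [
        DegreeRecord(n, g.in_degree(n), g.out_degree(n))
        for n in sorted(g.nodes)
    ]


def classify_half_life(
    g: SignedDigraph,
    overrides: Mapping[str, str] | None = None,
) -> list[HalfLifeClass]:
    """Classify every node's half-life regime from topology.

    Hubs (total degree >= 6), sinks (out-degree 0) and sources (in-degree 0)
    are the groups in which long and short half-lives are both well
    represented in proteome-wide stability surveys, so their class is
    ``ambiguous`` and the simulator runs both regimes for them.  Explicit
    per-node overrides (``"short"``/``"long"``) take precedence.
    """
    overrides = dict(overrides or {})
    for node, value in overrides.items():
        if not g.has_node(node):
            raise NetworkLookupError(f"half-life override for unknown node {node!r}")
        if value not in ("short", "long"):
            raise ValueError(f"override for {node!r} must be 'short' or 'long', got {value!r}")
    out = []
    for rec in degree_table(g):
        ambiguous = (
            rec.total_degree >= HALF_LIFE_DEGREE_THRESHOLD
            or rec.in_degree == 0
            or rec.out_degree == 0
        )
        override = overrides.get(rec.node)
        category = "ambiguous" if (ambiguous and override is None) else "default"
        out.append(HalfLifeClass(rec.node, category, override))
    return out


def write_degrees(
    g: SignedDigraph,
    path: str | Path,
    overrides: Mapping[str, str] | None = None,
) -> None:
    """Write degrees.tsv: node, in_degree, out_degree, total_degree, half_life_class."""
    classes = {h.node: h for h in classify_half_life(g, overrides)}
    lines = ["node\tin_degree\tout_degree\ttotal_degree\thalf_life_class"]
    for rec in degree_table(g):
        h = classes[rec.node]
        lines.append(
            f"{rec.node}\t{rec.in_degree}\t{rec.out_degree}\t{rec.total_degree}\t{h.effective}"
        )
    Path(path).write_text("\n".join(lines) + "\n")
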