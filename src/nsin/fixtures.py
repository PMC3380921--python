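"""Synthetic signed networks and experiment tables for tests and demos.

Provides the worked similarity-index motif (two connected nodes sharing
four common neighbors among eight distinct ones), simple signed cascades,
and seeded random signed networks shaped like curated signaling maps —
for example a hepatocyte-scale emulator with 7 ligands, ~40 nodes and ~15%
inhibitory edges.  Real curated networks can be supplied as edge-list files
through :func:`nsin.graph_io.read_network_files`; these generators exist so
every part of the package is exercisable without downloads.

All generators are pure functions of their arguments (and seed).
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .dynamics import StateTrajectory
from .graph_io import ACTIVATION, INHIBITION, SignedDigraph


def fig1_motif() -> SignedDigraph:
    """The worked NSI example: edge (i, j) with 4 shared and 4 private neighbors.

    Nodes i and j are joined by one directed edge; both connect to common
    neighbors m1..m4, i privately to a and b, j privately to c and d.  The
    NSI of (i, j) is therefore (4 + 1) / (8 + 1) = 5/9.
    """
    g = SignedDigraph()
    for n in ["i", "j", "m1", "m2", "m3", "m4", "a", "b", "c", "d"]:
        g.add_node(n)
    g.add_edge("i", "j", ACTIVATION)
    for m in ["m1", "m2", "m3", "m4"]:
        g.add_edge("i", m, ACTIVATION)
        g.add_edge("j", m, ACTIVATION)
    g.add_edge("i", "a", ACTIVATION)
    g.add_edge("i", "b", ACTIVATION)
    g.add_edge("j", "c", ACTIVATION)
    g.add_edge("j", "d", ACTIVATION)
    return g


def cascade(n: int, inhibitor_positions: set[int] | None = None) -> SignedDigraph:
    """Linear chain v1 -> v2 -> ... -> vn; 1-based edge positions in
    *inhibitor_positions* get sign -1."""
    if n < 2:
        raise ValueError(f"cascade needs n >= 2, got {n}")
    inhibitor_positions = inhibitor_positions or set()
    g = SignedDigraph()
    names = [f"v{k}" for k in range(1, n + 1)]
    for name in names:
        g.add_node(name)
    for k in range(1, n):
        sign = INHIBITION if k in inhibitor_positions else ACTIVATION
        g.add_edge(names[k - 1], names[k], sign)
    return g


@dataclass(frozen=True)
class SyntheticNetworkParams:
    """Shape parameters for a random signed signaling network."""

    n_nodes: int = 40
    n_ligands: int = 7
    edge_density: float = 0.06
    inhibitor_fraction: float = 0.15
    seed: int = 0

    def validate(self) -> None:
        if not 0 < self.n_ligands < self.n_nodes:
            raise ValueError("need 0 < n_ligands < n_nodes")
        if not 0.0 < self.edge_density < 1.0:
            raise ValueError("edge_density must be in (0,1)")
        if not 0.0 <= self.inhibitor_fraction <= 1.0:
            raise ValueError("inhibitor_fraction must be in [0,1]")


def random_signed_network(params: SyntheticNetworkParams) -> SignedDigraph:
    """Seeded random signed digraph with ligand sources and full reachability.

    Ligands (L1..Lk) have in-degree 0, like extracellular stimuli; every
    other node is reachable from the ligand set (missing connectivity is
    repaired with extra edges from already-reachable nodes).  Each edge is
    inhibitory with probability ``inhibitor_fraction``.
    """
    params.validate()
    rng = np.random.default_rng(params.seed)
    ligands = [f"L{k}" for k in range(1, params.n_ligands + 1)]
    interior = [f"N{k}" for k in range(1, params.n_nodes - params.n_ligands + 1)]
    g = SignedDigraph()
    for n in ligands + interior:
        g.add_node(n)

    def draw_sign() -> int:
        return INHIBITION if rng.random() < params.inhibitor_fraction else ACTIVATION

    for u in ligands + interior:
        for v in interior:  # ligands never receive edges
            if u == v:
                continue
            if rng.random() < params.edge_density:
                g.add_edge(u, v, draw_sign())

    # repair reachability: attach unreached nodes to a random reachable one
    import networkx as nx

    while True:
        reached = set(ligands)
        for lig in ligands:
            reached |= nx.descendants(g.to_networkx(), lig)
        missing = sorted(set(interior) - reached)
        if not missing:
            break
        anchor_pool = sorted(reached)
        for node in missing:
            anchor = anchor_pool[int(rng.integers(len(anchor_pool)))]
            if not g.has_edge(anchor, node):
                g.add_edge(anchor, node, draw_sign())
    return g


def hepatocyte_like_network(seed: int = 0) -> SignedDigraph:
    """Emulator of an inflammatory/growth signaling map: 7 ligands, 40 nodes,
    ~15% inhibitory edges."""
    return random_signed_network(
        SyntheticNetworkParams(n_nodes=40, n_ligands=7, edge_density=0.06,
                               inhibitor_fraction=0.15, seed=seed)
    )


def synthetic_experiment_table(
    traj: StateTrajectory,
    noise_sd: float,
    seed: int,
    condition: str = "baseline",
    summary: str = "mean",
    k: int = 10,
) -> pd.DataFrame:
    """Emulate a normalized micro-ELISA readout of a simulation.

    Per-node summary (same reduction the validation statistics use) plus
    i.i.d. Gaussian noise of standard deviation *noise_sd*, clamped to
    [0, 1].  Returns a (condition, node, value) table.
    """
    if noise_sd < 0:
        raise ValueError("noise_sd must be >= 0")
    rng = np.random.default_rng(seed)
    summ = traj.summary(method=summary, k=k)
    rows = []
    for node in traj.nodes:
        value = summ[node]
        if noise_sd > 0:
            value += rng.normal(0.0, noise_sd)
        rows.append(
            {"condition": condition, "node": node,
             "value": float(min(1.0, max(0.0, value)))}
        )
    return pd.DataFrame(rows)
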