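"""Semi-synchronized stochastic propagation of activity levels.

The state of node *j* at step *t*, ``X_j(t)`` in [0, 1], is the proportion
of its molecules in active (e.g. phosphorylated) form.  Each step every
reachable node is updated from its regulators:

    act = 1 - prod over activators i of (1 - w_ij * X_i)     (probabilistic OR)
    rep =     prod over repressors i of (1 - w_ij * X_i)
    X_j(t) = clamp01( R * X_j(t-1) + (1 - R * X_j(t-1)) * act * rep + xi )

``R`` is the relative stability of the active form, drawn fresh per node per
step (protein half-life is largely unknown, so it is treated as a random
retention factor: Uniform(0,1) by default, Uniform(0,0.5) for short-half-life
nodes, Uniform(0.5,1) for long), and ``xi`` is uniform noise on
[-eps, +eps].  Activators and repressors act independently, mirroring
transcription-factor binding at distinct promoter sites without interaction.

Updates are *semi-synchronous*: nodes are visited in ascending BFS-layer
order (ties broken by node id), and a regulator already updated in the
current sweep contributes its fresh step-*t* value while one not yet visited
contributes its step-(t-1) value.  Signal therefore crosses a whole
feed-forward cascade within a single step, while feedback from deeper layers
arrives with a one-step delay — a compromise between the artifacts of fully
synchronous updating and the bookkeeping of event-driven schemes.

Ligand sources ramp linearly: X_src(t) = (a_user / divisor) * (t / T).  The
default divisor of 10 caps the active receptor pool at 10% of its maximum,
the fraction of receptors typically found in the high-affinity form.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from pathlib import Path
from typing import Mapping

import numpy as np
import pandas as pd

from .errors import ValidationError
from .graph_io import (
    SignedDigraph,
    classify_half_life,
    reachable_subnetwork,
)
from .nsi import EdgeWeightMap
from .perturbation import PerturbationSpec, apply_inhibition

import networkx as nx

MAX_SOURCES = 10

#: stability ranges per half-life regime
R_RANGES: dict[str, tuple[float, float]] = {
    "default": (0.0, 1.0),
    "short": (0.0, 0.5),
    "long": (0.5, 1.0),
}


class StabilitySampler:
    """Seeded stream of per-step stability draws and noise terms."""

    def __init__(self, rng: np.random.Generator):
        self.rng = rng

    def stability(self, regime: str) -> float:
        lo, hi = R_RANGES[regime]
        return float(self.rng.uniform(lo, hi))

    def noise(self, amplitude: float) -> float:
        if amplitude == 0.0:
            return 0.0
        return float(self.rng.uniform(-amplitude, amplitude))


@dataclass
class SimulationConfig:
    """Everything a run needs besides the network and its edge weights."""

    sources: dict[str, float]
    iterations: int = 100
    seed: int = 0
    noise_amplitude: float = 0.01
    receptor_cap_divisor: float = 10.0
    perturbations: PerturbationSpec = field(default_factory=PerturbationSpec)
    half_life_mode: str = "both"  # "short" | "long" | "both"
    half_life_overrides: dict[str, str] = field(default_factory=dict)
    synchronous: bool = False  # test-only pure-synchronous schedule

    def validate(self, g: SignedDigraph) -> None:
        problems = []
        if not 1 <= len(self.sources) <= MAX_SOURCES:
            problems.append(
                f"number of sources must be 1..{MAX_SOURCES}, got {len(self.sources)}"
            )
        for node, a in self.sources.items():
            if not g.has_node(node):
                problems.append(f"source node {node!r} not in network")
            if not 0.0 <= a <= 1.0:
                problems.append(f"source activity for {node!r} outside [0,1]: {a}")
        if self.iterations < 1:
            problems.append(f"iterations must be >= 1, got {self.iterations}")
        if self.noise_amplitude < 0:
            problems.append(f"noise amplitude must be >= 0, got {self.noise_amplitude}")
        if self.receptor_cap_divisor <= 0:
            problems.append(
                f"receptor cap divisor must be > 0, got {self.receptor_cap_divisor}"
            )
        if self.half_life_mode not in ("short", "long", "both"):
            problems.append(f"half_life_mode must be short|long|both, got {self.half_life_mode!r}")
        for node, v in self.half_life_overrides.items():
            if v not in ("short", "long"):
                problems.append(f"half-life override for {node!r} must be short|long")
        if problems:
            raise ValidationError("; ".join(problems))
        self.perturbations.validate(g)

    def echo(self) -> dict:
        """Plain-dict rendering for manifests and trajectory metadata."""
        return {
            "sources": dict(self.sources),
            "iterations": self.iterations,
            "seed": self.seed,
            "noise_amplitude": self.noise_amplitude,
            "receptor_cap_divisor": self.receptor_cap_divisor,
            "half_life_mode": self.half_life_mode,
            "half_life_overrides": dict(self.half_life_overrides),
            "synchronous": self.synchronous,
            "inhibit": [
                {
                    "target": i.target,
                    "activity": i.activity,
                    "weight": i.weight,
                    "report": i.report_value,
                }
                for i in self.perturbations.inhibitions
            ],
            "fix": dict(self.perturbations.fixed_assignments),
        }


@dataclass
class StateTrajectory:
    """Activity levels X[node][t] for t = 0..T; the simulator's output."""

    nodes: list[str]
    values: np.ndarray  # shape (len(nodes), T + 1)
    variant: str = "default"
    metadata: dict = field(default_factory=dict)

    @property
    def node_index(self) -> dict[str, int]:
        return {n: k for k, n in enumerate(self.nodes)}

    @property
    def n_steps(self) -> int:
        return self.values.shape[1] - 1

    def series(self, node: str) -> np.ndarray:
        return self.values[self.node_index[node], :]

    def value(self, node: str, t: int) -> float:
        return float(self.values[self.node_index[node], t])

    def summary(self, method: str = "mean", k: int = 10) -> dict[str, float]:
        """Per-node scalar summary over iterations 1..T (t = 0 excluded).

        ``method="mean"`` averages the whole run; ``"last-k"`` averages the
        final *k* steps (a late/steady-state readout).
        """
        if method == "mean":
            block = self.values[:, 1:]
        elif method == "last-k":
            block = self.values[:, -min(k, self.n_steps):]
        else:
            raise ValueError(f"unknown summary method {method!r}")
        means = block.mean(axis=1)
        return {n: float(means[i]) for i, n in enumerate(self.nodes)}

    def to_frame(self) -> pd.DataFrame:
        cols = [f"t{t}" for t in range(self.values.shape[1])]
        return pd.DataFrame(self.values, index=self.nodes, columns=cols)

    def to_csv(self, path: str | Path) -> None:
        df = self.to_frame()
        df.index.name = "node"
        # fixed 6-decimal rendering keeps outputs bytewise reproducible
        df.to_csv(path, float_format="%.6f")

    def copy(self) -> "StateTrajectory":
        return StateTrajectory(
            list(self.nodes), self.values.copy(), self.variant, dict(self.metadata)
        )


def read_trajectory_csv(path: str | Path, variant: str = "default") -> StateTrajectory:
    """Load a trajectories.csv written by :meth:`StateTrajectory.to_csv`."""
    df = pd.read_csv(path, index_col="node")
    return StateTrajectory(
        nodes=list(df.index), values=df.to_numpy(dtype=float), variant=variant
    )


# ---------------------------------------------------------------------------
# primitive operations


def bfs_layers(g: SignedDigraph, sources) -> dict[str, int]:
    """BFS depth of every reachable node from the source set (sources at 0)."""
    sources = list(sources)
    if not sources:
        raise ValidationError("at least one source required for layering")
    for s in sources:
        if not g.has_node(s):
            from .errors import NetworkLookupError

            raise NetworkLookupError(f"unknown source node {s!r}")
    layers: dict[str, int] = {}
    for s in set(sources):
        for node, d in nx.single_source_shortest_path_length(g.to_networkx(), s).items():
            if node not in layers or d < layers[node]:
                layers[node] = d
    return layers


def source_activity(t: int, total_steps: int, a_user: float, divisor: float = 10.0) -> float:
    """Ligand/receptor driving: a linear ramp to a_user/divisor at t = T."""
    if divisor <= 0:
        raise ValueError(f"divisor must be > 0, got {divisor}")
    return (a_user / divisor) * (t / total_steps)


def node_update(
    x_prev: float,
    regulators,
    R: float,
    xi: float,
) -> float:
    """One node's update from its regulators' (value, sign, weight) triples.

    With no activators the activation term is 0 and the node purely decays
    to ``R * x_prev``; repressors attenuate incoming activation but do not
    erode the retained pool.  Order of regulators is irrelevant (products
    commute).
    """
    act_complement = 1.0
    rep = 1.0
    for value, sign, weight in regulators:
        if sign > 0:
            act_complement *= 1.0 - weight * value
        else:
            rep *= 1.0 - weight * value
    act = 1.0 - act_complement
    retained = R * x_prev
    x = retained + (1.0 - retained) * act * rep + xi
    return min(1.0, max(0.0, x))


def sweep(
    g: SignedDigraph,
    weights: EdgeWeightMap,
    layers: Mapping[str, int],
    prev_state: Mapping[str, float],
    t: int,
    config: SimulationConfig,
    sampler: StabilitySampler,
    regimes: Mapping[str, str],
) -> dict[str, float]:
    """Advance the whole network one step; returns the state at step *t*.

    Nodes are visited in ascending (layer, node id) order.  Under the
    semi-synchronous schedule a regulator already visited this sweep is read
    at step *t*, any other at step *t-1*; under ``config.synchronous`` all
    regulators are read at *t-1* (comparison mode).  Sources follow the ramp;
    fixed assignments hold their constants and consume no random draws.
    Complementary inhibitor nodes lie outside the BFS layering (they are not
    reachable from the sources), so they are not visited here: the caller
    clamps them after the sweep, and their targets read the previous-step
    value — the inhibitor's message arrives with the same one-step delay as
    any downstream regulator's.
    """
    fixed = config.perturbations.fixed_assignments
    state = dict(prev_state)
    reads = dict(prev_state) if config.synchronous else state
    order = sorted(layers, key=lambda n: (layers[n], n))
    for node in order:
        if node in fixed:
            state[node] = fixed[node]
            continue
        if node in config.sources:
            state[node] = source_activity(
                t, config.iterations, config.sources[node], config.receptor_cap_divisor
            )
            continue
        regulators = [
            (reads[i], g.sign(i, node), weights[(i, node)])
            for i in sorted(g.predecessors(node))
            if i != node  # self-loops excluded from the update
        ]
        R = sampler.stability(regimes.get(node, "default"))
        xi = sampler.noise(config.noise_amplitude)
        state[node] = node_update(reads[node] if config.synchronous else state[node],
                                  regulators, R, xi)
    return state


def _variant_regimes(
    g_full: SignedDigraph,
    nodes,
    overrides: Mapping[str, str],
    variant: str,
) -> dict[str, str]:
    """Map each node to its stability regime under the given variant."""
    classes = {h.node: h for h in classify_half_life(g_full, overrides)}
    regimes = {}
    for n in nodes:
        h = classes.get(n)
        if h is None:
            regimes[n] = "default"
        elif h.override is not None:
            regimes[n] = h.override
        elif h.category == "ambiguous" and variant in ("short", "long"):
            regimes[n] = variant
        else:
            regimes[n] = "default"
    return regimes


def simulate(
    g: SignedDigraph,
    weights: EdgeWeightMap,
    config: SimulationConfig,
) -> list[StateTrajectory]:
    """Run the full simulation; returns one trajectory per half-life variant.

    The network is first restricted to the subgraph reachable from the
    sources (unreachable nodes never see signal), then augmented with any
    complementary inhibitor nodes.  Non-source nodes start at 0.  With
    ``half_life_mode="both"`` and at least one ambiguous-half-life node, two
    trajectories (variants ``"short"`` and ``"long"``) are returned, run
    from the same seed; otherwise a single trajectory.  Complementary nodes
    are reported in metadata, not as trajectory rows.
    """
    config.validate(g)
    sub = reachable_subnetwork(g, config.sources)
    aug, w2, clamps = apply_inhibition(sub, weights, config.perturbations)
    layers = bfs_layers(aug, config.sources)
    report_nodes = sorted(sub.nodes)

    classes = classify_half_life(g, config.half_life_overrides)
    has_ambiguous = any(
        h.category == "ambiguous" and h.node in sub.nodes for h in classes
    )
    if config.half_life_mode == "both":
        variants = ["short", "long"] if has_ambiguous else ["default"]
    else:
        variants = [config.half_life_mode]

    out = []
    T = config.iterations
    for variant in variants:
        regimes = _variant_regimes(g, sub.nodes, config.half_life_overrides, variant)
        sampler = StabilitySampler(np.random.default_rng(config.seed))
        state = {n: 0.0 for n in aug.nodes}
        X = np.zeros((len(report_nodes), T + 1))
        for t in range(1, T + 1):
            state = sweep(aug, w2, layers, state, t, config, sampler, regimes)
            state.update(clamps)  # complementary nodes hold their constants
            for k, n in enumerate(report_nodes):
                X[k, t] = state[n]
        out.append(
            StateTrajectory(
                nodes=report_nodes,
                values=X,
                variant=variant,
                metadata={"config": config.echo(), "clamps": dict(clamps)},
            )
        )
    return out
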