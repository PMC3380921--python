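"""In silico perturbation experiments.

Chemical or siRNA inhibition is modeled with a *complementary node*: a fresh
node ``anti_<target>`` wired to the target by a single inhibitory edge and
clamped to a constant activity.  The target keeps receiving upstream signal
and can still transmit some of it, which is what inhibitor titration
experiments show; deleting the node (the knockout idiom of many logical
frameworks) would instead break the cascade entirely and is deliberately
not offered.

Gain-of-function mutations (e.g. constitutively active Ras) are modeled as
fixed activity assignments: the node's value is clamped to a constant for
the whole simulation, dominating both dynamics and noise.

When a measured molecule is itself inhibited its readout is unusable
experimentally, so reported trajectories replace the inhibited node's row
with a user-chosen report value (usually 0); internal dynamics are
untouched.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

from .errors import NetworkLookupError, ValidationError
from .graph_io import INHIBITION, SignedDigraph
from .nsi import EdgeWeightMap

COMPLEMENT_PREFIX = "anti_"


@dataclass(frozen=True)
class Inhibition:
    """One inhibitor: constant-activity complementary node onto *target*.

    ``activity`` < 1 models partial inhibition; ``weight`` is the inhibitory
    edge's transmission efficiency (1.0 by default — a complementary node has
    no neighbors, so the similarity index would give 1.0 anyway).
    """

    target: str
    activity: float = 1.0
    weight: float = 1.0
    report_value: float = 0.0

    @property
    def complement(self) -> str:
        return COMPLEMENT_PREFIX + self.target


@dataclass(frozen=True)
class PerturbationSpec:
    inhibitions: tuple[Inhibition, ...] = ()
    fixed_assignments: dict[str, float] = field(default_factory=dict)

    def validate(self, g: SignedDigraph) -> None:
        problems = []
        inhibited = set()
        for inh in self.inhibitions:
            if not g.has_node(inh.target):
                problems.append(f"inhibition target {inh.target!r} not in network")
            if not 0.0 <= inh.activity <= 1.0:
                problems.append(f"inhibitor activity for {inh.target!r} outside [0,1]")
            if not 0.0 < inh.weight <= 1.0:
                problems.append(f"inhibitor edge weight for {inh.target!r} outside (0,1]")
            if not 0.0 <= inh.report_value <= 1.0:
                problems.append(f"report value for {inh.target!r} outside [0,1]")
            inhibited.add(inh.target)
        for node, value in self.fixed_assignments.items():
            if not g.has_node(node):
                problems.append(f"fixed-assignment node {node!r} not in network")
            if not 0.0 <= value <= 1.0:
                problems.append(f"fixed activity for {node!r} outside [0,1]")
            if node in inhibited:
                problems.append(f"node {node!r} is both inhibited and fixed")
        if problems:
            raise ValidationError("; ".join(problems))

    @property
    def is_empty(self) -> bool:
        return not self.inhibitions and not self.fixed_assignments


def apply_inhibition(
    g: SignedDigraph,
    weights: EdgeWeightMap,
    spec: PerturbationSpec,
) -> tuple[SignedDigraph, EdgeWeightMap, dict[str, float]]:
    """Augment the network with complementary inhibitor nodes.

    Returns the augmented graph, the augmented weight map, and the clamp set
    mapping each complementary node to its constant activity.  Edge weights
    of the original network are not recomputed: the similarity weighting
    reflects the biology, not the intervention.
    """
    g2 = g.copy()
    w2 = dict(weights)
    clamps: dict[str, float] = {}
    for inh in spec.inhibitions:
        if not g.has_node(inh.target):
            raise NetworkLookupError(f"inhibition target {inh.target!r} not in network")
        comp = inh.complement
        if g.has_node(comp):
            raise ValidationError(
                f"cannot add complementary node {comp!r}: name already taken"
            )
        g2.add_node(comp)
        g2.add_edge(comp, inh.target, INHIBITION)
        w2[(comp, inh.target)] = inh.weight
        clamps[comp] = inh.activity
    return g2, w2, clamps


def apply_fixed_assignments(state: dict[str, float], spec: PerturbationSpec) -> dict[str, float]:
    """Overwrite fixed nodes with their assigned constants (in place)."""
    for node, value in spec.fixed_assignments.items():
        if node in state:
            state[node] = value
    return state


def mask_inhibited_readouts(traj, spec: PerturbationSpec):
    """Replace every inhibited target's row by its report value (reported copy).

    Cosmetic only: mirrors the experimental convention that an inhibited
    molecule's own measurement is not interpretable.  Downstream rows are
    untouched.
    """
    masked = traj.copy()
    for inh in spec.inhibitions:
        if inh.target in masked.node_index:
            masked.values[masked.node_index[inh.target], :] = inh.report_value
    return masked
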