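# Methods

`nsin` simulates signal transduction through a curated signaling network
using nothing but the network's topology: no rate constants, binding
affinities or initial concentrations are required. The state of each node
(protein) is the proportion of its molecules in active form, a number in
[0, 1] that evolves in discrete time as signal spreads from ligand sources.
This note records the model, its parameters and defaults, the numerical
conventions, and the design choices made where more than one reasonable
construction existed.

## Edge weighting: Normalized Similarity Index

Every directed edge (i, j) carries a transmission efficiency

    NSI_ij = (M + C) / (D + C)

with M the number of matching connections (third nodes adjacent to both i
and j), D the number of distinct neighbors of the pair (union of the two
neighborhoods, excluding i and j themselves) and C the number of directed
edges between i and j (1, or 2 for a reciprocal pair). Neighborhoods are
taken ignoring edge direction and sign: signs encode regulation, while the
similarity index measures shared wiring. The weight lies in (0, 1], equals
1 exactly when every neighbor of either endpoint is shared (M = D), is
symmetric in i and j, and is raised by shared neighbors and lowered by
private ones. In the worked motif — two connected nodes with four common
neighbors among eight distinct ones — the edge weighs (4+1)/(8+1) = 5/9.

Conventions: a self-loop edge receives weight 1.0 (neutral efficiency) and
self-loops never count toward M or D; an isolated connected pair weighs
(0+1)/(0+1) = 1.

## Propagation dynamics

Time is discrete, t = 1..T (default T = 100); the state at t = 0 is zero
for every non-source node. Each step, node j with previous value x and
regulators i (value x_i, weight w_ij) updates as

    act = 1 - prod_{activators} (1 - w_ij * x_i)
    rep =     prod_{repressors} (1 - w_ij * x_i)
    X_j(t) = clamp_[0,1]( R*x + (1 - R*x) * act * rep + xi )

* Activators combine by probabilistic OR and repressors attenuate
  multiplicatively, the standard independence assumption for regulators
  binding distinct sites without interacting. The update is invariant to
  regulator order.
* R is the relative stability of the active form, drawn fresh per node per
  step: Uniform(0, 1) by default, Uniform(0, 0.5) for short-half-life
  nodes, Uniform(0.5, 1) for long. Active-form half-lives are mostly
  unmeasured, so stability is treated as an exogenous random retention
  factor rather than a parameter.
* xi is i.i.d. uniform noise on [-eps, +eps], eps = 0.01 by default —
  zero-mean, time-uncorrelated, the least-structured stand-in for
  molecular-level stochasticity. The final clamp guarantees X in [0, 1]
  for any T.
* With no activators the node purely decays (X(t) = R * X(t-1) + xi
  clamped), so activity is never created by repression alone.

### Half-life classes

Topology predicts half-life imperfectly: in proteome-wide surveys, hubs
(total degree >= 6), sinks (out-degree 0) and sources (in-degree 0) are the
groups where long half-lives are strongly enriched yet not universal. Such
nodes are classed *ambiguous* and, under the default `half_life_mode="both"`,
the simulator reports two complete trajectories — one with all ambiguous
nodes on the short regime, one on the long regime — from the same seed.
Per-node user overrides (`short`/`long`) pin the regime and remove the
ambiguity. Degrees are computed on the full input network, not on the
stimulus-dependent reachable subgraph: half-life is a property of the
protein, not of the experiment.

### Scheduling: semi-synchronous update

Nodes are ranked by BFS depth from the source set (directed, over outgoing
edges) and visited in ascending (layer, node id) order within each step. A
regulator already visited this sweep contributes its fresh step-t value;
one not yet visited contributes its step-(t-1) value. On a feed-forward
cascade the signal therefore traverses the whole path within one step,
while feedback from deeper layers arrives with a one-step delay — the
intended middle ground between fully synchronous updating (every reaction
takes exactly one tick) and event-driven simulation. For mutually
regulating nodes in the same layer the fixed visiting order decides who
reads whom fresh; this is deterministic and reproducible. A pure
synchronous mode (`synchronous=True`) exists for comparison and testing
only. Nodes not reachable from any source are dropped before simulation.

### Source driving

A ligand/receptor source with user activity `a_user` in [0, 1] follows the
ramp X(t) = (a_user / divisor) * (t / T). The default divisor of 10 caps
the active receptor pool at 10% of maximum, since roughly a tenth of a
receptor pool is typically in the high-affinity, ligand-binding form. Up to
10 sources may be driven at once (single mode: one; set mode: several, each
with its own activity).

## Perturbations

* **Inhibition** adds a complementary node `anti_<target>` with one
  inhibitory edge (default weight 1.0) onto the target, clamped at a
  constant activity (default 1.0; lower values model partial inhibition).
  The target is *not* removed: upstream signal still reaches it and a small
  flow leaks through, as inhibitor-titration experiments show. The
  complementary node sits outside the BFS layering, so its message — like
  any downstream regulator's — arrives with a one-step delay; the clamp
  holds from the end of the first sweep onward. Complementary edges keep
  weight 1.0 rather than a recomputed similarity value (a fresh node with
  no neighbors would get 1.0 anyway), and the similarity weighting of the
  original network is never recomputed after augmentation. Clamped nodes
  consume no random draws, so paired runs with and without a perturbation
  see identical R and noise streams — the basis of the paired statistics
  below.
* **Fixed assignments** model gain-of-function mutations (e.g.
  constitutively active Ras): the node's value is held at a constant for
  every step t >= 1, dominating dynamics and noise, and decoupling its
  downstream from its upstream.
* **Readout masking**: an inhibited molecule's own measurement is not
  experimentally interpretable, so reported trajectories replace that row
  with a user-chosen report value (default 0). Masking is cosmetic; the
  internal dynamics and downstream rows are untouched.

## Validation statistics

* **Pearson agreement** between per-node simulation summaries and an
  experimental activity table over shared (condition, node) keys; two-sided
  p from the t-transform with n-2 degrees of freedom. The per-run summary
  is the mean of X over iterations 1..T (a `last-k` tail mean is available),
  chosen because the paired trend test below also pairs the per-iteration
  values of a whole run.
* **Wilcoxon signed-rank** for the effect of a perturbation on one node:
  the T per-iteration values of the normal and perturbed runs (same seed)
  are paired, zero differences dropped, absolute differences midranked, and
  W taken as the smaller of the positive/negative rank sums, so

      Z = (W - n(n+1)/4) / sqrt( n(n+1)(2n+1)/24 ) <= 0.

  No continuity correction and no tie correction are applied; with T = 100
  and all differences one-signed this saturates at Z = -8.68. Two-sided p
  comes from the normal approximation — adequate at T = 100, and within
  ~10% of the exact distribution in the central range at n >= 12, but
  anti-conservative deep in the tail at small n.
* **Trend calls** at significance alpha = 0.01: `up` if p < alpha and the
  perturbed mean exceeds the normal mean, `down` for the reverse, `none`
  otherwise (including exactly tied means). No multiple-testing correction
  is applied across nodes.

## Synthetic networks and experiment tables

The fixtures module generates everything the tests and the acceptance
script need:

* the worked similarity motif (10 nodes, deterministic);
* signed cascades of arbitrary length;
* seeded random signed networks with ligand sources (in-degree 0), full
  reachability from the ligand set (repaired by adding edges from reached
  nodes where needed) and a requested inhibitory-edge fraction. The
  hepatocyte-scale preset (7 ligands, 40 nodes, ~15% inhibitory edges,
  density 0.06) mirrors the shape of curated inflammatory/growth signaling
  maps;
* synthetic experiment tables: the per-node summary of a real simulated
  trajectory plus clamped Gaussian noise (sigma = 0.05 is the standard
  condition used throughout the checks), emulating a normalized bead-based
  micro-ELISA readout.

What these fixtures do *not* emulate: the modular, compartment-organized
topology of real curated maps (random graphs have no community structure),
biological measurement artifacts beyond additive Gaussian noise, and the
specific wiring of published case-study networks — real edge lists can be
supplied as TSV/SIF files instead. Consequently, passing tests demonstrate
the correctness and invariances of the algorithms, not predictive accuracy
on any real cell system. One visible consequence: simulated activity spans
roughly the receptor-cap scale (~0–0.1), so a noisy-recovery correlation at
sigma = 0.05 is signal-to-noise limited by construction and is reported as
a measured recovery, not as an agreement benchmark.

## Problem sizes and numerical notes

Randomized property checks use many small networks (4–16 nodes, 5–50
steps, a few hundred configurations) rather than few large ones — the
invariants being checked (boundedness, monotonicity, reproducibility,
oracle agreement) are size-independent, and small cases enumerate more
topologies per unit work. Case-study-style runs use T = 100, the standard
iteration count for the reported statistics. All randomness flows through
`numpy.random.default_rng` seeded from the run seed; identical (network,
config, seed) triples give bitwise-identical trajectories. Trajectory CSVs
are written with fixed 6-decimal formatting so repeated runs are
byte-identical.

## Known limitations

* The stability draw is memoryless (fresh each step); real degradation is
  autocorrelated.
* The linear source ramp is the minimal monotone realization of a
  capped, systematically increasing receptor drive; sigmoidal binding
  kinetics are not modeled.
* The normal-approximation p saturates (p < 1e-18 at T = 100), so very
  strong effects are indistinguishable by p alone.
* Same-layer feedback resolution depends on the lexicographic visiting
  order; renaming nodes can change individual trajectories (never their
  invariants).
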