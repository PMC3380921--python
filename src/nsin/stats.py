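"""Validation statistics: Pearson agreement and Wilcoxon trend calls.

Simulated activity summaries are compared with experimental phosphoprotein
measurements (micro-ELISA style, normalized to [0, 1]) by Pearson
correlation over all (condition, node) pairs.  The effect of a perturbation
on one node is tested with a paired Wilcoxon signed-rank over the per-step
activities of the normal and perturbed runs; a significant change is called
``up`` or ``down`` by the shift in mean activity.

The signed-rank Z uses the convention of reporting the *smaller* of the
positive/negative rank sums, so Z is always <= 0 and its magnitude carries
the evidence:

    Z = (W - n(n+1)/4) / sqrt(n(n+1)(2n+1)/24)

over the n nonzero differences, midranks for ties, no continuity correction,
two-sided p from the normal approximation.  For n = 100 all-same-sign pairs
this saturates at Z = -8.68.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats as sps

from .errors import DegenerateDataError, JoinError

TREND_ALPHA = 0.01


def pearson(x, y) -> tuple[float, float]:
    """Sample Pearson r and two-sided p (t-transform, n-2 df)."""
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.shape != y.shape:
        raise ValueError(f"length mismatch: {x.shape} vs {y.shape}")
    if x.size < 3:
        raise DegenerateDataError(f"need at least 3 pairs, got {x.size}")
    if np.ptp(x) == 0 or np.ptp(y) == 0:
        raise DegenerateDataError("zero variance in one of the vectors")
    r, p = sps.pearsonr(x, y)
    return float(r), float(p)


def wilcoxon_signed_rank(normal, perturbed) -> tuple[float, float]:
    """Paired signed-rank Z (smaller-rank-sum convention, Z <= 0) and p.

    Zero differences are dropped; absolute differences are midranked.
    """
    a = np.asarray(normal, dtype=float)
    b = np.asarray(perturbed, dtype=float)
    if a.shape != b.shape:
        raise ValueError(f"length mismatch: {a.shape} vs {b.shape}")
    d = b - a
    d = d[d != 0]
    n = d.size
    if n == 0:
        raise DegenerateDataError("all paired differences are zero")
    ranks = sps.rankdata(np.abs(d))
    w_pos = float(ranks[d > 0].sum())
    w_neg = float(ranks[d < 0].sum())
    w = min(w_pos, w_neg)
    mu = n * (n + 1) / 4.0
    sigma = np.sqrt(n * (n + 1) * (2 * n + 1) / 24.0)
    z = (w - mu) / sigma
    p = min(1.0, 2.0 * sps.norm.cdf(z))
    return float(z), float(p)


def trend_call(
    z: float,
    p: float,
    mean_normal: float,
    mean_perturbed: float,
    alpha: float = TREND_ALPHA,
) -> str:
    """Classify a perturbation response: ``up``, ``down`` or ``none``.

    ``none`` whenever p >= alpha, or when the means are exactly tied (no
    direction to call).
    """
    if p >= alpha:
        return "none"
    if mean_perturbed > mean_normal:
        return "up"
    if mean_perturbed < mean_normal:
        return "down"
    return "none"


_ARROWS = {"up": "↑", "down": "↓", "none": "-"}


@dataclass
class ValidationReport:
    """Joined simulation/experiment pairs with their agreement statistics."""

    pairs: pd.DataFrame  # columns: condition, node, simulated, experimental
    pearson_r: float
    pearson_p: float
    unmatched_sim: list[tuple[str, str]] = field(default_factory=list)
    unmatched_exp: list[tuple[str, str]] = field(default_factory=list)

    def to_tsv(self, path) -> None:
        with open(path, "w") as fh:
            fh.write(f"# pearson_r\t{self.pearson_r:.6f}\n")
            fh.write(f"# pearson_p\t{self.pearson_p:.3e}\n")
            if self.unmatched_sim:
                fh.write(f"# unmatched_simulation_keys\t{len(self.unmatched_sim)}\n")
            if self.unmatched_exp:
                fh.write(f"# unmatched_experiment_keys\t{len(self.unmatched_exp)}\n")
            self.pairs.to_csv(fh, sep="\t", index=False, float_format="%.6f")


def correlate_experiment(
    sim_summary: pd.DataFrame,
    exp_table: pd.DataFrame,
) -> ValidationReport:
    """Inner-join (condition, node) keyed tables and correlate the values.

    Both tables need columns ``condition``, ``node``, ``value``; keys present
    in only one table are flagged in the report, an empty intersection is an
    error.
    """
    for name, df in (("simulation", sim_summary), ("experiment", exp_table)):
        missing = {"condition", "node", "value"} - set(df.columns)
        if missing:
            raise ValueError(f"{name} table lacks columns {sorted(missing)}")
    merged = sim_summary.merge(
        exp_table, on=["condition", "node"], how="outer",
        suffixes=("_sim", "_exp"), indicator=True,
    )
    both = merged[merged["_merge"] == "both"]
    if both.empty:
        raise JoinError("simulation and experiment tables share no (condition, node) keys")
    unmatched_sim = [
        (r.condition, r.node)
        for r in merged[merged["_merge"] == "left_only"].itertuples()
    ]
    unmatched_exp = [
        (r.condition, r.node)
        for r in merged[merged["_merge"] == "right_only"].itertuples()
    ]
    pairs = both.rename(
        columns={"value_sim": "simulated", "value_exp": "experimental"}
    )[["condition", "node", "simulated", "experimental"]].reset_index(drop=True)
    r, p = pearson(pairs["simulated"], pairs["experimental"])
    return ValidationReport(pairs, r, p, unmatched_sim, unmatched_exp)


def compare_trajectories(
    normal,
    perturbed,
    nodes=None,
    alpha: float = TREND_ALPHA,
) -> pd.DataFrame:
    """Per-node Wilcoxon comparison of two trajectories (same seed, paired steps).

    Returns a table (node, Z, p, mean_normal, mean_perturbed, trend); nodes
    whose paired differences are all zero get Z = 0, p = 1, trend ``none``.
    """
    nodes = list(nodes) if nodes is not None else [
        n for n in normal.nodes if n in perturbed.node_index
    ]
    rows = []
    for n in nodes:
        a = normal.series(n)[1:]
        b = perturbed.series(n)[1:]
        try:
            z, p = wilcoxon_signed_rank(a, b)
        except DegenerateDataError:
            z, p = 0.0, 1.0
        m_a, m_b = float(a.mean()), float(b.mean())
        rows.append(
            {
                "node": n,
                "Z": z,
                "p": p,
                "mean_normal": m_a,
                "mean_perturbed": m_b,
                "trend": trend_call(z, p, m_a, m_b, alpha),
            }
        )
    return pd.DataFrame(rows)


def write_wilcoxon_table(table: pd.DataFrame, path) -> None:
    out = table.copy()
    out["arrow"] = out["trend"].map(_ARROWS)
    out.to_csv(path, sep="\t", index=False, float_format="%.6f")
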