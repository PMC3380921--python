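import dataclasses

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from nsin import (
    NetworkLookupError,
    SimulationConfig,
    StabilitySampler,
    ValidationError,
    bfs_layers,
    cascade,
    node_update,
    read_network,
    read_trajectory_csv,
    simulate,
    source_activity,
    weight_all_edges,
)

from conftest import quick_config


class TestBfsLayers:
    def test_chain(self, chain3):
        assert bfs_layers(chain3, {"v1"}) == {"v1": 0, "v2": 1, "v3": 2}

    def test_diamond_shortest_path(self):
        g = read_network(["A B +1", "A C +1", "B D +1", "C D +1"])
        assert bfs_layers(g, {"A"})["D"] == 2

    def test_two_sources_disjoint_chains(self):
        g = read_network(["A B +1", "E F +1"])
        layers = bfs_layers(g, {"A", "E"})
        assert layers == {"A": 0, "E": 0, "B": 1, "F": 1}

    def test_unknown_source(self, chain3):
        with pytest.raises(NetworkLookupError):
            bfs_layers(chain3, {"ghost"})

    def test_unreachable_nodes_absent(self):
        g = read_network(["A B +1", "C D +1"])
        assert set(bfs_layers(g, {"A"})) == {"A", "B"}


class TestSourceActivity:
    def test_zero_input_stays_zero(self):
        assert source_activity(7, 100, 0.0) == 0.0

    def test_full_input_caps_at_tenth(self):
        assert source_activity(100, 100, 1.0, 10.0) == pytest.approx(0.1)

    def test_halfway_ramp(self):
        assert source_activity(50, 100, 1.0, 10.0) == pytest.approx(0.05)

    def test_bad_divisor(self):
        with pytest.raises(ValueError):
            source_activity(1, 10, 0.5, 0.0)

    @given(t=st.integers(1, 100), a=st.floats(0, 1))
    @settings(max_examples=50, derandomize=True)
    def test_ramp_never_exceeds_cap(self, t, a):
        assert 0.0 <= source_activity(t, 100, a, 10.0) <= a / 10.0 + 1e-12


class TestNodeUpdate:
    def test_saturated_activator(self):
        assert node_update(0.0, [(1.0, +1, 1.0)], R=0.0, xi=0.0) == 1.0

    def test_pure_decay_under_repressor_only(self):
        assert node_update(0.8, [(1.0, -1, 1.0)], R=0.5, xi=0.0) == pytest.approx(0.4)

    def test_partial_activator(self):
        assert node_update(0.0, [(0.5, +1, 0.5)], R=0.0, xi=0.0) == pytest.approx(0.25)

    def test_decay_without_activators_is_monotone(self):
        rng = np.random.default_rng(5)
        x = 0.9
        for _ in range(50):
            x_next = node_update(x, [(0.3, -1, 1.0)], R=float(rng.uniform()), xi=0.0)
            assert x_next <= x
            x = x_next

    @given(
        regs=st.lists(
            st.tuples(st.floats(0, 1), st.sampled_from([+1, -1]), st.floats(0, 1)),
            max_size=6,
        ),
        x_prev=st.floats(0, 1),
        R=st.floats(0, 1),
        xi=st.floats(-0.05, 0.05),
    )
    @settings(max_examples=200, derandomize=True)
    def test_bounded_and_order_free(self, regs, x_prev, R, xi):
        out = node_update(x_prev, regs, R, xi)
        assert 0.0 <= out <= 1.0
        assert out == pytest.approx(node_update(x_prev, list(reversed(regs)), R, xi))


class TestSemiSynchronousSchedule:
    def test_single_sweep_reaches_chain_end(self):
        # weight-1 chain, no noise: at t=1 the whole cascade already carries
        # a nonzero echo of the source's fresh t=1 value
        g = cascade(3)
        w = {k: 1.0 for k in weight_all_edges(g)}
        cfg = quick_config(iterations=10, seed=4)
        traj = simulate(g, w, cfg)[0]
        assert traj.value("v3", 1) > 0.0

    def test_synchronous_mode_delays_by_layer_depth(self):
        g = cascade(3)
        w = {k: 1.0 for k in weight_all_edges(g)}
        sync = simulate(g, w, quick_config(iterations=10, seed=4, synchronous=True))[0]
        # under pure synchronous reads v3 sees nothing until t = 3
        assert sync.value("v3", 1) == 0.0
        assert sync.value("v3", 2) == 0.0
        assert sync.value("v3", 3) > 0.0

    def test_same_layer_feedback_reproducible(self):
        g = read_network(["A B +1", "A C +1", "B C +1", "C B +1"])
        w = weight_all_edges(g)
        cfg = SimulationConfig(sources={"A": 1.0}, iterations=30, seed=9)
        t1 = simulate(g, w, cfg)[0]
        t2 = simulate(g, w, cfg)[0]
        assert np.array_equal(t1.values, t2.values)


class TestStabilitySampler:
    @pytest.mark.parametrize("regime,lo,hi", [
        ("default", 0.0, 1.0), ("short", 0.0, 0.5), ("long", 0.5, 1.0),
    ])
    def test_draws_stay_in_class_range(self, regime, lo, hi):
        sampler = StabilitySampler(np.random.default_rng(0))
        draws = [sampler.stability(regime) for _ in range(500)]
        assert all(lo <= d <= hi for d in draws)
        assert max(draws) - min(draws) > (hi - lo) * 0.8  # actually spans the range

    def test_stream_reproducible(self):
        a = StabilitySampler(np.random.default_rng(3))
        b = StabilitySampler(np.random.default_rng(3))
        assert [a.stability("default") for _ in range(10)] == [
            b.stability("default") for _ in range(10)
        ]


class TestSimulate:
    def test_zero_sources_zero_noise_stays_zero(self, chain3):
        cfg = quick_config(sources={"v1": 0.0}, noise_amplitude=0.0)
        traj = simulate(chain3, weight_all_edges(chain3), cfg)[0]
        assert np.all(traj.values == 0.0)

    def test_nonsource_nodes_start_at_zero(self, chain3):
        traj = simulate(chain3, weight_all_edges(chain3), quick_config())[0]
        assert np.all(traj.values[:, 0] == 0.0)

    def test_bounded_with_noise(self, hepatocyte):
        cfg = SimulationConfig(
            sources={"L1": 1.0, "L2": 0.7}, iterations=100, seed=2,
            noise_amplitude=0.05, half_life_mode="short",
        )
        traj = simulate(hepatocyte, weight_all_edges(hepatocyte), cfg)[0]
        assert traj.values.min() >= 0.0
        assert traj.values.max() <= 1.0

    def test_seed_reproducibility_and_divergence(self, hepatocyte):
        w = weight_all_edges(hepatocyte)
        cfg = SimulationConfig(sources={"L1": 1.0}, iterations=50, seed=7,
                               half_life_mode="short")
        a = simulate(hepatocyte, w, cfg)[0]
        b = simulate(hepatocyte, w, cfg)[0]
        assert np.array_equal(a.values, b.values)
        c = simulate(hepatocyte, w, dataclasses.replace(cfg, seed=8))[0]
        assert not np.array_equal(a.values, c.values)

    def test_half_life_both_yields_two_variants(self, motif):
        # i is an ambiguous hub, so "both" runs short and long regimes
        cfg = SimulationConfig(sources={"i": 1.0}, iterations=20, seed=1)
        trajs = simulate(motif, weight_all_edges(motif), cfg)
        assert [t.variant for t in trajs] == ["short", "long"]

    def test_single_mode_yields_one(self, motif):
        cfg = SimulationConfig(sources={"i": 1.0}, iterations=20, seed=1,
                               half_life_mode="long")
        trajs = simulate(motif, weight_all_edges(motif), cfg)
        assert [t.variant for t in trajs] == ["long"]

    def test_unreachable_nodes_excluded_from_output(self):
        g = read_network(["A B +1", "C D +1"])
        traj = simulate(g, weight_all_edges(g), quick_config(sources={"A": 1.0}))[0]
        assert set(traj.nodes) == {"A", "B"}

    def test_config_validation_collects_all_failures(self, chain3):
        cfg = SimulationConfig(sources={"ghost": 2.0}, iterations=0,
                               noise_amplitude=-1.0)
        with pytest.raises(ValidationError) as err:
            simulate(chain3, {}, cfg)
        msg = str(err.value)
        for fragment in ("ghost", "iterations", "noise"):
            assert fragment in msg

    def test_too_many_sources_rejected(self, hepatocyte):
        cfg = SimulationConfig(sources={f"L{k}": 0.5 for k in range(1, 8)} |
                               {f"N{k}": 0.5 for k in range(1, 5)})
        with pytest.raises(ValidationError, match="1..10"):
            simulate(hepatocyte, weight_all_edges(hepatocyte), cfg)


class TestMonotoneStimulusResponse:
    def test_mean_activity_nondecreasing_in_stimulus(self):
        # activator-only feed-forward chain; average over 30 seeds
        g = cascade(4)
        w = weight_all_edges(g)
        levels = [0.2, 0.5, 1.0]
        means = {a: np.zeros(4) for a in levels}
        for seed in range(30):
            for a in levels:
                cfg = SimulationConfig(sources={"v1": a}, iterations=100,
                                       seed=seed, half_life_mode="short")
                traj = simulate(g, w, cfg)[0]
                s = traj.summary()
                means[a] += np.array([s[n] for n in traj.nodes])
        for lo, hi in zip(levels, levels[1:]):
            assert np.all(means[hi] >= means[lo])


def test_trajectory_csv_round_trip(tmp_path, chain3):
    traj = simulate(chain3, weight_all_edges(chain3), quick_config(iterations=20))[0]
    path = tmp_path / "traj.csv"
    traj.to_csv(path)
    loaded = read_trajectory_csv(path)
    assert loaded.nodes == traj.nodes
    assert np.allclose(loaded.values, traj.values, atol=1e-6)


def test_summary_reductions(chain3):
    traj = simulate(chain3, weight_all_edges(chain3), quick_config(iterations=40))[0]
    full = traj.summary("mean")
    tail = traj.summary("last-k", k=5)
    # the ramp grows, so the late window exceeds the whole-run mean at the source
    assert tail["v1"] > full["v1"]
    with pytest.raises(ValueError):
        traj.summary("median")
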