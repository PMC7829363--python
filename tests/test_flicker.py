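import numpy as np
import pytest
from scipy import stats

import cogmap as cm
from cogmap.flicker import (
    FlickerConfig,
    betti_time_series,
    clique_complex_at,
    evolve_flicker_timeline,
    find_stabilization_threshold,
    inject_replays,
    lifetime_statistics,
    link_activations,
    stability_summary,
)


def simple_acts():
    return {(0, 1): [1.0, 5.0, 9.0], (1, 2): [2.0], (0, 2): [3.0, 20.0]}


class TestEvolution:
    def test_infinite_tau_reproduces_perennial_graph(self, small_assembly):
        tl = evolve_flicker_timeline(
            small_assembly["acts"], FlickerConfig(tau=np.inf), small_assembly["duration"]
        )
        for link, acts in small_assembly["acts"].items():
            assert tl.intervals[link] == [(acts[0], small_assembly["duration"])]
        # cumulative first-appearance graph at every probed step
        for t in (100.0, 400.0, 800.0):
            active = set(tl.active_links(t))
            expected = {l for l, a in small_assembly["acts"].items() if a[0] <= t}
            assert active == expected

    def test_quenched_single_activation_support(self):
        tl = evolve_flicker_timeline(
            {(0, 1): [10.0]}, FlickerConfig(mode="quenched", tau=5.0), 100.0
        )
        assert tl.intervals[(0, 1)] == [(10.0, 15.0)]
        assert (0, 1) in tl.active_links(14.9)
        assert (0, 1) not in tl.active_links(15.1)

    def test_quenched_rejuvenation_extends_life(self):
        tl = evolve_flicker_timeline(
            {(0, 1): [10.0, 13.0]}, FlickerConfig(mode="quenched", tau=5.0), 100.0
        )
        assert tl.intervals[(0, 1)] == [(10.0, 18.0)]

    def test_exponential_survival_matches_exponential_law(self):
        """Links activated once: lifetimes are draws from Exp(tau)."""
        acts = {(i, 1000 + i): [0.0] for i in range(600)}
        tau = 30.0
        tl = evolve_flicker_timeline(
            acts, FlickerConfig(mode="exponential", tau=tau, seed=0), 1e9
        )
        lifetimes = np.array([iv[0][1] - iv[0][0] for iv in tl.intervals.values()])
        ks = stats.kstest(lifetimes, "expon", args=(0, tau))
        assert ks.pvalue > 0.01

    def test_unknown_mode_rejected(self):
        with pytest.raises(ValueError):
            FlickerConfig(mode="sublimation")

    def test_latency_step_floor_enforced(self):
        with pytest.raises(ValueError):
            FlickerConfig(mode="windowed", latency=100.0, latency_step=0.5)

    def test_windowed_activity_rule(self):
        cfg = FlickerConfig(mode="windowed", latency=10.0, latency_step=1.0)
        tl = evolve_flicker_timeline(simple_acts(), cfg, 40.0)
        assert (0, 2) in tl.active_links(12.9)
        assert (0, 2) not in tl.active_links(14.0)
        assert (0, 2) in tl.active_links(21.0)

    def test_random_control_matches_activation_rate(self):
        acts = {(0, 1): list(np.linspace(1, 999, 500))}
        cfg = FlickerConfig(mode="random-control", tau=np.inf, seed=4)
        tl = evolve_flicker_timeline(acts, cfg, 1000.0)
        assert tl.intervals[(0, 1)][0][1] == 1000.0

    def test_event_log_reconstructs_active_sets(self, small_assembly):
        cfg = FlickerConfig(mode="exponential", tau=60.0, seed=1)
        tl = evolve_flicker_timeline(
            small_assembly["acts"], cfg, small_assembly["duration"]
        )
        log = tl.event_log()
        for t in (150.0, 450.0, 850.0):
            replayed = set()
            for ts, u, v, kind in log:
                if ts > t:
                    break
                if kind == "birth":
                    replayed.add((u, v))
                else:
                    replayed.discard((u, v))
            assert replayed == set(tl.active_links(t))


class TestBettiSeries:
    def test_constant_active_set_constant_series(self):
        acts = {(0, 1): [0.0], (1, 2): [0.0], (0, 2): [0.0]}
        tl = evolve_flicker_timeline(acts, FlickerConfig(tau=np.inf), 50.0)
        ts, betti = betti_time_series(tl, d_max=1, times=np.arange(5.0, 50.0, 5.0))
        assert np.all(betti == betti[0])
        assert tuple(betti[0]) == (1, 0)  # filled triangle

    def test_matches_brute_force_betti_on_sampled_steps(self, small_assembly):
        cfg = FlickerConfig(mode="exponential", tau=50.0, seed=2)
        tl = evolve_flicker_timeline(
            small_assembly["acts"], cfg, small_assembly["duration"]
        )
        rng = np.random.default_rng(0)
        times = rng.uniform(100, 850, 5)
        ts, betti = betti_time_series(tl, d_max=1, times=times)
        for t, row in zip(ts, betti):
            assert tuple(row) == cm.betti_numbers(clique_complex_at(tl, t, 2), 1)

    def test_infinite_tau_series_reaches_perennial_limit(self, small_assembly):
        tl = evolve_flicker_timeline(
            small_assembly["acts"], FlickerConfig(tau=np.inf), small_assembly["duration"]
        )
        ts, betti = betti_time_series(
            tl, d_max=1, times=np.array([870.0, 880.0, 890.0])
        )
        final = cm.betti_numbers(
            clique_complex_at(tl, small_assembly["duration"], 2), 1
        )
        assert all(tuple(row) == final for row in betti)


class TestLifetimes:
    def test_pure_decay_fit_recovers_tau(self):
        acts = {(i, 1000 + i): [0.0] for i in range(800)}
        tau = 25.0
        tl = evolve_flicker_timeline(
            acts, FlickerConfig(mode="exponential", tau=tau, seed=3), 1e9
        )
        st = lifetime_statistics(tl, with_triangles=False)
        assert st.tau_e[2] == pytest.approx(tau, rel=0.15)
        assert st.survivor_fraction == 0.0

    def test_survivors_excluded_and_counted(self):
        acts = {(i, 100 + i): [0.0] for i in range(400)}
        tl = evolve_flicker_timeline(
            acts, FlickerConfig(mode="exponential", tau=50.0, seed=4), 60.0
        )
        st = lifetime_statistics(tl, with_triangles=False)
        assert 0 < st.survivor_fraction < 1
        assert np.all(st.lifetimes[2] < 60.0)

    def test_triangle_lifetime_bounded_by_link_spans(self):
        """Hand-built log: the triangle lives exactly on the intersection of
        its links' activity intervals."""
        acts = {(0, 1): [0.0], (1, 2): [2.0], (0, 2): [4.0]}
        tl = evolve_flicker_timeline(
            acts, FlickerConfig(mode="quenched", tau=10.0), 100.0
        )
        st = lifetime_statistics(tl)
        # links live on [0,10],[2,12],[4,14]; triangle on [4,10]
        assert st.lifetimes[3] == pytest.approx([6.0])

    def test_reactivation_interval_collapses_bursts(self):
        acts = {(0, 1): [0.0, 0.2, 0.4, 30.0, 30.2, 60.0]}
        tl = evolve_flicker_timeline(acts, FlickerConfig(tau=np.inf), 100.0)
        st = lifetime_statistics(tl, with_triangles=False)
        assert st.mean_reactivation_interval == pytest.approx(30.0)


class TestStability:
    def test_constant_correct_series_zero_fluctuation(self):
        times = np.arange(10.0, 100.0, 10.0)
        betti = np.tile([1, 1], (len(times), 1))
        ss = stability_summary(times, betti, (1, 1), 20.0)
        assert ss.fluctuation_fraction == 0.0

    def test_always_wrong_series_full_fluctuation(self):
        times = np.arange(10.0, 100.0, 10.0)
        betti = np.tile([2, 0], (len(times), 1))
        ss = stability_summary(times, betti, (1, 1), 0.0)
        assert ss.fluctuation_fraction == 1.0

    def test_threshold_finder(self):
        assert find_stabilization_threshold([50, 100, 150], [0.4, 0.0, 0.0]) == 100
        assert find_stabilization_threshold([50, 100], [0.4, 0.2]) is None

    def test_fluctuation_nonincreasing_in_tau(self, small_assembly):
        """Slower decay stabilizes the complex (paired seeds, small tau grid)."""
        acts = small_assembly["acts"]
        dur = small_assembly["duration"]
        times = np.arange(500.0, dur, 60.0)
        means = []
        for tau in (0.8, 2.5, 6.0):
            fr = []
            for seed in range(3):
                tl = evolve_flicker_timeline(
                    acts,
                    FlickerConfig(
                        mode="exponential",
                        tau=tau * small_assembly["reactivation"],
                        seed=seed,
                    ),
                    dur,
                )
                ts, betti = betti_time_series(tl, d_max=1, times=times)
                fr.append(
                    stability_summary(ts, betti, (1, 1), 500.0).fluctuation_fraction
                )
            means.append(np.mean(fr))
        assert means[0] >= means[1] >= means[2]

    def test_quenched_at_least_as_unstable_as_exponential(self, small_assembly):
        """Lifetime spread (the exponential tail) is what builds the stable
        core; deterministic lifetimes fluctuate more."""
        acts = small_assembly["acts"]
        dur = small_assembly["duration"]
        tau = 3.0 * small_assembly["reactivation"]
        times = np.arange(450.0, dur, 60.0)
        frs = {}
        for mode in ("exponential", "quenched"):
            vals = []
            for seed in range(3):
                tl = evolve_flicker_timeline(
                    acts, FlickerConfig(mode=mode, tau=tau, seed=seed), dur
                )
                ts, betti = betti_time_series(tl, d_max=1, times=times)
                vals.append(
                    stability_summary(ts, betti, (1, 1), 450.0).fluctuation_fraction
                )
            frs[mode] = np.mean(vals)
        assert frs["quenched"] >= frs["exponential"]

    def test_windowed_simplex_count_stable_and_pool_renewing(self, small_assembly):
        """For latencies past the formation time the complex keeps its size
        (count CV < 0.15) while its simplex pool turns over."""
        acts = small_assembly["acts"]
        dur = small_assembly["duration"]
        lat = 150.0
        tl = evolve_flicker_timeline(
            acts, FlickerConfig(mode="windowed", latency=lat, latency_step=7.5), dur
        )
        times = np.arange(300.0, dur, 40.0)
        counts, pools = [], []
        for t in times:
            simp = clique_complex_at(tl, t, 2)
            counts.append(len(simp))
            pools.append(set(simp))
        counts = np.array(counts)
        assert counts.std() / counts.mean() < 0.15
        # pool renewal: overlap decays with temporal separation beyond latency
        def jaccard(a, b):
            return len(a & b) / len(a | b)

        near = np.mean([jaccard(pools[i], pools[i + 1]) for i in range(len(pools) - 1)])
        sep = int(np.ceil(2 * lat / 40.0))
        far = np.mean(
            [jaccard(pools[i], pools[i + sep]) for i in range(len(pools) - sep)]
        )
        assert far < near


class TestReplays:
    def test_zero_rate_identity(self):
        acts = simple_acts()
        assert inject_replays(acts, 0.0, 100.0, seed=0) == acts

    def test_replays_reuse_previously_active_links(self):
        acts = simple_acts()
        out = inject_replays(acts, 600.0, 100.0, seed=1)
        for link, times in out.items():
            original = set(acts[link])
            for t in times:
                if t not in original:
                    assert t > acts[link][0]  # only after the link existed
        assert sum(map(len, out.values())) > sum(map(len, acts.values()))
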