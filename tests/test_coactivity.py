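import itertools
from math import comb

import numpy as np
import networkx as nx
import pytest
from hypothesis import given, settings, strategies as st

import cogmap as cm
from cogmap.coactivity import CoactivityEvent, _clique_accumulation_time


def raster(trains, duration):
    return cm.SpikeTrains([np.asarray(t, float) for t in trains], duration)


class TestEventDetection:
    def test_pair_in_same_window(self):
        sp = raster([[0.05], [0.12]], 1.0)
        ev = cm.detect_coactivity_events(sp, cm.CoactivityConfig(window=0.2))
        assert [(e.cells, e.t) for e in ev] == [((0, 1), 0.1)]

    def test_disjoint_windows_no_event(self):
        sp = raster([[0.05], [0.40]], 1.0)
        ev = cm.detect_coactivity_events(sp, cm.CoactivityConfig(window=0.2))
        assert ev == []

    def test_higher_orders_when_requested(self):
        sp = raster([[0.01], [0.05], [0.12]], 1.0)
        cfg = cm.CoactivityConfig(window=0.2, k_max=3)
        ev = cm.detect_coactivity_events(sp, cfg)
        cells = {e.cells for e in ev}
        assert cells == {(0, 1), (0, 2), (1, 2), (0, 1, 2)}

    def test_jitter_changes_counts_only_boundedly(self, small_session):
        """Event statistics are robust to 50% window jitter."""
        spikes = small_session["spikes"]
        base = len(
            cm.detect_coactivity_events(spikes, cm.CoactivityConfig(window=0.2))
        )
        counts = [
            len(
                cm.detect_coactivity_events(
                    spikes,
                    cm.CoactivityConfig(window=0.2, jitter=0.5, shift=True),
                    seed=s,
                )
            )
            for s in range(20)
        ]
        assert np.all(np.abs(np.array(counts) - base) / base < 0.25)

    def test_sliding_placement_superset_of_binned(self):
        sp = raster([[0.05, 0.31], [0.12, 0.38]], 1.0)
        binned = cm.detect_coactivity_events(sp, cm.CoactivityConfig(window=0.2))
        sliding = cm.detect_coactivity_events(
            sp, cm.CoactivityConfig(window=0.2, placement="sliding", step=0.05)
        )
        assert {e.cells for e in binned} <= {e.cells for e in sliding}


class TestCoactivityGraph:
    def test_empty_events_empty_graph(self):
        g = cm.build_coactivity_graph([], duration=10.0)
        assert g.number_of_edges() == 0

    def test_recurring_pair_history(self):
        ev = [CoactivityEvent((1, 2), t) for t in (0.1, 0.5, 1.1, 2.3, 4.0)]
        g = cm.build_coactivity_graph(ev, duration=60.0)
        assert g[1][2]["count"] == 5
        assert g[1][2]["first"] == 0.1
        assert g[1][2]["rate"] == pytest.approx(5.0)

    def test_edge_count_equals_distinct_pairs(self, small_session):
        g = small_session["graph"]
        pairs = {e.cells for e in small_session["events"] if len(e.cells) == 2}
        assert g.number_of_edges() == len(pairs)


class TestFilteredComplexConstruction:
    def test_clique_accumulation_triangle_at_last_link(self):
        ev = [
            CoactivityEvent((1, 2), 1.0),
            CoactivityEvent((2, 3), 2.0),
            CoactivityEvent((1, 3), 3.0),
        ]
        g = cm.build_coactivity_graph(ev, duration=10.0)
        fc = cm.build_filtered_complex(g, "clique-accumulation")
        assert fc.times[(1, 2, 3)] == 3.0

    def test_simplex_detection_needs_triple_event(self):
        ev = [
            CoactivityEvent((1, 2), 1.0),
            CoactivityEvent((2, 3), 2.0),
            CoactivityEvent((1, 3), 3.0),
        ]
        fc = cm.build_filtered_complex(ev, "simplex-detection")
        assert (1, 2, 3) not in fc.times

    def test_finite_integration_window_gates_cliques(self):
        ev = [
            CoactivityEvent((1, 2), 1.0),
            CoactivityEvent((2, 3), 2.0),
            CoactivityEvent((1, 3), 30.0),
        ]
        g = cm.build_coactivity_graph(ev, duration=60.0)
        tight = cm.build_filtered_complex(
            g, "clique-accumulation", cm.CoactivityConfig(integration_window=5.0)
        )
        assert (1, 2, 3) not in tight.times
        loose = cm.build_filtered_complex(
            g, "clique-accumulation", cm.CoactivityConfig(integration_window=60.0)
        )
        assert loose.times[(1, 2, 3)] == 30.0

    def test_accumulation_time_brute_force(self):
        rng = np.random.default_rng(0)
        for _ in range(50):
            edge_times = [
                sorted(rng.uniform(0, 100, rng.integers(1, 6)).tolist())
                for _ in range(3)
            ]
            lookback = rng.uniform(5, 50)
            got = _clique_accumulation_time(edge_times, lookback)
            # brute force over a fine grid of candidate times
            grid = sorted(set(itertools.chain.from_iterable(edge_times)))
            want = None
            for t in grid:
                if all(any(t - lookback <= a <= t for a in ts) for ts in edge_times):
                    want = t
                    break
            assert got == want

    def test_eta_matches_brute_force_pair_count(self, small_session):
        fc = cm.build_filtered_complex(
            small_session["graph"], "clique-accumulation", small_session["cfg"]
        )
        n = small_session["pf"].n_cells
        pairs = {e.cells for e in small_session["events"] if len(e.cells) == 2}
        assert fc.eta(n)[1] == pytest.approx(len(pairs) / comb(n, 2))

    def test_face_closure_and_monotonicity(self, small_session):
        fc = cm.build_filtered_complex(
            small_session["graph"], "clique-accumulation", small_session["cfg"]
        )
        fc.validate()  # raises on violation

    def test_growth_monotonicity(self, small_session):
        fc = cm.build_filtered_complex(
            small_session["graph"], "clique-accumulation", small_session["cfg"]
        )
        early = set(fc.subcomplex_at(300.0).times)
        late = set(fc.subcomplex_at(600.0).times)
        assert early <= late

    def test_detection_complex_inside_accumulation_complex(self):
        sp = raster(
            [[0.05, 1.05], [0.11, 2.11], [0.13, 2.13], [3.0]], 4.0
        )
        cfg = cm.CoactivityConfig(window=0.2, k_max=4)
        ev = cm.detect_coactivity_events(sp, cfg)
        det = cm.build_filtered_complex(ev, "simplex-detection", cfg)
        g = cm.build_coactivity_graph(ev, duration=4.0)
        acc = cm.build_filtered_complex(g, "clique-accumulation", cfg)
        assert set(det.times) <= set(acc.times)

    def test_complex_file_round_trip(self, tmp_path):
        ev = [
            CoactivityEvent((1, 2), 1.0),
            CoactivityEvent((2, 3), 2.0),
            CoactivityEvent((1, 3), 3.0),
        ]
        g = cm.build_coactivity_graph(ev, duration=10.0)
        fc = cm.build_filtered_complex(g, "clique-accumulation")
        path = tmp_path / "complex.txt"
        fc.write(path)
        back = cm.FilteredComplex.read(path)
        assert back.times == pytest.approx(fc.times)


@settings(max_examples=25, deadline=None, derandomize=True)
@given(st.lists(
    st.tuples(
        st.integers(0, 7), st.integers(0, 7),
        st.floats(0.1, 50, allow_nan=False)
    ),
    min_size=1, max_size=30,
))
def test_random_event_streams_yield_valid_complexes(raw):
    events = [
        CoactivityEvent((min(u, v), max(u, v)), t) for u, v, t in raw if u != v
    ]
    events.sort(key=lambda e: e.t)
    g = cm.build_coactivity_graph(events, duration=50.0)
    fc = cm.build_filtered_complex(g, "clique-accumulation")
    fc.validate()


class TestAssemblySelection:
    def test_zero_threshold_keeps_graph(self, small_session):
        g = small_session["graph"]
        gs = cm.select_assembly_subgraph(g, xi=0.0)
        assert gs.number_of_edges() == g.number_of_edges()

    def test_threshold_above_max_rate_empties(self, small_session):
        g = small_session["graph"]
        top = max(d["rate"] for _, _, d in g.edges(data=True))
        gs = cm.select_assembly_subgraph(g, xi=top + 1)
        assert gs.number_of_edges() == 0
        assert gs.number_of_nodes() == g.number_of_nodes()

    def test_top_n0_selection_builds_hubs_beyond_random_graph_tail(self, small_arena):
        """Keeping each cell's n0 most frequent partners yields hub cells
        whose degree exceeds the tail of a Poisson (random-graph) degree
        distribution at the same mean degree, while guaranteeing that no
        previously wired cell is disconnected."""
        from scipy.stats import poisson

        hubby = 0
        for seed in range(10):
            traj = cm.simulate_trajectory(small_arena, 240.0, seed=40 + seed)
            pf = cm.sample_place_field_map(small_arena, 15, 25, 120, seed=50 + seed)
            spikes = cm.generate_spike_trains(pf, traj, seed=60 + seed)
            ev = cm.detect_coactivity_events(spikes, cm.CoactivityConfig())
            g = cm.build_coactivity_graph(ev, duration=spikes.duration)
            gn = cm.select_assembly_subgraph(g, n0=3)
            degrees = np.array([d for _, d in gn.degree()])
            mean_deg = 2 * gn.number_of_edges() / gn.number_of_nodes()
            hubby += degrees.max() > poisson.ppf(0.999, mean_deg)
            for v, d in gn.degree():
                if g.degree(v) > 0:
                    assert d > 0
        assert hubby >= 7


class TestSynapticFilter:
    def _events(self, n=10000, seed=0):
        rng = np.random.default_rng(seed)
        return [
            CoactivityEvent((int(a), int(a + 1 + b)), float(t))
            for a, b, t in zip(
                rng.integers(0, 20, n), rng.integers(0, 5, n),
                np.sort(rng.uniform(0, 100, n)),
            )
        ]

    def test_perfect_synapses_identity(self):
        ev = self._events(500)
        out = cm.apply_synaptic_filter(ev, cm.SynapseModel(1.0, 0.0, 1.0, 0.0, seed=1))
        assert out == ev

    def test_zero_transmission_empties(self):
        ev = self._events(500)
        out = cm.apply_synaptic_filter(ev, cm.SynapseModel(0.0, 0.0, 1.0, 0.0, seed=1))
        assert out == []

    def test_retained_fraction_matches_binomial_oracle(self):
        ev = self._events(10000)
        model = cm.SynapseModel(0.7, 0.1, 0.9, 0.05, seed=2)
        out = cm.apply_synaptic_filter(ev, model)
        frac = len(out) / len(ev)
        # truncated-normal means are close to the modes here
        expect = 0.7 * 0.9
        assert frac == pytest.approx(expect, abs=0.05)


def test_nerve_of_dense_annular_cover_is_annulus():
    """Deterministic grid of fields over an arena with a hole: the nerve of
    the accessible cover has the annulus signature (1, 1)."""
    env = cm.make_environment(100, 100, [cm.RectHole(50, 50, 44, 44)])
    xs = np.arange(6.25, 100, 12.5)
    centers = np.array([[x, y] for x in xs for y in xs])
    n = len(centers)
    pf = cm.PlaceFieldMap(
        centers=centers, sizes=np.full(n, 36.0), rates=np.full(n, 10.0),
        s=36, f=10, a=0, b=0,
    )
    fc = cm.nerve_complex(pf, env, resolution=1.5, d_max=2)
    assert cm.betti_numbers(fc, 1) == (1, 1)
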