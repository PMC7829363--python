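"""Shared simulation fixtures.

Heavy pipelines are session-scoped: one exploration per arena, reused by
every test that only reads from it.  All randomness is seeded, so the suite
is deterministic.
"""

from __future__ import annotations

import numpy as np
import pytest

import cogmap as cm
from cogmap.flicker import (
    FlickerConfig,
    evolve_flicker_timeline,
    lifetime_statistics,
    link_activations,
)


@pytest.fixture(scope="session")
def small_arena():
    """80x80 cm arena with a 40x40 central hole (annular corridor)."""
    return cm.make_environment(80, 80, [cm.RectHole(40, 40, 40, 40)])


@pytest.fixture(scope="session")
def small_traj(small_arena):
    return cm.simulate_trajectory(small_arena, duration=900.0, seed=11)


@pytest.fixture(scope="session")
def small_session(small_arena, small_traj):
    """Full pipeline on the small arena: map, spikes, events, graph."""
    pf = cm.sample_place_field_map(small_arena, 15, 28, 300, seed=1)
    spikes = cm.generate_spike_trains(pf, small_traj, seed=2)
    cfg = cm.CoactivityConfig(d_max=2)
    events = cm.detect_coactivity_events(spikes, cfg, seed=3)
    graph = cm.build_coactivity_graph(events, duration=spikes.duration)
    return dict(pf=pf, spikes=spikes, cfg=cfg, events=events, graph=graph)


@pytest.fixture(scope="session")
def small_assembly(small_session):
    """Assembly subgraph activations and reactivation interval."""
    gs = cm.select_assembly_subgraph(small_session["graph"], xi=0.6)
    acts = link_activations(gs)
    duration = small_session["spikes"].duration
    perennial = evolve_flicker_timeline(acts, FlickerConfig(tau=np.inf), duration)
    dt = lifetime_statistics(perennial, with_triangles=False).mean_reactivation_interval
    return dict(
        graph=gs,
        acts=acts,
        duration=duration,
        reactivation=dt,
        full_graph=small_session["graph"],
    )


@pytest.fixture(scope="session")
def flicker_arena():
    """110x110 cm arena with a 60x60 hole: the transient-network testbed,
    whose link reactivation statistics sit at the ~30 s characteristic
    interval under default exploration."""
    return cm.make_environment(110, 110, [cm.RectHole(55, 55, 60, 60)])


@pytest.fixture(scope="session")
def flicker_traj(flicker_arena):
    return cm.simulate_trajectory(flicker_arena, duration=1500.0, seed=1)


@pytest.fixture(scope="session")
def flicker_assembly(flicker_arena, flicker_traj):
    """Dense ensemble (N=750) assembly network on the flicker arena."""
    pf = cm.sample_place_field_map(flicker_arena, 23, 28, 750, seed=2)
    spikes = cm.generate_spike_trains(pf, flicker_traj, seed=3)
    cfg = cm.CoactivityConfig(d_max=2)
    events = cm.detect_coactivity_events(spikes, cfg, seed=4)
    graph = cm.build_coactivity_graph(events, duration=spikes.duration)
    gs = cm.select_assembly_subgraph(graph, xi=0.6)
    return dict(acts=link_activations(gs), duration=spikes.duration)


@pytest.fixture(scope="session")
def flicker_betti_series(flicker_assembly):
    """Post-formation Betti series of the decaying assembly complex at
    decay constants 75 s and 125 s (six samples each)."""
    times = np.arange(720.0, 1500.0, 130.0)
    out = {}
    for tau in (75.0, 125.0):
        tl = evolve_flicker_timeline(
            flicker_assembly["acts"],
            FlickerConfig(mode="exponential", tau=tau, seed=5),
            flicker_assembly["duration"],
        )
        ts, betti = cm.betti_time_series(tl, d_max=1, times=times)
        out[tau] = (ts, betti)
    return out
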