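"""Learn the topology of an annular arena from simulated place-cell spiking.

Builds a 1.5 m arena with a central hole, simulates 20 minutes of
exploration and an ensemble of 350 place cells, assembles the filtered
clique coactivity complex, and reports the learning time: the moment from
which the complex's (b0, b1) equal the arena's (1, 1) for good.
"""

import cogmap as cm

env = cm.make_environment(150, 150, [cm.RectHole(75, 75, 60, 60)])
traj = cm.simulate_trajectory(env, duration=1200.0, seed=11)
pf = cm.sample_place_field_map(env, s=23, f=28, n_cells=350, seed=4)
spikes = cm.generate_spike_trains(pf, traj, seed=104)

cfg = cm.CoactivityConfig(window=0.2, d_max=2)
events = cm.detect_coactivity_events(spikes, cfg, seed=3)
graph = cm.build_coactivity_graph(events, duration=spikes.duration)
fc = cm.build_filtered_complex(graph, "clique-accumulation", cfg)
result = cm.learning_time(fc, env.reference_betti, horizon=spikes.duration)

print(f"arena reference Betti numbers : {env.reference_betti}")
print(f"spikes: {spikes.n_spikes}, links: {graph.number_of_edges()}, "
      f"simplexes: {len(fc)}")
print(f"learning succeeded            : {result.success}")
if result.success:
    print(f"learning time T_min           : {result.t_min:.1f} s")
print(f"final complex (b0, b1)        : {tuple(int(b) for b in result.betti[-1])}")
# T_min is the last moment a spurious topological defect (an extra
# component or transient hole) disappears from the growing complex.
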