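"""Theta-precession rescues borderline ensembles.

At a low peak firing rate the unmodulated ensemble often fails to form a
correct map within the session; phase precession concentrates spikes of
co-located cells at shared theta phases and raises the success rate over
the same place-field maps.
"""

import cogmap as cm

env = cm.make_environment(80, 80, [cm.RectHole(40, 40, 40, 40)])
traj = cm.simulate_trajectory(env, duration=600.0, seed=11)
cfg = cm.CoactivityConfig(window=0.2, d_max=2)


def successes(mod, n_maps=10):
    wins = 0
    for ms in range(n_maps):
        pf = cm.sample_place_field_map(env, s=15, f=4.0, n_cells=200, seed=100 + ms)
        spikes = cm.generate_spike_trains(pf, traj, mod, seed=200 + ms)
        ev = cm.detect_coactivity_events(spikes, cfg, seed=300 + ms)
        g = cm.build_coactivity_graph(ev, duration=spikes.duration)
        fc = cm.build_filtered_complex(g, "clique-accumulation", cfg)
        wins += cm.learning_time(fc, env.reference_betti,
                                 horizon=spikes.duration).success
    return wins


on = successes(cm.ModulationConfig(theta_on=True))
off = successes(None)
print(f"borderline ensemble (s=15 cm, f=4 Hz, N=200), 10 matched maps")
print(f"successful maps with theta-precession   : {on}/10")
print(f"successful maps without theta-precession: {off}/10")
# The same field maps succeed more often with precession: the rhythm
# enlarges the region of ensemble parameters that can learn the arena.
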