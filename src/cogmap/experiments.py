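"""Parameter-scan drivers: learning region, coactivity-window scan,
synaptic criticality and map additivity.

Statistical replicates follow the model's convention: one exploratory
trajectory per scan, many independently sampled place-field maps over it.
A run is *successful* when the complex attains the environment's (b0, b1)
and holds it to the end of the session; failed runs enter the success rate
but not the mean learning time.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats as sstats

from .environment import Environment, Trajectory
from .place_cells import ModulationConfig, generate_spike_trains, sample_place_field_map
from .coactivity import (
    CoactivityConfig,
    SynapseModel,
    apply_synaptic_filter,
    build_coactivity_graph,
    build_filtered_complex,
    detect_coactivity_events,
)
from .homology import LearningResult, learning_time


@dataclass
class EnsembleSpec:
    """(s, f, N) place-cell ensemble plus spread coefficients."""

    s: float = 23.0
    f: float = 28.0
    n_cells: int = 350
    a: float = 0.3
    b: float = 0.3


@dataclass
class LearningRun:
    result: LearningResult
    n_links: int
    n_simplices: int


def run_learning(
    env: Environment,
    traj: Trajectory,
    ensemble: EnsembleSpec,
    mod: ModulationConfig | None = None,
    cfg: CoactivityConfig | None = None,
    synapse: SynapseModel | None = None,
    seed: int | None = None,
    xi: float = 0.0,
) -> LearningRun:
    """One full pipeline pass: map -> spikes -> events -> clique complex ->
    learning time against the environment's reference signature.  ``xi > 0``
    restricts the coactivity graph to its assembly subgraph G(xi) first."""
    cfg = cfg or CoactivityConfig()
    ss = np.random.SeedSequence(seed)
    s_map, s_spk, s_det, s_syn = ss.spawn(4)
    pf = sample_place_field_map(
        env, ensemble.s, ensemble.f, ensemble.n_cells, ensemble.a, ensemble.b,
        seed=s_map,
    )
    spikes = generate_spike_trains(pf, traj, mod, seed=s_spk)
    events = detect_coactivity_events(spikes, cfg, seed=s_det)
    if synapse is not None:
        model = SynapseModel(
            synapse.p_star, synapse.dp, synapse.q_star, synapse.dq,
            seed=int(s_syn.generate_state(1)[0] % (2**31)),
        )
        events = apply_synaptic_filter(events, model)
    graph = build_coactivity_graph(events, duration=spikes.duration)
    if xi > 0:
        from .coactivity import select_assembly_subgraph

        graph = select_assembly_subgraph(graph, xi=xi)
    fc = build_filtered_complex(graph, "clique-accumulation", cfg)
    res = learning_time(fc, env.reference_betti, horizon=spikes.duration)
    return LearningRun(res, graph.number_of_edges(), len(fc))


def _summarize(tmins: list[float | None]) -> tuple[float, float]:
    """(mean T_min over successes, success rate)."""
    ok = [t for t in tmins if t is not None]
    rate = len(ok) / len(tmins) if tmins else 0.0
    return (float(np.mean(ok)) if ok else np.nan), rate


@dataclass
class LearningRegionMap:
    """Mean learning time and success rate over an (s, f, N) lattice."""

    table: pd.DataFrame  # columns s, f, n_cells, mean_tmin, success_rate, reps
    success_level: float

    def region_mask(self) -> pd.Series:
        return self.table["success_rate"] >= self.success_level

    def contains(self, s: float, f: float, n_cells: int) -> bool:
        t = self.table
        row = t[(t.s == s) & (t.f == f) & (t.n_cells == n_cells)]
        return bool(len(row)) and bool(
            (row["success_rate"] >= self.success_level).iloc[0]
        )


def run_learning_region_scan(
    env: Environment,
    traj: Trajectory,
    s_values,
    f_values,
    n_values,
    reps: int = 3,
    mod: ModulationConfig | None = None,
    cfg: CoactivityConfig | None = None,
    seed: int | None = None,
    success_level: float = 0.9,
    a: float = 0.3,
    b: float = 0.3,
) -> LearningRegionMap:
    """Map the learning region over the (s, f, N) lattice: per point, ``reps``
    independent place-field maps over the fixed trajectory."""
    ss = np.random.SeedSequence(seed)
    rows = []
    for s in s_values:
        for f in f_values:
            for n in n_values:
                tmins = []
                for rep_seed in ss.spawn(reps):
                    run = run_learning(
                        env, traj, EnsembleSpec(s, f, n, a, b), mod, cfg,
                        seed=int(rep_seed.generate_state(1)[0] % (2**31)),
                    )
                    tmins.append(run.result.t_min)
                mean_t, rate = _summarize(tmins)
                rows.append(
                    dict(s=s, f=f, n_cells=n, mean_tmin=mean_t,
                         success_rate=rate, reps=reps)
                )
    return LearningRegionMap(pd.DataFrame(rows), success_level)


def fit_power_law(
    x: np.ndarray, y: np.ndarray, n_boot: int = 200, seed: int | None = None,
    min_points: int = 4,
) -> dict:
    """OLS fit of log y = c - alpha log x; bootstrap CI over the points.

    Returns {'exponent', 'ci_low', 'ci_high', 'n_points'}; requires
    ``min_points`` points, otherwise {'exponent': nan, 'flag': ...}.
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    good = np.isfinite(x) & np.isfinite(y) & (x > 0) & (y > 0)
    x, y = x[good], y[good]
    if len(x) < min_points:
        return {"exponent": np.nan, "flag": "insufficient points", "n_points": len(x)}
    lx, ly = np.log(x), np.log(y)
    slope = np.polyfit(lx, ly, 1)[0]
    rng = np.random.default_rng(seed)
    boots = []
    for _ in range(n_boot):
        idx = rng.integers(0, len(x), len(x))
        if len(np.unique(lx[idx])) < 2:
            continue
        boots.append(np.polyfit(lx[idx], ly[idx], 1)[0])
    lo, hi = (np.percentile(boots, [2.5, 97.5]) if boots else (np.nan, np.nan))
    return {
        "exponent": float(-slope),
        "ci_low": float(-hi),
        "ci_high": float(-lo),
        "n_points": int(len(x)),
    }


@dataclass
class ScanResult:
    table: pd.DataFrame
    fits: dict


def run_window_scan(
    env: Environment,
    traj: Trajectory,
    ensemble: EnsembleSpec,
    w_values,
    reps: int = 3,
    mod: ModulationConfig | None = None,
    seed: int | None = None,
    success_floor: float = 0.5,
    plateau_slope: float = 0.5,
    base_cfg: CoactivityConfig | None = None,
) -> ScanResult:
    """Learning time versus coactivity-window width.

    Fits T_min(w) ~ w^(-alpha) on the decreasing branch (successful points up
    to the minimum of the mean learning time) and reports the stable plateau
    range where |d log T_min / d log w| falls below ``plateau_slope`` with
    maximal success."""
    w_values = np.asarray(sorted(w_values), dtype=float)
    ss = np.random.SeedSequence(seed)
    rows = []
    for w in w_values:
        cfg = CoactivityConfig(
            window=float(w),
            d_max=(base_cfg.d_max if base_cfg else 3),
            integration_window=(
                base_cfg.integration_window if base_cfg else np.inf
            ),
        )
        tmins = []
        for rep_seed in ss.spawn(reps):
            run = run_learning(
                env, traj, ensemble, mod, cfg,
                seed=int(rep_seed.generate_state(1)[0] % (2**31)),
            )
            tmins.append(run.result.t_min)
        mean_t, rate = _summarize(tmins)
        rows.append(dict(w=w, mean_tmin=mean_t, success_rate=rate, reps=reps))
    table = pd.DataFrame(rows)
    ok = table[(table.success_rate >= success_floor) & np.isfinite(table.mean_tmin)]
    fits: dict = {}
    if len(ok) >= 2:
        w_at_min = ok.w[ok.mean_tmin.idxmin()]
        branch = ok[ok.w <= w_at_min]
        fits["alpha"] = fit_power_law(
            branch.w.to_numpy(), branch.mean_tmin.to_numpy(), seed=seed
        )
        lw, lt = np.log(ok.w.to_numpy()), np.log(ok.mean_tmin.to_numpy())
        slopes = np.abs(np.diff(lt) / np.diff(lw))
        flat = ok.w.to_numpy()[:-1][slopes < plateau_slope]
        fits["plateau_range"] = (
            (float(flat.min()), float(flat.max())) if len(flat) else None
        )
    else:
        fits["alpha"] = {"exponent": np.nan, "flag": "insufficient points"}
        fits["plateau_range"] = None
    return ScanResult(table, fits)


def run_synaptic_scan(
    env: Environment,
    traj: Trajectory,
    ensemble: EnsembleSpec,
    p_values=None,
    q_values=None,
    reps: int = 3,
    mod: ModulationConfig | None = None,
    cfg: CoactivityConfig | None = None,
    seed: int | None = None,
    dp: float = 0.0,
    dq: float = 0.0,
    success_floor: float = 0.5,
    xi: float = 0.0,
) -> ScanResult:
    """Learning versus synaptic transmission (p*) and readout response (q*)
    probabilities.  p_crit is the largest probability whose success rate
    stays below the floor; kappa and delta are fitted on log scales above
    p_crit.

    ``xi`` (activations/min) applies Hebbian assembly selection to the
    synaptically filtered coactivity graph: links whose surviving-event rate
    falls below xi are not wired into the assembly network.  With xi > 0
    weakening synapses genuinely prune connections (the oversampled raw
    event stream otherwise hides all but total failures)."""
    ss = np.random.SeedSequence(seed)
    rows = []
    for kind, values in (("p", p_values), ("q", q_values)):
        if values is None:
            continue
        for v in values:
            syn = (
                SynapseModel(p_star=float(v), dp=dp)
                if kind == "p"
                else SynapseModel(q_star=float(v), dq=dq)
            )
            tmins, links, spurious = [], [], []
            for rep_seed in ss.spawn(reps):
                run = run_learning(
                    env, traj, ensemble, mod, cfg, synapse=syn,
                    seed=int(rep_seed.generate_state(1)[0] % (2**31)), xi=xi,
                )
                tmins.append(run.result.t_min)
                links.append(run.n_links)
                if len(run.result.betti):
                    spurious.append(
                        max(int(run.result.betti[-1][1]) - env.reference_betti[1], 0)
                    )
            mean_t, rate = _summarize(tmins)
            rows.append(
                dict(kind=kind, prob=v, mean_tmin=mean_t, success_rate=rate,
                     n_links=float(np.mean(links)),
                     spurious_b1=float(np.mean(spurious)) if spurious else np.nan,
                     reps=reps)
            )
    table = pd.DataFrame(rows)
    fits: dict = {}
    pt = table[table.kind == "p"].sort_values("prob")
    if len(pt):
        sub = pt[pt.success_rate < success_floor]
        p_crit = float(sub.prob.max()) if len(sub) else None
        fits["p_crit"] = p_crit
        if p_crit is None:
            fits["flag"] = "no sub-critical points observed"
        else:
            above = pt[(pt.prob > p_crit) & np.isfinite(pt.mean_tmin)]
            # kappa is the exponent of the divergence, so it is fitted on the
            # scaling region near p_crit: points whose learning time exceeds
            # twice the large-p plateau level
            plateau = above.mean_tmin.iloc[-2:].mean()
            branch = above[above.mean_tmin >= 2 * plateau]
            fits["kappa"] = fit_power_law(
                branch.prob.to_numpy() - p_crit,
                branch.mean_tmin.to_numpy(),
                seed=seed,
                min_points=3,
            )
            dfit = fit_power_law(
                above.prob.to_numpy() - p_crit, above.n_links.to_numpy(), seed=seed
            )
            # link count grows with p - p_crit: flip the sign convention
            dfit["exponent"] = -dfit["exponent"]
            if "ci_low" in dfit:
                dfit["ci_low"], dfit["ci_high"] = -dfit["ci_high"], -dfit["ci_low"]
            fits["delta"] = dfit
    return ScanResult(table, fits)


def restrict_spikes_to_region(
    spikes, traj: Trajectory, region_fn, compress_clock: bool = False
):
    """Keep only spikes emitted while the animal is inside the region
    (membership tested on the trajectory sample nearest each spike).

    With ``compress_clock`` spike times are mapped onto the cumulative time
    spent inside the region, so the restricted raster is a self-contained
    session of duration equal to the region's dwell time — the natural clock
    for learning a subdomain from its own spikes.
    """
    from .place_cells import SpikeTrains

    inside = region_fn(traj.positions[:, 0], traj.positions[:, 1])
    if compress_clock:
        # dwell clock accumulated over *previous* samples, so that with the
        # whole arena selected the clock reproduces the original times
        dwell = np.concatenate([[0.0], np.cumsum(inside[:-1])]) * traj.dt
        duration = float(inside.sum() * traj.dt)
    else:
        duration = spikes.duration
    trains = []
    for tr in spikes.trains:
        if not len(tr):
            trains.append(tr)
            continue
        idx = np.clip(np.searchsorted(traj.times, tr), 0, len(traj.times) - 1)
        keep = inside[idx]
        kept = tr[keep]
        if compress_clock:
            kept = dwell[idx[keep]]
        trains.append(kept)
    return SpikeTrains(trains, duration)


@dataclass
class AdditivityResult:
    table: pd.DataFrame  # per replicate: t_full, t_left, t_right
    mean_difference: float  # mean of (t_left + t_right) - t_full
    p_value: float


def run_additivity_experiment(
    env: Environment,
    traj: Trajectory,
    ensemble: EnsembleSpec,
    cut_x: float,
    reps: int = 20,
    mod: ModulationConfig | None = None,
    cfg: CoactivityConfig | None = None,
    seed: int | None = None,
) -> AdditivityResult:
    """Split the arena at x = cut_x into subdomains that meet but do not
    overlap; learn each from the spikes fired inside it and compare
    T(E1) + T(E2) with T(E) by a paired t-test."""
    from .environment import make_environment

    if not 0 < cut_x <= env.width:
        raise ValueError("cut must fall inside the arena")
    for h in env.holes:
        x0, x1, _, _ = h.bounds
        if x0 < cut_x < x1:
            raise ValueError("cut passes through a hole; subdomain invalid")
    left_holes = [h for h in env.holes if h.bounds[1] <= cut_x]
    right_holes = [h for h in env.holes if h.bounds[0] >= cut_x]
    ref_left = (1, len(left_holes))
    ref_right = (1, len(right_holes))
    degenerate_right = cut_x >= env.width

    cfg = cfg or CoactivityConfig()
    ss = np.random.SeedSequence(seed)
    rows = []
    for rep_seed in ss.spawn(reps):
        s_map, s_spk, s_det = rep_seed.spawn(3)
        pf = sample_place_field_map(
            env, ensemble.s, ensemble.f, ensemble.n_cells, ensemble.a, ensemble.b,
            seed=s_map,
        )
        spikes = generate_spike_trains(pf, traj, mod, seed=s_spk)

        def learn(spk, reference):
            events = detect_coactivity_events(spk, cfg, seed=s_det)
            graph = build_coactivity_graph(events, duration=spk.duration)
            fc = build_filtered_complex(graph, "clique-accumulation", cfg)
            return learning_time(fc, reference, horizon=spk.duration)

        t_full = learn(spikes, env.reference_betti).t_min
        left = restrict_spikes_to_region(
            spikes, traj, lambda x, y: x <= cut_x, compress_clock=True
        )
        t_left = learn(left, ref_left).t_min
        if degenerate_right:
            t_right = 0.0
        else:
            right = restrict_spikes_to_region(
                spikes, traj, lambda x, y: x >= cut_x, compress_clock=True
            )
            t_right = learn(right, ref_right).t_min
        rows.append(dict(t_full=t_full, t_left=t_left, t_right=t_right))
    table = pd.DataFrame(rows)
    ok = table.dropna()
    if len(ok) < 2:
        return AdditivityResult(table, np.nan, np.nan)
    diff = (ok.t_left + ok.t_right) - ok.t_full
    if np.allclose(diff, diff.iloc[0]):
        p = 1.0 if np.allclose(diff, 0) else 0.0
    else:
        p = float(sstats.ttest_rel(ok.t_left + ok.t_right, ok.t_full).pvalue)
    return AdditivityResult(table, float(diff.mean()), p)
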