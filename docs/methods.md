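# Methods

`cogmap` simulates how a population of hippocampal place cells can encode
the topology of an environment, and measures when, whether, and how robustly
that encoding emerges.  This note records the model, its parameters, the
numerical choices, and the limits of what the synthetic experiments show.

## Model overview

The pipeline has five stages:

1. **Environment and exploration.**  A planar arena (cm units) minus
   axis-aligned rectangular or circular holes.  The accessible region is
   connected by construction and its Betti numbers are known exactly:
   `b0 = 1`, `b1 = number of holes`.  Exploration is a momentum-smoothed
   random walk: scalar speed follows an Ornstein–Uhlenbeck process
   (exact discretization) around a target mean, the heading diffuses, and
   the walker reflects off walls and hole boundaries.
2. **Place fields and spiking.**  Each of `N` cells has a Gaussian firing
   field with peak rate `f_i` and size `s_i` (the diameter at which the
   rate falls to `0.2 f_i`; Gaussian SD `s_i / (2 sqrt(2 ln 5))`).  Sizes
   and rates are log-normal across the ensemble with modes `(s, f)` and
   SDs `b*s`, `a*f`.  Spikes are an inhomogeneous Poisson process
   (Bernoulli thinning, at most one spike per cell per step).
3. **Coactivity.**  Cells co-firing inside a window `w` (default 200 ms,
   consecutive non-overlapping bins) produce coactivity events; pairwise
   events build a coactivity graph whose cliques, stamped with
   accumulation times, form a filtered clique (flag) complex.  An
   alternative simplex-detection mode requires all `k+1` cells to co-fire
   inside one window.
4. **Homology.**  Betti numbers over Z2 by boundary-matrix rank (sparse
   Gaussian elimination over GF(2)); persistence by the standard column
   reduction in filtration order.  The learning time `T_min` is the
   earliest moment after which `(b0, b1)` match the environment and stay
   matched through the session.
5. **Transient (flickering) networks.**  Links of the coactivity graph
   decay and are rejuvenated by reactivation; per-step clique complexes
   give Betti time series, lifetime statistics, and stability summaries.

## Parameters that matter

| parameter | default | units | role |
|---|---|---|---|
| mean speed / SD | 20 / 8 | cm/s | OU speed process |
| heading diffusion | 0.6 | rad/sqrt(s) | exploration persistence |
| trajectory step `dt` | 10 | ms | thinning and position grid |
| `(s, f, N)` | 23, 28, 350 | cm, Hz, cells | ensemble operating point |
| `a`, `b` | 0.3 | – | rate/size spread coefficients |
| window `w` | 200 | ms | coactivity detection |
| `d_max` | 3 | – | simplex dimension cap |
| θ frequency / depth | 8 Hz / 0.8 | – | precession factor |
| γ frequency / τ | 60 Hz / 0.5 | – | trough-locking temperature |
| decay constant τ | run-specific | s | link decay |
| assembly threshold ξ | 0.6 | events/min | Hebbian link selection |

Heading diffusion 0.6 makes the walker circulate persistently: every
corridor of an annular arena is revisited on the ~100 s scale, and the
characteristic interval between successive activations of a coactivity
link comes out near 30 s in a 1.1 m annulus — the regime in which the
transient-network results are stated.  Larger values (≥1.5) produce
minute-long neglect of whole corridors, which no longer resembles steady
exploratory coverage.

## Rhythmic modulation is rate-preserving

θ-precession multiplies the rate by a raised cosine of the offset between
the current θ phase and the cell's preferred phase, which sweeps from 2π to
0 as the animal crosses the field (the preferred phase is computed from the
projection of the animal's offset onto its heading).  γ coupling multiplies
the rate by the Boltzmann factor `exp(-A_γ(t)/τ_i)` with
`A_γ = (1 + cos 2π f_γ t)/2`.

Both factors are normalized by their cycle averages (the γ normalization is
the partition term `exp(-1/2τ) I0(1/2τ)`), so by default the rhythms
*redistribute* spikes across the cycle rather than delete them: a timing
code, not a gain change.  This is essential: a pure thinning factor `≤ 1`
lowers pairwise coincidence rates at every window width (its second moment
is below its squared mean), so synchronization could never help learning.
With rate preservation the trough-locking gain is
`E[m^2]/E[m]^2 ≈ 1.41` at τ = 0.5, and γ-locked ensembles outperform
unsynchronized ones at windows shorter than half a γ period.  Set
`rate_preserving=False` for the raw thinning factors.

Spike times resolve the trajectory grid (10 ms).  For γ experiments the
grid is finer than the 16.7 ms γ period via `time_oversample` (positions
linearly interpolated); otherwise the 60 Hz factor is aliased and no
trough clustering can occur.

## Link decay: the patience clock

In the exponentially decaying mode, a link draws a *patience*
`T ~ Exponential(τ)` at each (re)birth and dies when the time since its
last activation exceeds `T`; reactivations reset the activation clock but
keep `T`.  Three consequences match the transient-network phenomenology:

* with no reactivation, survival is exactly `exp(-t/τ)`;
* reactivation at a characteristic interval Δt extends effective
  lifetimes — at τ = 3Δt the fitted mean of completed link lifetimes is
  roughly twice τ — and the long-`T` draws form a pool of session-long
  survivors, the *stable core* of the complex;
* the quenched variant (deterministic death exactly τ after the last
  activation) has no lifetime spread, hence no survivor core, and
  fluctuates more at matched τ.

A memoryless hazard (redrawing the death clock at every activation) was
rejected: by the memoryless property the birth-to-death span is exactly
`Exponential(τ)` no matter how often a link reactivates, so effective
lifetimes could never exceed τ and the stable core would not exist.

The decaying graph is the **cell-assembly** graph: links are wired only
when their activation rate exceeds ξ (default 0.6 events/min).  Once-only
links — pairs that co-fired a single time in a session — are not treated
as assembly connections; including them buries the lifetime statistics in
pure-decay flutterers and riddles the per-step complexes with isolated
vertices and open cycles.

Vertices never decay.  Per-step complexes are flag complexes of the active
link set, capped at dimension `d_max + 1` (triangles when only `(b0, b1)`
are tracked), and their Betti numbers are recomputed exactly per step —
the stability statements here are statements about `b_k(t)`, so per-step
recomputation replaces zigzag persistence.

## Learning experiments

A run is *successful* when `(b0, b1)` equal the environment's signature
from some time `T_min` to the end of the session; failed runs count
toward success rates but not mean learning times.  Statistical replicates
keep one trajectory fixed and resample place-field maps, which isolates
ensemble statistics from behavioural variability.

Two geometric regimes of the arena matter:

* The hole must be wider than twice the place-field *reach* (≈ `0.98 s_i`
  for the 3.5σ evaluation cutoff), including the log-normal size tail —
  otherwise cells whose centers fall inside the hole fire on both sides
  and their links close the loop.  The 150 cm arena with a 60 cm hole is
  comfortably in the learnable regime for `s = 23`; small arenas used for
  fast scans use `s = 15` with `b = 0.2`.
* Long sessions accumulate rare tail-speed coactivities between cells
  ~50 cm apart; in small arenas these can eventually bridge a hole.  This
  is a genuine feature of window-based coactivity detection, not noise.

Synaptic filtering thins every pairwise event by a transmission draw
(truncated Gaussian on [0, 1] with mode `p*`, spread Δp) and a readout
response draw (`q*`, Δq), sampled once per link.  Criticality arises by
weak-link extinction: links with few events lose all of them at small
`p*`, the complex stays incomplete, learning times diverge, and below
`p_crit` success collapses.  The divergence exponent κ is fitted on the
scaling region near `p_crit` (points whose learning time is at least twice
the large-`p*` plateau).  With the minimal one-link assemblies used here,
`p*` and `q*` are statistically equivalent channels, so the package can
bound the response-probability effect by the transmission effect but not
demonstrate a strict asymmetry; that would require multi-cell assemblies
in which `p*` enters once per constituent link but `q*` once per readout.

Map additivity splits the arena at a vertical cut avoiding holes; each
subdomain is learned from the spikes fired inside it, on a clock that
counts only the time spent there (the dwell-time clock).  The sum of the
subdomain learning times is then compared with the full-arena time by a
paired t-test.

## Problem sizes

The built-in experiments run on one CPU.  Unit and property suites use
arenas of 80–110 cm, ensembles of 120–350 cells and sessions of 4–25 min;
the dense stability analysis uses 750 cells on the 1.1 m annulus with six
Betti evaluations per decay constant; paired brain-wave comparisons use
8–10 matched place-field maps per arm; the additivity test uses 20 paired
replicates.  These sizes were chosen as the smallest at which each effect
is stable across seeds.

## What the generator does and does not emulate

Emulated: bounded non-preferential exploration at rodent speeds; unimodal
field-size/rate heterogeneity; Poisson spiking with θ-phase precession and
γ trough-locking; oversampled coactivity statistics with jittered windows;
decaying, windowed and randomly rewired connectivity.

Not emulated: goal-directed or wall-following behaviour; conductance-based
spiking, bursting, refractoriness; plasticity (synaptic probabilities are
stationary); LFP structure beyond two sinusoidal rhythms; remapping across
environments; 3D navigation.  Passing tests therefore demonstrate the
internal consistency of the topological machinery and the direction of the
physiological effects under these idealizations — not quantitative
predictions for recorded data.

## Numerical choices and degenerate inputs

* Z2 coefficients throughout; boundary ranks by sparse column elimination;
  persistence pairs by low-index reduction; equal-time simplexes ordered
  by dimension then lexicographically.
* Betti timelines are evaluated at simplex-arrival times (event-driven),
  so no change can fall between samples.
* Zero-length persistence intervals are dropped.
* The log-normal (mode, SD) parameterization solves for the shape
  parameter by bracketed root finding; `SD = 0` degenerates to a point
  mass.
* Duration-zero trajectories are a single point; empty complexes have
  empty barcodes; a trajectory that never meets a place field yields an
  empty simplicial path.
* Clique enumeration is by common-neighbor intersection (explicit up to
  4-cliques), which is what makes per-step Betti series affordable.

## Known limitations

* Learning times under this explorer are coverage-limited and reach
  minutes where multi-hour times are possible under slower, preferential
  behaviour; quantities proportional to `T_min` (e.g. the learning time
  at the smallest workable window, or stabilization latencies expressed
  in units of `T_min`) therefore sit at different absolute scales than
  under slow exploration, and the corresponding checks document this.
* The windowed-mode stabilization latency is governed by the tail of the
  link reactivation intervals (several multiples of Δt), not by `T_min`.
* Scale-free degree statistics of the top-`n0` assembly graphs do not
  emerge in these geometric ensembles: a cell can only be a "most
  frequent partner" of its spatial neighbours, which caps preferential
  attachment.  The hub property (degrees far beyond the Poisson tail) does
  hold.
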