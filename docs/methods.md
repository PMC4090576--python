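# Methods

## Stochastic simulation

`ssastream.engine` implements the Gillespie direct method: at state `x`
and time `t` the total propensity `a0(x, t)` is accumulated over all
reactions, a waiting time `τ ~ Exp(a0)` is drawn, and a reaction `j` is
selected with probability `a_j/a0`.  Mass-action propensities use the
*combinatorial* convention, `c·∏_s C(n_s, m_s)` — `n(n−1)/2` distinct
pairs for a homodimerisation, `n(n−1)(n−2)/6` triples for a third-order
step.  This convention matters: with plain powers `n²/n³` the Schlögl
rate equation has a single positive fixed point and the system would be
monostable, contradicting its defining behaviour; with combinatorial
counts the cubic `0.015A² − (10⁻⁴/6)A³ + 200 − 3.5A` has three positive
roots (≈ 85.5 and ≈ 566.9 stable, ≈ 247.6 unstable — located
independently in `meanfield.schlogl_fixed_points` by polynomial root
finding).

A reaction may instead carry a *rate function* `f(counts, t)`; its value
is the propensity itself, with no additional reactant-multiplicity
factor.  Only this convention makes the Neurospora parameter set below
coincide with the referenced mean-field ODE model after discretisation.
Buffered species (Schlögl's B) participate in propensities but are never
changed by a firing.

**Time-varying rates.**  Rates driven by the dark/light schedule are
piecewise constant.  When a proposed firing would cross the next phase
boundary, the clock moves to the boundary without firing and the waiting
time is re-drawn — exact for piecewise-constant rates by memorylessness.
Boundary times are global constants of the run, so this never interacts
with how the run is sliced into quanta.

**Sampling.**  Trajectories are reported on the fixed grid
`t_i = i·Δ_S` with right-continuous step interpolation: the sample at
`t_i` is the state at the largest event time ≤ `t_i`.

**Quantum invariance.**  A worker advances a task one *simulation
quantum* at a time.  The last step of a quantum is allowed to overshoot
the quantum target — the event still fires — so the event sequence of a
trajectory is a function of its seed alone and the emitted samples are
bit-identical whether the task is advanced in one call or in thousands.
Each task's random stream is seeded `base_seed + task_id`, which makes
ensemble results independent of worker count, quantum size and
scheduling order.  The worker pool itself is deterministic: each round
advances the `workers` lowest-clock tasks (ties to the lowest id), which
keeps the ensemble aligned in simulation time and bounds the alignment
buffer.  Execution is serial in-process; the `workers` knob controls
scheduling width, and the pipelining/farming arithmetic for sizing a
truly parallel deployment lives in `ssastream.perf`.

## Built-in models

**Schlögl** — `2A → 3A` (c = 0.03), `3A → 2A` (c = 0.0001), `B → B + A`
(c = 200, B buffered at 1), `A → ∅` (c = 3.5), starting from A = 250
(essentially the unstable fixed point), so an ensemble splits between
the two basins within a few relaxation times (τ ≈ 1/2.6 time units).

**λ-phage switch** — repressor dimerisation `2CI ⇌ CI2`
(0.05 / 0.5), CI2 binding to the promoting and repressing operator
sites of the phage DNA (0.026 each way, both sites), second-site binding
on the promoting complex (0.13 each way), transcription
`D_act + P → D_act + P + 2CI` (c = 40; two CI monomers per transcript)
and slow monomer degradation `CI → ∅` (c = 0.0007).  Initial state
10 CI, one D, one P; DNA and polymerase counts are conserved by the
stoichiometry.  The CI level is bistable between a repressed state
(CI ≲ 15, DNA sequestered by operator-bound dimers with few free
dimers around) and an expressing state (CI ≈ 20–60).

**Neurospora circadian oscillator** — transcription
`FRQin → FRQin + M` at `f_FRQ(t) = v_s(t)·K_I⁴/(FRQin⁴ + K_I⁴)`
(Hill repression by *nuclear* FRQ), translation `M → M + FRQ`
(k_s = 0.5), Michaelis–Menten degradations `M → ∅` at
`v_m·M/(K_m + M)` and `FRQ → ∅` at `v_d·FRQ/(K_d + FRQ)`, and
nuclear transport `FRQ ⇌ FRQin` (k₁ = 0.5 / k₂ = 0.6).  Parameters
(per hour, molecule units at 1 nM = 100 molecules): v_m = 50.5,
v_d = 140, K_m = 50, K_I = 100, K_d = 13.  `v_s` is 160 in constant
darkness and alternates 160 (dark) / 200 (light) with phase length
T = 12 h under forcing; phases are left-closed (`[2nT, (2n+1)T)` dark).
The initial state M = FRQ = FRQin = 10 (0.1 nM) is a conventional small
seed — the limit cycle is the global attractor and transients are
discarded before any period estimate.  The companion mean-field ODE
(`meanfield.neurospora_rhs`) oscillates with a 21.51 h period in
constant darkness and entrains slowly toward 24 h under forcing.

## Analysis defaults

* Quantiles by linear interpolation between order statistics; standard
  deviation with the n−1 denominator (0 for a single trajectory).
* Savitzky–Golay coefficients come from `scipy.signal.savgol_coeffs`
  (window 9, order 3 by default); the test suite checks them against an
  explicit least-squares polynomial fit.  Derivative stencils are
  applied with a `1/Δ_S` scale.  The clustering features are the
  smoothed centre value and the one-step forecast
  `x^E = x̂ + x̂′·Δ_S`, unnormalised, with Euclidean distance.
* K-means is Lloyd's algorithm with seeded initial centres (k distinct
  data points), tolerance 1e−6 on centre movement, at most 100
  iterations, and empty clusters repaired by reassigning the point
  farthest from its centre.  `k` must be supplied — K-means is for
  switch systems whose cluster count is known in advance.
* QT clustering grows, from every remaining point, a candidate cluster
  by the point whose inclusion least increases the diameter (maximum
  pairwise distance) under the threshold, commits the largest candidate
  (ties to the lowest seed index) and repeats; it stops when the largest
  candidate falls below `min_size`, leaving the rest unclustered.  It is
  the default when the number of clusters is not known.
* Peak detection: candidate peaks at +→− sign changes of the
  SG-estimated derivative, refined to the local maximum of the smoothed
  curve; peaks standing less than `min_height_frac` (default 0.1) of
  the series range above the neighbouring minima are dropped; peaks
  closer than `min_separation` samples are merged keeping the higher.
  Local periods are successive peak-time differences; the ensemble
  period series is their pooled, time-ordered moving average.
* Sliding windows: odd Δ_W, stride 1 by default (maximal overlap), no
  partial windows at either end.

## Study configurations

Problem sizes are scaled so each study runs in seconds to a couple of
minutes on one core while keeping the target quantity's standard error
well inside its tolerance.

**Circadian period, constant dark** — 16 trajectories (10 in the test
suite), t_end = 200 h, Δ_S = 0.25 h; peaks of the mRNA M with a
21-point SG window (5.25 h) and 4 h minimum separation; intervals before
the 48 h transient are discarded.  Yields ≈ 21.4–21.6 h from > 100
inter-peak intervals, matching the ODE's 21.51 h.

**Circadian period, dark/light alternation (T = 12 h)** — the
free-running oscillator (21.5 h) entrains slowly to the 24 h forcing:
even the noiseless ODE only reaches local periods of 23.9 h past
~200 h.  The study therefore measures the entrained regime: t_end =
300 h with the first 96 h discarded, giving ≈ 23.4–23.6 h (noise-induced
phase slips keep the stochastic ensemble slightly below the ODE's
asymptote; the value sits within ±1 h of the 24 h forcing period).

**Schlögl bistability** — 120 trajectories, Δ_S = 0.5, t_end = 16,
QT threshold 150 on the (x̂, x^E) features of the last full window
(centred t = 14), min cluster size 5 % of the ensemble.  Two scales
motivate these numbers: the high basin's stationary fluctuation
(sd ≈ 45 by a linear-noise estimate) must be averaged down below the
diameter threshold, so the SG window spans ≈ 4.5 time units ≈ 11
relaxation times; and commitment out of the unstable starting point can
straggle for several time units, so the clustered window sits ≥ 8 units
after the last stragglers.  Late switchers and in-transit trajectories
fall below the 5 % minimum size and are reported unclustered.

**λ-phage two equilibria** — 48 trajectories, Δ_S = 1 h, t_end = 120 h
(the ensemble CI distribution is quasi-stationary past ≈ 100 h; much
later the repressed state slowly drains into the expressing one), QT
threshold 50 — between the expressing state's spread (≈ 30–35 raw) and
the repressed/expressing separation (≈ 45–60) — with min cluster size
10 %.

## What the synthetic generator does and does not emulate

`analysis.synth_ensemble` produces constant, sinusoidal and
two-mode-switching cut streams with Gaussian noise, used to exercise the
analysis operators against known structure without the simulator.  It
reproduces the *shape* features the operators consume (modes, periodic
peaks, noise) but not SSA statistics: counts are rounded Gaussians, not
birth-death processes, there is no time correlation in the noise and no
propensity-driven variance scaling.  Passing tests on synthetic streams
therefore validate the operators' contracts, while the model studies
above validate behaviour on genuine SSA output.

## Numerical and degenerate-input choices

* Exact grid hits: a sample that coincides with an event time takes the
  post-event state (right continuity); schedule boundaries are
  left-closed.
* Zero total propensity with no boundary ahead absorbs the task at
  t_end and emits the remaining grid samples at the frozen state.
* A rate function returning a negative or non-finite value, a negative
  count after a firing, duplicate or out-of-sequence samples in the
  aligner — all hard errors, never silently repaired.
* Trajectories with fewer than two peaks contribute nothing to period
  estimates; an ensemble with no periods reports NaN.
* Worker counts and the speedup bound round to the nearest integer
  (5.3/0.11 → 48, 5.8/0.11 → 53), minimum one worker.

## Known limitations

* The engine is exact SSA only — no tau-leaping or hybrid acceleration —
  and pure Python: ensembles beyond ~10⁷ events per study are slow.
* Execution is serial; the worker/farm abstractions model and schedule
  parallel structure but do not spawn threads or processes.
* QT clustering is O(n³) per window; fine for hundreds of trajectories
  per window, not for tens of thousands.
* The rule-file format covers flat (well-mixed, single-compartment)
  chemistry with integer stoichiometry; no compartments, no SBML.
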