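# Methods

## The single-cell oscillator

Each clock neuron is a five-variable negative-feedback oscillator for the
PER protein loop of the *Drosophila* circadian clock. *per* mRNA (`M`) is
transcribed at a maximal rate `vs` under cooperative Hill repression by
nuclear PER (`PN`) with threshold `KI` and exponent `n`, and degraded by a
Michaelis–Menten sink (`vm`, `Km`). The translated protein (`P0`) is
reversibly phosphorylated twice (`P0 ⇄ P1 ⇄ P2`; maximal rates `V1..V4`,
Michaelis constants `K1..K4`). Fully phosphorylated cytosolic PER (`P2`) is

* degraded enzymatically in the dark at maximal rate `vd` (Michaelis
  constant `Kd`),
* degraded linearly at rate `dL` while the lights are on (the only way
  light enters the model), and
* exchanged with the nucleus by first-order transport (`k1` in, `k2` out).

With `dL = 0` (or in constant darkness) the system is the autonomous
Goldbeter-type oscillator. Under the package defaults it reaches a stable
limit cycle with a free-running period that grows from 23.5 h to 26.25 h as
`vd` moves across the scanned bracket [2.7, 3.0] nM/h; a 12:12
light–dark (LD) cycle at mid-range `dL` entrains it to exactly 24 h.

Units throughout: concentrations in nM, time in hours, rates in nM/h or
1/h.

### Parameter table and an ambiguity

The default constants are a single flat table (`defaults.toml`), so any
alternative assignment can be tried without code changes. The assignment of
the three trailing nM constants (`Kd = 0.10`, `KI = 1.50`, `Km = 0.20`) is
the only one of the six possible permutations of those printed values that
produces a sustained circadian (20–28 h) limit cycle; the other oscillatory
permutation runs at 19.75–21.75 h and the rest do not oscillate at all.
This calibration gate is enforced by a test.

## Network and coupling

`N` identical neurons (default 50) form a fully connected mean-field
network without self-interaction. The coupling signal seen by neuron *i*
is the cytosolic fully phosphorylated PER averaged over all *other*
neurons,

    S_i = (1/(N−1)) Σ_{j≠i} P2_j ,

mimicking release of a synchronizing agent (PDF neuropeptide) gated by the
clock state. `S_i` modulates kinetic constants of neuron *i* linearly,
clipped at zero for the decreasing laws:

| target   | law                                | hypothesis |
|----------|------------------------------------|------------|
| `k1_up`  | k1 → k1 (1 + g·S)                  | promote nuclear entry |
| `k2_down`| k2 → max(0, k2 (1 − g·S))          | hinder nuclear exit |
| `vd_up`  | vd → vd (1 + g·S)                  | promote dark degradation |
| `vd_down`| vd → max(0, vd (1 − g·S))          | hinder dark degradation |

All gains default to `g = 2.0` per nM (the table's coupling-gain entry);
0.5 and 4.0 are the documented alternative gains. The linear-with-clipping
law is the simplest form consistent with "increase and/or decrease the
parameter"; it is a genuinely open design choice, and the results that
depend on its *strength* (see Limitations) should be read with that in
mind.

## Stochastic integration

* Deterministic part: classical 4th-order Runge–Kutta with step
  `dt = 0.1 min`. The mean field, and hence the modulated constants, are
  frozen at each step's start (at this step size a sub-step refresh is
  immaterial); the light indicator is evaluated at each substage time.
* Noise: one independent multiplicative white-noise term per state
  component per neuron, added after the deterministic update as an
  Euler–Maruyama increment `σ·X·√dt·ξ`, `ξ ~ N(0,1)`, with `X` the
  component value at the step's start. This per-component placement is the
  minimal surrogate for molecular noise affecting every process.
* Non-negativity: each component is clipped at 0 after every step; clip
  counts are recorded on the result.
* Noise amplitude: `σ` is calibrated rather than copied — the package
  default `σ = 0.05` is the smallest value on the grid {0.05, 0.1, 0.2}
  for which an *uncoupled* ensemble entrained by 9 LD days loses
  free-running synchrony (R < 0.5) within 6 days of constant darkness
  (`calibrate_sigma`). At 0.05 the ensemble crosses that threshold on the
  second DD day.
* Reproducibility: a single master seed drives the initial-phase draw and
  the noise stream (sub-seeds derived via `SeedSequence`); runs and scans
  are bitwise reproducible.

## Protocol and initial conditions

The standard protocol is 9 LD days (lights on during the first 12 h of
each day, from t = 0) followed by 7 days of constant darkness (DD). A
noise-free reference clock is first relaxed for 10 LD days; neuron *i*
starts in the reference state at `t_b + θ_i` with `θ_i ~ N(0, 1 h)`
(clipped to ±6 h), so the ensemble begins as a phase-dispersed cloud on
the entrained orbit. Output is sampled every 0.1 h.

## Rhythm analysis

* **Cosinor**: `y(t) = M0 + A cos(2π(t−φ)/τ)` fitted by exhaustive search
  of `τ` over 16–32 h in 15-min steps; at fixed τ the fit is linear
  (intercept, cosine, sine), so the grid search is exact and free of local
  minima. No off-grid refinement is attempted — the grid *is* the
  estimator, and its 0.25 h resolution bounds the precision of every
  period statement. `φ` is the signed offset of the fitted peak nearest to
  the first day onset in the window, wrapped to (−τ/2, τ/2]. A series with
  numerically zero variance yields a flagged sentinel fit (A = 0,
  τ = NaN) rather than an error.
* **Synchronization degree**: `R = Var_t(⟨y_i⟩_i) / ⟨Var_t(y_i)⟩_i`
  computed on nuclear PER over a window; 1 for identical traces, ≈1/N for
  independent ones, 0 for exactly cancelling phases. The power-mean
  inequality bounds it in [0, 1]; it is invariant under a common affine
  rescaling of all traces.
* **Windows**: all condition summaries cover the last 5 days of the
  condition, half-open — LD days 5–9 ([96 h, 216 h)) and DD days 3–7
  ([264 h, 384 h)) of the standard protocol.
* **Population summaries**: procedure (i) fits each neuron and averages
  (period arithmetically, phase circularly via the resultant vector, with
  the arithmetic mean also reported); procedure (ii) averages the nuclear
  PER trace first and fits once. The two agree when the ensemble is
  synchronized; under desynchronization the averaged trace loses
  amplitude, so procedure (i) is the default everywhere.
* **Actograms**: double-plotted (days d and d+1 per row) on the native
  within-day sampling grid.

## Parameter-plane experiments

Scans cover `dL ∈ [0.2, 8.5]` 1/h × `vd ∈ [2.7, 3.0]` nM/h — the printed
exploration brackets — with a default desk-scale resolution of 8×7 cells
and 3 replicate seeds per cell (the published maps are dense; the package
trades resolution for tractability and exposes the grid). Per-cell
replicate seeds derive deterministically from the master seed. Cells are
classified *circadian* (|τ − 24| ≤ 0.5 h, i.e. two period-grid steps),
*synchronized in DD* (R_DD ≥ 0.3) and *phase-stable*
(|φ_LD − φ_DD| ≤ 1 h); the operating point is the cell passing all flags
with maximal R_DD (ties: period closest to 24 h, then smallest dL).

Problem sizes of the headline recomputations (`scripts/acceptance.py`):
the LD-boundary sweep uses N = 10 and 13 vd values at one seed each; the
k1 operating-point scan uses the 8×7 grid at N = 10 with 2 seeds plus one
full N = 50 rerun; the joint-modulation run uses N = 50 and 3 seeds; the
vd-down scan uses a 6×5 grid at N = 10 with 3 seeds (its qualifying cells
sit near the synchrony threshold, so it keeps the full default replicate
count). These sizes were
chosen so the whole reproduction completes in minutes on one core while
keeping replicate noise well below the effect sizes of interest.

## What the simulations do and do not show

The generator *is* the study system — there is no external data. The
ensemble is deliberately homogeneous: period and phase dispersion arise
solely from multiplicative molecular noise, not from cell-to-cell
parameter variation. Consequently the simulations say nothing about
heterogeneous populations, spatial structure, transmission delays, or the
biophysics of PDF signalling; the mean-field signal is an abstraction of
"clock state gates synchronizer release".

Robust qualitative outcomes (insensitive to the coupling-law details):

* entrainment synchronizes, free run disperses (R_LD ≫ R_DD uncoupled);
* positive modulation of nuclear entry restores free-running synchrony
  (R_DD ≈ 0.8 vs ≈ 0.2 uncoupled at default settings), with poor synchrony
  at gain 0.5 and shorter periods at gain 4;
* positive modulation of dark degradation never synchronizes;
* the DD sync degree is insensitive to N (S is normalized by N − 1).

## Limitations

* The mean-field modulation law is linear with the table's gain of 2.0.
  Because the time-averaged coupling signal is S̄ ≈ 0.85 nM, this is a
  large perturbation (k1 effectively ≈ 2.7×), and the coupled free-running
  period lands near 19–21 h rather than 24 h; the quantitative
  operating-point period, the joint-modulation phase advance, and the
  vd-down period floor all inherit this sensitivity. A weaker or
  saturating feedback would preserve the period; the law is exposed
  per-gain in the configuration precisely so such variants can be
  explored.
* The LD entrainment boundary in vd is not observed at mid-range dL: the
  light input entrains the entire scanned vd bracket, so the boundary
  sweep returns the bracket edge (3.0 nM/h).
* RK4's formal order holds for the smooth drift; the light on/off
  discontinuity and the zero-clipping make individual steps first-order
  accurate at those isolated events.
* Noise is per-component multiplicative white noise, not per-reaction
  (chemical Langevin) noise; σ calibrates the desynchronization timescale,
  not a molecule count.
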