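# clocknet

Stochastic simulation of a network of circadian clock neurons, and the
rhythm-analysis toolkit to quantify when the network's output is coherent.

In *Drosophila*, molecular clock oscillations persist for weeks in single
pacemaker neurons, yet the *behavioral* rhythm in constant darkness
requires the neurons to stay synchronized — molecular noise alone slowly
disperses their phases once the light cue is gone. `clocknet` implements a
mean-field network model to explore which kind of interneuron feedback can
rescue free-running coherence: `N` identical Goldbeter-type PER oscillators
(five variables per cell: *per* mRNA `M`, cytosolic phosphoforms
`P0, P1, P2`, nuclear PER `PN`), each subject to multiplicative molecular
noise, driven by light through a linear degradation of `P2` (rate `dL`,
zero in darkness), and coupled through the network-averaged signal

    S_i = (1/(N−1)) Σ_{j≠i} P2_j ,

which modulates the nuclear-entry rate `k1` (up), nuclear-exit rate `k2`
(down), or the dark degradation rate `vd` (up or down) linearly in `S`
with gain `g` (default 2.0), clipped at zero.

The analysis layer provides:

* **grid cosinor fits** — `y(t) = M0 + A·cos(2π(t−φ)/τ)` with τ searched
  exhaustively over 16–32 h at 15-min resolution (linear least squares at
  each τ, so the search is exact on the grid);
* **synchronization degree** — `R = Var_t(⟨PN_i⟩_i) / ⟨Var_t(PN_i)⟩_i`,
  1 for perfect synchrony, ≈1/N for independent neurons;
* **population summaries** over the last 5 days of the entrained (LD)
  or free-running (DD) condition, double-plot **actograms**, phase/period
  **histograms**, and **(dL, vd) parameter-plane scans** with
  circadian-region classification.

See `docs/methods.md` for the model equations in words, all numerical
choices, and known limitations.

## Worked example

```python
from clocknet import (ModulationSpec, NetworkConfig, population_summary,
                      simulate)

# 50 noisy clock neurons, 9 LD days then 7 DD days, no coupling
uncoupled = NetworkConfig(N=50, seed=3)
res = simulate(uncoupled)
ld = population_summary(res, "LD")
dd = population_summary(res, "DD")
print(f"uncoupled: LD tau={ld.mean_tau:.2f} h R={ld.R:.2f} | "
      f"DD tau={dd.mean_tau:.2f} h R={dd.R:.2f}")

# same ensemble with the nuclear-entry feedback switched on
coupled = uncoupled.with_(modulation=ModulationSpec.k1_up(2.0))
res = simulate(coupled)
ld = population_summary(res, "LD")
dd = population_summary(res, "DD")
print(f"k1-coupled: LD tau={ld.mean_tau:.2f} h R={ld.R:.2f} | "
      f"DD tau={dd.mean_tau:.2f} h R={dd.R:.2f}")
```

prints

```
uncoupled: LD tau=24.12 h R=0.96 | DD tau=25.08 h R=0.18
k1-coupled: LD tau=24.14 h R=0.90 | DD tau=19.73 h R=0.80
```

Read: under the light–dark cycle both ensembles are entrained to 24 h and
tightly synchronized (R ≈ 0.9–0.96). Released into constant darkness, the
uncoupled ensemble keeps oscillating cell by cell but loses collective
coherence (R drops to 0.18, and the mean period drifts to the free-running
25.1 h); with the mean-field feedback on nuclear entry the population stays
synchronized in darkness (R = 0.80), at the cost of a shortened period —
at this default gain the coupling is a strong perturbation (see the
limitations section of `docs/methods.md`).

The same workflow is available from the shell:

```sh
clocknet simulate --config my.toml --seed 3 --out run/
clocknet analyze --traj run/trajectories.csv --condition dd --out analysis/
clocknet actogram --traj run/trajectories.csv --out actogram.csv
clocknet scan --hypothesis k1 --replicates 2 --out scan/
clocknet calibrate-noise --grid 0.05,0.1,0.2
```

Configuration is TOML with `[params]`, `[network]`, `[modulation]` and
`[protocol]` sections; anything omitted falls back to the packaged
`defaults.toml` (the standard parameter table).

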