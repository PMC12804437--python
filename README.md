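# rdapso

Estimation of insect dispersal from mark-release-recapture (MRR) field
experiments.

In an MRR study, a batch of marked insects (typically mosquitoes such as
*Aedes aegypti*) is released from a single point; over the following days,
researchers record how many are recovered on each collection day and in
each concentric annular zone around the release point. Because dispersal in
such settings is well approximated by isotropic diffusion, the central
quantity of interest is the diffusion coefficient *D* (m²/day), which feeds
directly into spatial models of vector abundance and disease risk.

The package implements four estimators of *D*, all driven by the same
inputs — the temporal recapture ratios τᵢ (fraction of recaptures on day
*i*) and spatial ratios σⱼ (fraction in zone *j*):

* **MDT-based**: closed form from the empirical mean distance traveled,
  `D = (1/π) (MDT / Σᵢ τᵢ √tᵢ)²`.
* **Time-corrected (TC)**: least-squares fit of
  `σⱼ = Σᵢ τᵢ [exp(−r²ⱼ₋₁/4Dtᵢ) − exp(−r²ⱼ/4Dtᵢ)]`,
  the τ-weighted annulus occupancy of the 2-D diffusion kernel.
* **Area-and-time-corrected (ATC)**: the same fit after rescaling counts by
  the Lillie trap-density correction `(nT_tot/nTⱼ)(Aⱼ/A_tot)`.
* **RDA-PSO** (the main method): an agent-based forward model —
  *N* walkers take *S* fixed steps of length `k·h` per day and may be
  captured at sites modelled as a collection disk (radius `q·h`) inside an
  attracting annulus (width `p·h`) with Bernoulli efficiency `s_e` —
  inverted by a grid search plus particle swarm optimization that matches
  simulated to observed ratios. The recovered step multiplier `k` gives
  `D = (S/4)(k·h)²`. Unlike the continuum baselines, this method needs no
  area correction and works at realistic (few percent) recapture rates.

Intended users: vector ecologists and modellers analyzing MRR campaigns,
and anyone needing a defensible *D* for reaction–diffusion models of insect
spread.

## Worked example

Three published studies are bundled (`rdapso.datasets`): two village
releases on Hainan Island (15 m zones, six daily collections) and one in a
Cairns suburb (50 m zones, collections on days 5, 8, 11, 15).

```python
import rdapso as r
from rdapso.datasets import hainan_center
from rdapso.mrr import ratios

study = hainan_center()           # 105 recaptures over six days
rs = ratios(study.table)
print(round(r.estimate_D_mdt(rs.temporal, rs.collection_days, study.mdt_emp), 2))
print(round(r.fit_tc_table(study.table).D_hat, 2))
print(round(r.k_to_D(study.reported_mean_k), 2))
```

prints

```
32.1
12.81
40.78
```

i.e. the MDT-based estimate is 32.10 m²/day, the time-corrected fit gives
12.81 m²/day (uncorrected for the village's uneven house density, hence the
low value), and the published mean step multiplier k = 36.87 from repeated
swarm runs converts to D_RDA = 40.78 m²/day — a mean daily displacement of
√(πD) ≈ 11.3 m.

A full synthetic inverse run with known ground truth:

```python
spec = r.ScenarioSpec(k=35.0)                  # D = 36.75 m^2/day exactly
layout, census = r.make_layout(spec, seed=1)
obs = r.simulate(layout, r.WalkConfig(k=35, n_days=6), seed=42).ratio_set()
walk = r.WalkConfig(k=1.0, n_days=6, N=2000, reps=2)   # reduced-N inner sims
cfg = r.PSOConfig(k_bounds=(15, 55), q_bounds=(5, 30))
res = r.run_replicates(obs, layout, walk, cfg, n_runs=10, seed=3, grid_resolution=6)
print(round(res.D, 2), [round(x, 2) for x in res.D_ci])
```

prints `39.02 [37.59, 40.48]` — within 7% of the generating 36.75 m²/day,
with the truth approached as swarm effort grows.

The same workflows are scriptable from the shell (`rdapso estimate-mdt`,
`fit-tc`, `fit-atc`, `simulate`, `rda-pso`, `scenario`); every stochastic
command accepts `--seed` and writes a manifest for bit-exact replay.

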