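# Methods

## Model and assumptions

Dispersal is modelled as isotropic diffusion from a point release. At time
*t* (days), the radial presence density of a walker with diffusion
coefficient *D* (m²/day) is

    P_t(r) = r/(2Dt) · exp(−r²/4Dt),

the radial marginal of a centered Gaussian with per-axis variance 2Dt.
From it follow the annulus occupancy Q_t(a, b) = exp(−a²/4Dt) −
exp(−b²/4Dt), the mean distance traveled ⟨r⟩_t = √(πDt) and the mean square
distance 4Dt. The estimators assume no advection (wind), no explicit
mortality, and that recapture samples presence; depletion of the marked
pool (by capture, death or emigration) is absorbed into the temporal ratios
τᵢ, which weight every time-averaged formula.

Units are meters and days throughout the public API. The simulator's
reference length h (default 0.1 m) only scales the step multiplier k and
the trap radii q, p; there is no lattice — positions are continuous.

## Estimators

**MDT-based.** `D_MDT = (1/π)(MDT_emp / Σᵢ τᵢ√tᵢ)²`, inverting the
τ-weighted aggregation of daily mean distances. Exact closed form; inherits
whatever bias the reported empirical MDT carries.

**Time-corrected (TC).** Fits σⱼ against Σᵢ τᵢ Q_{tᵢ}(r_{j−1}, r_j) by
unweighted least squares. The scalar minimization is a bounded
derivative-free search (Brent) on log D over [10⁻³, 10⁵] m²/day with
tolerance 1e−10 on log D. The log parameterization removes scale
sensitivity and guarantees positivity; on model-generated data the fit
recovers the generating D to better than 0.1%. The hourly-collection
variant is the same fit with fractional tᵢ — nothing else changes.

**Area-and-time-corrected (ATC).** Applies the Lillie correction
N_jᶜ = N_j (nT_tot/nT_j)(A_j/A_tot) before the TC fit. The per-zone factor
is day-independent, so cell-wise application reproduces the classical
corrected zone totals while preserving temporal structure; `scope`
controls whether τ is recomputed from corrected counts
(`spatial_and_temporal`) or kept raw (`spatial_only`, the only option when
day-by-zone counts are not reported, as in the Hainan studies). Corrected
counts are real-valued by default; nearest-integer rounding is opt-in to
reproduce the historical round-off-sensitive workflow, and rounding is
applied per cell.

Zone conventions: zones are half-open annuli (r_{j−1}, r_j]; a point at a
boundary belongs to the inner-indexed zone, and the release point itself to
zone 1. Zero-capture zones are retained (σⱼ = 0) and included in fits by
default; a zone mask can exclude them. The default all-inclusive mask is
what reproduces the published TC values on all three bundled studies,
including the edge release whose first zone holds no capture sites.

## Forward model

Each of N walkers takes S = 12 steps per day (12 active hours, one step per
hour) of fixed length k·h in a uniformly random direction. Capture sites
are concentric: a collection disk of radius q·h and an attracting annulus
of width p·h. Per step and walker, the nearest site within (q+p)·h triggers
one Bernoulli draw with probability s_e: success inside the disk captures
the walker (credited to the site's zone at the current step); success in
the annulus redirects the next k·h displacement at the site center, clipped
to land on the center when closer than one step; failure leaves the walker
diffusing (it may drift out of the annulus naturally). Ties between
equidistant sites go to the lowest site index. Walkers crossing the
rectangular region boundary (by default the square circumscribing the
outermost zone) are removed permanently. With s_e = 1 and p = 0 the disk is
absorbing at step resolution.

The attracted-displacement rule (same length k·h as a free step, aimed at
the center) is this package's convention; only the existence of a locally
biased motion toward the trap is dictated by the model class.

Capture times are recorded per step, so daily and hourly (per-step)
temporal ratios come from the same simulation, and irregular collection
schedules bin captures into (t_{i−1}, t_i]. Replicates (default 5) use
independent child streams spawned from one master seed; outputs are
bit-identical for identical seed and configuration. Ratios are averaged
across replicates, excluding replicates with zero captures. Two kernels
implement identical dynamics: a compiled (numba) per-walker loop and a
vectorized numpy fallback; they consume random numbers in different orders,
so seeds reproduce exactly within a backend, not across backends.

## Inverse solver

The error between simulated and observed ratios is
E = ½(‖σ − σᵒ‖₂ + ‖τ − τᵒ‖₂). The solve has two stages:

1. **Grid search** over (k, q) with p = 0, s_e = 1 on a uniform grid
   (default 8×8) to map the error landscape; the argmin cell padded by one
   cell becomes the swarm's initialization box.
2. **PSO** over (k, q, p, s_e) with N_p = 36 particles and N_g = 12
   generations by default. Coefficients use the constriction set w = 0.729,
   c1 = c2 = 1.49445 (the package's choice; any standard setting works),
   velocities are clamped to 20% of each bound range, out-of-bound
   positions are clipped with the offending velocity component zeroed, and
   initial velocities are zero. Any parameter can be pinned. Particle
   evaluations draw fresh seeds (no common random numbers), and evaluations
   with zero captures return NaN, causing the particle to be resampled
   inside the bounds. During evaluation q and p are clamped so that
   (q+p)·h disks never overlap on the fixed site geometry.

The trap parameters (q, p, s_e) trade off against each other and are not
individually identifiable; k is. A study-level estimate repeats grid
search + PSO n_runs times with independent seeds, discards runs whose
final error exceeds mean(E) + c·sd(E) (c = 1 by default, 0.5 for stricter
filtering), and reports mean and SD of k, a Shapiro–Wilk p-value for
normality of k, D = (S/4)(k_mean h)², and a 95% interval obtained by
transforming the normal-theory interval for the mean of k through the
monotone map k ↦ (S/4)(kh)² — exact under the empirically supported
normality of k, and preferable to a delta-method linearization of a
quadratic map.

## Synthetic experiments

`ScenarioSpec` defaults define the reference virtual study: six 15 m zones
(region: the circumscribing 180 m square), area-proportional site counts
anchored at one site in zone 1 — (1, 3, 5, 7, 9, 11), the low-density
design; the high-density variant multiplies counts by 4 — trap q = 10,
p = 0, s_e = 3%, k = 35 (D = 36.75 m²/day exactly), N = 10,000 walkers,
5 replicates, 6 days. Random placement is uniform per annulus with
rejection to keep centers ≥ 5 m apart (house-scale spacing) and clear of
the release point; a deterministic angular-lattice placement is also
available. Manifests record the generating k and D so every study is
scored against exact ground truth.

What the generator does *not* emulate: correlated walks, wind, mortality,
trap depletion or competition, heterogeneous per-site efficiencies, and
real building footprints. Passing recovery tests therefore demonstrate
correctness of the inverse machinery under the model's own assumptions,
not robustness to model misspecification in field data.

## Numerical choices and problem sizes

* Infinite outer radii are evaluated in closed form (exp(−∞) = 0), never by
  truncated quadrature.
* Observation sets for recovery studies are generated at full scale
  (N = 10,000, 5 replicates); forward simulations inside the optimizer use
  N = 2,000 with 2 replicates and a 6×6 grid — sizes chosen so a ten-run
  study completes in minutes on one core while leaving the recovered D
  well within the method's sampling spread. The bias study uses 20
  replicates at N = 4,000.
* Ten aggregation runs is the small end of the recommended 10–20; the
  normality check on k at that size is qualitative.
* The MDT and TC estimators are deterministic; TC reproducibility is
  limited only by the 1e−10 search tolerance.

## Known limitations

* The attracted-step and multi-site tie-break rules are conventions (see
  above); alternative reasonable choices perturb (q, p, s_e) but, by the
  identifiability structure, barely move k.
* Field-data ATC requires a per-zone trap census; when only zone totals of
  sites are known approximately, the correction inherits that uncertainty.
* The continuum estimators assume collection exactly samples presence;
  their daily-collection downward bias is reproduced, not corrected, here.
* Very high trap densities deplete the walker pool and make ratios
  sensitive to s_e; the robustness results hold in the low-density regime
  typical of real MRR campaigns.
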