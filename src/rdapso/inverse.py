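"""Inverse problem: recover walk and trap parameters from observed ratios.

The forward model maps a parameter 4-tuple ``(k, q, p, s_e)`` — step
multiplier, collection-disk radius, attracting-annulus width, site
efficiency — to simulated temporal and spatial recapture ratios.  The
inverse solver minimizes the discrepancy

    E = 1/2 * ( ||sigma_sim - sigma_obs||_2 + ||tau_sim - tau_obs||_2 )

in two stages: a coarse grid search over ``(k, q)`` with ``p = 0`` and
``s_e = 1`` to locate the basin of the global minimum, then particle swarm
optimization (PSO) over all four parameters initialized inside the best
grid cell.  The trap parameters trade off against one another and are not
individually identifiable, but the step multiplier ``k`` — and therefore
the diffusion coefficient ``D = (S/4) (k h)^2`` — is.

Because a single swarm run is stochastic, the recommended workflow repeats
grid search + PSO a dozen or more times, drops runs whose final error is an
outlier, and reports the mean and spread of ``k``; the ``k`` estimates are
close to normally distributed, so a normal-theory interval transformed
through ``D = (S/4)(k h)^2`` quantifies the uncertainty on ``D``.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy import stats

from .forward import StudyLayout, WalkConfig, simulate
from .mrr import RatioSet

__all__ = [
    "PSOConfig",
    "PSOResult",
    "GridSearchResult",
    "RDAResult",
    "error_E",
    "k_to_D",
    "D_to_k",
    "grid_search",
    "pso_optimize",
    "run_replicates",
]

_PARAM_ORDER = ("k", "q", "p", "s_e")


def error_E(sim: RatioSet, obs: RatioSet) -> float:
    """Half-sum of Euclidean distances between spatial and temporal ratios."""
    if not sim.same_grids(obs):
        raise ValueError("simulated and observed ratios are on different day/zone grids")
    e_spatial = float(np.linalg.norm(sim.spatial - obs.spatial))
    e_temporal = float(np.linalg.norm(sim.temporal - obs.temporal))
    return 0.5 * (e_spatial + e_temporal)


def k_to_D(k: float, h: float = 0.1, S: int = 12) -> float:
    """Diffusion coefficient of a fixed-step isotropic walk: ``D = (S/4)(k h)^2``."""
    if k < 0 or h <= 0 or S <= 0:
        raise ValueError("k must be >= 0 and h, S positive")
    return (S / 4.0) * (k * h) ** 2


def D_to_k(D: float, h: float = 0.1, S: int = 12) -> float:
    """Exact inverse of :func:`k_to_D`."""
    if D < 0 or h <= 0 or S <= 0:
        raise ValueError("D must be >= 0 and h, S positive")
    return float(np.sqrt(4.0 * D / S) / h)


@dataclass(frozen=True)
class PSOConfig:
    """Swarm settings and parameter bounds (k, q, p in units of h).

    Defaults use the constriction coefficient set (w = 0.729,
    c1 = c2 = 1.49445); velocities are clamped to ``velocity_clamp`` times
    each bound range, and out-of-bound positions are clipped with the
    offending velocity component zeroed.  Entries of ``fixed`` pin a
    parameter (e.g. ``{"p": 0.0, "s_e": 1.0}``) for simplified fits.
    """

    k_bounds: tuple[float, float]
    q_bounds: tuple[float, float]
    p_bounds: tuple[float, float] = (0.0, 15.0)
    s_e_bounds: tuple[float, float] = (0.001, 1.0)
    n_particles: int = 36
    n_generations: int = 12
    w: float = 0.729
    c1: float = 1.49445
    c2: float = 1.49445
    velocity_clamp: float = 0.2
    fixed: dict = field(default_factory=dict)

    def __post_init__(self):
        if self.n_particles < 2 or self.n_generations < 1:
            raise ValueError("need n_particles >= 2 and n_generations >= 1")
        for name in _PARAM_ORDER:
            lo, hi = self.bounds(name)
            if name in self.fixed:
                continue
            if not lo < hi:
                raise ValueError(f"degenerate bounds for {name}: {(lo, hi)}")
        lo, hi = self.s_e_bounds
        if not (0 < lo <= hi <= 1):
            raise ValueError("s_e bounds must satisfy 0 < lo <= hi <= 1")

    def bounds(self, name: str) -> tuple[float, float]:
        if name in self.fixed:
            v = float(self.fixed[name])
            return (v, v)
        return getattr(self, f"{name}_bounds")

    def bounds_array(self) -> np.ndarray:
        return np.array([self.bounds(n) for n in _PARAM_ORDER], dtype=float)


@dataclass(frozen=True)
class PSOResult:
    k: float
    q: float
    p: float
    s_e: float
    E: float
    gbest_history: np.ndarray  # best error after each generation (non-increasing)

    def as_tuple(self) -> tuple[float, float, float, float, float]:
        return (self.k, self.q, self.p, self.s_e, self.E)


@dataclass(frozen=True)
class GridSearchResult:
    k_values: np.ndarray
    q_values: np.ndarray
    errors: np.ndarray       # shape (len(k_values), len(q_values))
    best_k: float
    best_q: float
    best_error: float
    init_box: dict           # {"k": (lo, hi), "q": (lo, hi)} — argmin cell +/- one cell

    def to_frame(self):
        import pandas as pd

        kk, qq = np.meshgrid(self.k_values, self.q_values, indexing="ij")
        return pd.DataFrame({"k": kk.ravel(), "q": qq.ravel(), "E": self.errors.ravel()})


class _Objective:
    """Error of the replicate-averaged forward simulation at a parameter point.

    Trap radii are clamped so that ``(q + p) * h`` disks never overlap on
    the fixed site geometry; each evaluation uses a fresh seed drawn from
    the supplied generator (no common random numbers across particles).
    """

    def __init__(self, obs: RatioSet, layout: StudyLayout, walk: WalkConfig, rng):
        self.obs = obs
        self.layout = layout
        self.walk = walk
        self.rng = rng
        # largest site reach that keeps neighbouring disks disjoint
        self.max_reach = layout.min_center_distance() / (2.0 * layout.h) * 0.999
        self.n_evals = 0

    def clamp(self, k, q, p, s_e):
        q = min(q, self.max_reach)
        p = min(p, self.max_reach - q)
        return k, q, p, s_e

    def __call__(self, k, q, p, s_e) -> float:
        k, q, p, s_e = self.clamp(k, q, p, s_e)
        seed = int(self.rng.integers(0, 2**31 - 1))
        walk = WalkConfig(k=k, n_days=self.walk.n_days, S=self.walk.S,
                          N=self.walk.N, reps=self.walk.reps, seed=seed)
        out = simulate(self.layout, walk, site_params=(q, p, s_e))
        self.n_evals += 1
        try:
            sim = out.ratio_set(collection_days=self.obs.collection_days)
        except ValueError:
            return np.nan  # no captures anywhere: uninformative point
        return error_E(sim, self.obs)


def _walk_for(obs: RatioSet, walk: WalkConfig) -> WalkConfig:
    n_days = int(np.ceil(obs.collection_days.max()))
    if walk.n_days != n_days:
        walk = WalkConfig(k=walk.k, n_days=n_days, S=walk.S, N=walk.N, reps=walk.reps, seed=walk.seed)
    return walk


def grid_search(
    obs: RatioSet,
    layout: StudyLayout,
    walk: WalkConfig,
    k_range: tuple[float, float],
    q_range: tuple[float, float],
    resolution: int = 8,
    seed: int | None = None,
) -> GridSearchResult:
    """Map the error landscape on a uniform ``(k, q)`` grid with ``p = 0``,
    ``s_e = 1``, and return the argmin cell padded by one cell as the PSO
    initialization box."""
    if resolution < 1:
        raise ValueError("resolution must be >= 1")
    if not (k_range[0] <= k_range[1] and q_range[0] <= q_range[1]):
        raise ValueError("empty parameter range")
    walk = _walk_for(obs, walk)
    rng = np.random.default_rng(seed)
    objective = _Objective(obs, layout, walk, rng)
    k_values = np.linspace(k_range[0], k_range[1], resolution)
    q_values = np.linspace(q_range[0], q_range[1], resolution)
    errors = np.empty((len(k_values), len(q_values)))
    for i, k in enumerate(k_values):
        for j, q in enumerate(q_values):
            errors[i, j] = objective(k, q, 0.0, 1.0)
    flat = np.where(np.isnan(errors), np.inf, errors)
    i, j = np.unravel_index(np.argmin(flat), errors.shape)

    def pad(values, idx, bounds):
        lo = values[max(idx - 1, 0)]
        hi = values[min(idx + 1, len(values) - 1)]
        return (max(lo, bounds[0]), min(hi, bounds[1]))

    return GridSearchResult(
        k_values=k_values,
        q_values=q_values,
        errors=errors,
        best_k=float(k_values[i]),
        best_q=float(q_values[j]),
        best_error=float(errors[i, j]),
        init_box={"k": pad(k_values, i, k_range), "q": pad(q_values, j, q_range)},
    )


def pso_optimize(
    obs: RatioSet,
    layout: StudyLayout,
    walk: WalkConfig,
    config: PSOConfig,
    init_box: dict | None = None,
    seed: int | None = None,
) -> PSOResult:
    """Particle swarm minimization of the ratio-matching error.

    The swarm starts uniformly inside ``init_box`` for ``k`` and ``q``
    (full bounds otherwise) with zero initial velocities; each generation
    re-evaluates every particle with the stochastic forward model and moves
    it toward its personal best and the global best.
    """
    walk = _walk_for(obs, walk)
    rng = np.random.default_rng(seed)
    objective = _Objective(obs, layout, walk, rng)
    bounds = config.bounds_array()
    span = bounds[:, 1] - bounds[:, 0]
    vmax = config.velocity_clamp * span

    init = bounds.copy()
    if init_box:
        for name, rng_pair in init_box.items():
            d = _PARAM_ORDER.index(name)
            if name not in config.fixed:
                init[d] = (max(rng_pair[0], bounds[d, 0]), min(rng_pair[1], bounds[d, 1]))

    n = config.n_particles
    x = rng.uniform(init[:, 0], init[:, 1], size=(n, 4))
    v = np.zeros((n, 4))

    def evaluate(row) -> float:
        return objective(*row)

    f = np.array([evaluate(row) for row in x])
    for i in np.nonzero(np.isnan(f))[0]:  # resample uninformative starts
        x[i] = rng.uniform(bounds[:, 0], bounds[:, 1])
        f[i] = evaluate(x[i])
    f = np.where(np.isnan(f), np.inf, f)

    pbest_x, pbest_f = x.copy(), f.copy()
    g = int(np.argmin(pbest_f))
    gbest_x, gbest_f = pbest_x[g].copy(), float(pbest_f[g])
    history = [gbest_f]

    for _ in range(config.n_generations):
        u1 = rng.random((n, 4))
        u2 = rng.random((n, 4))
        v = config.w * v + config.c1 * u1 * (pbest_x - x) + config.c2 * u2 * (gbest_x - x)
        v = np.clip(v, -vmax, vmax)
        x = x + v
        low, high = x < bounds[:, 0], x > bounds[:, 1]
        v[low | high] = 0.0
        x = np.clip(x, bounds[:, 0], bounds[:, 1])

        f = np.array([evaluate(row) for row in x])
        bad = np.isnan(f)
        for i in np.nonzero(bad)[0]:
            x[i] = rng.uniform(bounds[:, 0], bounds[:, 1])
            v[i] = 0.0
            f[i] = evaluate(x[i])
        f = np.where(np.isnan(f), np.inf, f)

        better = f < pbest_f
        pbest_x[better], pbest_f[better] = x[better], f[better]
        g = int(np.argmin(pbest_f))
        if pbest_f[g] < gbest_f:
            gbest_x, gbest_f = pbest_x[g].copy(), float(pbest_f[g])
        history.append(gbest_f)

    k, q, p, s_e = objective.clamp(*gbest_x)
    return PSOResult(k=float(k), q=float(q), p=float(p), s_e=float(s_e),
                     E=gbest_f, gbest_history=np.array(history))


@dataclass(frozen=True)
class RDAResult:
    """Aggregated outcome of repeated grid-search + PSO runs."""

    tuples: list            # per-run (k, q, p, s_e, E)
    kept: np.ndarray        # boolean mask after outlier removal
    outlier_rule: str
    threshold: float        # error threshold used
    k_mean: float
    k_sd: float
    shapiro_p: float
    D: float                # m^2/day, from k_mean
    D_ci: tuple[float, float]
    h: float
    S: int

    def to_dict(self) -> dict:
        return {
            "tuples": [list(t) for t in self.tuples],
            "kept": self.kept.tolist(),
            "outlier_rule": self.outlier_rule,
            "threshold": self.threshold,
            "k_mean": self.k_mean,
            "k_sd": self.k_sd,
            "shapiro_p": self.shapiro_p,
            "D": self.D,
            "D_ci": list(self.D_ci),
            "h": self.h,
            "S": self.S,
        }


def _parse_outlier_rule(rule: str) -> float:
    table = {"mean+1.0sd": 1.0, "mean+0.5sd": 0.5}
    if rule not in table:
        raise ValueError(f"outlier_rule must be one of {sorted(table)}")
    return table[rule]


def run_replicates(
    obs: RatioSet,
    layout: StudyLayout,
    walk: WalkConfig,
    config: PSOConfig,
    n_runs: int,
    outlier_rule: str = "mean+1.0sd",
    seed: int | None = None,
    grid_resolution: int = 8,
) -> RDAResult:
    """Repeat grid search + PSO ``n_runs`` times and aggregate ``k``.

    Runs whose final error exceeds ``mean(E) + c * sd(E)`` (c = 1 or 0.5
    per ``outlier_rule``) are discarded; the surviving ``k`` values give the
    point estimate ``D = (S/4)(k_mean h)^2`` and a normal-theory 95%
    interval for the mean ``k``, transformed through the same monotone map.
    """
    if n_runs < 2:
        raise ValueError("need at least two runs to aggregate")
    factor = _parse_outlier_rule(outlier_rule)
    seeds = np.random.SeedSequence(seed).spawn(n_runs)
    tuples = []
    for ss in seeds:
        child = ss.generate_state(2)
        gs = grid_search(obs, layout, walk, config.k_bounds, config.q_bounds,
                         resolution=grid_resolution, seed=int(child[0] % 2**31))
        res = pso_optimize(obs, layout, walk, config, init_box=gs.init_box,
                           seed=int(child[1] % 2**31))
        tuples.append(res.as_tuple())

    E = np.array([t[4] for t in tuples])
    threshold = float(E.mean() + factor * E.std(ddof=0))
    kept = E <= threshold + 1e-15
    if not np.any(kept):
        raise ValueError("outlier rule removed every run")
    k = np.array([t[0] for t in tuples])[kept]
    k_mean = float(k.mean())
    k_sd = float(k.std(ddof=1)) if k.size > 1 else 0.0
    if k.size >= 3 and k_sd > 0:
        shapiro_p = float(stats.shapiro(k).pvalue)
    else:
        shapiro_p = float("nan")
    se = k_sd / np.sqrt(k.size) if k.size else 0.0
    zcrit = stats.norm.ppf(0.975)
    k_lo, k_hi = max(k_mean - zcrit * se, 0.0), k_mean + zcrit * se
    h, S = layout.h, walk.S
    return RDAResult(
        tuples=tuples,
        kept=kept,
        outlier_rule=outlier_rule,
        threshold=threshold,
        k_mean=k_mean,
        k_sd=k_sd,
        shapiro_p=shapiro_p,
        D=k_to_D(k_mean, h, S),
        D_ci=(k_to_D(k_lo, h, S), k_to_D(k_hi, h, S)),
        h=h,
        S=S,
    )
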