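"""Agent-based forward model of diffusing walkers with attracting traps.

``N`` independent walkers start at the release point and take ``S`` fixed
steps per day, each of length ``k * h`` meters in a uniformly random
direction (``h`` is a reference length, 0.1 m by default; positions are
continuous — there is no lattice).  Each capture site is a pair of
concentric regions: an inner collection disk of radius ``q * h`` and an
attracting annulus of width ``p * h`` around it.  At every step, a walker
whose nearest site center lies within ``(q + p) * h`` makes a Bernoulli
draw with success probability ``s_e`` (the site efficiency):

* success inside the collection disk -> the walker is captured and removed,
  and the capture is credited to the site's zone at the current step;
* success inside the attracting annulus -> the walker's next displacement
  of length ``k * h`` points at the site center (clipped to land exactly on
  the center when closer than one step);
* failure -> an ordinary isotropic step.

Walkers that cross the rectangular region boundary are removed permanently
and never counted as captures.  Capture times are recorded per step, so the
same simulation yields daily or hourly (per-step) temporal ratios.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, replace

import numpy as np

from .mrr import RatioSet, RecaptureTable

__all__ = [
    "CaptureSite",
    "StudyLayout",
    "WalkConfig",
    "SimOutput",
    "simulate",
    "zone_of_site",
    "collection_schedule",
]


@dataclass(frozen=True)
class CaptureSite:
    """A trap or collection house.

    ``q`` (collection-disk radius) and ``p`` (attracting-annulus width) are
    expressed in units of the layout mesh ``h``; ``s_e`` is the per-step
    Bernoulli capture efficiency in (0, 1].
    """

    x: float
    y: float
    q: float
    p: float = 0.0
    s_e: float = 1.0

    def __post_init__(self):
        if self.q <= 0:
            raise ValueError("collection-disk radius q must be positive")
        if self.p < 0:
            raise ValueError("attracting-annulus width p must be non-negative")
        if not 0 < self.s_e <= 1:
            raise ValueError("site efficiency s_e must be in (0, 1]")

    @property
    def center(self) -> tuple[float, float]:
        return (self.x, self.y)


@dataclass(frozen=True)
class StudyLayout:
    """Geometry of a (real or virtual) MRR experiment.

    ``region`` is ``(xmin, ymin, xmax, ymax)`` in meters; walkers leaving it
    are removed.  By default it is the square circumscribing the outermost
    zone.  ``zone_bounds`` are the annular radii used to bin captures.
    """

    release: tuple[float, float]
    zone_bounds: np.ndarray
    sites: tuple[CaptureSite, ...] = ()
    region: tuple[float, float, float, float] | None = None
    h: float = 0.1

    def __post_init__(self):
        bounds = np.asarray(self.zone_bounds, dtype=float)
        object.__setattr__(self, "zone_bounds", bounds)
        object.__setattr__(self, "release", (float(self.release[0]), float(self.release[1])))
        object.__setattr__(self, "sites", tuple(self.sites))
        if self.h <= 0:
            raise ValueError("mesh length h must be positive")
        if bounds.ndim != 1 or len(bounds) < 2 or bounds[0] < 0 or np.any(np.diff(bounds) <= 0):
            raise ValueError("zone_bounds must be non-negative and strictly increasing")
        if self.region is None:
            r = float(bounds[-1])
            cx, cy = self.release
            object.__setattr__(self, "region", (cx - r, cy - r, cx + r, cy + r))
        xmin, ymin, xmax, ymax = self.region
        if not (xmin < xmax and ymin < ymax):
            raise ValueError("region must be a non-degenerate rectangle")
        cx, cy = self.release
        if not (xmin <= cx <= xmax and ymin <= cy <= ymax):
            raise ValueError("release point must lie inside the region")
        for s in self.sites:
            if not (xmin <= s.x <= xmax and ymin <= s.y <= ymax):
                raise ValueError("all capture sites must lie inside the region")
        self._check_overlap([(s.q + s.p) * self.h for s in self.sites])

    def _check_overlap(self, radii) -> None:
        n = len(self.sites)
        xy = np.array([[s.x, s.y] for s in self.sites]) if n else np.empty((0, 2))
        radii = np.asarray(radii, dtype=float)
        for i in range(n):
            d = np.hypot(xy[i + 1 :, 0] - xy[i, 0], xy[i + 1 :, 1] - xy[i, 1])
            if np.any(d < radii[i] + radii[i + 1 :]):
                raise ValueError("capture-site disks of radius (q+p)*h overlap")

    @property
    def n_zones(self) -> int:
        return len(self.zone_bounds) - 1

    def site_zones(self) -> np.ndarray:
        return np.array([zone_of_site(s, self) for s in self.sites], dtype=int)

    def min_center_distance(self) -> float:
        """Smallest pairwise distance between site centers (inf if < 2 sites)."""
        if len(self.sites) < 2:
            return np.inf
        xy = np.array([[s.x, s.y] for s in self.sites])
        d = np.hypot(xy[:, None, 0] - xy[None, :, 0], xy[:, None, 1] - xy[None, :, 1])
        return float(d[np.triu_indices(len(self.sites), 1)].min())

    def with_site_params(self, q: float, p: float, s_e: float) -> "StudyLayout":
        """Same geometry with every site's (q, p, s_e) replaced."""
        sites = tuple(replace(s, q=q, p=p, s_e=s_e) for s in self.sites)
        return replace(self, sites=sites)

    def to_json(self, path) -> None:
        obj = {
            "release": list(self.release),
            "region": list(self.region),
            "zone_bounds": self.zone_bounds.tolist(),
            "h": self.h,
            "sites": [
                {"x": s.x, "y": s.y, "q": s.q, "p": s.p, "s_e": s.s_e} for s in self.sites
            ],
        }
        with open(path, "w") as fh:
            json.dump(obj, fh, indent=2)

    @classmethod
    def from_json(cls, path) -> "StudyLayout":
        with open(path) as fh:
            obj = json.load(fh)
        sites = tuple(CaptureSite(**s) for s in obj.get("sites", []))
        return cls(
            release=tuple(obj["release"]),
            zone_bounds=np.asarray(obj["zone_bounds"], float),
            sites=sites,
            region=tuple(obj["region"]) if obj.get("region") else None,
            h=obj.get("h", 0.1),
        )


@dataclass(frozen=True)
class WalkConfig:
    """Random-walk parameters: step multiplier ``k`` (step = ``k*h`` m),
    ``S`` steps per day, ``N`` walkers, horizon in days, replicate count."""

    k: float
    n_days: int
    S: int = 12
    N: int = 10_000
    reps: int = 5
    seed: int | None = None

    def __post_init__(self):
        if self.k <= 0:
            raise ValueError("step multiplier k must be positive")
        if self.S < 1 or self.N < 1 or self.reps < 1 or self.n_days < 1:
            raise ValueError("S, N, reps and n_days must all be >= 1")


def zone_of_site(site: CaptureSite, layout: StudyLayout) -> int:
    """0-based zone index of a site: ``j`` with ``r_j < ||c - release|| <= r_{j+1}``.

    Boundaries belong to the inner zone (half-open annuli); the release
    point itself belongs to zone 0.
    """
    d = float(np.hypot(site.x - layout.release[0], site.y - layout.release[1]))
    idx = int(np.searchsorted(layout.zone_bounds, d, side="left")) - 1
    if idx >= layout.n_zones:
        raise ValueError(f"site at distance {d} m lies beyond the outermost zone radius")
    return max(idx, 0)


def collection_schedule(n_days: int, granularity: str = "daily", S: int = 12) -> np.ndarray:
    """Collection times in days: ``1..n_days`` (daily) or every step (hourly)."""
    if n_days < 1:
        raise ValueError("n_days must be >= 1")
    if granularity == "daily":
        return np.arange(1, n_days + 1, dtype=float)
    if granularity == "hourly":
        return np.arange(1, n_days * S + 1, dtype=float) / S
    raise ValueError("granularity must be 'daily' or 'hourly'")


@dataclass(frozen=True)
class SimOutput:
    """Forward-simulation result: per-replicate, per-step capture counts.

    ``step_counts`` has shape ``(reps, n_steps, n_zones)``; step ``s``
    (0-based) corresponds to elapsed time ``(s + 1) / S`` days.  Derived
    ratios average the per-replicate ratio vectors, matching the replicate
    averaging of the inverse method.
    """

    step_counts: np.ndarray
    exited: np.ndarray       # per replicate
    remaining: np.ndarray    # per replicate (still diffusing at the horizon)
    layout: StudyLayout
    walk: WalkConfig

    @property
    def captured(self) -> np.ndarray:
        return self.step_counts.sum(axis=(1, 2))

    def conservation_ok(self) -> bool:
        total = self.captured + self.exited + self.remaining
        return bool(np.all(total == self.walk.N))

    def _binned(self, collection_days: np.ndarray) -> np.ndarray:
        """Counts per (rep, collection interval, zone); interval i is (t_{i-1}, t_i]."""
        S = self.walk.S
        n_steps = self.step_counts.shape[1]
        step_times = np.arange(1, n_steps + 1) / S
        edges = np.concatenate(([0.0], np.asarray(collection_days, dtype=float)))
        # interval i is (t_{i-1}, t_i]; step times at an edge belong to the earlier bin
        idx = np.searchsorted(edges, step_times, side="left") - 1
        n_bins = len(collection_days)
        keep = (idx >= 0) & (idx < n_bins)
        out = np.zeros((self.step_counts.shape[0], n_bins, self.step_counts.shape[2]))
        for b in range(n_bins):
            sel = keep & (idx == b)
            if np.any(sel):
                out[:, b, :] = self.step_counts[:, sel, :].sum(axis=1)
        return out

    def table(self, granularity: str = "daily", collection_days=None) -> RecaptureTable:
        """Pooled (summed over replicates) counts as a :class:`RecaptureTable`."""
        days = self._days(granularity, collection_days)
        counts = self._binned(days).sum(axis=0)
        return RecaptureTable(counts=counts, collection_days=days,
                              zone_bounds=self.layout.zone_bounds, released=self.walk.N)

    def _days(self, granularity, collection_days) -> np.ndarray:
        if collection_days is not None:
            return np.asarray(collection_days, dtype=float)
        return collection_schedule(self.walk.n_days, granularity, self.walk.S)

    def ratio_set(self, granularity: str = "daily", collection_days=None) -> RatioSet:
        """Replicate-averaged temporal and spatial ratios.

        Replicates with zero captures carry no ratio information and are
        excluded from the average; if every replicate caught nothing a
        ``ValueError`` is raised.
        """
        days = self._days(granularity, collection_days)
        binned = self._binned(days)
        totals = binned.sum(axis=(1, 2))
        ok = totals > 0
        if not np.any(ok):
            raise ValueError("no captures in any replicate; ratios are undefined")
        tau = (binned[ok].sum(axis=2) / totals[ok, None]).mean(axis=0)
        sigma = (binned[ok].sum(axis=1) / totals[ok, None]).mean(axis=0)
        return RatioSet(temporal=tau, spatial=sigma, collection_days=days,
                        zone_bounds=self.layout.zone_bounds)


try:  # compiled kernel; the numpy path below is semantically identical
    import numba as _numba
except ImportError:  # pragma: no cover - exercised only without numba
    _numba = None


def _kernel_numpy(rng, centers, reach, collect, eff, zones, release, region,
                  kh, n_steps, N, n_zones):
    counts = np.zeros((n_steps, n_zones), dtype=np.int64)
    xmin, ymin, xmax, ymax = region
    pos = np.tile(np.asarray(release, dtype=float), (N, 1))
    exited = 0
    have_sites = centers.shape[0] > 0
    c2 = (centers**2).sum(axis=1) if have_sites else None

    for step in range(n_steps):
        m = pos.shape[0]
        if m == 0:
            break
        if have_sites:
            d2 = pos @ (-2.0 * centers.T)
            d2 += c2
            d2 += (pos**2).sum(axis=1)[:, None]
            nearest = d2.argmin(axis=1)
            dmin = np.sqrt(np.maximum(d2[np.arange(m), nearest], 0.0))
            in_range = dmin <= reach[nearest]
            engaged = np.zeros(m, dtype=bool)
            idx = np.nonzero(in_range)[0]
            if idx.size:
                engaged[idx] = rng.random(idx.size) < eff[nearest[idx]]
            captured = engaged & (dmin <= collect[nearest])
            attracted = engaged & ~captured
            if captured.any():
                np.add.at(counts[step], zones[nearest[captured]], 1)
            iso = ~engaged
        else:
            iso = np.ones(m, dtype=bool)
            captured = np.zeros(m, dtype=bool)
            attracted = captured

        n_iso = int(iso.sum())
        if n_iso:
            ang = rng.uniform(0.0, 2.0 * np.pi, n_iso)
            step_vec = np.empty((n_iso, 2))
            np.cos(ang, out=step_vec[:, 0])
            np.sin(ang, out=step_vec[:, 1])
            pos[iso] += kh * step_vec
        if attracted.any():
            ai = np.nonzero(attracted)[0]
            d = dmin[ai]
            unit = (centers[nearest[ai]] - pos[ai]) / d[:, None]
            pos[ai] += unit * np.minimum(kh, d)[:, None]

        pos = pos[~captured]
        inside = (
            (pos[:, 0] >= xmin) & (pos[:, 0] <= xmax)
            & (pos[:, 1] >= ymin) & (pos[:, 1] <= ymax)
        )
        exited += int((~inside).sum())
        pos = pos[inside]

    return counts, exited, pos.shape[0]


if _numba is not None:

    @_numba.njit(cache=False)
    def _kernel_compiled(rng, centers, reach2, collect2, eff, zones, rx, ry,
                         xmin, ymin, xmax, ymax, kh, n_steps, N, n_zones):
        counts = np.zeros((n_steps, n_zones), dtype=np.int64)
        px = np.full(N, rx)
        py = np.full(N, ry)
        alive = N
        exited = 0
        n_sites = centers.shape[0]
        for step in range(n_steps):
            i = 0
            while i < alive:
                x = px[i]
                y = py[i]
                best = -1
                bd = 1e300
                for j in range(n_sites):
                    dx = centers[j, 0] - x
                    dy = centers[j, 1] - y
                    d2 = dx * dx + dy * dy
                    if d2 < bd:  # strict: ties keep the lowest site index
                        bd = d2
                        best = j
                moved = False
                if best >= 0 and bd <= reach2[best]:
                    if rng.random() < eff[best]:
                        if bd <= collect2[best]:
                            counts[step, zones[best]] += 1
                            alive -= 1
                            px[i] = px[alive]
                            py[i] = py[alive]
                            continue
                        d = np.sqrt(bd)
                        length = kh if kh < d else d
                        x += (centers[best, 0] - x) / d * length
                        y += (centers[best, 1] - y) / d * length
                        moved = True
                if not moved:
                    ang = rng.uniform(0.0, 2.0 * np.pi)
                    x += kh * np.cos(ang)
                    y += kh * np.sin(ang)
                if x < xmin or x > xmax or y < ymin or y > ymax:
                    exited += 1
                    alive -= 1
                    px[i] = px[alive]
                    py[i] = py[alive]
                    continue
                px[i] = x
                py[i] = y
                i += 1
        return counts, exited, alive


def _run_replicate(rng, layout: StudyLayout, walk: WalkConfig) -> tuple[np.ndarray, int, int]:
    h = layout.h
    kh = walk.k * h
    n_steps = walk.n_days * walk.S
    xmin, ymin, xmax, ymax = layout.region

    if layout.sites:
        centers = np.array([[s.x, s.y] for s in layout.sites], dtype=float)
        reach = np.array([(s.q + s.p) * h for s in layout.sites])
        collect = np.array([s.q * h for s in layout.sites])
        eff = np.array([s.s_e for s in layout.sites])
        zones = layout.site_zones()
        d0 = np.hypot(centers[:, 0] - layout.release[0], centers[:, 1] - layout.release[1])
        if np.any(d0 <= collect):
            raise ValueError("release point lies inside a collection disk")
    else:
        centers = np.empty((0, 2))
        reach = collect = eff = np.empty(0)
        zones = np.empty(0, dtype=np.int64)

    if _numba is not None:
        counts, exited, alive = _kernel_compiled(
            rng, centers, reach**2, collect**2, eff, zones.astype(np.int64),
            float(layout.release[0]), float(layout.release[1]),
            float(xmin), float(ymin), float(xmax), float(ymax),
            kh, n_steps, walk.N, layout.n_zones,
        )
        return counts, int(exited), int(alive)
    return _kernel_numpy(rng, centers, reach, collect, eff, zones,
                         layout.release, layout.region, kh, n_steps, walk.N,
                         layout.n_zones)


def simulate(
    layout: StudyLayout,
    walk: WalkConfig,
    site_params: tuple[float, float, float] | None = None,
    seed: int | None = None,
) -> SimOutput:
    """Run the forward model for ``walk.reps`` independent replicates.

    ``site_params = (q, p, s_e)`` overrides the parameters of every site in
    the layout, which is how the inverse solver explores trap parameters on
    a fixed geometry.  ``seed`` takes precedence over ``walk.seed``; each
    replicate gets an independent child stream, so outputs are bit-identical
    for identical seeds and configurations.
    """
    if site_params is not None:
        layout = layout.with_site_params(*site_params)
    master = seed if seed is not None else walk.seed
    streams = np.random.SeedSequence(master).spawn(walk.reps)
    all_counts, exited, remaining = [], [], []
    for ss in streams:
        c, e, r = _run_replicate(np.random.default_rng(ss), layout, walk)
        all_counts.append(c)
        exited.append(e)
        remaining.append(r)
    return SimOutput(
        step_counts=np.stack(all_counts),
        exited=np.array(exited),
        remaining=np.array(remaining),
        layout=layout,
        walk=walk,
    )


def free_walk_positions(layout: StudyLayout, walk: WalkConfig, seed: int | None = None) -> np.ndarray:
    """Positions of free diffusers (no sites, no boundary) after every step.

    Returns an array of shape ``(n_steps + 1, N, 2)`` including the initial
    release position; used as the microscopic oracle for mean-square
    displacement and zone-occupancy checks.
    """
    rng = np.random.default_rng(seed if seed is not None else walk.seed)
    kh = walk.k * layout.h
    n_steps = walk.n_days * walk.S
    out = np.empty((n_steps + 1, walk.N, 2))
    out[0] = np.asarray(layout.release, dtype=float)
    for s in range(1, n_steps + 1):
        ang = rng.uniform(0.0, 2.0 * np.pi, walk.N)
        out[s, :, 0] = out[s - 1, :, 0] + kh * np.cos(ang)
        out[s, :, 1] = out[s - 1, :, 1] + kh * np.sin(ang)
    return out
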