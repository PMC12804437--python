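"""Mark-release-recapture (MRR) data containers and recapture ratios.

An MRR study releases a batch of marked insects from a single point and
records, on each collection day, how many are recovered in each concentric
annular zone around the release point.  All estimators in this package
consume the data through two normalized summaries:

* temporal ratios ``tau_i`` — fraction of all recaptures made on collection
  day ``i``;
* spatial ratios ``sigma_j`` — fraction of all recaptures made in zone ``j``.

Both are invariant under a constant overall recapture efficiency, which is
why they are preferred over raw counts.

The module also implements the Lillie area correction for unevenly
distributed capture sites: counts in zone ``j`` are rescaled by
``(nT_tot / nT_j) * (A_j / A_tot)`` so that a zone holding fewer traps per
unit area than average is up-weighted.
"""

from __future__ import annotations

import io
import json
from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd

__all__ = [
    "RecaptureTable",
    "RatioSet",
    "TrapCensus",
    "temporal_ratios",
    "spatial_ratios",
    "ratios",
    "lillie_correction",
    "corrected_ratios",
    "zone_areas",
    "read_recapture_csv",
    "write_recapture_csv",
    "read_trap_census_json",
    "write_trap_census_json",
]

_CORRECTION_SCOPES = ("none", "spatial_only", "spatial_and_temporal")


def zone_areas(zone_bounds: np.ndarray) -> np.ndarray:
    """Areas ``A_j = pi (r_j^2 - r_{j-1}^2)`` of the annular zones, in m^2."""
    r = np.asarray(zone_bounds, dtype=float)
    return np.pi * (r[1:] ** 2 - r[:-1] ** 2)


@dataclass(frozen=True)
class RecaptureTable:
    """Recapture counts indexed by (collection day, annular zone).

    Parameters
    ----------
    counts
        Array of shape ``(n_days, n_zones)``.  Raw field data are
        non-negative integers; area-corrected tables may hold real values.
    collection_days
        Elapsed days ``t_i`` since release, strictly increasing and positive.
        These are the actual calendar offsets (collections need not happen
        every day), and they enter every time-weighted formula directly.
    zone_bounds
        Radii ``r_0 < r_1 < ... < r_{n_z}`` in meters delimiting the zones;
        zone ``j`` is the half-open annulus ``(r_{j-1}, r_j]``.
    released
        Total number of insects released, if known.
    """

    counts: np.ndarray
    collection_days: np.ndarray
    zone_bounds: np.ndarray
    released: int | None = None

    def __post_init__(self):
        counts = np.atleast_2d(np.asarray(self.counts, dtype=float))
        days = np.asarray(self.collection_days, dtype=float)
        bounds = np.asarray(self.zone_bounds, dtype=float)
        object.__setattr__(self, "counts", counts)
        object.__setattr__(self, "collection_days", days)
        object.__setattr__(self, "zone_bounds", bounds)
        if counts.ndim != 2:
            raise ValueError("counts must be a 2-D (day x zone) array")
        if np.any(counts < 0) or not np.all(np.isfinite(counts)):
            raise ValueError("counts must be finite and non-negative")
        if days.ndim != 1 or len(days) != counts.shape[0]:
            raise ValueError("collection_days must match the first counts axis")
        if np.any(days <= 0) or np.any(np.diff(days) <= 0):
            raise ValueError("collection_days must be positive and strictly increasing")
        if bounds.ndim != 1 or len(bounds) != counts.shape[1] + 1:
            raise ValueError("need n_zones + 1 zone bounds")
        if bounds[0] < 0 or np.any(np.diff(bounds) <= 0):
            raise ValueError("zone_bounds must be non-negative and strictly increasing")
        if self.released is not None and self.released <= 0:
            raise ValueError("released must be a positive integer")

    @property
    def n_days(self) -> int:
        return self.counts.shape[0]

    @property
    def n_zones(self) -> int:
        return self.counts.shape[1]

    @property
    def total_recaptured(self) -> float:
        return float(self.counts.sum())

    @property
    def day_totals(self) -> np.ndarray:
        return self.counts.sum(axis=1)

    @property
    def zone_totals(self) -> np.ndarray:
        return self.counts.sum(axis=0)

    def scaled(self, factor: float) -> "RecaptureTable":
        return replace(self, counts=self.counts * factor)


@dataclass(frozen=True)
class RatioSet:
    """Temporal and spatial recapture ratios, each summing to one.

    Carries the day and zone grids alongside the ratios so that two ratio
    sets can be compared only when they refer to the same collection
    schedule and zone geometry.
    """

    temporal: np.ndarray
    spatial: np.ndarray
    collection_days: np.ndarray
    zone_bounds: np.ndarray
    corrected: bool = False
    correction_scope: str = "none"

    def __post_init__(self):
        tau = np.asarray(self.temporal, dtype=float)
        sigma = np.asarray(self.spatial, dtype=float)
        object.__setattr__(self, "temporal", tau)
        object.__setattr__(self, "spatial", sigma)
        object.__setattr__(self, "collection_days", np.asarray(self.collection_days, dtype=float))
        object.__setattr__(self, "zone_bounds", np.asarray(self.zone_bounds, dtype=float))
        if self.correction_scope not in _CORRECTION_SCOPES:
            raise ValueError(f"correction_scope must be one of {_CORRECTION_SCOPES}")
        for name, v in (("temporal", tau), ("spatial", sigma)):
            if np.any(v < -1e-12) or np.any(v > 1 + 1e-12):
                raise ValueError(f"{name} ratios must lie in [0, 1]")
            if abs(v.sum() - 1.0) > 1e-9:
                raise ValueError(f"{name} ratios must sum to 1 (got {v.sum()!r})")

    def same_grids(self, other: "RatioSet") -> bool:
        return (
            self.temporal.shape == other.temporal.shape
            and self.spatial.shape == other.spatial.shape
            and np.allclose(self.collection_days, other.collection_days)
            and np.allclose(self.zone_bounds, other.zone_bounds)
        )


@dataclass(frozen=True)
class TrapCensus:
    """Per-zone capture-site counts and zone areas for the Lillie correction."""

    sites_per_zone: np.ndarray
    zone_areas: np.ndarray
    total_area: float = 0.0
    total_sites: int = 0

    def __post_init__(self):
        n = np.asarray(self.sites_per_zone, dtype=float)
        a = np.asarray(self.zone_areas, dtype=float)
        object.__setattr__(self, "sites_per_zone", n)
        object.__setattr__(self, "zone_areas", a)
        if len(n) != len(a):
            raise ValueError("sites_per_zone and zone_areas must have equal length")
        if np.any(n < 0) or np.any(a <= 0):
            raise ValueError("site counts must be >= 0 and zone areas > 0")
        if not self.total_sites:
            object.__setattr__(self, "total_sites", int(round(n.sum())))
        elif int(round(n.sum())) != self.total_sites:
            raise ValueError("sites_per_zone must sum to total_sites")
        if not self.total_area:
            object.__setattr__(self, "total_area", float(a.sum()))

    @classmethod
    def from_zone_bounds(cls, zone_bounds, sites_per_zone) -> "TrapCensus":
        return cls(sites_per_zone=np.asarray(sites_per_zone, float), zone_areas=zone_areas(zone_bounds))

    @property
    def correction_factors(self) -> np.ndarray:
        """Lillie factor ``CF_j = (A_j / A_tot) * nT_tot`` per zone."""
        return self.zone_areas / self.total_area * self.total_sites


def temporal_ratios(table: RecaptureTable) -> np.ndarray:
    """Fraction ``tau_i`` of all recaptures made on each collection day."""
    total = table.total_recaptured
    if total <= 0:
        raise ValueError("cannot form ratios: no recaptured individuals")
    return table.day_totals / total


def spatial_ratios(table: RecaptureTable) -> np.ndarray:
    """Fraction ``sigma_j`` of all recaptures made in each annular zone."""
    total = table.total_recaptured
    if total <= 0:
        raise ValueError("cannot form ratios: no recaptured individuals")
    return table.zone_totals / total


def ratios(table: RecaptureTable, corrected: bool = False, correction_scope: str = "none") -> RatioSet:
    """Bundle temporal and spatial ratios of *table* into a :class:`RatioSet`."""
    return RatioSet(
        temporal=temporal_ratios(table),
        spatial=spatial_ratios(table),
        collection_days=table.collection_days,
        zone_bounds=table.zone_bounds,
        corrected=corrected,
        correction_scope=correction_scope,
    )


def lillie_correction(
    table: RecaptureTable,
    census: TrapCensus,
    rounding_mode: str = "none",
) -> RecaptureTable:
    """Rescale counts for uneven trap density: ``N^c_j = N_j (nT_tot/nT_j)(A_j/A_tot)``.

    The per-zone factor is day-independent, so applying it cell-wise leaves
    temporal structure intact while reproducing the classical corrected zone
    totals.  Corrected counts are real-valued unless
    ``rounding_mode="nearest"``, which rounds each corrected cell to the
    nearest integer (the historical workflow; rounding feeds visible
    round-off error into downstream estimates).

    Zones with zero registered sites are passed through unchanged when they
    also hold zero captures, and are an error otherwise.
    """
    if rounding_mode not in ("none", "nearest"):
        raise ValueError("rounding_mode must be 'none' or 'nearest'")
    if len(census.sites_per_zone) != table.n_zones:
        raise ValueError("census does not match the table's zone count")
    nT = census.sites_per_zone
    empty = nT == 0
    if np.any(empty & (table.zone_totals > 0)):
        raise ValueError("captures recorded in a zone with zero registered capture sites")
    factor = np.ones(table.n_zones)
    nz = ~empty
    factor[nz] = census.correction_factors[nz] / nT[nz]
    corrected = table.counts * factor
    if rounding_mode == "nearest":
        corrected = np.rint(corrected)
    return replace(table, counts=corrected)


def corrected_ratios(
    table: RecaptureTable,
    census: TrapCensus,
    scope: str = "spatial_and_temporal",
    rounding_mode: str = "none",
) -> RatioSet:
    """Ratios after the Lillie correction.

    ``scope="spatial_and_temporal"`` recomputes both ratio families from the
    corrected counts.  ``scope="spatial_only"`` corrects only the spatial
    ratios and keeps the raw temporal ratios — the workflow forced on
    studies that report day totals and zone totals but not the full
    day-by-zone breakdown.
    """
    if scope not in ("spatial_only", "spatial_and_temporal"):
        raise ValueError("scope must be 'spatial_only' or 'spatial_and_temporal'")
    ct = lillie_correction(table, census, rounding_mode=rounding_mode)
    tau = temporal_ratios(ct if scope == "spatial_and_temporal" else table)
    return RatioSet(
        temporal=tau,
        spatial=spatial_ratios(ct),
        collection_days=table.collection_days,
        zone_bounds=table.zone_bounds,
        corrected=True,
        correction_scope=scope,
    )


# ---------------------------------------------------------------------------
# File I/O: long-format CSV with columns day,zone,count (zone is 1-based).

def read_recapture_csv(path_or_buf, zone_bounds, released: int | None = None) -> RecaptureTable:
    df = pd.read_csv(path_or_buf)
    required = {"day", "zone", "count"}
    if not required.issubset(df.columns):
        raise ValueError(f"recapture CSV needs columns {sorted(required)}, got {list(df.columns)}")
    days = np.sort(df["day"].unique()).astype(float)
    bounds = np.asarray(zone_bounds, dtype=float)
    n_zones = len(bounds) - 1
    counts = np.zeros((len(days), n_zones))
    day_index = {d: i for i, d in enumerate(days)}
    for _, row in df.iterrows():
        j = int(row["zone"]) - 1
        if not 0 <= j < n_zones:
            raise ValueError(f"zone index {row['zone']} outside 1..{n_zones}")
        counts[day_index[float(row["day"])], j] += row["count"]
    return RecaptureTable(counts=counts, collection_days=days, zone_bounds=bounds, released=released)


def write_recapture_csv(table: RecaptureTable, path_or_buf) -> None:
    rows = [
        {"day": day, "zone": j + 1, "count": table.counts[i, j]}
        for i, day in enumerate(table.collection_days)
        for j in range(table.n_zones)
    ]
    pd.DataFrame(rows, columns=["day", "zone", "count"]).to_csv(path_or_buf, index=False)


def read_trap_census_json(path_or_buf) -> TrapCensus:
    if isinstance(path_or_buf, (str, bytes)):
        with open(path_or_buf) as fh:
            obj = json.load(fh)
    elif isinstance(path_or_buf, io.IOBase):
        obj = json.load(path_or_buf)
    else:
        obj = path_or_buf
    if "zone_bounds" in obj:
        return TrapCensus.from_zone_bounds(obj["zone_bounds"], obj["sites_per_zone"])
    return TrapCensus(sites_per_zone=np.asarray(obj["sites_per_zone"], float),
                      zone_areas=np.asarray(obj["zone_areas"], float))


def write_trap_census_json(census: TrapCensus, path) -> None:
    with open(path, "w") as fh:
        json.dump(
            {
                "sites_per_zone": census.sites_per_zone.tolist(),
                "zone_areas": census.zone_areas.tolist(),
                "total_area": census.total_area,
                "total_sites": census.total_sites,
            },
            fh,
            indent=2,
        )
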