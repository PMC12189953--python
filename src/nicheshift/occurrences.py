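"""Occurrence records and quality control.

Cleans presence points the way presence-only modeling pipelines do before
fitting: exact-coordinate deduplication, suspicious-coordinate filters
(identical lon/lat, null island, out-of-range, imprecise), removal of points
on land, and spatial thinning to a minimum great-circle distance.

The fixed pipeline order is duplicates → suspicious → land → thin; every
filter appends (name, n_removed) to the provenance log so removals reconcile
with the input/output sizes.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from sklearn.metrics.pairwise import haversine_distances

from .grid import EARTH_RADIUS_KM, RasterLayer


@dataclass
class OccurrenceSet:
    """Presence points of one species plus a per-filter removal log.

    ``table`` has columns ``lon``/``lat`` in degrees.  ``flags`` is an
    optional hidden sidecar (synthetic contaminant labels aligned with rows);
    QC operations subset it alongside the table but never read it, so tests
    can score contaminant recall without leaking labels into the pipeline.
    """

    species_id: str
    table: pd.DataFrame
    provenance_log: list[tuple[str, int]] = field(default_factory=list)
    flags: np.ndarray | None = None

    def __post_init__(self) -> None:
        self.table = self.table.reset_index(drop=True)
        if self.flags is not None:
            self.flags = np.asarray(self.flags)
            assert len(self.flags) == len(self.table)

    def __len__(self) -> int:
        return len(self.table)

    @property
    def lons(self) -> np.ndarray:
        return self.table["lon"].to_numpy(dtype=float)

    @property
    def lats(self) -> np.ndarray:
        return self.table["lat"].to_numpy(dtype=float)

    def _subset(self, keep: np.ndarray, filter_name: str) -> "OccurrenceSet":
        keep = np.asarray(keep, dtype=bool)
        removed = int((~keep).sum())
        return OccurrenceSet(
            species_id=self.species_id,
            table=self.table.loc[keep].reset_index(drop=True),
            provenance_log=[*self.provenance_log, (filter_name, removed)],
            flags=None if self.flags is None else self.flags[keep],
        )


def remove_duplicates(occ: OccurrenceSet) -> OccurrenceSet:
    """Drop records sharing identical coordinates at 6-decimal rounding.

    The first instance is kept.
    """
    key = pd.MultiIndex.from_arrays(
        [occ.table["lon"].round(6), occ.table["lat"].round(6)]
    )
    keep = ~key.duplicated(keep="first")
    return occ._subset(np.asarray(keep), "duplicates")


def _imprecise(coords: np.ndarray, precision_decimals: int) -> np.ndarray:
    """True where a coordinate is expressible with fewer than
    ``precision_decimals`` decimal places."""
    scaled = coords * 10.0 ** (precision_decimals - 1)
    return np.abs(scaled - np.round(scaled)) < 1e-6


def flag_suspicious(occ: OccurrenceSet, precision_decimals: int = 2) -> OccurrenceSet:
    """Remove suspicious records.

    Removed: identical longitude and latitude; (0, 0); coordinates outside
    [−180, 180] × [−90, 90]; records whose *both* coordinates carry fewer than
    ``precision_decimals`` decimals (rounded data-entry artefacts).
    """
    lon, lat = occ.lons, occ.lats
    identical = np.round(lon, 6) == np.round(lat, 6)
    null_island = (lon == 0.0) & (lat == 0.0)
    out_of_range = (np.abs(lon) > 180.0) | (np.abs(lat) > 90.0)
    imprecise = _imprecise(lon, precision_decimals) & _imprecise(lat, precision_decimals)
    bad = identical | null_island | out_of_range | imprecise
    return occ._subset(~bad, "suspicious")


def mask_land(occ: OccurrenceSet, land_mask: RasterLayer) -> OccurrenceSet:
    """Remove records falling on land cells or outside the grid extent.

    Cell assignment uses the containing-cell rule
    ``floor((coord − origin) / cell_size)``.  Out-of-extent records are logged
    under their own filter name, not raised as errors.
    """
    spec = land_mask.spec
    rows, cols, inside = spec.cells_of(occ.lons, occ.lats)
    on_land = np.zeros(len(occ), dtype=bool)
    on_land[inside] = land_mask.values[rows[inside], cols[inside]] != 0
    step1 = occ._subset(inside, "outside_extent")
    return step1._subset(~on_land[inside], "land")


def _haversine_km(lons: np.ndarray, lats: np.ndarray) -> np.ndarray:
    pts = np.radians(np.column_stack([lats, lons]))
    return haversine_distances(pts) * EARTH_RADIUS_KM


def thin(occ: OccurrenceSet, min_dist_km: float = 5.5, seed: int = 0) -> OccurrenceSet:
    """Spatially thin records to a minimum pairwise great-circle distance.

    Greedy removal of the record with the most neighbours closer than
    ``min_dist_km`` (haversine, R = 6371 km), ties broken by seeded random
    choice, followed by a re-addition pass that restores any removed record
    whose neighbourhood was itself entirely removed.  The result satisfies the
    distance constraint and is maximal: no removed record can be re-added
    without violating it.
    """
    if min_dist_km <= 0:
        raise ValueError(f"min_dist_km must be positive, got {min_dist_km}")
    n = len(occ)
    if n <= 1:
        return occ._subset(np.ones(n, dtype=bool), "thin")

    rng = np.random.default_rng(np.random.SeedSequence(seed))
    dist = _haversine_km(occ.lons, occ.lats)
    conflict = (dist < min_dist_km) & ~np.eye(n, dtype=bool)
    alive = np.ones(n, dtype=bool)
    degree = conflict.sum(axis=1)
    removal_order: list[int] = []
    while True:
        max_deg = degree[alive].max() if alive.any() else 0
        if max_deg == 0:
            break
        candidates = np.flatnonzero(alive & (degree == max_deg))
        victim = int(rng.choice(candidates))
        alive[victim] = False
        removal_order.append(victim)
        degree[conflict[victim]] -= 1
        degree[victim] = 0
    # maximality: re-add removed points that no longer conflict (reverse order
    # so the last-removed, least-connected points get first chance)
    for idx in reversed(removal_order):
        if not (conflict[idx] & alive).any():
            alive[idx] = True
    return occ._subset(alive, "thin")


def run_qc(
    occ: OccurrenceSet,
    land_mask: RasterLayer,
    min_dist_km: float = 5.5,
    precision_decimals: int = 2,
    seed: int = 0,
) -> OccurrenceSet:
    """Full QC pipeline in the fixed order duplicates → suspicious → land → thin."""
    out = remove_duplicates(occ)
    out = flag_suspicious(out, precision_decimals=precision_decimals)
    out = mask_land(out, land_mask)
    return thin(out, min_dist_km=min_dist_km, seed=seed)
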