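"""Hotspots and conservation-gap overlays.

Multi-species hotspots are cells whose min-max standardized summed suitability
strictly exceeds a cutoff (default 0.80).  Overlays intersect the hotspot mask
with protected areas and economic-zone labels using spherical cell areas, and
cross-tabulate projected richness change against high-traffic shipping cells.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .errors import ConfigurationError, DegenerateStandardizationError
from .grid import (
    RasterLayer,
    ZoneLayers,
    cell_area_km2,
    require_coregistered,
    row_areas_km2,
)


@dataclass
class HotspotMap:
    """Summed, standardized, and thresholded multi-species suitability."""

    summed: RasterLayer
    standardized: RasterLayer
    hotspot_mask: RasterLayer
    cutoff: float
    scenario_tag: str


def hotspot_map(suitability_maps: dict[str, RasterLayer],
                cutoff: float = 0.80,
                scenario_tag: str = "current") -> HotspotMap:
    """Sum continuous suitability maps, min-max standardize, threshold.

    The standardized layer is ``(sum − min) / (max − min)`` over valid cells
    (exactly 0 at the minimum, 1 at the maximum); a cell is a hotspot iff its
    standardized value is strictly greater than ``cutoff``.
    """
    if len(suitability_maps) < 2:
        raise ConfigurationError("hotspots need at least 2 species maps")
    layers = list(suitability_maps.values())
    spec = require_coregistered(*layers)
    total = np.zeros(spec.shape)
    mask = np.zeros(spec.shape, dtype=bool)
    for lyr in layers:
        total += np.where(lyr.valid, lyr.values, 0.0)
        mask |= lyr.mask
    total[mask] = np.nan
    vmin = np.nanmin(total)
    vmax = np.nanmax(total)
    if not np.isfinite(vmin) or vmax == vmin:
        raise DegenerateStandardizationError(
            "summed suitability constant over valid cells; cannot standardize"
        )
    std = (total - vmin) / (vmax - vmin)
    hot = np.where(mask, np.nan, (std > cutoff).astype(float))
    tag = scenario_tag
    return HotspotMap(
        summed=RasterLayer(spec, total, mask, name=f"summed_{tag}"),
        standardized=RasterLayer(spec, std, mask, name=f"standardized_{tag}"),
        hotspot_mask=RasterLayer(spec, hot, mask, name=f"hotspots_{tag}"),
        cutoff=cutoff,
        scenario_tag=tag,
    )


@dataclass
class OverlapReport:
    """Hotspot area inside/outside protection, overall and per zone.

    Areas in km²; percentages in [0, 100] or None when the hotspot area is
    zero.  ``per_zone`` has one row per EEZ label present (0 = high seas) with
    columns zone, hotspot_km2, protected_km2, pct_protected.
    """

    total_km2: float
    protected_km2: float
    unprotected_km2: float
    pct_protected: float | None
    per_zone: pd.DataFrame


def overlap_report(hotspots: HotspotMap, zones: ZoneLayers) -> OverlapReport:
    """Intersect the hotspot mask with MPA and EEZ layers, area-weighted."""
    hs = hotspots.hotspot_mask
    require_coregistered(hs, zones.land)
    spec = hs.spec
    areas = np.broadcast_to(row_areas_km2(spec)[:, None], spec.shape)
    hot = hs.valid & (hs.values == 1)
    mpa = zones.mpa.values != 0
    total = float(areas[hot].sum())
    protected = float(areas[hot & mpa].sum())
    unprotected = total - protected
    pct = 100.0 * protected / total if total > 0 else None

    zone_ids = np.unique(zones.eez.values[zones.eez.valid]).astype(int)
    rows = []
    for z in zone_ids:
        in_zone = hot & (zones.eez.values == z) & zones.eez.valid
        z_tot = float(areas[in_zone].sum())
        z_prot = float(areas[in_zone & mpa].sum())
        rows.append({
            "zone": int(z),
            "hotspot_km2": z_tot,
            "protected_km2": z_prot,
            "pct_protected": 100.0 * z_prot / z_tot if z_tot > 0 else None,
        })
    per_zone = pd.DataFrame(rows, columns=["zone", "hotspot_km2",
                                           "protected_km2", "pct_protected"])
    return OverlapReport(total, protected, unprotected, pct, per_zone)


def shipping_transform(density: RasterLayer) -> tuple[RasterLayer, RasterLayer]:
    """Square-root rescale and above-mean high-traffic mask.

    Returns ``(sqrt_layer, high_mask)`` where the mask is 1 on valid cells
    whose square-root density strictly exceeds the mean square-root density
    over valid cells.
    """
    if np.nanmin(np.where(density.mask, 0.0, density.values)) < 0:
        raise ConfigurationError("vessel density must be nonnegative")
    sqrt_vals = np.where(density.mask, np.nan, np.sqrt(density.values))
    mean = np.nanmean(sqrt_vals) if density.valid.any() else np.nan
    high = np.where(density.mask, np.nan, (sqrt_vals > mean).astype(float))
    spec = density.spec
    return (
        RasterLayer(spec, sqrt_vals, density.mask, name=f"{density.name}_sqrt"),
        RasterLayer(spec, high, density.mask, name=f"{density.name}_high"),
    )


def cooccurrence_summary(net_change: RasterLayer, high_shipping: RasterLayer,
                         zones: ZoneLayers) -> pd.DataFrame:
    """Area (km²) of richness increase / stable / decline cells inside vs
    outside high-shipping cells, over sea cells with a defined change class."""
    require_coregistered(net_change, high_shipping, zones.land)
    spec = net_change.spec
    areas = np.broadcast_to(row_areas_km2(spec)[:, None], spec.shape)
    defined = net_change.valid & high_shipping.valid & zones.sea
    inside = high_shipping.values == 1
    classes = {
        "increase": net_change.values > 0,
        "stable": net_change.values == 0,
        "decline": net_change.values < 0,
    }
    rows = []
    for name, sel in classes.items():
        cells = defined & sel
        rows.append({
            "change_class": name,
            "inside_shipping_km2": float(areas[cells & inside].sum()),
            "outside_shipping_km2": float(areas[cells & ~inside].sum()),
        })
    return pd.DataFrame(rows)
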