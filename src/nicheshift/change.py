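"""Range-change accounting between current and projected binary maps.

Per species: pixels lost (1→0), stable (1→1), and gained (0→1), with
percentages relative to the current presence count.  Across species: stacked
richness maps and the per-pixel net change (species gained − species lost).
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .errors import ConfigurationError
from .grid import RasterLayer, require_coregistered, row_areas_km2


@dataclass(frozen=True)
class RangeChange:
    """Pixel bookkeeping between two co-registered binary maps.

    Percentages are ×100 relative to the current presence count and are None
    when the current range is empty.
    """

    n_lost: int
    n_stable: int
    n_gained: int
    pct_loss: float | None
    pct_gain: float | None
    pct_net: float | None


def range_change(current_bin: RasterLayer, future_bin: RasterLayer) -> RangeChange:
    """Count lost / stable / gained cells between two binary maps."""
    require_coregistered(current_bin, future_bin)
    valid = current_bin.valid & future_bin.valid
    cur = (current_bin.values == 1) & valid
    fut = (future_bin.values == 1) & valid
    n_lost = int((cur & ~fut).sum())
    n_stable = int((cur & fut).sum())
    n_gained = int((~cur & fut).sum())
    n_current = n_lost + n_stable
    if n_current == 0:
        return RangeChange(n_lost, n_stable, n_gained, None, None, None)
    pct_loss = 100.0 * n_lost / n_current
    pct_gain = 100.0 * n_gained / n_current
    return RangeChange(n_lost, n_stable, n_gained,
                       pct_loss, pct_gain, pct_gain - pct_loss)


def stack_richness(binary_maps: dict[str, RasterLayer],
                   scenario_tag: str = "current") -> RasterLayer:
    """Per-cell species count from one binary map per species."""
    if not binary_maps:
        raise ConfigurationError("no binary maps supplied")
    names = list(binary_maps)
    if len(set(names)) != len(names):
        raise ConfigurationError("duplicate species ids")
    layers = list(binary_maps.values())
    spec = require_coregistered(*layers)
    counts = np.zeros(spec.shape)
    any_valid = np.zeros(spec.shape, dtype=bool)
    for lyr in layers:
        counts += np.where(lyr.valid, lyr.values, 0.0)
        any_valid |= lyr.valid
    counts[~any_valid] = np.nan
    return RasterLayer(spec, counts, ~any_valid, name=f"richness_{scenario_tag}")


def net_change_map(changes: dict[str, tuple[RasterLayer, RasterLayer]],
                   scenario_tag: str = "future") -> RasterLayer:
    """Per-cell (species gained − species lost) across species.

    ``changes`` maps species id to (current_bin, future_bin).  A cell where
    equal numbers of species appear and disappear scores 0.
    """
    if not changes:
        raise ConfigurationError("no change pairs supplied")
    layers = [lyr for pair in changes.values() for lyr in pair]
    spec = require_coregistered(*layers)
    net = np.zeros(spec.shape)
    any_valid = np.zeros(spec.shape, dtype=bool)
    for cur, fut in changes.values():
        valid = cur.valid & fut.valid
        gained = (cur.values == 0) & (fut.values == 1) & valid
        lost = (cur.values == 1) & (fut.values == 0) & valid
        net += gained.astype(float) - lost.astype(float)
        any_valid |= valid
    net[~any_valid] = np.nan
    return RasterLayer(spec, net, ~any_valid, name=f"net_change_{scenario_tag}")


def latitudinal_density(bin_map: RasterLayer, band_width: float = 1.0) -> pd.DataFrame:
    """Suitable-cell count and area per latitude band.

    Bands tile [−90, 90) half-open ``[low, high)``; a cell belongs to the band
    containing its centre latitude.  Returns a DataFrame with columns
    ``band_low``, ``band_high``, ``count``, ``area_km2``.
    """
    spec = bin_map.spec
    lat = spec.lat_centers()
    areas = row_areas_km2(spec)
    suitable_per_row = np.where(bin_map.valid, bin_map.values == 1, False).sum(axis=1)
    band_idx = np.floor((lat + 90.0) / band_width).astype(int)
    n_bands = int(np.ceil(180.0 / band_width))
    counts = np.zeros(n_bands)
    area = np.zeros(n_bands)
    np.add.at(counts, band_idx, suitable_per_row)
    np.add.at(area, band_idx, suitable_per_row * areas)
    lows = -90.0 + band_width * np.arange(n_bands)
    return pd.DataFrame({
        "band_low": lows,
        "band_high": lows + band_width,
        "count": counts.astype(int),
        "area_km2": area,
    })


def presence_weighted_mean_abs_lat(bin_map: RasterLayer) -> float:
    """Mean |latitude| of suitable cells, weighted by cell count per row.

    The summary used to quantify poleward displacement of a projected range.
    """
    spec = bin_map.spec
    per_row = np.where(bin_map.valid, bin_map.values == 1, False).sum(axis=1)
    total = per_row.sum()
    if total == 0:
        return float("nan")
    return float((np.abs(spec.lat_centers()) * per_row).sum() / total)
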