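"""Georeferenced grids and raster layers.

The whole pipeline operates on a single plate-carrée longitude/latitude grid
(EPSG:4326 semantics).  Arrays are stored with row 0 at the *northern* edge,
matching the row order of common raster formats.  Cell assignment of a point
follows the containing-cell rule ``floor((coord - origin) / cell_size)`` with
half-open cells ``[low, high)``.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np

from .errors import CoRegistrationError, InvalidSpecError

EARTH_RADIUS_KM = 6371.0


@dataclass(frozen=True)
class GridSpec:
    """Regular lon/lat grid definition.

    Parameters
    ----------
    lon_min, lat_min
        Coordinates of the south-west corner, in degrees.
    cell_size
        Cell edge length in degrees (0.05 ≈ 5.5 km at the equator).
    n_rows, n_cols
        Grid dimensions.
    """

    lon_min: float
    lat_min: float
    cell_size: float
    n_rows: int
    n_cols: int

    def __post_init__(self) -> None:
        if self.cell_size <= 0:
            raise InvalidSpecError(f"cell_size must be positive, got {self.cell_size}")
        if self.n_rows <= 0 or self.n_cols <= 0:
            raise InvalidSpecError(
                f"grid dimensions must be positive, got {self.n_rows}x{self.n_cols}"
            )
        if not (-90.0 <= self.lat_min and self.lat_max <= 90.0):
            raise InvalidSpecError("latitude extent must lie within [-90, 90]")
        if not (-180.0 <= self.lon_min and self.lon_max <= 180.0):
            raise InvalidSpecError("longitude extent must lie within [-180, 180]")

    @property
    def lat_max(self) -> float:
        return self.lat_min + self.n_rows * self.cell_size

    @property
    def lon_max(self) -> float:
        return self.lon_min + self.n_cols * self.cell_size

    @property
    def shape(self) -> tuple[int, int]:
        return (self.n_rows, self.n_cols)

    def lat_centers(self) -> np.ndarray:
        """Latitude of each row centre, row 0 northernmost."""
        return self.lat_max - (np.arange(self.n_rows) + 0.5) * self.cell_size

    def lon_centers(self) -> np.ndarray:
        return self.lon_min + (np.arange(self.n_cols) + 0.5) * self.cell_size

    def cell_of(self, lon: float, lat: float) -> tuple[int, int] | None:
        """Containing cell (row, col) of a point, or None outside the extent."""
        col = math.floor((lon - self.lon_min) / self.cell_size)
        i_south = math.floor((lat - self.lat_min) / self.cell_size)
        if not (0 <= col < self.n_cols and 0 <= i_south < self.n_rows):
            return None
        return self.n_rows - 1 - i_south, col

    def cells_of(self, lons: np.ndarray, lats: np.ndarray) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
        """Vectorized cell assignment.

        Returns ``(rows, cols, inside)``; rows/cols are meaningless where
        ``inside`` is False.
        """
        lons = np.asarray(lons, dtype=float)
        lats = np.asarray(lats, dtype=float)
        cols = np.floor((lons - self.lon_min) / self.cell_size).astype(int)
        i_south = np.floor((lats - self.lat_min) / self.cell_size).astype(int)
        inside = (cols >= 0) & (cols < self.n_cols) & (i_south >= 0) & (i_south < self.n_rows)
        rows = self.n_rows - 1 - i_south
        return rows, cols, inside

    def cell_center(self, row: int, col: int) -> tuple[float, float]:
        """(lon, lat) of a cell centre."""
        lon = self.lon_min + (col + 0.5) * self.cell_size
        lat = self.lat_max - (row + 0.5) * self.cell_size
        return lon, lat


def cell_area_km2(spec: GridSpec, row: int | np.ndarray) -> float | np.ndarray:
    """Area of the cell(s) in a given row, spherical-cap formula.

    area = R² · Δλ · (sin φ_top − sin φ_bottom), R = 6371 km.  All cells in a
    row share the same area on a plate-carrée grid.
    """
    row = np.asarray(row)
    phi_top = np.radians(spec.lat_max - row * spec.cell_size)
    phi_bot = np.radians(spec.lat_max - (row + 1) * spec.cell_size)
    dlam = math.radians(spec.cell_size)
    area = EARTH_RADIUS_KM**2 * dlam * (np.sin(phi_top) - np.sin(phi_bot))
    return float(area) if area.ndim == 0 else area


def row_areas_km2(spec: GridSpec) -> np.ndarray:
    """Per-row cell area, length n_rows."""
    return cell_area_km2(spec, np.arange(spec.n_rows))


@dataclass
class RasterLayer:
    """A named grid of values with a nodata mask.

    ``mask`` is True where the cell carries *no data* (e.g. land in a marine
    layer); masked cells are excluded from every statistic.
    """

    spec: GridSpec
    values: np.ndarray
    mask: np.ndarray = None  # type: ignore[assignment]
    name: str = ""

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=float)
        if self.mask is None:
            self.mask = np.zeros(self.spec.shape, dtype=bool)
        self.mask = np.asarray(self.mask, dtype=bool)
        if self.values.shape != self.spec.shape or self.mask.shape != self.spec.shape:
            raise CoRegistrationError(
                f"layer {self.name!r}: array shape {self.values.shape} does not match "
                f"grid {self.spec.shape}"
            )

    @property
    def valid(self) -> np.ndarray:
        return ~self.mask

    def valid_values(self) -> np.ndarray:
        return self.values[~self.mask]

    def copy(self, name: str | None = None) -> "RasterLayer":
        return RasterLayer(self.spec, self.values.copy(), self.mask.copy(),
                           self.name if name is None else name)


def require_coregistered(*layers: RasterLayer) -> GridSpec:
    """Assert all layers share one grid; return it."""
    spec = layers[0].spec
    for lyr in layers[1:]:
        if lyr.spec != spec:
            raise CoRegistrationError(
                f"layers {layers[0].name!r} and {lyr.name!r} are on different grids"
            )
    return spec


@dataclass
class EnvStack:
    """A co-registered set of environmental layers for one scenario."""

    spec: GridSpec
    layers: dict[str, RasterLayer] = field(default_factory=dict)
    scenario_tag: str = "current"

    def __post_init__(self) -> None:
        for name, lyr in self.layers.items():
            if lyr.spec != self.spec:
                raise CoRegistrationError(f"layer {name!r} not on the stack grid")

    @property
    def names(self) -> list[str]:
        return list(self.layers)

    def __getitem__(self, name: str) -> RasterLayer:
        return self.layers[name]

    def __contains__(self, name: str) -> bool:
        return name in self.layers

    def combined_mask(self, names: list[str] | None = None) -> np.ndarray:
        """Union of nodata masks over the given (default: all) layers."""
        mask = np.zeros(self.spec.shape, dtype=bool)
        for name in names if names is not None else self.names:
            mask |= self.layers[name].mask
        return mask

    def table(self, rows: np.ndarray, cols: np.ndarray, names: list[str] | None = None):
        """Extract a (n_points × n_layers) value matrix at cell indices."""
        import pandas as pd

        names = names if names is not None else self.names
        data = {name: self.layers[name].values[rows, cols] for name in names}
        return pd.DataFrame(data)


@dataclass
class ZoneLayers:
    """Land, MPA, and EEZ partitions on the common grid.

    ``land``: boolean layer, True(1) = land.  ``mpa``: boolean layer on sea
    cells.  ``eez``: integer labels, 0 = high seas, defined on sea cells.
    """

    land: RasterLayer
    mpa: RasterLayer
    eez: RasterLayer

    def __post_init__(self) -> None:
        require_coregistered(self.land, self.mpa, self.eez)

    @property
    def spec(self) -> GridSpec:
        return self.land.spec

    @property
    def sea(self) -> np.ndarray:
        return self.land.values == 0
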