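"""File formats.

Rasters are stored as ESRI ASCII grids (.asc) — a plain-text single-band
format every GIS reads — with rows north to south, matching the in-memory
layout.  Environmental stacks are directories of .asc layers plus a
``stack.json`` manifest recording layer order, the grid, and the scenario
tag.  Occurrences travel as CSV with the field-standard column names
``species``, ``decimalLongitude``, ``decimalLatitude``.  Zone polygons may be
supplied as GeoJSON and are rasterized on load by cell-centre containment.
"""

from __future__ import annotations

import json
from pathlib import Path

import numpy as np
import pandas as pd

from .errors import CoRegistrationError, SchemaError
from .grid import EnvStack, GridSpec, RasterLayer, ZoneLayers
from .occurrences import OccurrenceSet

_NODATA = -9999.0


def write_raster(layer: RasterLayer, path: str | Path) -> Path:
    """Write one layer as an ESRI ASCII grid."""
    path = Path(path)
    spec = layer.spec
    vals = np.where(layer.mask, _NODATA, layer.values)
    header = (
        f"ncols {spec.n_cols}\n"
        f"nrows {spec.n_rows}\n"
        f"xllcorner {spec.lon_min!r}\n"
        f"yllcorner {spec.lat_min!r}\n"
        f"cellsize {spec.cell_size!r}\n"
        f"NODATA_value {_NODATA}\n"
    )
    with open(path, "w") as fh:
        fh.write(header)
        np.savetxt(fh, vals, fmt="%.9g")
    return path


def read_raster(path: str | Path, name: str | None = None) -> RasterLayer:
    """Read an ESRI ASCII grid."""
    path = Path(path)
    header: dict[str, float] = {}
    with open(path) as fh:
        for _ in range(6):
            key, val = fh.readline().split()
            header[key.lower()] = float(val)
        vals = np.loadtxt(fh)
    n_rows, n_cols = int(header["nrows"]), int(header["ncols"])
    vals = vals.reshape(n_rows, n_cols)
    spec = GridSpec(header["xllcorner"], header["yllcorner"],
                    header["cellsize"], n_rows, n_cols)
    nodata = header.get("nodata_value", _NODATA)
    mask = vals == nodata
    vals = np.where(mask, np.nan, vals)
    return RasterLayer(spec, vals, mask, name=name or path.stem)


def write_stack(stack: EnvStack, directory: str | Path) -> Path:
    """Write a stack as one .asc per layer plus stack.json."""
    directory = Path(directory)
    directory.mkdir(parents=True, exist_ok=True)
    for name, lyr in stack.layers.items():
        write_raster(lyr, directory / f"{name}.asc")
    manifest = {
        "scenario_tag": stack.scenario_tag,
        "layers": stack.names,
        "grid": {
            "lon_min": stack.spec.lon_min, "lat_min": stack.spec.lat_min,
            "cell_size": stack.spec.cell_size,
            "n_rows": stack.spec.n_rows, "n_cols": stack.spec.n_cols,
        },
    }
    (directory / "stack.json").write_text(json.dumps(manifest, indent=1))
    return directory


def read_stack(directory: str | Path) -> EnvStack:
    """Read a stack directory; all layers must share the manifest grid."""
    directory = Path(directory)
    manifest = json.loads((directory / "stack.json").read_text())
    g = manifest["grid"]
    spec = GridSpec(g["lon_min"], g["lat_min"], g["cell_size"],
                    g["n_rows"], g["n_cols"])
    layers = {}
    for name in manifest["layers"]:
        lyr = read_raster(directory / f"{name}.asc", name=name)
        if lyr.spec != spec:
            raise CoRegistrationError(
                f"layer file {name}.asc grid differs from stack.json in {directory}"
            )
        layers[name] = lyr
    return EnvStack(spec, layers, manifest["scenario_tag"])


def write_occurrences(occ: OccurrenceSet, path: str | Path) -> Path:
    path = Path(path)
    pd.DataFrame({
        "species": occ.species_id,
        "decimalLongitude": occ.table["lon"],
        "decimalLatitude": occ.table["lat"],
    }).to_csv(path, index=False)
    return path


def read_occurrences(path: str | Path, species_id: str | None = None) -> OccurrenceSet:
    df = pd.read_csv(path)
    required = {"species", "decimalLongitude", "decimalLatitude"}
    missing = required - set(df.columns)
    if missing:
        raise SchemaError(f"occurrence CSV {path} lacks columns {sorted(missing)}")
    if species_id is not None:
        df = df[df["species"] == species_id]
    elif df["species"].nunique() > 1:
        raise SchemaError("multiple species in file; pass species_id")
    sid = species_id or (df["species"].iloc[0] if len(df) else "unknown")
    return OccurrenceSet(
        species_id=str(sid),
        table=pd.DataFrame({
            "lon": df["decimalLongitude"].to_numpy(dtype=float),
            "lat": df["decimalLatitude"].to_numpy(dtype=float),
        }),
    )


def write_qc_report(occ: OccurrenceSet, path: str | Path) -> Path:
    path = Path(path)
    path.write_text(json.dumps({
        "species": occ.species_id,
        "n_retained": len(occ),
        "removals": [{"filter": f, "removed": n} for f, n in occ.provenance_log],
    }, indent=1))
    return path


def rasterize_geojson(path: str | Path, spec: GridSpec,
                      value_property: str | None = None) -> RasterLayer:
    """Rasterize GeoJSON polygons by cell-centre containment.

    Cells whose centre falls inside any feature get that feature's
    ``value_property`` (or 1); others get 0.
    """
    from shapely.geometry import shape
    from shapely import contains_xy

    path = Path(path)
    gj = json.loads(path.read_text())
    features = gj["features"] if gj.get("type") == "FeatureCollection" else [gj]
    lon = np.broadcast_to(spec.lon_centers()[None, :], spec.shape)
    lat = np.broadcast_to(spec.lat_centers()[:, None], spec.shape)
    vals = np.zeros(spec.shape)
    for feat in features:
        geom = shape(feat["geometry"])
        v = 1.0
        if value_property is not None:
            v = float(feat.get("properties", {}).get(value_property, 1.0))
        inside = contains_xy(geom, lon, lat)
        vals[inside] = v
    return RasterLayer(spec, vals, name=path.stem)


def read_zones(land_path: str | Path, mpa_path: str | Path,
               eez_path: str | Path, spec: GridSpec | None = None) -> ZoneLayers:
    """Read zone layers from .asc rasters or .geojson polygon files."""
    def load(p, name):
        p = Path(p)
        if p.suffix.lower() in (".geojson", ".json"):
            if spec is None:
                raise SchemaError("GeoJSON zones need a target GridSpec")
            prop = "zone" if name == "eez" else None
            return rasterize_geojson(p, spec, value_property=prop)
        return read_raster(p, name=name)

    land = load(land_path, "land")
    mpa = load(mpa_path, "mpa")
    eez = load(eez_path, "eez")
    sea = land.values == 0
    mpa = RasterLayer(mpa.spec, np.where(sea, mpa.values, 0.0), ~sea, name="mpa")
    eez = RasterLayer(eez.spec, np.where(sea, eez.values, 0.0), ~sea, name="eez")
    return ZoneLayers(land=land, mpa=mpa, eez=eez)
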