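"""Synthetic ground-truth world generator.

Emulates the statistical structure the downstream analysis assumes: spatially
autocorrelated environmental fields with a latitudinal temperature gradient,
species presences drawn from known Gaussian niche functions, spatially uniform
additive warming per scenario, blocky land/MPA/EEZ masks, and a heavy-tailed
shipping-lane density field.  Because every niche is known exactly, each
pipeline stage can be tested against the truth without external downloads.

All generators are pure functions of (parameters, seed).
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import ndimage

from .errors import CannotSampleError, ConfigurationError
from .grid import EnvStack, GridSpec, RasterLayer, ZoneLayers
from .occurrences import OccurrenceSet

# Deterministic layer catalogue: (name, base level, noise s.d.).  Temperature
# is always present and carries the latitudinal gradient on top.
_AUX_LAYERS = [
    ("chlorophyll", 5.0, 3.0),
    ("salinity", 35.0, 1.5),
    ("oxygen", 250.0, 20.0),
    ("ph", 8.1, 0.05),
    ("nitrate", 8.0, 4.0),
    ("current_velocity", 0.3, 0.15),
    ("bathymetry", -2000.0, 800.0),
    ("silicate", 10.0, 5.0),
    ("phosphate", 0.8, 0.4),
]


@dataclass(frozen=True)
class NicheParams:
    """Ground-truth Gaussian niche of one synthetic species.

    Suitability is the product over used variables of
    ``exp(-(e_v - mu_v)² / (2 sigma_v²))``: 1 at the joint optimum, strictly
    decreasing as any variable departs it.
    """

    species_id: str
    mu: dict[str, float]
    sigma: dict[str, float]

    def __post_init__(self) -> None:
        if not self.mu:
            raise ConfigurationError("niche must use at least one variable")
        if set(self.mu) != set(self.sigma):
            raise ConfigurationError("mu and sigma must cover the same variables")
        for v, s in self.sigma.items():
            if s <= 0:
                raise ConfigurationError(f"sigma must be positive for {v!r}, got {s}")

    @property
    def variables_used(self) -> list[str]:
        return list(self.mu)


def smoothed_noise(rng: np.random.Generator, shape: tuple[int, int],
                   smooth_cells: int = 8, sd: float = 1.0) -> np.ndarray:
    """Spatially autocorrelated Gaussian field: moving-average smoothed white
    noise rescaled to the target standard deviation."""
    white = rng.standard_normal(shape)
    smooth = ndimage.uniform_filter(white, size=smooth_cells, mode="nearest")
    s = smooth.std()
    if s > 0:
        smooth = smooth / s * sd
    return smooth


def generate_env_stack(
    spec: GridSpec,
    n_vars: int = 8,
    warming_deltas: dict[str, float] | None = None,
    seed: int = 0,
    temp_offset: float = 30.0,
    temp_lat_slope: float = 0.5,
    temp_noise_sd: float = 0.5,
    smooth_cells: int = 8,
) -> dict[str, EnvStack]:
    """Generate the current stack plus one stack per warming scenario.

    The "temperature" layer is a monotone latitudinal gradient
    ``T(lat) = temp_offset − temp_lat_slope · lat`` plus smoothed noise; the
    other layers are constant base levels plus independent smoothed-noise
    fields.  Scenario stacks equal the current stack except that temperature
    is increased everywhere by the scenario's delta.

    Returns a dict keyed by scenario tag; "current" is always present.
    """
    if n_vars < 2:
        raise ConfigurationError(f"n_vars must be >= 2, got {n_vars}")
    if n_vars - 1 > len(_AUX_LAYERS):
        raise ConfigurationError(
            f"at most {len(_AUX_LAYERS) + 1} variables available, requested {n_vars}"
        )
    warming_deltas = dict(warming_deltas or {})

    ss = np.random.SeedSequence(seed)
    child_seeds = ss.spawn(n_vars)

    lat = spec.lat_centers()[:, None] * np.ones((1, spec.n_cols))
    rng_t = np.random.default_rng(child_seeds[0])
    temp = temp_offset - temp_lat_slope * lat
    if temp_noise_sd > 0:
        temp = temp + smoothed_noise(rng_t, spec.shape, smooth_cells, temp_noise_sd)

    layers: dict[str, np.ndarray] = {"temperature": temp}
    for i, (name, base, sd) in enumerate(_AUX_LAYERS[: n_vars - 1]):
        rng = np.random.default_rng(child_seeds[i + 1])
        layers[name] = base + smoothed_noise(rng, spec.shape, smooth_cells, sd)

    def build(tag: str, delta: float) -> EnvStack:
        out = {}
        for name, vals in layers.items():
            v = vals + delta if name == "temperature" else vals.copy()
            out[name] = RasterLayer(spec, v, name=name)
        return EnvStack(spec, out, scenario_tag=tag)

    stacks = {"current": build("current", 0.0)}
    for tag, delta in warming_deltas.items():
        stacks[tag] = build(tag, float(delta))
    return stacks


def true_suitability(params: NicheParams, stack: EnvStack) -> RasterLayer:
    """Evaluate the ground-truth Gaussian niche over a stack.

    Returns a layer in (0, 1]; nodata is the union of the used layers' masks.
    """
    missing = [v for v in params.variables_used if v not in stack]
    if missing:
        raise ConfigurationError(f"stack lacks niche variables {missing}")
    log_s = np.zeros(stack.spec.shape)
    for v in params.variables_used:
        e = stack[v].values
        log_s -= (e - params.mu[v]) ** 2 / (2.0 * params.sigma[v] ** 2)
    mask = stack.combined_mask(params.variables_used)
    vals = np.exp(log_s)
    vals[mask] = np.nan
    return RasterLayer(stack.spec, vals, mask, name=f"truth_{params.species_id}")


def apply_land_mask(stack: EnvStack, land: RasterLayer) -> EnvStack:
    """Return a copy of the stack with land cells set to nodata."""
    landmask = land.values != 0
    layers = {}
    for name, lyr in stack.layers.items():
        vals = lyr.values.copy()
        vals[landmask] = np.nan
        layers[name] = RasterLayer(stack.spec, vals, lyr.mask | landmask, name=name)
    return EnvStack(stack.spec, layers, stack.scenario_tag)


_CONTAMINANT_ORDER = ["duplicate", "zero_coord", "land", "low_precision"]


def sample_occurrences(
    truth: RasterLayer,
    n_target: int,
    error_rates: dict[str, float] | None = None,
    seed: int = 0,
    species_id: str = "species",
) -> OccurrenceSet:
    """Draw presence points from a truth layer, plus flagged contaminants.

    Clean points fall in cells with probability proportional to suitability,
    jittered uniformly within the cell.  Contaminant records are appended in a
    fixed order (duplicates of clean rows, (0,0) records, points on nodata/land
    cells, coordinates rounded to one decimal) with counts
    ``round(rate · n_target)`` each.  Their class labels travel in the hidden
    ``flags`` sidecar so QC tests have an oracle; the QC stage never sees them.
    """
    error_rates = dict(error_rates or {})
    for k, r in error_rates.items():
        if k not in _CONTAMINANT_ORDER:
            raise ConfigurationError(f"unknown contaminant class {k!r}")
        if not (0.0 <= r < 1.0):
            raise ConfigurationError(f"error rate {k}={r} outside [0, 1)")

    spec = truth.spec
    rng = np.random.default_rng(np.random.SeedSequence(seed))
    probs = np.where(truth.mask, 0.0, np.nan_to_num(truth.values, nan=0.0)).ravel()
    total = probs.sum()
    if total <= 0:
        raise CannotSampleError("truth layer has no positive suitability to sample from")
    probs = probs / total

    flat = rng.choice(probs.size, size=n_target, replace=True, p=probs)
    rows, cols = np.unravel_index(flat, spec.shape)
    u = rng.random(n_target)
    v = rng.random(n_target)
    lons = spec.lon_min + (cols + u) * spec.cell_size
    lats = spec.lat_max - (rows + v) * spec.cell_size

    recs = [pd.DataFrame({"lon": lons, "lat": lats})]
    flags = ["clean"] * n_target

    counts = {k: int(round(error_rates.get(k, 0.0) * n_target)) for k in _CONTAMINANT_ORDER}
    if counts["duplicate"]:
        idx = rng.choice(n_target, size=counts["duplicate"], replace=True)
        recs.append(pd.DataFrame({"lon": lons[idx], "lat": lats[idx]}))
        flags += ["duplicate"] * counts["duplicate"]
    if counts["zero_coord"]:
        recs.append(pd.DataFrame({"lon": np.zeros(counts["zero_coord"]),
                                  "lat": np.zeros(counts["zero_coord"])}))
        flags += ["zero_coord"] * counts["zero_coord"]
    if counts["land"]:
        land_flat = np.flatnonzero(truth.mask.ravel())
        if land_flat.size == 0:
            raise CannotSampleError("land contaminants requested but truth has no nodata cells")
        pick = rng.choice(land_flat, size=counts["land"], replace=True)
        r2, c2 = np.unravel_index(pick, spec.shape)
        recs.append(pd.DataFrame({
            "lon": spec.lon_min + (c2 + rng.random(counts["land"])) * spec.cell_size,
            "lat": spec.lat_max - (r2 + rng.random(counts["land"])) * spec.cell_size,
        }))
        flags += ["land"] * counts["land"]
    if counts["low_precision"]:
        n = counts["low_precision"]
        sea_flat = np.flatnonzero((~truth.mask).ravel())
        pick = rng.choice(sea_flat, size=n, replace=True)
        r3, c3 = np.unravel_index(pick, spec.shape)
        lon3 = np.round(spec.lon_min + (c3 + 0.5) * spec.cell_size, 1)
        lat3 = np.round(spec.lat_max - (r3 + 0.5) * spec.cell_size, 1)
        # avoid colliding with other contaminant classes
        bump = (lon3 == lat3) | ((lon3 == 0) & (lat3 == 0))
        lon3 = np.where(bump, lon3 + 0.1, lon3)
        recs.append(pd.DataFrame({"lon": lon3, "lat": lat3}))
        flags += ["low_precision"] * n

    table = pd.concat(recs, ignore_index=True)
    return OccurrenceSet(species_id=species_id, table=table,
                         provenance_log=[], flags=np.array(flags))


def generate_zones(
    spec: GridSpec,
    mpa_fraction: float = 0.1,
    n_eez: int = 5,
    seed: int = 0,
    land_cols_fraction: float = 0.15,
    coast_buffer_cells: int = 12,
) -> ZoneLayers:
    """Blocky land band, MPA patches, and a coastal EEZ partition.

    Land is a contiguous band along the eastern edge with a wavy coastline.
    The MPA mask covers ``round(mpa_fraction · n_sea)`` sea cells (grown from
    random seeds into blocky patches, trimmed to the exact count).  EEZ labels
    1..n_eez partition the coastal buffer into latitudinal strips; 0 elsewhere
    (high seas).
    """
    if not (0.0 <= mpa_fraction <= 1.0):
        raise ConfigurationError(f"mpa_fraction={mpa_fraction} outside [0, 1]")
    if n_eez < 1:
        raise ConfigurationError(f"n_eez must be >= 1, got {n_eez}")

    rng = np.random.default_rng(np.random.SeedSequence(seed))
    land = np.zeros(spec.shape, dtype=float)
    base_width = max(1, int(round(land_cols_fraction * spec.n_cols)))
    # wavy coastline: per-row land width varies smoothly around the base width
    wave = smoothed_noise(rng, (spec.n_rows, 1), smooth_cells=max(4, spec.n_rows // 8), sd=1.0)
    widths = np.clip(base_width + np.round(wave[:, 0] * base_width * 0.4).astype(int),
                     1, spec.n_cols - 2)
    for r in range(spec.n_rows):
        land[r, spec.n_cols - widths[r]:] = 1.0
    sea = land == 0

    # MPA: grow blocky patches from random sea seeds, then trim/pad to count
    n_sea = int(sea.sum())
    target = int(round(mpa_fraction * n_sea))
    mpa = np.zeros(spec.shape, dtype=bool)
    if target > 0:
        n_patches = max(1, target // 40)
        sea_idx = np.flatnonzero(sea.ravel())
        seeds = rng.choice(sea_idx, size=min(n_patches, sea_idx.size), replace=False)
        grown = np.zeros(spec.shape, dtype=bool)
        grown.ravel()[seeds] = True
        while (grown & sea).sum() < target:
            grown = ndimage.binary_dilation(grown) & sea
            if grown.all():
                break
        candidates = np.flatnonzero((grown & sea).ravel())
        if candidates.size >= target:
            keep = rng.choice(candidates, size=target, replace=False)
        else:  # pad from remaining sea cells
            rest = np.setdiff1d(sea_idx, candidates)
            extra = rng.choice(rest, size=target - candidates.size, replace=False)
            keep = np.concatenate([candidates, extra])
        mpa.ravel()[keep] = True

    # EEZ: coastal buffer split into n_eez latitudinal strips
    coast = ndimage.binary_dilation(land > 0, iterations=coast_buffer_cells) & sea
    eez = np.zeros(spec.shape, dtype=float)
    edges = np.linspace(0, spec.n_rows, n_eez + 1).astype(int)
    for z in range(n_eez):
        rows = slice(edges[z], edges[z + 1])
        strip = np.zeros(spec.shape, dtype=bool)
        strip[rows, :] = True
        eez[coast & strip] = z + 1

    return ZoneLayers(
        land=RasterLayer(spec, land, name="land"),
        mpa=RasterLayer(spec, mpa.astype(float), mask=~sea, name="mpa"),
        eez=RasterLayer(spec, eez, mask=~sea, name="eez"),
    )


def generate_shipping(
    spec: GridSpec,
    n_lanes: int = 6,
    seed: int = 0,
    land: RasterLayer | None = None,
    lane_width_cells: float = 2.0,
) -> RasterLayer:
    """Heavy-tailed vessel-density field concentrated along linear corridors.

    Each lane is a straight segment between two random points with a Gaussian
    cross-section and a log-normal intensity (heavy tail across lanes); a
    multiplicative log-normal speckle roughens the field within lanes.  Zero on
    land.
    """
    if n_lanes < 0:
        raise ConfigurationError(f"n_lanes must be >= 0, got {n_lanes}")
    rng = np.random.default_rng(np.random.SeedSequence(seed))
    density = np.zeros(spec.shape)
    rr, cc = np.mgrid[0: spec.n_rows, 0: spec.n_cols]
    for _ in range(n_lanes):
        p0 = rng.random(2) * [spec.n_rows, spec.n_cols]
        p1 = rng.random(2) * [spec.n_rows, spec.n_cols]
        d = p1 - p0
        norm2 = (d**2).sum()
        if norm2 == 0:
            continue
        t = ((rr - p0[0]) * d[0] + (cc - p0[1]) * d[1]) / norm2
        t = np.clip(t, 0.0, 1.0)
        dist = np.hypot(rr - (p0[0] + t * d[0]), cc - (p0[1] + t * d[1]))
        amplitude = rng.lognormal(mean=2.0, sigma=1.0)
        density += amplitude * np.exp(-0.5 * (dist / lane_width_cells) ** 2)
    if n_lanes > 0:
        density *= rng.lognormal(mean=0.0, sigma=0.5, size=spec.shape)
    mask = np.zeros(spec.shape, dtype=bool)
    if land is not None:
        mask = land.values != 0
        density[mask] = 0.0
    return RasterLayer(spec, density, mask, name="shipping")


# ---------------------------------------------------------------------------
# Default species community

@dataclass(frozen=True)
class WorldConfig:
    """Grid and community defaults for the synthetic study region.

    A 100 × 200 cell northern-hemisphere basin at 0.5° resolution
    (lat 0–50°N, lon 0–100°E) with seven species whose thermal optima are
    spread over the tropical–temperate gradient; each niche is driven by
    temperature and chlorophyll only, leaving the remaining layers as
    uninformative decoys for variable selection to reject.
    """

    lat_min: float = 0.0
    lon_min: float = 0.0
    cell_size: float = 0.5
    n_rows: int = 100
    n_cols: int = 200
    n_vars: int = 8
    n_species: int = 7

    def grid(self) -> GridSpec:
        return GridSpec(self.lon_min, self.lat_min, self.cell_size,
                        self.n_rows, self.n_cols)


def default_species(n_species: int = 7) -> list[NicheParams]:
    """Seven synthetic species spanning thermal optima 17–27 °C.

    Niches are deliberately sharp (σ_T = 0.8 °C, σ_chl = 1.2) so the presence
    signal over the 50°-latitude basin is strong — the regime in which
    presence/pseudoabsence ensembles are expected to reach high held-out
    skill — and thermal optima stay well inside the domain under every
    warming scenario.
    """
    optima = np.linspace(27.0, 17.0, n_species)
    species = []
    for i, t_opt in enumerate(optima):
        species.append(NicheParams(
            species_id=f"sp{i + 1:02d}",
            mu={"temperature": float(t_opt), "chlorophyll": 5.0},
            sigma={"temperature": 0.8, "chlorophyll": 1.2},
        ))
    return species
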