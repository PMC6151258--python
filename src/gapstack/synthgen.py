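"""Virtual landscapes, reserve zoning, virtual species, and biased sampling.

This module builds everything the downstream pipeline needs without any field
data: a mountain-reserve-scale landscape (elevation ~375-2,118 m on a planar
meter grid), elevation-driven climate layers in annual/summer/winter groups,
nested core/buffer/experimental zoning, roads, and virtual species with known
product-Gaussian niches sampled through camera/transect/interview/specimen
detection processes with a road-proximity sampling bias.

Because every virtual species has a known true distribution, the whole
ensemble-modeling workflow can be validated as a recovery experiment.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
import shapely
from scipy.ndimage import gaussian_filter
from shapely.geometry import LineString

from .envstack import EnvStack
from .grid import Grid

__all__ = [
    "ClimateLayerSpec", "SyntheticLandscape", "VirtualSpecies", "ZoneMask",
    "generate_landscape", "suitability", "true_distribution",
    "generate_zones_and_roads", "generate_camera_sites", "sample_occurrences",
    "default_virtual_species", "distance_to_roads",
    "ZONE_CODES", "ZONE_LABELS", "GROUP_SEASON",
]

#: Integer codes used in zone rasters.
ZONE_CODES = {"outside": 0, "core": 1, "buffer_zone": 2, "experimental": 3,
              "margin_1km": 4}
ZONE_LABELS = {v: k for k, v in ZONE_CODES.items()}

#: Phenology group -> climate season its distribution is modeled with.
GROUP_SEASON = {"mammal": "annual", "resident_bird": "annual",
                "summer_bird": "summer", "winter_bird": "winter"}

#: Seasonal activity windows used for synthetic timestamps.
SEASON_WINDOWS = {
    "annual": ("2017-01-01", "2017-12-31"),
    "summer": ("2017-05-01", "2017-09-30"),
    "winter": ("2016-11-01", "2017-02-28"),
}

#: Reserve zone areas (km^2) of the emulated reserve: core, buffer, experimental.
RESERVE_ZONE_KM2 = (37.95, 24.04, 80.48)
RESERVE_TOTAL_KM2 = 142.47


@dataclass(frozen=True)
class ClimateLayerSpec:
    """One synthetic climate layer: an affine function of elevation plus
    spatially smoothed noise.  ``lapse`` is the per-meter elevation slope
    (e.g. -0.0065 degC/m for mean temperature)."""

    name: str
    season: str              # annual | summer | winter
    lapse: float
    intercept: float
    noise_sigma: float       # std dev of the smoothed-noise term, layer units


def default_climate_specs() -> list[ClimateLayerSpec]:
    """Seven climate layers in three seasonal groups (with elevation and slope
    they make the nine-variable default stack)."""
    return [
        ClimateLayerSpec("tmean_annual", "annual", -0.0065, 12.0, 0.4),
        ClimateLayerSpec("prec_annual", "annual", 0.25, 600.0, 25.0),
        ClimateLayerSpec("srad_annual", "annual", 0.004, 140.0, 4.0),
        ClimateLayerSpec("tmax_summer", "summer", -0.0060, 26.0, 0.4),
        ClimateLayerSpec("prec_summer", "summer", 0.15, 380.0, 18.0),
        ClimateLayerSpec("tmin_winter", "winter", -0.0070, -6.0, 0.5),
        ClimateLayerSpec("prec_winter", "winter", 0.02, 25.0, 2.0),
    ]


@dataclass
class SyntheticLandscape:
    grid: Grid
    elevation: np.ndarray                       # m
    slope: np.ndarray                           # degrees, >= 0
    climate: dict[str, tuple[np.ndarray, str]]  # name -> (raster, season)
    roads: list[LineString] = field(default_factory=list)
    seed: int = 0

    def env_stack(self) -> EnvStack:
        layers = {"elevation": self.elevation, "slope": self.slope}
        season = {"elevation": "annual", "slope": "annual"}
        for name, (arr, grp) in self.climate.items():
            layers[name] = arr
            season[name] = grp
        return EnvStack(layers=layers, season=season, grid=self.grid,
                        topography=frozenset({"elevation", "slope"}))


@dataclass(frozen=True)
class VirtualSpecies:
    """A species with a known unimodal niche: suitability is the product of
    Gaussian responses exp(-(x_v - opt_v)^2 / (2 * breadth_v^2)) over its
    niche variables, and truth is suitability >= prevalence_threshold."""

    species_id: str
    group: str                                   # mammal | resident_bird | summer_bird | winter_bird
    niche: dict[str, tuple[float, float]]        # variable -> (optimum, breadth)
    prevalence_threshold: float = 0.3

    def __post_init__(self) -> None:
        if self.group not in GROUP_SEASON:
            raise ValueError(f"unknown group {self.group!r}")
        for var, (_, breadth) in self.niche.items():
            if not breadth > 0:
                raise ValueError(f"{self.species_id}: breadth for {var!r} must be > 0")


@dataclass
class ZoneMask:
    """Reserve zoning raster with integer codes per ``ZONE_CODES``."""

    zone: np.ndarray
    grid: Grid

    def zone_areas(self) -> dict[str, float]:
        """km^2 per zone label (all labels reported, zeros included)."""
        counts = np.bincount(self.zone.ravel().astype(int), minlength=len(ZONE_CODES))
        return {label: float(counts[code] * self.grid.cell_area_km2)
                for label, code in ZONE_CODES.items()}

    def reserve_mask(self) -> np.ndarray:
        return np.isin(self.zone, [ZONE_CODES["core"], ZONE_CODES["buffer_zone"],
                                   ZONE_CODES["experimental"]])


# --------------------------------------------------------------------------- fields
def _smooth_field(shape: tuple[int, int], sigma_cells: float,
                  rng: np.random.Generator) -> np.ndarray:
    """Standardized Gaussian white noise smoothed by an isotropic kernel."""
    white = rng.standard_normal(shape)
    if sigma_cells > 0:
        f = gaussian_filter(white, sigma=sigma_cells, mode="reflect")
    else:
        f = white
    sd = f.std()
    if sd == 0:
        return np.zeros(shape)
    return (f - f.mean()) / sd


def generate_landscape(extent: tuple[float, float, float, float] = (0.0, 0.0, 12000.0, 12000.0),
                       cell_size: float = 200.0,
                       elev_range: tuple[float, float] = (375.0, 2118.0),
                       climate_specs: list[ClimateLayerSpec] | None = None,
                       n_climate_layers: int | None = None,
                       length_scale_m: float = 2500.0,
                       noise_scale: float = 1.0,
                       seed: int = 0) -> SyntheticLandscape:
    """Generate a synthetic reserve-scale landscape.

    Elevation is a smoothed random field rescaled exactly to ``elev_range``;
    slope comes from central differences of elevation; each climate layer is
    ``lapse * elevation + intercept + noise_sigma * noise_scale * smoothed
    noise``.  Deterministic for a fixed seed.
    """
    grid = Grid.from_extent(extent, cell_size)
    if grid.nrows < 4 or grid.ncols < 4:
        raise ValueError(f"degenerate extent: grid {grid.shape} smaller than 4x4")
    lo, hi = elev_range
    if hi < lo:
        raise ValueError(f"invalid elev_range {elev_range}")
    rng = np.random.default_rng(seed)
    sigma_cells = length_scale_m / cell_size

    f = _smooth_field(grid.shape, sigma_cells, rng)
    span = f.max() - f.min()
    if span == 0 or hi == lo:
        elevation = np.full(grid.shape, (lo + hi) / 2.0)
    else:
        elevation = (f - f.min()) / span * (hi - lo) + lo

    gy, gx = np.gradient(elevation, cell_size)
    slope = np.degrees(np.arctan(np.hypot(gx, gy)))

    if climate_specs is None:
        climate_specs = default_climate_specs()
    if n_climate_layers is not None:
        if n_climate_layers < 2:
            raise ValueError("need at least 2 climate layers")
        climate_specs = climate_specs[:n_climate_layers]
    climate: dict[str, tuple[np.ndarray, str]] = {}
    for spec in climate_specs:
        if spec.season not in ("annual", "summer", "winter"):
            raise ValueError(f"layer {spec.name!r}: unknown season {spec.season!r}")
        noise = spec.noise_sigma * noise_scale * _smooth_field(grid.shape, sigma_cells / 2, rng)
        climate[spec.name] = (spec.lapse * elevation + spec.intercept + noise, spec.season)

    return SyntheticLandscape(grid=grid, elevation=elevation, slope=slope,
                              climate=climate, roads=[], seed=seed)


# --------------------------------------------------------------------------- species
def suitability(vs: VirtualSpecies, env: EnvStack | SyntheticLandscape) -> np.ndarray:
    """Product-of-Gaussians habitat suitability in [0, 1] per cell."""
    if isinstance(env, SyntheticLandscape):
        env = env.env_stack()
    missing = [v for v in vs.niche if v not in env.layers]
    if missing:
        raise KeyError(f"{vs.species_id}: niche variables missing from stack: {missing}")
    log_s = np.zeros(env.grid.shape)
    for var, (opt, breadth) in vs.niche.items():
        if math.isinf(breadth):
            continue
        log_s -= (env.layers[var] - opt) ** 2 / (2.0 * breadth ** 2)
    return np.exp(log_s)


def true_distribution(vs: VirtualSpecies, env: EnvStack | SyntheticLandscape) -> np.ndarray:
    """Boolean truth raster: present iff suitability >= prevalence threshold."""
    thr = vs.prevalence_threshold
    if not 0.0 < thr < 1.0:
        raise ValueError(f"prevalence_threshold must be in (0, 1), got {thr}")
    return suitability(vs, env) >= thr


# --------------------------------------------------------------------------- zoning & roads
def generate_zones_and_roads(landscape: SyntheticLandscape,
                             zone_fractions: tuple[float, float, float] | None = None,
                             n_roads: int = 2,
                             seed: int = 0) -> tuple[ZoneMask, list[LineString]]:
    """Nested reserve zoning (core innermost, then buffer, then experimental)
    plus roads crossing the outer experimental/outside band.

    Default fractions keep the emulated reserve's core : buffer : experimental
    proportions (37.95 : 24.04 : 80.48) while scaling the reserve to 60% of
    the landscape so that an outside region and margin ring exist.  Zone areas
    land within one cell of the requested fractions.  Roads are attached to
    ``landscape.roads``.
    """
    grid = landscape.grid
    if zone_fractions is None:
        scale = 0.6 / RESERVE_TOTAL_KM2
        zone_fractions = tuple(a * scale for a in RESERVE_ZONE_KM2)  # type: ignore[assignment]
    f1, f2, f3 = zone_fractions
    if min(f1, f2, f3) < 0:
        raise ValueError(f"zone fractions must be non-negative, got {zone_fractions}")
    if f1 + f2 + f3 > 1.0 + 1e-9:
        raise ValueError(f"zone fractions sum to {f1 + f2 + f3} > 1")

    X, Y = grid.cell_centers()
    cx = (grid.xmin + grid.xmax) / 2.0
    cy = (grid.ymin + grid.ymax) / 2.0
    d = np.hypot(X - cx, Y - cy).ravel()
    order = np.argsort(d, kind="stable")
    n = grid.n_cells
    n1 = round(f1 * n)
    n2 = round((f1 + f2) * n) - n1
    n3 = round((f1 + f2 + f3) * n) - n1 - n2
    zone = np.zeros(n, dtype=int)
    zone[order[:n1]] = ZONE_CODES["core"]
    zone[order[n1:n1 + n2]] = ZONE_CODES["buffer_zone"]
    zone[order[n1 + n2:n1 + n2 + n3]] = ZONE_CODES["experimental"]
    mask = ZoneMask(zone=zone.reshape(grid.shape), grid=grid)

    rng = np.random.default_rng(seed)
    height = grid.ymax - grid.ymin
    roads: list[LineString] = []
    n_stations = 6
    xs = np.linspace(grid.xmin + grid.cell_size / 2, grid.xmax - grid.cell_size / 2,
                     n_stations)
    for k in range(n_roads):
        # roads run left-right through the outer band (south for even k,
        # north for odd), following low terrain: at each station the road
        # picks the lowest-elevation crossing within its band, like a valley
        # road skirting the reserve
        if k % 2 == 0:
            y_lo, y_hi = grid.ymin + 0.04 * height, grid.ymin + 0.40 * height
        else:
            y_lo, y_hi = grid.ymin + 0.60 * height, grid.ymin + 0.96 * height
        cand_y = np.linspace(y_lo, y_hi, 12)
        ys = []
        for x in xs:
            elevs = [landscape.elevation[grid.point_cell(x, y)] for y in cand_y]
            y = cand_y[int(np.argmin(elevs))] + rng.uniform(-0.01, 0.01) * height
            ys.append(float(np.clip(y, y_lo, y_hi)))
        roads.append(LineString(np.column_stack([xs, ys])))
    landscape.roads = roads
    return mask, roads


def distance_to_roads(roads: list[LineString], grid: Grid) -> np.ndarray:
    """Distance (m) from every cell center to the nearest road polyline."""
    if not roads:
        raise ValueError("empty road set")
    X, Y = grid.cell_centers()
    pts = shapely.points(X.ravel(), Y.ravel())
    d = np.full(grid.n_cells, np.inf)
    for road in roads:
        d = np.minimum(d, shapely.distance(pts, road))
    return d.reshape(grid.shape)


# --------------------------------------------------------------------------- sampling
def generate_camera_sites(landscape: SyntheticLandscape,
                          spacing_m: float = 600.0,
                          zone_mask: ZoneMask | None = None,
                          jitter_frac: float = 0.15,
                          seed: int = 0) -> pd.DataFrame:
    """A fixed camera-site design on a jittered regular grid.

    With ``jitter_frac`` <= 0.15 the minimum pairwise distance is at least
    0.7 * spacing (420 m at the 600 m default), honouring the emulated
    block design's >400 m inter-camera spacing.  If a zone mask is given,
    sites are restricted to the core and buffer zones, mirroring the block
    design that placed cameras only there.
    """
    grid = landscape.grid
    rng = np.random.default_rng(seed)
    xs = np.arange(grid.xmin + spacing_m / 2, grid.xmax, spacing_m)
    ys = np.arange(grid.ymin + spacing_m / 2, grid.ymax, spacing_m)
    XX, YY = np.meshgrid(xs, ys)
    x = XX.ravel() + rng.uniform(-jitter_frac, jitter_frac, XX.size) * spacing_m
    y = YY.ravel() + rng.uniform(-jitter_frac, jitter_frac, YY.size) * spacing_m
    x = np.clip(x, grid.xmin, np.nextafter(grid.xmax, -np.inf))
    y = np.clip(y, grid.ymin, np.nextafter(grid.ymax, -np.inf))
    df = pd.DataFrame({"site_id": [f"site{i:04d}" for i in range(x.size)],
                       "x": x, "y": y})
    if zone_mask is not None:
        rows, cols = grid.points_to_cells(df[["x", "y"]].to_numpy())
        keep = np.isin(zone_mask.zone[rows, cols],
                       [ZONE_CODES["core"], ZONE_CODES["buffer_zone"]])
        df = df[keep].reset_index(drop=True)
    return df


def _season_timestamps(season: str, n: int, rng: np.random.Generator) -> pd.Series:
    start, end = SEASON_WINDOWS[season]
    t0 = pd.Timestamp(start)
    total = int((pd.Timestamp(end) + pd.Timedelta(days=1) - t0).total_seconds())
    secs = rng.integers(0, total, size=n)
    return pd.Series(t0 + pd.to_timedelta(secs, unit="s"))


def sample_occurrences(vs: VirtualSpecies, landscape: SyntheticLandscape, n: int,
                       sources_mix: dict[str, float] | None = None,
                       bias_strength: float = 0.0,
                       seed: int = 0,
                       sites: pd.DataFrame | None = None,
                       invalid_fraction: float = 0.0) -> pd.DataFrame:
    """Draw ``n`` biased multi-source occurrence records from true-presence cells.

    Cells are sampled with weight proportional to
    ``exp(-bias_strength * distance_to_road)``; camera records snap to the
    fixed site design (>400 m spacing); timestamps fall in the species'
    seasonal activity window; interview/specimen records carry no timestamp.
    Deterministic for a fixed seed.
    """
    if n < 0:
        raise ValueError("n must be >= 0")
    if sources_mix is None:
        sources_mix = {"camera": 0.4, "transect": 0.4, "interview": 0.15, "specimen": 0.05}
    tot = sum(sources_mix.values())
    if abs(tot - 1.0) > 1e-9:
        raise ValueError(f"sources_mix proportions sum to {tot}, expected 1")
    grid = landscape.grid
    cols_schema = ["species_id", "source", "x", "y", "elevation", "timestamp",
                   "site_id", "group", "valid"]
    if n == 0:
        return pd.DataFrame(columns=cols_schema)

    env = landscape.env_stack()
    presence = true_distribution(vs, env)
    pres_idx = np.flatnonzero(presence.ravel())
    if pres_idx.size == 0:
        raise ValueError(f"{vs.species_id}: no true-presence cell to sample from")

    rng = np.random.default_rng(seed)
    if bias_strength > 0 and landscape.roads:
        dist = distance_to_roads(landscape.roads, grid).ravel()
        logw = -bias_strength * dist[pres_idx]
        logw -= logw.max()
        w = np.exp(logw)
    else:
        w = np.ones(pres_idx.size)
    w = w / w.sum()

    # largest-remainder apportionment of n across sources (deterministic)
    src_order = ["camera", "transect", "interview", "specimen"]
    quotas = {s: n * sources_mix.get(s, 0.0) for s in src_order}
    counts = {s: int(math.floor(q)) for s, q in quotas.items()}
    rem = n - sum(counts.values())
    for s in sorted(src_order, key=lambda s: (-(quotas[s] - counts[s]), src_order.index(s)))[:rem]:
        counts[s] += 1

    season = GROUP_SEASON[vs.group]
    cs = grid.cell_size
    frames: list[pd.DataFrame] = []

    n_cam = counts["camera"]
    if n_cam > 0:
        if sites is None:
            sites = generate_camera_sites(landscape, seed=seed)
        srows, scols = grid.points_to_cells(sites[["x", "y"]].to_numpy())
        sflat = srows * grid.ncols + scols
        eligible = np.isin(sflat, pres_idx)
        if eligible.any():
            elig = sites[eligible].reset_index(drop=True)
            eflat = sflat[eligible]
            if bias_strength > 0 and landscape.roads:
                sw = np.exp(-bias_strength * (dist[eflat] - dist[eflat].min()))
            else:
                sw = np.ones(len(elig))
            sw = sw / sw.sum()
            pick = rng.choice(len(elig), size=n_cam, replace=True, p=sw)
            cam_x = elig["x"].to_numpy()[pick]
            cam_y = elig["y"].to_numpy()[pick]
            cam_site = elig["site_id"].to_numpy()[pick]
        else:
            # no site falls in a presence cell: sample presence cells directly
            pick = rng.choice(pres_idx.size, size=n_cam, replace=True, p=w)
            cells = pres_idx[pick]
            r, c = cells // grid.ncols, cells % grid.ncols
            cam_x = grid.xmin + (c + 0.5) * cs
            cam_y = grid.ymax - (r + 0.5) * cs
            cam_site = np.array([f"adhoc{i:04d}" for i in range(n_cam)])
        r, c = grid.points_to_cells(np.column_stack([cam_x, cam_y]))
        frames.append(pd.DataFrame({
            "species_id": vs.species_id, "source": "camera",
            "x": cam_x, "y": cam_y, "elevation": landscape.elevation[r, c],
            "timestamp": _season_timestamps(season, n_cam, rng).to_numpy(),
            "site_id": cam_site, "group": vs.group}))

    for src in ("transect", "interview", "specimen"):
        k = counts[src]
        if k == 0:
            continue
        pick = rng.choice(pres_idx.size, size=k, replace=True, p=w)
        cells = pres_idx[pick]
        r, c = cells // grid.ncols, cells % grid.ncols
        # jitter kept off the cell edge so float rounding cannot flip the cell
        x = grid.xmin + (c + rng.uniform(0.001, 0.999, k)) * cs
        y = grid.ymax - (r + rng.uniform(0.001, 0.999, k)) * cs
        ts = (_season_timestamps(season, k, rng).to_numpy() if src == "transect"
              else np.full(k, np.datetime64("NaT", "ns")))
        frames.append(pd.DataFrame({
            "species_id": vs.species_id, "source": src,
            "x": x, "y": y, "elevation": landscape.elevation[r, c],
            "timestamp": ts, "site_id": None, "group": vs.group}))

    df = pd.concat(frames, ignore_index=True)
    df["valid"] = True
    if invalid_fraction > 0:
        flip = rng.uniform(0, 1, len(df)) < invalid_fraction
        df.loc[flip, "valid"] = False
    return df[cols_schema]


def default_virtual_species(landscape: SyntheticLandscape,
                            group_mix: dict[str, int] | None = None,
                            prevalence_threshold: float = 0.5,
                            seed: int = 0) -> list[VirtualSpecies]:
    """A default community of virtual species with coherent 2-variable niches.

    Each species responds to elevation plus one climate layer of its group's
    season.  The climate optimum is taken at a cell near the elevation
    optimum, so every species has a non-empty true distribution.  Breadths
    and the prevalence threshold are calibrated so per-species range sizes
    fall in the tens-of-km^2 band typical of a 142 km^2 montane reserve
    community (roughly 5-45% of the landscape).
    """
    if group_mix is None:
        group_mix = {"mammal": 2, "resident_bird": 3, "summer_bird": 2, "winter_bird": 1}
    rng = np.random.default_rng(seed)
    env = landscape.env_stack()
    elev = landscape.elevation
    lo, hi = float(elev.min()), float(elev.max())
    span = max(hi - lo, 1.0)
    by_season: dict[str, list[str]] = {"annual": [], "summer": [], "winter": []}
    for name, (_, grp) in landscape.climate.items():
        by_season[grp].append(name)

    species: list[VirtualSpecies] = []
    i = 0
    for group in ("mammal", "resident_bird", "summer_bird", "winter_bird"):
        for _ in range(group_mix.get(group, 0)):
            season = GROUP_SEASON[group]
            clim_names = by_season[season] or by_season["annual"]
            clim = clim_names[i % len(clim_names)]
            # mid-elevation optima: per-species mean elevations in the emulated
            # community span roughly the 0.25-0.70 quantile band of the relief
            e_opt = float(rng.uniform(lo + 0.25 * span, lo + 0.70 * span))
            e_breadth = float(rng.uniform(0.06, 0.14) * span)
            # climate value at the cell whose elevation is nearest the optimum
            j = int(np.abs(elev.ravel() - e_opt).argmin())
            c_vals = env.layers[clim].ravel()
            c_opt = float(c_vals[j])
            c_breadth = float(max(np.std(c_vals) * rng.uniform(0.5, 0.9), 1e-6))
            species.append(VirtualSpecies(
                species_id=f"sp{i:03d}_{group}", group=group,
                niche={"elevation": (e_opt, e_breadth), clim: (c_opt, c_breadth)},
                prevalence_threshold=prevalence_threshold))
            i += 1
    return species
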