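"""Spatial lattice, monthly environmental layers, and a synthetic ocean.

The lattice is a regular latitude/longitude grid of square arc-minute
cells, row 0 northernmost, with all public coordinates at cell centers in
decimal degrees.  Dynamic layers (current speed/direction, sea-surface
temperature, chlorophyll) are 12-month climatologies recycled across
simulation years; depth and the land mask are static.

The synthetic generator emulates the physical structure of a western-
boundary-current shelf sea: a coast-parallel jet that separates from the
coast at a configurable latitude, a weak-flow retention zone inshore of
the separation point, a shallow (< 40 m) shelf strip along the coast, a
meridional SST gradient with a seasonal cycle that drops below the 16 °C
tolerance north of a cold latitude in winter, and a coastal chlorophyll
gradient decaying offshore.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import xarray as xr

__all__ = [
    "GridSpec",
    "EnvironmentStack",
    "SuitabilityVerdict",
    "SyntheticOceanParams",
    "generate_synthetic_environment",
    "cell_suitability",
    "read_environment",
    "read_ascii_grid",
    "write_ascii_grid",
    "EnvironmentError",
]

#: metres per degree of latitude (and of longitude at the equator)
M_PER_DEGREE = 111_200.0

DYNAMIC_LAYERS = ("current_speed", "current_direction", "sst", "chlorophyll")


class EnvironmentError(ValueError):
    """Malformed, missing or inconsistent environmental input."""


@dataclass(frozen=True)
class GridSpec:
    """Regular lat/lon lattice; row 0 is the northernmost row."""

    lat_min: float
    lat_max: float
    lon_min: float
    lon_max: float
    resolution: float = 6.0  # arc-minutes

    def __post_init__(self):
        if self.lat_min >= self.lat_max:
            raise EnvironmentError("lat_min must be < lat_max")
        if self.lon_min >= self.lon_max:
            raise EnvironmentError("lon_min must be < lon_max")
        if self.resolution <= 0:
            raise EnvironmentError("resolution must be > 0")

    @property
    def n_rows(self) -> int:
        return round((self.lat_max - self.lat_min) * 60.0 / self.resolution)

    @property
    def n_cols(self) -> int:
        return round((self.lon_max - self.lon_min) * 60.0 / self.resolution)

    @property
    def cell_deg(self) -> float:
        return self.resolution / 60.0

    def cell_center(self, row: int, col: int) -> tuple[float, float]:
        """(lat, lon) of the center of cell (row, col)."""
        lat = self.lat_max - (row + 0.5) * self.cell_deg
        lon = self.lon_min + (col + 0.5) * self.cell_deg
        return lat, lon

    def cell_of(self, lat: float, lon: float) -> tuple[int, int]:
        """Cell containing the point; raises if outside the grid."""
        if not (self.lat_min <= lat <= self.lat_max and self.lon_min <= lon <= self.lon_max):
            raise EnvironmentError(f"point ({lat}, {lon}) outside grid")
        row = min(int((self.lat_max - lat) / self.cell_deg), self.n_rows - 1)
        col = min(int((lon - self.lon_min) / self.cell_deg), self.n_cols - 1)
        return row, col

    def lat_centers(self) -> np.ndarray:
        return self.lat_max - (np.arange(self.n_rows) + 0.5) * self.cell_deg

    def lon_centers(self) -> np.ndarray:
        return self.lon_min + (np.arange(self.n_cols) + 0.5) * self.cell_deg

    def cell_width_m(self, row: int) -> float:
        """East-west width of a cell at this row's latitude, metres."""
        lat = self.lat_max - (row + 0.5) * self.cell_deg
        return self.cell_deg * M_PER_DEGREE * np.cos(np.radians(lat))

    def to_dict(self) -> dict:
        return {
            "lat_min": self.lat_min, "lat_max": self.lat_max,
            "lon_min": self.lon_min, "lon_max": self.lon_max,
            "resolution": self.resolution,
        }


@dataclass
class EnvironmentStack:
    """Co-registered monthly climatology layers on one grid.

    Dynamic arrays have shape (12, n_rows, n_cols), month index 0 = January;
    ``depth`` (positive metres down) and boolean ``land_mask`` are
    (n_rows, n_cols).  Land cells never pass suitability.
    """

    grid: GridSpec
    current_speed: np.ndarray      # m s⁻¹, >= 0
    current_direction: np.ndarray  # degrees clockwise from north, [0, 360)
    sst: np.ndarray                # °C
    chlorophyll: np.ndarray        # µg L⁻¹
    depth: np.ndarray              # m, positive down; land where <= 0
    land_mask: np.ndarray          # True on land

    def __post_init__(self):
        shape = (self.grid.n_rows, self.grid.n_cols)
        for name in DYNAMIC_LAYERS:
            arr = getattr(self, name)
            if arr.shape != (12, *shape):
                raise EnvironmentError(f"{name}: expected shape {(12, *shape)}, got {arr.shape}")
        for name in ("depth", "land_mask"):
            arr = getattr(self, name)
            if arr.shape != shape:
                raise EnvironmentError(f"{name}: expected shape {shape}, got {arr.shape}")
        if np.any(self.current_speed < 0):
            raise EnvironmentError("current_speed: negative values")
        self.current_direction = np.mod(self.current_direction, 360.0)
        # cells above sea level are land by convention
        self.land_mask = self.land_mask | (self.depth <= 0)

    @property
    def marine_mask(self) -> np.ndarray:
        return ~self.land_mask

    def is_marine(self, row: int, col: int) -> bool:
        return bool(self.marine_mask[row, col])

    def month_index(self, calendar_month: int) -> int:
        if not 1 <= calendar_month <= 12:
            raise EnvironmentError("calendar month must lie in 1..12")
        return calendar_month - 1

    # ------------------------------------------------------------------ I/O

    def to_dataset(self) -> xr.Dataset:
        coords = {
            "month": np.arange(1, 13),
            "lat": self.grid.lat_centers(),
            "lon": self.grid.lon_centers(),
        }
        data = {
            name: (("month", "lat", "lon"), getattr(self, name))
            for name in DYNAMIC_LAYERS
        }
        data["depth"] = (("lat", "lon"), self.depth)
        data["land_mask"] = (("lat", "lon"), self.land_mask.astype(np.int8))
        ds = xr.Dataset(data, coords=coords)
        ds.attrs["grid"] = json.dumps(self.grid.to_dict())
        return ds

    def to_netcdf(self, path: str | Path) -> None:
        """Write the whole stack as a single NetCDF3 file."""
        self.to_dataset().to_netcdf(str(path), engine="scipy")

    @classmethod
    def from_netcdf(cls, path: str | Path) -> "EnvironmentStack":
        with xr.open_dataset(str(path), engine="scipy") as ds:
            grid = GridSpec(**json.loads(ds.attrs["grid"]))
            kwargs = {name: ds[name].values.astype(float) for name in DYNAMIC_LAYERS}
            depth = ds["depth"].values.astype(float)
            land = ds["land_mask"].values.astype(bool)
        return cls(grid=grid, depth=depth, land_mask=land, **kwargs)

    def save_dir(self, path: str | Path) -> None:
        """Write the stack as a directory of ESRI ASCII grids + metadata."""
        path = Path(path)
        path.mkdir(parents=True, exist_ok=True)
        (path / "grid.json").write_text(json.dumps(self.grid.to_dict(), indent=1))
        for name in DYNAMIC_LAYERS:
            arr = getattr(self, name)
            for m in range(12):
                write_ascii_grid(path / f"{name}_{m + 1:02d}.asc", arr[m], self.grid)
        write_ascii_grid(path / "depth.asc", self.depth, self.grid)
        write_ascii_grid(path / "land_mask.asc", self.land_mask.astype(float), self.grid)

    @classmethod
    def load_dir(cls, path: str | Path) -> "EnvironmentStack":
        path = Path(path)
        grid = GridSpec(**json.loads((path / "grid.json").read_text()))
        paths = {
            name: [path / f"{name}_{m + 1:02d}.asc" for m in range(12)]
            for name in DYNAMIC_LAYERS
        }
        paths["depth"] = path / "depth.asc"
        paths["land_mask"] = path / "land_mask.asc"
        return read_environment(paths, grid)


@dataclass(frozen=True)
class SuitabilityVerdict:
    """Per-parameter habitability of one cell in one month."""

    sst_ok: bool
    cc_ok: bool
    depth_ok: bool
    sst_score: float
    cc_score: float
    depth_score: float

    @property
    def all_ok(self) -> bool:
        return self.sst_ok and self.cc_ok and self.depth_ok


# --------------------------------------------------------------------------
# ESRI ASCII Grid I/O (plain-text single-layer rasters, row 0 = north)
# --------------------------------------------------------------------------

def write_ascii_grid(path: str | Path, array: np.ndarray, grid: GridSpec,
                     nodata: float = -9999.0) -> None:
    array = np.asarray(array, dtype=float)
    if array.shape != (grid.n_rows, grid.n_cols):
        raise EnvironmentError(
            f"array shape {array.shape} does not match grid "
            f"{(grid.n_rows, grid.n_cols)}")
    out = np.where(np.isnan(array), nodata, array)
    header = (
        f"ncols {grid.n_cols}\n"
        f"nrows {grid.n_rows}\n"
        f"xllcorner {grid.lon_min:.10g}\n"
        f"yllcorner {grid.lat_min:.10g}\n"
        f"cellsize {grid.cell_deg:.10g}\n"
        f"NODATA_value {nodata:.10g}\n"
    )
    with open(path, "w") as fh:
        fh.write(header)
        np.savetxt(fh, out, fmt="%.6g")


def read_ascii_grid(path: str | Path) -> tuple[np.ndarray, GridSpec]:
    """Read one ESRI ASCII grid; NODATA cells become NaN."""
    path = Path(path)
    if not path.exists():
        raise EnvironmentError(f"unreadable file: {path}")
    header: dict[str, float] = {}
    with open(path) as fh:
        lines = fh.readlines()
    i = 0
    while i < len(lines) and lines[i].split() and not _is_number(lines[i].split()[0]):
        key, value = lines[i].split()[:2]
        header[key.lower()] = float(value)
        i += 1
    try:
        ncols = int(header["ncols"])
        nrows = int(header["nrows"])
        cellsize = header["cellsize"]
        xll = header.get("xllcorner", header.get("xllcenter", 0.0) - cellsize / 2)
        yll = header.get("yllcorner", header.get("yllcenter", 0.0) - cellsize / 2)
    except KeyError as exc:
        raise EnvironmentError(f"{path}: missing header field {exc}") from exc
    data = np.loadtxt(lines[i:], dtype=float)
    data = np.atleast_2d(data)
    if data.shape != (nrows, ncols):
        raise EnvironmentError(f"{path}: data shape {data.shape} != header {(nrows, ncols)}")
    nodata = header.get("nodata_value")
    if nodata is not None:
        data = np.where(data == nodata, np.nan, data)
    grid = GridSpec(lat_min=yll, lat_max=yll + nrows * cellsize,
                    lon_min=xll, lon_max=xll + ncols * cellsize,
                    resolution=cellsize * 60.0)
    return data, grid


def _is_number(tok: str) -> bool:
    try:
        float(tok)
        return True
    except ValueError:
        return False


def read_environment(raster_paths: dict, grid: GridSpec) -> EnvironmentStack:
    """Assemble a stack from per-layer ASCII-grid files.

    ``raster_paths`` maps each dynamic layer name to a list of 12 monthly
    files (January first) and ``depth``/``land_mask`` to single files.
    Current may alternatively be supplied as ``current_u``/``current_v``
    (eastward/northward m s⁻¹), which are converted to speed + direction.
    Cells that are NODATA in any layer are forced to land.
    """
    paths = dict(raster_paths)
    has_uv = "current_u" in paths or "current_v" in paths
    dynamic = list(DYNAMIC_LAYERS)
    if has_uv:
        if "current_u" not in paths or "current_v" not in paths:
            raise EnvironmentError("current_u and current_v must both be given")
        dynamic = ["current_u", "current_v", "sst", "chlorophyll"]

    layers: dict[str, np.ndarray] = {}
    shape = (grid.n_rows, grid.n_cols)
    for name in dynamic:
        months = paths.get(name)
        if months is None or len(months) != 12:
            n = 0 if months is None else len(months)
            raise EnvironmentError(f"{name}: expected 12 monthly rasters, got {n}")
        stack = np.empty((12, *shape))
        for m, p in enumerate(months):
            if p is None or not Path(p).exists():
                raise EnvironmentError(f"{name}: missing month {m + 1}")
            arr, agrid = read_ascii_grid(p)
            if arr.shape != shape:
                raise EnvironmentError(
                    f"{name} month {m + 1}: shape {arr.shape} does not match grid {shape}")
            stack[m] = arr
        layers[name] = stack

    depth, _ = read_ascii_grid(paths["depth"])
    if depth.shape != shape:
        raise EnvironmentError(f"depth: shape {depth.shape} does not match grid {shape}")
    if "land_mask" in paths and paths["land_mask"] is not None:
        mask_arr, _ = read_ascii_grid(paths["land_mask"])
        land = np.nan_to_num(mask_arr, nan=1.0) > 0.5
    else:
        land = np.zeros(shape, dtype=bool)

    if has_uv:
        u, v = layers.pop("current_u"), layers.pop("current_v")
        layers["current_speed"] = np.hypot(u, v)
        layers["current_direction"] = np.mod(np.degrees(np.arctan2(u, v)), 360.0)

    # NODATA anywhere -> land; NaN depth and negative depth also land
    nan_any = np.zeros(shape, dtype=bool)
    for arr in layers.values():
        nan_any |= np.isnan(arr).any(axis=0)
    nan_any |= np.isnan(depth)
    land = land | nan_any
    depth = np.nan_to_num(depth, nan=0.0)
    for name, arr in layers.items():
        layers[name] = np.nan_to_num(arr, nan=0.0)

    return EnvironmentStack(grid=grid, depth=depth, land_mask=land, **layers)


# --------------------------------------------------------------------------
# Synthetic ocean
# --------------------------------------------------------------------------

@dataclass
class SyntheticOceanParams:
    """Geometry and forcing of the synthetic shelf sea.

    Defaults give a 6°×6° domain (60×60 cells at 6 arc-minutes) shaped
    like a subtropical western-boundary shelf: land to the west, a
    northward jet hugging the coast that separates offshore at
    ``separation_lat``, and winter water colder than 16 °C north of
    ``cold_lat``.
    """

    coast_lon: float = -80.2          # mean coastline longitude
    coast_meander_amp: float = 0.15   # degrees
    coast_meander_wavelength: float = 3.0  # degrees latitude
    jet_offset: float = 0.5           # jet axis, degrees east of the coast
    jet_width: float = 0.4            # gaussian e-folding half-width, degrees
    peak_speed: float = 1.8           # m s⁻¹, exact grid/12-month maximum
    separation_lat: float = 27.5      # jet leaves the coast here
    separation_slope: float = 1.5     # °lon eastward per °lat past separation
    background_speed: float = 0.10    # offshore drift, m s⁻¹
    retention_speed: float = 0.18     # gyre offshore (delivery) branch, m s⁻¹
    counter_current_speed: float = 0.06  # gyre coastal (back-fill) branch, m s⁻¹
    seasonal_speed_amp: float = 0.10  # relative monthly modulation of the jet
    shelf_width: float = 0.6          # degrees; depth <= 40 m inside shelf bands
    shelf_depth_min: float = 3.0      # m at the waterline
    shelf_bands: tuple = ((24.3, 25.1), (25.8, 26.6), (27.6, 28.4), (28.9, 29.7))
    #: latitude bands holding shallow shelf habitat; between them the coast
    #: drops steeply below the 40 m habitable limit
    offshore_depth: float = 4000.0    # m cap
    gap_depth: float = 60.0           # nearshore depth between shelf bands, m
    sst_south: float = 29.5           # annual-mean SST at the southern edge, °C
    sst_gradient: float = 2.9         # °C per degree latitude, cooling north
    sst_seasonal_amp: float = 3.0     # °C, peak in August, trough in February
    sst_noise: float = 0.10           # °C, uniform ±
    cold_lat: float = 29.0            # north of this, winter SST < 16 °C
    chl_coast: float = 1.2            # µg L⁻¹ coastal enhancement
    chl_scale: float = 0.5            # offshore e-folding, degrees
    chl_background: float = 0.05      # µg L⁻¹ open-ocean floor
    direction_noise: float = 10.0     # degrees, uniform ±


def generate_synthetic_environment(
    grid: GridSpec | None = None,
    params: SyntheticOceanParams | None = None,
    seed: int = 0,
) -> EnvironmentStack:
    """Deterministic synthetic climatology on ``grid`` for a given seed."""
    if grid is None:
        grid = GridSpec(lat_min=24.0, lat_max=30.0, lon_min=-81.0, lon_max=-75.0)
    p = params or SyntheticOceanParams()
    rng = np.random.default_rng(seed)

    lat = grid.lat_centers()[:, None]           # (rows, 1)
    lon = grid.lon_centers()[None, :]           # (1, cols)
    nrows, ncols = grid.n_rows, grid.n_cols

    coast = p.coast_lon + p.coast_meander_amp * np.sin(
        2 * np.pi * (lat - grid.lat_min) / p.coast_meander_wavelength)
    if np.all(coast < grid.lon_min) or np.all(coast > grid.lon_max):
        raise EnvironmentError("jet axis outside grid: coastline does not intersect domain")
    land = np.broadcast_to(lon < coast, (nrows, ncols)).copy()
    dist_off = np.clip(lon - coast, 0.0, None)  # degrees east of the coastline

    # bathymetry: linear shelf to 40 m inside the habitat bands, then a
    # steep slope; between bands the nearshore floor sits below 40 m, so
    # habitable patches are discrete stepping stones along the coast
    shelf_profile = np.where(
        dist_off <= p.shelf_width,
        p.shelf_depth_min + (40.0 - p.shelf_depth_min) * dist_off / p.shelf_width,
        40.0 + (p.offshore_depth - 40.0)
        * np.clip((dist_off - p.shelf_width) / 1.5, 0.0, 1.0),
    )
    in_band = np.zeros((nrows, 1), dtype=bool)
    for lo, hi in p.shelf_bands:
        in_band |= (lat >= lo) & (lat <= hi)
    gap_profile = np.maximum(shelf_profile, p.gap_depth)
    depth = np.where(np.broadcast_to(in_band, (nrows, ncols)),
                     shelf_profile, gap_profile)
    depth = np.where(land, 0.0, depth)

    # jet axis: coast-parallel below the separation latitude, then veering
    # offshore to the north-east
    axis = coast + p.jet_offset + np.where(
        lat > p.separation_lat, (lat - p.separation_lat) * p.separation_slope, 0.0)
    axis_dist = np.abs(lon - axis)
    jet_profile = np.exp(-((axis_dist / p.jet_width) ** 2))
    jet_dir = np.where(
        lat > p.separation_lat,
        np.degrees(np.arctan2(p.separation_slope, 1.0)),  # toward NE
        0.0,                                              # due north
    )
    # retention zone: inshore of the departed jet axis, north of separation.
    # Flow there is a weak cyclonic recirculation (an inshore counter-current):
    # northward on the offshore flank, westward along the top, southward along
    # the coast — larvae that leave the jet near the separation point are
    # carried to the far end of the zone first and back-fill southward.
    retention = np.broadcast_to(
        (lat > p.separation_lat) & (lon < axis - p.jet_width), (nrows, ncols))
    gyre_lat_c = 0.5 * (p.separation_lat + grid.lat_max)
    gyre_lon_c = float(np.mean(coast)) + 0.5 * p.jet_offset
    dy = np.broadcast_to(lat - gyre_lat_c, (nrows, ncols))
    dx = np.broadcast_to(lon - gyre_lon_c, (nrows, ncols))
    gyre_dir = np.degrees(np.arctan2(-dy, dx)) % 360.0  # counter-clockwise tangent
    # offshore (delivery) branch runs faster than the coastal back-fill branch
    gyre_speed = np.where(dx > 0, p.retention_speed, p.counter_current_speed)

    base_speed = p.background_speed + (p.peak_speed - p.background_speed) * jet_profile
    base_speed = np.where(retention, gyre_speed, base_speed)

    months = np.arange(1, 13)
    seasonal_speed = 1.0 + p.seasonal_speed_amp * np.cos(2 * np.pi * (months - 8) / 12.0)
    speed = seasonal_speed[:, None, None] * base_speed[None, :, :]
    speed = np.where(land[None, :, :], 0.0, speed)
    speed *= p.peak_speed / speed.max()  # exact construction maximum

    direction = np.where(retention, gyre_dir, np.broadcast_to(jet_dir, (nrows, ncols)))
    meander = rng.uniform(-p.direction_noise, p.direction_noise, size=(12, nrows, ncols))
    # retention flow meanders strongly; elsewhere small directional noise
    meander = np.where(retention[None, :, :], meander * 4.0, meander)
    direction = np.mod(direction[None, :, :] + meander, 360.0)

    seasonal_sst = p.sst_seasonal_amp * np.cos(2 * np.pi * (months - 8) / 12.0)
    sst = (p.sst_south - p.sst_gradient * (lat - grid.lat_min))[None, :, :] \
        + seasonal_sst[:, None, None] \
        + rng.uniform(-p.sst_noise, p.sst_noise, size=(12, nrows, ncols))

    chl_seasonal = 1.0 + 0.2 * np.cos(2 * np.pi * (months - 3) / 12.0)  # spring bloom
    chl = p.chl_background + p.chl_coast * chl_seasonal[:, None, None] \
        * np.exp(-dist_off / p.chl_scale)[None, :, :]
    chl = chl * np.exp(rng.normal(0.0, 0.05, size=(12, nrows, ncols)))
    chl = np.clip(chl, 0.01, None)

    return EnvironmentStack(
        grid=grid,
        current_speed=speed,
        current_direction=direction,
        sst=sst,
        chlorophyll=chl,
        depth=depth,
        land_mask=land,
    )


# --------------------------------------------------------------------------
# Suitability
# --------------------------------------------------------------------------

def _range_score(value: float, lo: float, hi: float, graded: bool) -> float:
    if not lo <= value <= hi:
        return 0.0
    if not graded:
        return 1.0
    mid = 0.5 * (lo + hi)
    half = 0.5 * (hi - lo)
    if half == 0:
        return 1.0
    return 1.0 - abs(value - mid) / half


def cell_suitability(stack: EnvironmentStack, cell: tuple[int, int],
                     calendar_month: int, config) -> SuitabilityVerdict:
    """Check one marine cell's SST, chlorophyll and depth against the
    configured tolerances for a calendar month.

    Scores are binary in/out of range by default (``config.graded_suitability``
    switches to a triangular profile peaking mid-range).  Raises on land.
    """
    row, col = cell
    if stack.land_mask[row, col]:
        raise EnvironmentError(f"cell {cell} is land")
    m = stack.month_index(calendar_month)
    g = config.graded_suitability
    s_sst = _range_score(stack.sst[m, row, col], *config.sst_range, g)
    s_cc = _range_score(stack.chlorophyll[m, row, col], *config.cc_range, g)
    s_od = _range_score(stack.depth[row, col], *config.depth_range, g)
    return SuitabilityVerdict(
        sst_ok=s_sst > 0, cc_ok=s_cc > 0, depth_ok=s_od > 0,
        sst_score=s_sst, cc_score=s_cc, depth_score=s_od,
    )


def suitability_rasters(stack: EnvironmentStack, config) -> np.ndarray:
    """Binary suitability score per (month, row, col, parameter).

    Returns an array of shape (12, rows, cols, 3) with the SST, chlorophyll
    and depth scores; land cells are all-zero.  Used by the engine to build
    per-month scoring fields in one vectorized pass.
    """
    g = config.graded_suitability
    out = np.zeros((12,) + stack.depth.shape + (3,))

    def score(arr, lo, hi):
        inside = (arr >= lo) & (arr <= hi)
        if not g:
            return inside.astype(float)
        mid, half = 0.5 * (lo + hi), 0.5 * (hi - lo)
        graded = 1.0 - np.abs(arr - mid) / half if half else np.ones_like(arr)
        return np.where(inside, graded, 0.0)

    out[..., 0] = score(stack.sst, *config.sst_range)
    out[..., 1] = score(stack.chlorophyll, *config.cc_range)
    out[..., 2] = score(stack.depth, *config.depth_range)[None, :, :]
    out *= stack.marine_mask[None, :, :, None]
    return out
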