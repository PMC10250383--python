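"""Synthetic coastal ocean scenarios: flow fields, bathymetry and habitat.

This module stands in for a regional hydrodynamic hindcast.  It builds
analytic velocity fields (uniform flow, solid-body rotation) that serve as
exact oracles for the particle-tracking kernel, and a semi-realistic
"double-gyre coastal" scenario whose statistical structure mirrors the
north-western New Zealand shelf as the dispersal analysis assumes it:

* a southward offshore jet (West Auckland Current analogue),
* a northward inshore band in the southern half of the domain,
* a convergence zone where the two alongshore regimes meet and export
  water offshore,
* one or more Gaussian retention eddies near the coast, and
* a rocky-shore habitat split into two blocks of 5 x 5 km sites by a long
  sandy gap with no mussel habitat (Ripiro Beach analogue).

All coordinates live in a local projected plane: x east, y north, both in
meters; z in meters positive down; time in seconds from scenario start.
Horizontal velocities of the coastal scenario are derived from a discrete
streamfunction by centred differences, so the centred-difference divergence
of the stored (u, v) arrays vanishes identically (to rounding) at every
interior cell.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field, asdict
from typing import Sequence

import numpy as np
import xarray as xr
import yaml
from scipy.special import erf
from shapely.geometry import Polygon, mapping, shape


class FlowFormatError(ValueError):
    """A flow-field file does not declare the expected variables/dimensions."""


# ---------------------------------------------------------------------------
# Grids and fields
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class GridSpec:
    """Regular Arakawa-A grid: cell centers at origin + (i + 0.5) * dx."""

    x_origin: float
    y_origin: float
    nx: int
    ny: int
    dx: float = 5000.0
    dy: float = 5000.0
    z_levels: tuple[float, ...] = (0.0,)
    t0: float = 0.0
    dt_field: float = 3600.0
    nt: int = 1

    def __post_init__(self) -> None:
        if self.nx < 1 or self.ny < 1 or self.nt < 1:
            raise ValueError("nx, ny, nt must be >= 1")
        if self.dx <= 0 or self.dy <= 0:
            raise ValueError("dx, dy must be positive")
        z = np.asarray(self.z_levels, dtype=float)
        if z.size < 1 or z[0] != 0.0 or np.any(np.diff(z) <= 0):
            raise ValueError("z_levels must be strictly increasing from 0")

    @property
    def nz(self) -> int:
        return len(self.z_levels)

    @property
    def x_centers(self) -> np.ndarray:
        return self.x_origin + (np.arange(self.nx) + 0.5) * self.dx

    @property
    def y_centers(self) -> np.ndarray:
        return self.y_origin + (np.arange(self.ny) + 0.5) * self.dy

    @property
    def times(self) -> np.ndarray:
        return self.t0 + np.arange(self.nt) * self.dt_field

    @property
    def extent(self) -> tuple[float, float, float, float]:
        """(x_min, x_max, y_min, y_max) of the covered area."""
        return (
            self.x_origin,
            self.x_origin + self.nx * self.dx,
            self.y_origin,
            self.y_origin + self.ny * self.dy,
        )


@dataclass
class FlowField:
    """Gridded velocity field with land/sea mask and bathymetry.

    u, v, w have shape (nt, nz, ny, nx) in m/s; ``mask`` is True on sea
    cells; ``bathymetry`` is seafloor depth in meters (0 on land).  A field
    with ``nt == 1`` is steady (valid at every time).
    """

    grid: GridSpec
    u: np.ndarray
    v: np.ndarray
    w: np.ndarray
    mask: np.ndarray
    bathymetry: np.ndarray

    def __post_init__(self) -> None:
        shp = (self.grid.nt, self.grid.nz, self.grid.ny, self.grid.nx)
        for name in ("u", "v", "w"):
            arr = np.asarray(getattr(self, name), dtype=float)
            if arr.shape != shp:
                raise ValueError(f"{name} has shape {arr.shape}, expected {shp}")
            setattr(self, name, arr)
        self.mask = np.asarray(self.mask, dtype=bool)
        self.bathymetry = np.asarray(self.bathymetry, dtype=float)
        if self.mask.shape != (self.grid.ny, self.grid.nx):
            raise ValueError("mask shape mismatch")
        if self.bathymetry.shape != (self.grid.ny, self.grid.nx):
            raise ValueError("bathymetry shape mismatch")
        sea = self.mask
        if not np.all(np.isfinite(self.u[:, :, sea])):
            raise ValueError("non-finite velocity on sea cells")
        if np.any((self.bathymetry <= 0) & sea) or np.any((self.bathymetry > 0) & ~sea):
            raise ValueError("mask inconsistent with bathymetry (land <=> depth 0)")

    @property
    def steady(self) -> bool:
        return self.grid.nt == 1


@dataclass
class HabitatSite:
    """One 5 x 5 km settlement/spawning site belonging to a population."""

    site_id: int
    population_id: int
    polygon: Polygon
    area_km2: float

    def __post_init__(self) -> None:
        if not self.polygon.is_valid:
            raise ValueError(f"site {self.site_id}: invalid polygon")
        if self.area_km2 <= 0:
            raise ValueError(f"site {self.site_id}: non-positive area")


def build_grid(
    extent_m: tuple[float, float],
    resolution_m: tuple[float, float],
    z_levels: Sequence[float] = (0.0,),
    time_axis: tuple[float, float, int] = (0.0, 3600.0, 1),
    origin: tuple[float, float] = (0.0, 0.0),
) -> GridSpec:
    """Build a regular grid covering ``extent_m`` at ``resolution_m``.

    The cell count per axis is ceil(extent / resolution), so the grid always
    covers the requested extent.
    """
    ex, ey = extent_m
    rx, ry = resolution_m
    if rx <= 0 or ry <= 0:
        raise ValueError("resolution must be positive")
    if ex <= 0 or ey <= 0:
        raise ValueError("extent must be positive")
    nx = int(np.ceil(ex / rx - 1e-9))
    ny = int(np.ceil(ey / ry - 1e-9))
    t0, dtf, nt = time_axis
    return GridSpec(
        x_origin=origin[0], y_origin=origin[1],
        nx=nx, ny=ny, dx=rx, dy=ry,
        z_levels=tuple(float(z) for z in z_levels),
        t0=float(t0), dt_field=float(dtf), nt=int(nt),
    )


def _full_field(grid: GridSpec, u2d, v2d, w2d, mask, bathy) -> FlowField:
    shp = (grid.nt, grid.nz, grid.ny, grid.nx)
    u = np.broadcast_to(u2d, shp).copy()
    v = np.broadcast_to(v2d, shp).copy()
    w = np.broadcast_to(w2d, shp).copy()
    return FlowField(grid=grid, u=u, v=v, w=w, mask=mask, bathymetry=bathy)


def uniform_flow(grid: GridSpec, u0: float, v0: float, w0: float = 0.0,
                 depth: float = 100.0) -> FlowField:
    """Spatially and temporally constant velocity; all-sea mask."""
    mask = np.ones((grid.ny, grid.nx), dtype=bool)
    bathy = np.full((grid.ny, grid.nx), float(depth))
    return _full_field(grid, u0, v0, w0, mask, bathy)


def solid_body_rotation(grid: GridSpec, omega: float,
                        center: tuple[float, float],
                        depth: float = 100.0) -> FlowField:
    """Rigid rotation about ``center``: (u, v) = (-w*(y-yc), w*(x-xc)), w = 0."""
    xc, yc = center
    x0, x1, y0, y1 = grid.extent
    if not (x0 <= xc <= x1 and y0 <= yc <= y1):
        raise ValueError("rotation center must lie inside the grid")
    X, Y = np.meshgrid(grid.x_centers, grid.y_centers)
    u = -omega * (Y - yc)
    v = omega * (X - xc)
    mask = np.ones((grid.ny, grid.nx), dtype=bool)
    bathy = np.full((grid.ny, grid.nx), float(depth))
    return _full_field(grid, u, v, 0.0, mask, bathy)


# ---------------------------------------------------------------------------
# Habitat layout
# ---------------------------------------------------------------------------

def generate_habitat(
    coast_line: Sequence[tuple[float, float]],
    n_populations: int,
    sites_per_population: int | Sequence[int],
    site_size_m: float = 5000.0,
    start_site_id: int = 0,
    start_population_id: int = 0,
) -> list[HabitatSite]:
    """Lay contiguous square sites along a coast polyline, grouped contiguously
    alongshore into populations.

    Squares sit on the left-hand side of the polyline direction of travel
    (traverse the coast with the ocean on the left).  ``sites_per_population``
    may be a single count or one count per population.
    """
    pts = np.asarray(coast_line, dtype=float)
    if pts.ndim != 2 or pts.shape[0] < 2:
        raise ValueError("coast_line needs at least two vertices")
    if np.isscalar(sites_per_population):
        counts = [int(sites_per_population)] * n_populations
    else:
        counts = [int(c) for c in sites_per_population]
        if len(counts) != n_populations:
            raise ValueError("sites_per_population length != n_populations")
    n_sites = sum(counts)

    seg = np.diff(pts, axis=0)
    seg_len = np.hypot(seg[:, 0], seg[:, 1])
    cum = np.concatenate([[0.0], np.cumsum(seg_len)])
    if n_sites * site_size_m > cum[-1] + 1e-6:
        raise ValueError(
            f"{n_sites} sites of {site_size_m} m exceed coast length {cum[-1]:.0f} m"
        )

    def point_at(d: float) -> tuple[np.ndarray, np.ndarray]:
        i = min(np.searchsorted(cum, d, side="right") - 1, len(seg) - 1)
        frac = (d - cum[i]) / seg_len[i]
        p = pts[i] + frac * seg[i]
        tang = seg[i] / seg_len[i]
        return p, tang

    sites: list[HabitatSite] = []
    sid = start_site_id
    pop = start_population_id
    d = 0.0
    for count in counts:
        for _ in range(count):
            p0, tang = point_at(d)
            p1 = p0 + tang * site_size_m
            normal = np.array([-tang[1], tang[0]])
            ring = [tuple(p0), tuple(p1),
                    tuple(p1 + normal * site_size_m),
                    tuple(p0 + normal * site_size_m)]
            poly = Polygon(ring)
            sites.append(HabitatSite(
                site_id=sid, population_id=pop, polygon=poly,
                area_km2=poly.area / 1e6,
            ))
            sid += 1
            d += site_size_m
        pop += 1
    return sites


def population_areas(sites: Sequence[HabitatSite]) -> dict[int, float]:
    """Total area in km^2 per population."""
    areas: dict[int, float] = {}
    for s in sites:
        areas[s.population_id] = areas.get(s.population_id, 0.0) + s.area_km2
    return areas


def site_to_population(sites: Sequence[HabitatSite]) -> dict[int, int]:
    return {s.site_id: s.population_id for s in sites}


# ---------------------------------------------------------------------------
# Coastal scenario
# ---------------------------------------------------------------------------

@dataclass
class ScenarioConfig:
    """Parameters of a synthetic scenario.  Every stochastic downstream choice
    (releases, turbulence) is fixed by ``seed``; the field itself is
    deterministic in the parameters.

    Lengths are km for readability; speeds m/s; the eddy amplitude is a
    streamfunction amplitude in m^2/s (peak swirl speed ~ A / (radius * e^0.5)).
    """

    name: str = "double_gyre_coastal"
    extent_km: tuple[float, float] = (100.0, 600.0)   # (cross-shore x, alongshore y)
    resolution_m: float = 5000.0
    z_levels: tuple[float, ...] = (0.0, 10.0, 30.0, 60.0)
    coast_x_km: float = 80.0            # land at x > coast_x
    v_inshore: float = 0.05             # alongshore inshore band speed
    inshore_width_km: float = 10.0
    v_offshore: float = 0.10            # southward offshore jet peak speed
    jet_offset_km: float = 40.0         # jet distance offshore
    jet_width_km: float = 15.0
    convergence_y_km: float | None = None   # default: centre of habitat gap
    convergence_width_km: float = 15.0
    # eddies: (x_km, y_km, amplitude_m2_s, radius_km); one offshore of the
    # bay near the beach, plus one retention eddy beside each habitat block
    # driving local retention and bidirectional alongshore exchange
    eddies: tuple[tuple[float, float, float, float], ...] = (
        (62.0, 400.0, 1200.0, 8.0),
        (70.0, 300.0, 800.0, 8.0),
        (70.0, 100.0, 800.0, 8.0),
    )
    # optional coastal meander: alternating cells along the coast (off by
    # default; the profile vanishes at the shoreline when enabled)
    meander_amplitude_m2_s: float = 0.0
    meander_wavelength_km: float = 70.0
    meander_width_km: float = 10.0
    depth_coast_m: float = 5.0
    depth_slope: float = 0.002
    depth_max_m: float = 150.0
    bottom_speed_factor: float = 0.7    # linear attenuation of u, v at depth
    n_populations: int = 18
    sites_per_population: tuple[int, ...] = (3, 3, 3, 3, 3, 3, 3, 3,    # southern block
                                             3, 3, 3, 2, 2, 3, 3, 2, 2, 2)  # northern block
    habitat_y0_km: float = 40.0
    gap_after_population: int = 8       # habitat gap inserted after this many populations
    gap_km: float = 107.0
    # the northern block is itself split by a sandy, site-free stretch that
    # holds the spat-collection beach; the last few populations sit north of it
    populations_north_of_beach: int = 2
    north_gap_km: float = 118.0
    beach_y_km: tuple[float, float] = (372.0, 422.0)  # spat-collection beach span
    beach_width_km: float = 5.0
    site_size_m: float = 5000.0
    seed: int = 0

    @classmethod
    def from_yaml(cls, path: str) -> "ScenarioConfig":
        with open(path) as fh:
            raw = yaml.safe_load(fh) or {}
        known = {f for f in cls.__dataclass_fields__}
        unknown = set(raw) - known
        if unknown:
            raise ValueError(f"unknown scenario keys: {sorted(unknown)}")
        for key in ("extent_km", "z_levels", "sites_per_population", "beach_y_km"):
            if key in raw and isinstance(raw[key], list):
                raw[key] = tuple(raw[key])
        if "eddies" in raw and isinstance(raw["eddies"], list):
            raw["eddies"] = tuple(tuple(e) for e in raw["eddies"])
        return cls(**raw)

    def to_yaml(self, path: str) -> None:
        with open(path, "w") as fh:
            yaml.safe_dump(_listify(asdict(self)), fh, sort_keys=False)

    # Derived geometry -----------------------------------------------------
    @property
    def gap_span_km(self) -> tuple[float, float]:
        """Alongshore (south, north) extent of the habitat gap in km."""
        n_south = sum(self.sites_per_population[: self.gap_after_population])
        y0 = self.habitat_y0_km + n_south * self.site_size_m / 1000.0
        return (y0, y0 + self.gap_km)

    @property
    def beach_polygon(self) -> Polygon:
        y0, y1 = (v * 1000.0 for v in self.beach_y_km)
        x1 = self.coast_x_km * 1000.0
        x0 = x1 - self.beach_width_km * 1000.0
        return Polygon([(x0, y0), (x1, y0), (x1, y1), (x0, y1)])


def _listify(obj):
    if isinstance(obj, dict):
        return {k: _listify(v) for k, v in obj.items()}
    if isinstance(obj, tuple):
        return [_listify(v) for v in obj]
    return obj


def coastal_scenario(config: ScenarioConfig) -> tuple[FlowField, list[HabitatSite]]:
    """Build the two-block coastal flow field and its habitat sites.

    The horizontal velocity is obtained by centred differences of a discrete
    streamfunction sampled on an extended cell-centre grid, which makes the
    centred-difference divergence vanish identically.  The streamfunction sums
    three analytic parts: the opposed alongshore jets merged with a tanh
    profile across the convergence latitude, a southward offshore Gaussian
    jet, and Gaussian retention eddies.
    """
    c = config
    ex_km, ey_km = c.extent_km
    if c.gap_km * 1000.0 >= ey_km * 1000.0:
        raise ValueError("habitat gap wider than domain")
    grid = build_grid(
        (ex_km * 1000.0, ey_km * 1000.0),
        (c.resolution_m, c.resolution_m),
        z_levels=c.z_levels,
    )

    y_conv = (c.convergence_y_km if c.convergence_y_km is not None
              else 0.5 * (c.gap_span_km[0] + c.gap_span_km[1])) * 1000.0
    x_coast = c.coast_x_km * 1000.0
    L_in = c.inshore_width_km * 1000.0
    L_jet = c.jet_width_km * 1000.0
    s_jet = c.jet_offset_km * 1000.0
    L_conv = c.convergence_width_km * 1000.0

    # Extended cell-centre coordinates (one ghost ring each side).
    xe = grid.x_origin + (np.arange(-1, grid.nx + 1) + 0.5) * grid.dx
    ye = grid.y_origin + (np.arange(-1, grid.ny + 1) + 0.5) * grid.dy
    X, Y = np.meshgrid(xe, ye)
    s = np.clip(x_coast - X, 0.0, None)          # distance offshore, 0 on land

    # Alongshore system: v = -tanh((y - yc)/Lc) * V_in exp(-s/L_in),
    # streamfunction psi1 = -tanh * F with dF/dx = V_in exp(-s/L_in).
    F = -c.v_inshore * L_in * (1.0 - np.exp(-s / L_in))
    psi = -np.tanh((Y - y_conv) / L_conv) * F
    # Southward offshore jet: v2 = -V_off exp(-((s - s_jet)/L_jet)^2).
    psi += c.v_offshore * L_jet * (np.sqrt(np.pi) / 2.0) * erf((s - s_jet) / L_jet)
    # Coastal meander cells: psi_m = A sin(2 pi y / lambda) (s/L) exp(-s/L);
    # the profile vanishes at the shoreline, so the cross-shore component
    # cannot pin particles against the coast.
    if c.meander_amplitude_m2_s:
        L_m = c.meander_width_km * 1000.0
        lam = c.meander_wavelength_km * 1000.0
        psi += (c.meander_amplitude_m2_s * np.sin(2 * np.pi * Y / lam)
                * (s / L_m) * np.exp(-s / L_m))
    # Retention eddies.
    for (ex_e, ey_e, amp, rad) in c.eddies:
        r2 = (X - ex_e * 1000.0) ** 2 + (Y - ey_e * 1000.0) ** 2
        psi += amp * np.exp(-r2 / (2.0 * (rad * 1000.0) ** 2))

    u2 = -(psi[2:, 1:-1] - psi[:-2, 1:-1]) / (2.0 * grid.dy)
    v2 = (psi[1:-1, 2:] - psi[1:-1, :-2]) / (2.0 * grid.dx)

    Xc, _ = np.meshgrid(grid.x_centers, grid.y_centers)
    mask = Xc < x_coast
    sc = np.clip(x_coast - Xc, 0.0, None)
    bathy = np.where(mask,
                     np.minimum(c.depth_max_m, c.depth_coast_m + c.depth_slope * sc),
                     0.0)

    # Depth attenuation: factor depends on z only, so per-level horizontal
    # divergence stays zero.
    zl = np.asarray(grid.z_levels)
    zmax = zl[-1] if zl[-1] > 0 else 1.0
    factor = 1.0 - (1.0 - c.bottom_speed_factor) * zl / zmax
    u = (factor[:, None, None] * u2[None, :, :])[None, :, :, :]
    v = (factor[:, None, None] * v2[None, :, :])[None, :, :, :]
    w = np.zeros_like(u)
    fld = FlowField(grid=grid, u=u, v=v, w=w, mask=mask, bathymetry=bathy)

    # Habitat: a southern block, the long habitat gap, then the northern
    # block split in two by the site-free beach stretch.
    x_sites = x_coast - c.site_size_m          # seaward edge of the site band
    n_south = c.gap_after_population
    n_far_north = c.populations_north_of_beach
    n_mid = c.n_populations - n_south - n_far_north
    if n_mid < 0:
        raise ValueError("populations_north_of_beach exceeds the northern block")
    counts = list(c.sites_per_population)
    segments = [
        (c.habitat_y0_km * 1000.0, n_south, counts[:n_south]),
    ]
    y = segments[0][0] + sum(counts[:n_south]) * c.site_size_m + c.gap_km * 1000.0
    segments.append((y, n_mid, counts[n_south:n_south + n_mid]))
    y += sum(counts[n_south:n_south + n_mid]) * c.site_size_m + c.north_gap_km * 1000.0
    segments.append((y, n_far_north, counts[n_south + n_mid:]))
    y_end = y + sum(counts[n_south + n_mid:]) * c.site_size_m
    if y_end > grid.extent[3]:
        raise ValueError("habitat layout exceeds the domain alongshore extent")

    sites: list[HabitatSite] = []
    pop0 = 0
    for y_seg, n_pop, seg_counts in segments:
        if n_pop == 0:
            continue
        coast = [(x_coast, y_seg),
                 (x_coast, y_seg + sum(seg_counts) * c.site_size_m)]
        sites += generate_habitat(coast, n_pop, seg_counts, c.site_size_m,
                                  start_site_id=len(sites),
                                  start_population_id=pop0)
        pop0 += n_pop
    # Sanity: the site band must be in water.
    assert x_sites >= grid.extent[0]
    return fld, sites


# ---------------------------------------------------------------------------
# I/O
# ---------------------------------------------------------------------------

_FLOW_VARS = ("u", "v", "w", "mask", "bathymetry")


def write_flow(field: FlowField, path: str) -> None:
    """Write a FlowField to NetCDF (dims time, z, y, x; SI units)."""
    g = field.grid
    ds = xr.Dataset(
        {
            "u": (("time", "z", "y", "x"), field.u, {"units": "m s-1"}),
            "v": (("time", "z", "y", "x"), field.v, {"units": "m s-1"}),
            "w": (("time", "z", "y", "x"), field.w, {"units": "m s-1"}),
            "mask": (("y", "x"), field.mask.astype(np.int8),
                     {"long_name": "sea mask (1=sea)"}),
            "bathymetry": (("y", "x"), field.bathymetry, {"units": "m"}),
        },
        coords={
            "time": ("time", g.times,
                     {"units": "s", "long_name": "seconds from scenario start"}),
            "z": ("z", np.asarray(g.z_levels, dtype=float),
                  {"units": "m", "positive": "down"}),
            "y": ("y", g.y_centers, {"units": "m"}),
            "x": ("x", g.x_centers, {"units": "m"}),
        },
        attrs={
            "x_origin": g.x_origin, "y_origin": g.y_origin,
            "dx": g.dx, "dy": g.dy,
            "t0": g.t0, "dt_field": g.dt_field,
        },
    )
    ds.to_netcdf(path, engine="scipy")


def read_flow(path: str) -> FlowField:
    """Read a FlowField written by :func:`write_flow`.

    Raises :class:`FlowFormatError` naming the first missing variable.
    """
    with xr.open_dataset(path, engine="scipy", decode_times=False) as ds:
        ds.load()
    for name in _FLOW_VARS:
        if name not in ds.variables:
            raise FlowFormatError(f"missing variable {name}")
    for dim in ("time", "z", "y", "x"):
        if dim not in ds.dims:
            raise FlowFormatError(f"missing dimension {dim}")
    x = ds["x"].values
    y = ds["y"].values
    z = ds["z"].values
    t = ds["time"].values.astype(float)
    attrs = ds.attrs
    dx = float(attrs.get("dx", x[1] - x[0] if len(x) > 1 else 1.0))
    dy = float(attrs.get("dy", y[1] - y[0] if len(y) > 1 else 1.0))
    grid = GridSpec(
        x_origin=float(attrs.get("x_origin", x[0] - 0.5 * dx)),
        y_origin=float(attrs.get("y_origin", y[0] - 0.5 * dy)),
        nx=len(x), ny=len(y), dx=dx, dy=dy,
        z_levels=tuple(float(v) for v in z),
        t0=float(attrs.get("t0", t[0])),
        dt_field=float(attrs.get("dt_field", t[1] - t[0] if len(t) > 1 else 3600.0)),
        nt=len(t),
    )
    return FlowField(
        grid=grid,
        u=ds["u"].values, v=ds["v"].values, w=ds["w"].values,
        mask=ds["mask"].values.astype(bool),
        bathymetry=ds["bathymetry"].values,
    )


def write_habitat(sites: Sequence[HabitatSite], path: str) -> None:
    """Write habitat sites as a GeoJSON FeatureCollection (planar meters)."""
    features = [
        {
            "type": "Feature",
            "geometry": mapping(s.polygon),
            "properties": {
                "site_id": s.site_id,
                "population_id": s.population_id,
                "area_km2": s.area_km2,
            },
        }
        for s in sites
    ]
    with open(path, "w") as fh:
        json.dump({"type": "FeatureCollection", "features": features}, fh)


def lonlat_to_plane(lon, lat, lon0: float, lat0: float):
    """Equirectangular projection onto the local plane (meters).

    Adequate at the sub-degree scale of a coastal domain; used only at the
    I/O boundary — the core works exclusively in the projected plane.
    """
    R = 6_371_000.0
    lon = np.asarray(lon, dtype=float)
    lat = np.asarray(lat, dtype=float)
    x = np.deg2rad(lon - lon0) * R * np.cos(np.deg2rad(lat0))
    y = np.deg2rad(lat - lat0) * R
    return x, y


def plane_to_lonlat(x, y, lon0: float, lat0: float):
    """Inverse of :func:`lonlat_to_plane`."""
    R = 6_371_000.0
    lon = lon0 + np.rad2deg(np.asarray(x, dtype=float)
                            / (R * np.cos(np.deg2rad(lat0))))
    lat = lat0 + np.rad2deg(np.asarray(y, dtype=float) / R)
    return lon, lat


def read_habitat(path: str) -> list[HabitatSite]:
    with open(path) as fh:
        fc = json.load(fh)
    sites = []
    for feat in fc["features"]:
        props = feat["properties"]
        poly = shape(feat["geometry"])
        sites.append(HabitatSite(
            site_id=int(props["site_id"]),
            population_id=int(props["population_id"]),
            polygon=poly,
            area_km2=float(props.get("area_km2", poly.area / 1e6)),
        ))
    return sites
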