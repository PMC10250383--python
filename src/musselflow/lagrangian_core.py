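"""Particle trajectory integration with mussel settlement biology.

Forward or backward advection through a :class:`~musselflow.synthetic_ocean.FlowField`
with a classical RK4 kernel, optional random-walk turbulence and constant
sinking, a move-back coastline/seafloor rule, and a settlement-competency
window restricted to habitat polygons.

Per step the operator order is: advection (RK4, signed dt) -> horizontal
diffusion -> vertical diffusion (substepped) -> sinking -> boundary rule ->
settlement check.  Backward integration uses a negative signed dt in the same
kernel; turbulence and sinking are off in backward mode by default, and
forcing them on raises a warning (the stochastic terms are not part of the
deterministic backtracking they would contaminate).

Randomness is counter-based (Philox keyed on the master seed, counter = step
index): the Gaussian increments drawn for particle *i* at step *k* depend
only on (seed, i, k), never on which other particles are active, so results
are independent of batch partitioning and bit-reproducible under a fixed
seed.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass
from enum import Enum
from typing import Sequence

import numpy as np
import pandas as pd
import shapely
import xarray as xr
from shapely.strtree import STRtree

from .synthetic_ocean import FlowField, HabitatSite


class OutOfDomainError(ValueError):
    """A queried position or time lies outside the flow-field domain."""


class Status(str, Enum):
    ACTIVE = "active"
    SETTLED = "settled"
    EXPIRED = "expired"
    REMOVED = "removed"


@dataclass
class IntegrationConfig:
    """Numerical and biological parameters of one integration.

    dt                      integration step, s (900 s default)
    direction               "forward" | "backward"
    pld_max                 maximum pelagic duration, s (lag excluded)
    competency_start        age at which settlement becomes possible, s
    horizontal_diffusivity  K_h, m^2/s (0.1176 default; 0 disables)
    vertical_diffusivity    K_v, m^2/s (0.01 default), applied over
                            ``vertical_substep`` (90 s) sub-increments
    sinking_velocity        w_s, m/s downward (0.001 default)
    diffusion / sinking     master switches for the stochastic/sinking terms
    advect_field_w          include the field's own w in RK4 advection
    seed                    master seed for all randomness
    save_every              record every k-th step into the trajectory store
    store_trajectories      keep the position history (memory-heavy)
    """

    pld_max: float
    competency_start: float
    dt: float = 900.0
    direction: str = "forward"
    horizontal_diffusivity: float = 0.1176
    vertical_diffusivity: float = 0.01
    vertical_substep: float = 90.0
    sinking_velocity: float = 0.001
    diffusion: bool = True
    sinking: bool = True
    advect_field_w: bool = True
    seed: int = 0
    save_every: int = 1
    store_trajectories: bool = False

    def __post_init__(self) -> None:
        if self.dt <= 0:
            raise ValueError("dt must be positive")
        if self.competency_start > self.pld_max:
            raise ValueError("competency_start must be <= pld_max")
        if self.horizontal_diffusivity < 0 or self.vertical_diffusivity < 0:
            raise ValueError("diffusivities must be >= 0")
        n_sub = self.dt / self.vertical_substep
        if abs(n_sub - round(n_sub)) > 1e-9:
            raise ValueError("vertical_substep must divide dt")
        if self.direction not in ("forward", "backward"):
            raise ValueError("direction must be 'forward' or 'backward'")

    @property
    def n_substeps(self) -> int:
        return int(round(self.dt / self.vertical_substep))

    @property
    def sign(self) -> int:
        return 1 if self.direction == "forward" else -1


# ---------------------------------------------------------------------------
# Field sampling
# ---------------------------------------------------------------------------

class FieldSampler:
    """Vectorised multilinear sampler of a FlowField.

    Trilinear in (x, y, z) with constant extrapolation in the half-cell rim
    and beyond the shallowest/deepest level; linear in time for unsteady
    fields.  Returns an ``inside`` mask instead of raising, so the caller
    decides particle fate.
    """

    def __init__(self, field: FlowField):
        g = field.grid
        self.g = g
        self.u, self.v, self.w = field.u, field.v, field.w
        self.mask = field.mask
        self.bathy = field.bathymetry
        self.zl = np.asarray(g.z_levels, dtype=float)
        self.steady = g.nt == 1
        self.x0, self.x1, self.y0, self.y1 = g.extent
        self.t_min = g.t0
        self.t_max = g.t0 + (g.nt - 1) * g.dt_field

    def _hindex(self, x, y):
        g = self.g
        fx = (x - g.x_origin) / g.dx - 0.5
        fy = (y - g.y_origin) / g.dy - 0.5
        i0 = np.clip(np.floor(fx).astype(np.int64), 0, max(g.nx - 2, 0))
        j0 = np.clip(np.floor(fy).astype(np.int64), 0, max(g.ny - 2, 0))
        ax = np.clip(fx - i0, 0.0, 1.0)
        ay = np.clip(fy - j0, 0.0, 1.0)
        if g.nx == 1:
            ax = np.zeros_like(ax)
        if g.ny == 1:
            ay = np.zeros_like(ay)
        return i0, j0, ax, ay

    def _zindex(self, z):
        zl = self.zl
        if zl.size == 1:
            k0 = np.zeros(z.shape, dtype=np.int64)
            return k0, np.zeros_like(z)
        zc = np.clip(z, zl[0], zl[-1])
        k1 = np.clip(np.searchsorted(zl, zc, side="right"), 1, zl.size - 1)
        k0 = k1 - 1
        az = (zc - zl[k0]) / (zl[k1] - zl[k0])
        return k0, np.clip(az, 0.0, 1.0)

    def _interp3(self, arr, k0, j0, i0, az, ay, ax):
        # arr: (nz, ny, nx); all index arrays are 1-D and equal length
        nz = arr.shape[0]
        k1 = np.minimum(k0 + 1, nz - 1)
        j1 = np.minimum(j0 + 1, arr.shape[1] - 1)
        i1 = np.minimum(i0 + 1, arr.shape[2] - 1)
        c000 = arr[k0, j0, i0]; c001 = arr[k0, j0, i1]
        c010 = arr[k0, j1, i0]; c011 = arr[k0, j1, i1]
        c100 = arr[k1, j0, i0]; c101 = arr[k1, j0, i1]
        c110 = arr[k1, j1, i0]; c111 = arr[k1, j1, i1]
        c00 = c000 * (1 - ax) + c001 * ax
        c01 = c010 * (1 - ax) + c011 * ax
        c10 = c100 * (1 - ax) + c101 * ax
        c11 = c110 * (1 - ax) + c111 * ax
        c0 = c00 * (1 - ay) + c01 * ay
        c1 = c10 * (1 - ay) + c11 * ay
        return c0 * (1 - az) + c1 * az

    def sample(self, x, y, z, t):
        """Velocity components and an inside-domain mask at points (x, y, z, t)."""
        x = np.asarray(x, dtype=float)
        y = np.asarray(y, dtype=float)
        z = np.asarray(z, dtype=float)
        inside = (x >= self.x0) & (x <= self.x1) & (y >= self.y0) & (y <= self.y1)
        if not self.steady:
            tt = np.broadcast_to(np.asarray(t, dtype=float), x.shape)
            inside = inside & (tt >= self.t_min - 1e-6) & (tt <= self.t_max + 1e-6)
        i0, j0, ax, ay = self._hindex(x, y)
        k0, az = self._zindex(z)
        if self.steady:
            uu = self._interp3(self.u[0], k0, j0, i0, az, ay, ax)
            vv = self._interp3(self.v[0], k0, j0, i0, az, ay, ax)
            ww = self._interp3(self.w[0], k0, j0, i0, az, ay, ax)
        else:
            g = self.g
            ft = (np.clip(tt, self.t_min, self.t_max) - g.t0) / g.dt_field
            n0 = np.clip(np.floor(ft).astype(np.int64), 0, g.nt - 2)
            at = np.clip(ft - n0, 0.0, 1.0)
            uu = vv = ww = None
            outs = []
            for arr in (self.u, self.v, self.w):
                lo = self._interp3_t(arr, n0, k0, j0, i0, az, ay, ax, 0)
                hi = self._interp3_t(arr, n0, k0, j0, i0, az, ay, ax, 1)
                outs.append(lo * (1 - at) + hi * at)
            uu, vv, ww = outs
        return uu, vv, ww, inside

    def _interp3_t(self, arr, n0, k0, j0, i0, az, ay, ax, off):
        n = np.minimum(n0 + off, arr.shape[0] - 1)
        nz, nyy, nxx = arr.shape[1:]
        k1 = np.minimum(k0 + 1, nz - 1)
        j1 = np.minimum(j0 + 1, nyy - 1)
        i1 = np.minimum(i0 + 1, nxx - 1)
        a = arr
        c000 = a[n, k0, j0, i0]; c001 = a[n, k0, j0, i1]
        c010 = a[n, k0, j1, i0]; c011 = a[n, k0, j1, i1]
        c100 = a[n, k1, j0, i0]; c101 = a[n, k1, j0, i1]
        c110 = a[n, k1, j1, i0]; c111 = a[n, k1, j1, i1]
        c00 = c000 * (1 - ax) + c001 * ax
        c01 = c010 * (1 - ax) + c011 * ax
        c10 = c100 * (1 - ax) + c101 * ax
        c11 = c110 * (1 - ax) + c111 * ax
        c0 = c00 * (1 - ay) + c01 * ay
        c1 = c10 * (1 - ay) + c11 * ay
        return c0 * (1 - az) + c1 * az

    def cell_index(self, x, y):
        g = self.g
        i = np.floor((np.asarray(x) - g.x_origin) / g.dx).astype(np.int64)
        j = np.floor((np.asarray(y) - g.y_origin) / g.dy).astype(np.int64)
        return np.clip(i, 0, g.nx - 1), np.clip(j, 0, g.ny - 1)

    def on_land(self, x, y):
        i, j = self.cell_index(x, y)
        return ~self.mask[j, i]

    def seafloor_depth(self, x, y):
        i, j = self.cell_index(x, y)
        return self.bathy[j, i]


# ---------------------------------------------------------------------------
# Elementary steps (functional spec surface)
# ---------------------------------------------------------------------------

def interpolate_velocity(field: FlowField, position, time: float):
    """Interpolated (u, v, w) at a single position and time.

    Raises :class:`OutOfDomainError` outside the grid extent or time axis.
    """
    x, y, z = position
    s = FieldSampler(field)
    u, v, w, inside = s.sample(np.atleast_1d(float(x)), np.atleast_1d(float(y)),
                               np.atleast_1d(float(z)), float(time))
    if not bool(inside[0]):
        raise OutOfDomainError(f"position {position} / time {time} outside domain")
    return float(u[0]), float(v[0]), float(w[0])


def _rk4(sampler: FieldSampler, x, y, z, t, dt_signed, advect_w=True):
    """Vectorised RK4 advection; returns new positions and an ok mask."""
    h = dt_signed

    def rhs(xs, ys, zs, ts):
        u, v, w, ok = sampler.sample(xs, ys, zs, ts)
        if not advect_w:
            w = np.zeros_like(u)
        return u, v, w, ok

    u1, v1, w1, ok1 = rhs(x, y, z, t)
    u2, v2, w2, ok2 = rhs(x + 0.5 * h * u1, y + 0.5 * h * v1, z + 0.5 * h * w1, t + 0.5 * h)
    u3, v3, w3, ok3 = rhs(x + 0.5 * h * u2, y + 0.5 * h * v2, z + 0.5 * h * w2, t + 0.5 * h)
    u4, v4, w4, ok4 = rhs(x + h * u3, y + h * v3, z + h * w3, t + h)
    xn = x + (h / 6.0) * (u1 + 2 * u2 + 2 * u3 + u4)
    yn = y + (h / 6.0) * (v1 + 2 * v2 + 2 * v3 + v4)
    zn = z + (h / 6.0) * (w1 + 2 * w2 + 2 * w3 + w4)
    return xn, yn, zn, ok1 & ok2 & ok3 & ok4


def rk4_step(position, time: float, dt_signed: float, field: FlowField,
             advect_w: bool = True):
    """One classical RK4 step; backward integration passes negative dt.

    Raises :class:`OutOfDomainError` if any stage evaluation leaves the domain.
    """
    s = FieldSampler(field)
    x, y, z = (np.atleast_1d(float(c)) for c in position)
    xn, yn, zn, ok = _rk4(s, x, y, z, float(time), float(dt_signed), advect_w)
    if not bool(ok[0]):
        raise OutOfDomainError("RK4 stage evaluation left the domain")
    return float(xn[0]), float(yn[0]), float(zn[0])


def diffusion_step(position, K_h: float, K_v: float, dt: float,
                   vertical_substep: float, rng: np.random.Generator):
    """Random-walk increment: per-axis horizontal std sqrt(2 K_h dt); the
    vertical as dt/substep consecutive increments of std sqrt(2 K_v substep)."""
    x, y, z = position
    if K_h > 0:
        sig_h = np.sqrt(2.0 * K_h * dt)
        x = x + rng.normal(0.0, sig_h)
        y = y + rng.normal(0.0, sig_h)
    if K_v > 0:
        n_sub = int(round(dt / vertical_substep))
        sig_v = np.sqrt(2.0 * K_v * vertical_substep)
        z = z + sig_v * rng.standard_normal(n_sub).sum()
    return x, y, z


def sinking_step(position, w_s: float, dt: float):
    """Deepen z by w_s * dt (positive down); seafloor clamping is the
    boundary rule's job."""
    x, y, z = position
    return x, y, z + w_s * dt


def apply_boundary(previous_position, proposed_position, field: FlowField,
                   can_settle_here: bool = False):
    """Coastline/seafloor rule: a move onto land or below the seafloor is
    rejected (particle put back), unless settlement is permitted there; a
    surface breach clamps z to 0."""
    s = FieldSampler(field)
    x, y, z = proposed_position
    if z < 0:
        z = 0.0
    land = bool(s.on_land(np.atleast_1d(x), np.atleast_1d(y))[0])
    below = z > float(s.seafloor_depth(np.atleast_1d(x), np.atleast_1d(y))[0])
    if (land or below) and not can_settle_here:
        return tuple(previous_position)
    return (x, y, z)


class SiteIndex:
    """Spatial index over settlement polygons for bulk point-in-polygon queries."""

    def __init__(self, sites: Sequence[HabitatSite] | Sequence[tuple[object, object]]):
        # Accept HabitatSite objects or (target_id, polygon) pairs.
        self.ids = []
        geoms = []
        for s in sites:
            if isinstance(s, HabitatSite):
                self.ids.append(s.site_id)
                geoms.append(s.polygon)
            else:
                tid, poly = s
                self.ids.append(tid)
                geoms.append(poly)
        self.geoms = np.array(geoms, dtype=object)
        self.tree = STRtree(list(self.geoms)) if geoms else None

    def locate(self, x, y):
        """Index (into ids) of the containing polygon per point, -1 if none.
        First containing polygon wins on (zero-area) boundary ties."""
        n = len(np.atleast_1d(x))
        out = np.full(n, -1, dtype=np.int64)
        if self.tree is None or n == 0:
            return out
        pts = shapely.points(np.asarray(x, dtype=float), np.asarray(y, dtype=float))
        pi, gi = self.tree.query(pts, predicate="within")
        if len(pi):
            # keep lowest polygon index per point
            order = np.lexsort((gi, pi))
            pi, gi = pi[order], gi[order]
            first = np.concatenate([[True], np.diff(pi) != 0])
            out[pi[first]] = gi[first]
        return out


def check_settlement(position, age: float, sites, competency_start: float,
                     pld_max: float):
    """Containing site id iff competency_start <= age <= pld_max and the
    horizontal position lies inside a site polygon; else None."""
    if not (competency_start <= age <= pld_max):
        return None
    index = sites if isinstance(sites, SiteIndex) else SiteIndex(sites)
    x, y, _ = position
    hit = index.locate(np.atleast_1d(float(x)), np.atleast_1d(float(y)))[0]
    return None if hit < 0 else index.ids[hit]


def release_lag(release_y: float, south_y: float, north_y: float,
                max_lag: float = 5.5 * 86400.0) -> float:
    """Spat age lag, linear from 0 at the beach's southern end to ``max_lag``
    at the northern end."""
    if not (south_y <= release_y <= north_y):
        raise ValueError("release position outside the beach alongshore extent")
    if north_y == south_y:
        return 0.0
    return max_lag * (release_y - south_y) / (north_y - south_y)


# ---------------------------------------------------------------------------
# Ensemble integration
# ---------------------------------------------------------------------------

@dataclass
class TrajectoryEnsemble:
    """Sub-sampled position history of an integrated particle batch.

    positions[i, k, :] is particle i at saved step k (NaN before release or
    after finalisation); ``times`` are the absolute saved times; ages follow
    from |t - release_time|.
    """

    particle_ids: np.ndarray
    release_times: np.ndarray
    lags: np.ndarray
    times: np.ndarray            # (n_saved,)
    positions: np.ndarray        # (n, n_saved, 3)
    direction: str

    @property
    def ages(self) -> np.ndarray:
        sgn = 1.0 if self.direction == "forward" else -1.0
        return sgn * (self.times[None, :] - self.release_times[:, None])

    def trajectory(self, i: int) -> pd.DataFrame:
        """Single-particle view: time, x, y, z, age rows actually recorded."""
        pos = self.positions[i]
        keep = np.isfinite(pos[:, 0])
        return pd.DataFrame({
            "time": self.times[keep],
            "x": pos[keep, 0], "y": pos[keep, 1], "z": pos[keep, 2],
            "age": self.ages[i, keep],
        })

    def to_netcdf(self, path: str) -> None:
        ds = xr.Dataset(
            {
                "x": (("particle", "obs"), self.positions[:, :, 0]),
                "y": (("particle", "obs"), self.positions[:, :, 1]),
                "z": (("particle", "obs"), self.positions[:, :, 2]),
                "release_time": (("particle",), self.release_times),
                "lag": (("particle",), self.lags),
            },
            coords={"particle": self.particle_ids, "time": (("obs",), self.times)},
            attrs={"direction": self.direction},
        )
        ds.to_netcdf(path, engine="scipy")


def _step_normals(seed: int, step: int, n: int, n_cols: int) -> np.ndarray:
    """Counter-based Gaussian block for one step: rows indexed by particle id."""
    bitgen = np.random.Philox(key=np.uint64(seed), counter=[0, 0, 0, step])
    return np.random.Generator(bitgen).standard_normal((n, n_cols))


def integrate(particles: pd.DataFrame, field: FlowField, sites,
              config: IntegrationConfig):
    """Integrate a particle batch; returns (TrajectoryEnsemble | None, records).

    ``particles`` columns: particle_id, release_point_id, release_time, x, y,
    z and optionally lag (seconds, Experiment-1 style; extends the tracked
    duration, not the competency window).  ``sites`` is a SiteIndex, a list
    of HabitatSite / (id, polygon) pairs, or None (no settlement).

    Records account for every particle exactly once as settled, expired or
    removed.
    """
    cfg = config
    if cfg.direction == "backward" and (cfg.diffusion or cfg.sinking):
        warnings.warn("backward integration with diffusion/sinking enabled; "
                      "deterministic backtracking normally excludes both",
                      stacklevel=2)
    n = len(particles)
    sgn = cfg.sign
    ids = particles["particle_id"].to_numpy()
    rel_t = particles["release_time"].to_numpy(dtype=float)
    lag = (particles["lag"].to_numpy(dtype=float)
           if "lag" in particles.columns else np.zeros(n))
    rx = particles["x"].to_numpy(dtype=float)
    ry = particles["y"].to_numpy(dtype=float)
    rz = particles["z"].to_numpy(dtype=float)
    rpid = (particles["release_point_id"].to_numpy()
            if "release_point_id" in particles.columns else np.arange(n))

    sampler = FieldSampler(field)
    site_index = (sites if isinstance(sites, SiteIndex) or sites is None
                  else SiteIndex(sites))

    # Snap releases to the step grid anchored at the earliest (forward) or
    # latest (backward) release.
    t_anchor = rel_t.min() if sgn > 0 else rel_t.max()
    k_rel = np.rint(sgn * (rel_t - t_anchor) / cfg.dt).astype(np.int64)
    dur = cfg.pld_max + lag
    k_end = k_rel + np.ceil(dur / cfg.dt - 1e-9).astype(np.int64)
    total_steps = int(k_end.max())

    if not field.steady:
        t_last = t_anchor + sgn * total_steps * cfg.dt
        lo, hi = sorted((t_anchor, t_last))
        if lo < sampler.t_min - 1e-6 or hi > sampler.t_max + 1e-6:
            raise ValueError("field time axis shorter than the requested "
                             "integration span")

    PEND, ACT, SETT, EXP, REM = -1, 0, 1, 2, 3
    status = np.full(n, PEND, dtype=np.int8)
    x = rx.copy(); y = ry.copy(); z = rz.copy()
    settle_site = np.full(n, -1, dtype=np.int64)
    settle_time = np.full(n, np.nan)
    end_age = np.full(n, np.nan)

    store = cfg.store_trajectories
    if store:
        saved_ks = np.arange(0, total_steps + 1, cfg.save_every)
        pos_hist = np.full((n, len(saved_ks), 3), np.nan)
        save_slot = {int(k): s for s, k in enumerate(saved_ks)}

    diffusing = cfg.diffusion and (cfg.horizontal_diffusivity > 0
                                   or cfg.vertical_diffusivity > 0)
    n_sub = cfg.n_substeps
    sig_h = np.sqrt(2.0 * cfg.horizontal_diffusivity * cfg.dt)
    sig_v = np.sqrt(2.0 * cfg.vertical_diffusivity * cfg.vertical_substep)

    for k in range(total_steps + 1):
        t = t_anchor + sgn * k * cfg.dt
        # activations
        newly = (status == PEND) & (k_rel == k)
        if newly.any():
            status[newly] = ACT
            if store and k in save_slot:
                s = save_slot[k]
                pos_hist[newly, s, 0] = x[newly]
                pos_hist[newly, s, 1] = y[newly]
                pos_hist[newly, s, 2] = z[newly]
        if k == total_steps:
            break

        act = status == ACT
        if act.any():
            idx = np.nonzero(act)[0]
            px, py, pz = x[idx], y[idx], z[idx]
            nx_, ny_, nz_, ok = _rk4(sampler, px, py, pz, t, sgn * cfg.dt,
                                     cfg.advect_field_w)
            if diffusing:
                normals = _step_normals(cfg.seed, k, n, 2 + n_sub)[idx]
                if cfg.horizontal_diffusivity > 0:
                    nx_ = nx_ + sig_h * normals[:, 0]
                    ny_ = ny_ + sig_h * normals[:, 1]
                if cfg.vertical_diffusivity > 0:
                    nz_ = nz_ + sig_v * normals[:, 2:].sum(axis=1)
            if cfg.sinking and cfg.sinking_velocity > 0:
                nz_ = nz_ + sgn * cfg.sinking_velocity * cfg.dt

            # boundary rule
            nz_ = np.maximum(nz_, 0.0)      # surface breach clamps to z = 0
            lat_in = ((nx_ >= sampler.x0) & (nx_ <= sampler.x1)
                      & (ny_ >= sampler.y0) & (ny_ <= sampler.y1))
            removed = ~ok | ~lat_in
            safe_x = np.where(lat_in, nx_, px)
            safe_y = np.where(lat_in, ny_, py)
            blocked = (sampler.on_land(safe_x, safe_y)
                       | (nz_ > sampler.seafloor_depth(safe_x, safe_y)))
            revert = blocked & ~removed
            nx_ = np.where(revert, px, safe_x)
            ny_ = np.where(revert, py, safe_y)
            nz_ = np.where(revert, pz, nz_)

            x[idx], y[idx], z[idx] = nx_, ny_, nz_
            rem_idx = idx[removed]
            status[rem_idx] = REM
            end_age[rem_idx] = (k + 1 - k_rel[rem_idx]) * cfg.dt

            # settlement at the post-move position
            age_next = (k + 1 - k_rel[idx]) * cfg.dt
            if site_index is not None:
                competent = (~removed & (age_next >= cfg.competency_start)
                             & (age_next <= cfg.pld_max))
                if competent.any():
                    cj = idx[competent]
                    hits = site_index.locate(x[cj], y[cj])
                    hit = hits >= 0
                    if hit.any():
                        sj = cj[hit]
                        status[sj] = SETT
                        settle_site[sj] = hits[hit]
                        settle_time[sj] = t + sgn * cfg.dt
                        end_age[sj] = age_next[competent][hit]

            # expiry
            expd = (status[idx] == ACT) & (k + 1 >= k_end[idx])
            ej = idx[expd]
            status[ej] = EXP
            end_age[ej] = (k + 1 - k_rel[ej]) * cfg.dt

            if store and (k + 1) in save_slot:
                s = save_slot[k + 1]
                live = idx[status[idx] == ACT]
                pos_hist[live, s, 0] = x[live]
                pos_hist[live, s, 1] = y[live]
                pos_hist[live, s, 2] = z[live]

    # zero-duration edge: anything still pending/active expires at its horizon
    leftover = (status == PEND) | (status == ACT)
    status[leftover] = EXP
    end_age[leftover] = np.where(np.isnan(end_age[leftover]),
                                 dur[leftover], end_age[leftover])

    status_map = {SETT: Status.SETTLED.value, EXP: Status.EXPIRED.value,
                  REM: Status.REMOVED.value}
    site_ids = np.empty(n, dtype=object)
    if site_index is not None:
        site_ids[:] = [site_index.ids[i] if i >= 0 else None
                       for i in settle_site]
    records = pd.DataFrame({
        "particle_id": ids,
        "release_point_id": rpid,
        "release_time": rel_t,
        "release_x": rx, "release_y": ry, "release_z": rz,
        "lag": lag,
        "status": [status_map[s] for s in status],
        "settlement_site_id": site_ids,
        "settlement_time": settle_time,
        "age_final": end_age,
        "final_x": x, "final_y": y, "final_z": z,
    })

    traj = None
    if store:
        traj = TrajectoryEnsemble(
            particle_ids=ids,
            release_times=rel_t,
            lags=lag,
            times=t_anchor + sgn * saved_ks * cfg.dt,
            positions=pos_hist,
            direction=cfg.direction,
        )
    return traj, records


def write_settlement_records(records: pd.DataFrame, path: str) -> None:
    """Settlement records to CSV (one row per particle)."""
    records.to_csv(path, index=False)
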