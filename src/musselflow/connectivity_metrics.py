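"""Dispersal metrics: trajectory densities, connectivity matrices, kernels.

Three complementary summaries of the particle-tracking output:

* probability-density grids of trajectory samples, from which primary
  settlement areas are extracted by density thresholding plus a buffer;
* source x sink connectivity matrices of settlement fractions (primary,
  secondary as a product of rectangular stage matrices, and their total);
* dispersal kernels, the settlement probability as a function of distance
  from release.

An EOF (SVD) decomposition of the year-to-year connectivity anomalies
summarises inter-annual variance.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass
from typing import Sequence

import numpy as np
import pandas as pd
import xarray as xr
from scipy import ndimage
from shapely.geometry import Polygon, box
from shapely.ops import unary_union

from .lagrangian_core import TrajectoryEnsemble


# ---------------------------------------------------------------------------
# Trajectory density and settlement-area extraction
# ---------------------------------------------------------------------------

@dataclass
class DensityGrid:
    """Probability of particle presence per cell (sums to 1 when non-empty)."""

    bbox: tuple[float, float, float, float]   # x_min, x_max, y_min, y_max (m)
    probability: np.ndarray                   # (ny, nx)
    cell_area_km2: float
    n_particles: int
    n_samples: int
    empty: bool = False

    @property
    def shape(self) -> tuple[int, int]:
        return self.probability.shape

    def to_netcdf(self, path: str) -> None:
        ny, nx = self.probability.shape
        x0, x1, y0, y1 = self.bbox
        xc = x0 + (np.arange(nx) + 0.5) * (x1 - x0) / nx
        yc = y0 + (np.arange(ny) + 0.5) * (y1 - y0) / ny
        ds = xr.Dataset(
            {"probability": (("y", "x"), self.probability)},
            coords={"x": xc, "y": yc},
            attrs={"cell_area_km2": self.cell_area_km2,
                   "n_particles": self.n_particles,
                   "n_samples": self.n_samples},
        )
        ds.to_netcdf(path, engine="scipy")


def trajectory_density(
    trajectories: TrajectoryEnsemble,
    bbox: tuple[float, float, float, float],
    n_cells: tuple[int, int] = (299, 299),
    age_window: tuple[float, float] = (0.0, np.inf),
    lag_extends_upper: bool = True,
) -> DensityGrid:
    """Bin trajectory samples with age inside ``age_window`` onto a grid.

    For lagged (spat) releases the upper age edge is extended by each
    particle's lag, mirroring the "10 to 20-25.5 days" dispersal window.
    Samples falling outside ``bbox`` are dropped with a warning count.
    """
    x0, x1, y0, y1 = bbox
    nx, ny = n_cells
    ages = trajectories.ages
    lo, hi = age_window
    upper = hi + (trajectories.lags[:, None] if lag_extends_upper else 0.0)
    sel = np.isfinite(trajectories.positions[:, :, 0]) \
        & (ages >= lo) & (ages <= upper)
    xs = trajectories.positions[:, :, 0][sel]
    ys = trajectories.positions[:, :, 1][sel]
    inside = (xs >= x0) & (xs <= x1) & (ys >= y0) & (ys <= y1)
    n_out = int((~inside).sum())
    if n_out:
        warnings.warn(f"{n_out} trajectory samples outside the density bbox "
                      "were dropped", stacklevel=2)
    xs, ys = xs[inside], ys[inside]
    counts, _, _ = np.histogram2d(
        ys, xs, bins=[ny, nx], range=[[y0, y1], [x0, x1]])
    total = counts.sum()
    cell_area_km2 = ((x1 - x0) / nx) * ((y1 - y0) / ny) / 1e6
    if total == 0:
        return DensityGrid(bbox, counts, cell_area_km2,
                           len(trajectories.particle_ids), 0, empty=True)
    return DensityGrid(bbox, counts / total, cell_area_km2,
                       len(trajectories.particle_ids), int(total))


@dataclass
class SettlementArea:
    label: str
    polygon: Polygon
    area_km2: float


def extract_settlement_areas(
    density: DensityGrid,
    threshold_per_km2: float = 0.6,
    buffer_m: float = 500.0,
    n_particles: int | None = None,
) -> list[SettlementArea]:
    """High-density areas: threshold, label, polygonise, buffer.

    The threshold is in expected particles per km^2: a cell is kept when
    probability * n_particles / cell_area_km2 >= threshold (probabilities
    alone are unitless, so the released-particle count restores the stated
    unit).  Kept cells are grouped 4-connected, each component is the union
    of its cell rectangles dilated by ``buffer_m``; overlapping buffered
    components merge into the earlier label.  Labels run A, B, C, ...
    """
    n_part = n_particles if n_particles is not None else density.n_particles
    per_km2 = density.probability * n_part / density.cell_area_km2
    keep = per_km2 >= threshold_per_km2
    if not keep.any():
        return []
    labels, n_comp = ndimage.label(keep)  # default structure = 4-connectivity
    x0, x1, y0, y1 = density.bbox
    ny, nx = density.shape
    dx = (x1 - x0) / nx
    dy = (y1 - y0) / ny

    merged: list[SettlementArea] = []
    for comp in range(1, n_comp + 1):
        jj, ii = np.nonzero(labels == comp)
        cells = [box(x0 + i * dx, y0 + j * dy, x0 + (i + 1) * dx, y0 + (j + 1) * dy)
                 for j, i in zip(jj, ii)]
        poly = unary_union(cells).buffer(buffer_m)
        target = None
        for existing in merged:
            # positive-area overlap only: corner-touching stays distinct
            if existing.polygon.intersection(poly).area > 0:
                target = existing
                break
        if target is None:
            merged.append(SettlementArea(
                label=chr(ord("A") + len(merged)), polygon=poly,
                area_km2=poly.area / 1e6))
        else:
            target.polygon = unary_union([target.polygon, poly])
            target.area_km2 = target.polygon.area / 1e6
    return merged


def write_settlement_areas(areas: Sequence[SettlementArea], path: str) -> None:
    import json
    from shapely.geometry import mapping
    fc = {"type": "FeatureCollection", "features": [
        {"type": "Feature", "geometry": mapping(a.polygon),
         "properties": {"label": a.label, "area_km2": a.area_km2}}
        for a in areas]}
    with open(path, "w") as fh:
        json.dump(fc, fh)


# ---------------------------------------------------------------------------
# Connectivity matrices
# ---------------------------------------------------------------------------

@dataclass
class ConnectivityMatrix:
    """Source x sink settlement fractions.

    values[i, j] = settlers from source i arriving at sink j divided by the
    releases of source i; rows are sources, columns sinks; the diagonal of a
    square site matrix is local retention.
    """

    values: np.ndarray
    source_ids: list
    sink_ids: list
    kind: str = "primary"            # primary | secondary | total
    years: tuple = ()

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=float)
        if self.values.shape != (len(self.source_ids), len(self.sink_ids)):
            raise ValueError("values shape does not match id lists")
        if np.any(self.values < -1e-12) or np.any(self.values > 1 + 1e-12):
            raise ValueError("connectivity entries must lie in [0, 1]")

    def to_csv(self, path: str) -> None:
        pd.DataFrame(self.values, index=self.source_ids,
                     columns=self.sink_ids).to_csv(path)

    @classmethod
    def from_csv(cls, path: str, kind: str = "primary") -> "ConnectivityMatrix":
        df = pd.read_csv(path, index_col=0)
        return cls(values=df.to_numpy(), source_ids=list(df.index),
                   sink_ids=list(df.columns), kind=kind)


def connectivity_matrix(
    records: pd.DataFrame,
    source_ids: Sequence,
    released_per_source: dict,
    sink_ids: Sequence | None = None,
    sink_kind: str = "site",
    kind: str = "primary",
) -> ConnectivityMatrix:
    """Settlement-fraction matrix from settlement records.

    ``records`` carries release_group (source) and settlement_site_id
    (targets labelled ("site", id) / ("area", id) / ("pop", id)); only sinks
    of ``sink_kind`` enter the matrix.  Unknown source or sink ids raise.
    """
    if sink_ids is None:
        sink_ids = list(source_ids)
    src_pos = {s: i for i, s in enumerate(source_ids)}
    snk_pos = {s: j for j, s in enumerate(sink_ids)}
    vals = np.zeros((len(source_ids), len(sink_ids)))
    settled = records[records["status"] == "settled"]
    for _, row in settled.iterrows():
        tgt = row["settlement_site_id"]
        tkind, tid = tgt if isinstance(tgt, tuple) else ("site", tgt)
        if tkind != sink_kind:
            continue
        src = row["release_group"]
        if src not in src_pos:
            raise ValueError(f"record with unknown source id {src!r}")
        if tid not in snk_pos:
            raise ValueError(f"record with unknown sink id {tid!r}")
        vals[src_pos[src], snk_pos[tid]] += 1.0
    rel = np.array([released_per_source[s] for s in source_ids], dtype=float)
    if np.any(rel <= 0):
        raise ValueError("every source needs a positive release count")
    vals /= rel[:, None]
    return ConnectivityMatrix(vals, list(source_ids), list(sink_ids), kind=kind)


def average_matrices(yearly: Sequence[ConnectivityMatrix]) -> ConnectivityMatrix:
    """Element-wise mean of per-year matrices (identical site sets required)."""
    if not yearly:
        raise ValueError("no matrices to average")
    first = yearly[0]
    for m in yearly[1:]:
        if m.values.shape != first.values.shape \
                or m.source_ids != first.source_ids or m.sink_ids != first.sink_ids:
            raise ValueError("matrices have mismatched dimensions or ids")
    mean = np.mean([m.values for m in yearly], axis=0)
    years = tuple(y for m in yearly for y in m.years)
    return ConnectivityMatrix(mean, first.source_ids, first.sink_ids,
                              kind=first.kind, years=years)


def secondary_connectivity(primary_to_areas: ConnectivityMatrix,
                           areas_to_sites: ConnectivityMatrix) -> ConnectivityMatrix:
    """Site-to-site connectivity via the primary settlement areas: the
    product of the (sites x areas) and (areas x sites) stage matrices."""
    if primary_to_areas.sink_ids != areas_to_sites.source_ids:
        raise ValueError("inner (primary settlement area) dimensions mismatch")
    vals = primary_to_areas.values @ areas_to_sites.values
    return ConnectivityMatrix(vals, primary_to_areas.source_ids,
                              areas_to_sites.sink_ids, kind="secondary")


def total_connectivity(primary: ConnectivityMatrix,
                       secondary: ConnectivityMatrix) -> ConnectivityMatrix:
    """Element-wise sum of the primary and secondary matrices."""
    if primary.values.shape != secondary.values.shape:
        raise ValueError("matrices have mismatched dimensions")
    return ConnectivityMatrix(np.clip(primary.values + secondary.values, 0, 1),
                              primary.source_ids, primary.sink_ids, kind="total")


# ---------------------------------------------------------------------------
# Dispersal kernels
# ---------------------------------------------------------------------------

@dataclass
class DispersalKernel:
    """Per-distance-bin settlement proportion relative to the group's releases."""

    bin_edges_km: np.ndarray
    proportions: np.ndarray
    group: str

    @property
    def mode_km(self) -> float:
        """Centre of the most probable distance bin."""
        i = int(np.argmax(self.proportions))
        return 0.5 * (self.bin_edges_km[i] + self.bin_edges_km[i + 1])

    def percentile_km(self, q: float) -> float:
        """Distance below which q% of the settled mass lies (bin-linear)."""
        mass = self.proportions / self.proportions.sum()
        cum = np.cumsum(mass)
        i = int(np.searchsorted(cum, q / 100.0))
        i = min(i, len(mass) - 1)
        prev = cum[i - 1] if i > 0 else 0.0
        frac = (q / 100.0 - prev) / max(mass[i], 1e-300)
        lo, hi = self.bin_edges_km[i], self.bin_edges_km[i + 1]
        return float(lo + np.clip(frac, 0, 1) * (hi - lo))

    def to_csv(self, path: str) -> None:
        pd.DataFrame({
            "bin_lo_km": self.bin_edges_km[:-1],
            "bin_hi_km": self.bin_edges_km[1:],
            "proportion": self.proportions,
        }).to_csv(path, index=False)


def dispersal_kernel(
    records: pd.DataFrame,
    n_released: int,
    bin_km: float = 20.0,
    max_km: float | None = None,
    group: str = "all",
) -> DispersalKernel:
    """Kernel from settlement records: straight-line release-to-settlement
    distances binned; per-bin proportion relative to ``n_released``, so the
    kernel mass equals the group's settled fraction."""
    settled = records[records["status"] == "settled"]
    d_km = np.hypot(settled["final_x"] - settled["release_x"],
                    settled["final_y"] - settled["release_y"]) / 1000.0
    if max_km is None:
        max_km = max(float(np.ceil((d_km.max() if len(d_km) else 0.0)
                                   / bin_km)), 1.0) * bin_km
    edges = np.arange(0.0, max_km + bin_km, bin_km)
    counts, _ = np.histogram(d_km, bins=edges)
    return DispersalKernel(edges, counts / float(n_released), group)


def kernel_from_matrix(
    C: ConnectivityMatrix,
    source_centroids: dict,
    sink_centroids: dict,
    released_per_source: dict,
    bin_km: float = 20.0,
    max_km: float | None = None,
    group: str = "matrix",
) -> DispersalKernel:
    """Kernel implied by a connectivity matrix using site-centroid distances
    (the natural form for the secondary/total matrices, whose two-stage
    paths have no single release-to-settlement record)."""
    rel = np.array([released_per_source[s] for s in C.source_ids], dtype=float)
    mass = C.values * rel[:, None]
    sx = np.array([source_centroids[s][0] for s in C.source_ids])
    sy = np.array([source_centroids[s][1] for s in C.source_ids])
    kx = np.array([sink_centroids[s][0] for s in C.sink_ids])
    ky = np.array([sink_centroids[s][1] for s in C.sink_ids])
    d_km = np.hypot(sx[:, None] - kx[None, :], sy[:, None] - ky[None, :]) / 1000.0
    if max_km is None:
        max_km = max(float(np.ceil(d_km.max() / bin_km)), 1.0) * bin_km
    edges = np.arange(0.0, max_km + bin_km, bin_km)
    counts, _ = np.histogram(d_km.ravel(), bins=edges, weights=mass.ravel())
    return DispersalKernel(edges, counts / rel.sum(), group)


# ---------------------------------------------------------------------------
# Inter-annual EOF decomposition
# ---------------------------------------------------------------------------

def eof_interannual(
    yearly: Sequence[ConnectivityMatrix],
) -> tuple[list[np.ndarray], np.ndarray]:
    """SVD of the stacked, mean-removed yearly matrices.

    Returns (modes, explained variance fractions); modes are reshaped to
    matrix form.  Identical years (zero variance) give an empty mode list.
    """
    if len(yearly) < 2:
        raise ValueError("need at least two years")
    shape = yearly[0].values.shape
    stack = np.stack([m.values.ravel() for m in yearly])
    anom = stack - stack.mean(axis=0, keepdims=True)
    scale = max(np.abs(stack).max(), 1e-300)
    if np.abs(anom).max() <= 1e-12 * scale:  # identical years up to rounding
        return [], np.array([])
    _, s, vt = np.linalg.svd(anom, full_matrices=False)
    frac = s**2 / np.sum(s**2)
    keep = s > s[0] * 1e-12
    modes = [vt[i].reshape(shape) for i in range(len(s)) if keep[i]]
    return modes, frac[keep]
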