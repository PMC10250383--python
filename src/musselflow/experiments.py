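"""The four numbered dispersal experiments.

Two backtracking experiments locate where beach-cast spat first settled
(Experiment 1) and which populations spawned them (Experiment 2); two
forward-tracking experiments estimate regional primary connectivity among
habitat sites (Experiment 3) and the secondary, bottom-drifting spat
connectivity out of the primary settlement areas (Experiment 4).

Presets mirror the published modelling parameters:

====  =========  ==========  ===========  =============  ========================  =====================
exp   PLD        competency  rel. depth   diffusion      release area              settlement area
====  =========  ==========  ===========  =============  ========================  =====================
1     20 d + lag 10 d + lag  seafloor+1m  no             beach                     (none; trajectories)
2     35 d       21 d        0-30 m       no             primary settlement areas  source populations
3     35 d       21 d        0-20 m       yes + sinking  all sites (20 pts each)   sites + primary areas
4     30 d       10 d        seafloor+1m  yes + sinking  primary settlement areas  sites
====  =========  ==========  ===========  =============  ========================  =====================

1000 particles are released per point per month, evenly spaced in time
within the month.  Scaled-down runs override the point/particle counts and
the month/year lists without touching the biology.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from typing import Sequence

import numpy as np
import pandas as pd
from scipy import stats
from shapely.geometry import Polygon

from . import lagrangian_core as lc
from .synthetic_ocean import FlowField, HabitatSite, population_areas

DAY = 86400.0

# month name -> day count, in seasonal order
MONTH_DAYS = {"jun": 30, "jul": 31, "aug": 31, "sep": 30, "oct": 31, "nov": 30}


def month_bounds(months: Sequence[str]) -> dict[str, tuple[float, float]]:
    """(start, end) seconds from season start for each month, laid end to end
    in the order of MONTH_DAYS."""
    out = {}
    t = 0.0
    for name, days in MONTH_DAYS.items():
        if name in months:
            out[name] = (t, t + days * DAY)
        t += days * DAY
    missing = set(months) - set(out)
    if missing:
        raise ValueError(f"unknown months: {sorted(missing)}")
    return out


@dataclass
class ExperimentConfig:
    """One row of the experiment parameter table."""

    experiment_id: int
    direction: str
    pld_max: float                    # seconds, lag excluded
    competency_start: float
    release_depth: str                # "seafloor+1" | "uniform:a:b"
    diffusion: bool
    sinking: bool
    release_area: str                 # "beach" | "primary_areas" | "sites"
    settlement_targets: str           # "none" | "populations" | "sites+areas" | "sites"
    n_release_points: int
    particles_per_point_per_month: int
    months: tuple[str, ...]
    years: tuple[int, ...]
    lag_max: float = 0.0              # Experiment 1 spat-age lag, seconds
    sinking_velocity: float = 0.001

    @property
    def particles_total(self) -> int:
        return (self.n_release_points * self.particles_per_point_per_month
                * len(self.months) * len(self.years))


def make_experiment_config(experiment_id: int) -> ExperimentConfig:
    """Preset faithful to the published parameter table."""
    if experiment_id == 1:
        return ExperimentConfig(
            experiment_id=1, direction="backward",
            pld_max=20 * DAY, competency_start=10 * DAY,
            release_depth="seafloor+1", diffusion=False, sinking=False,
            release_area="beach", settlement_targets="none",
            n_release_points=200, particles_per_point_per_month=1000,
            months=("jul", "aug", "sep", "oct", "nov"),
            years=(2015, 2016, 2017), lag_max=5.5 * DAY,
        )
    if experiment_id == 2:
        return ExperimentConfig(
            experiment_id=2, direction="backward",
            pld_max=35 * DAY, competency_start=21 * DAY,
            release_depth="uniform:0:30", diffusion=False, sinking=False,
            release_area="primary_areas", settlement_targets="populations",
            n_release_points=200, particles_per_point_per_month=1000,
            months=("jul", "aug", "sep", "oct", "nov"),
            years=(2015, 2016, 2017),
        )
    if experiment_id == 3:
        return ExperimentConfig(
            experiment_id=3, direction="forward",
            pld_max=35 * DAY, competency_start=21 * DAY,
            release_depth="uniform:0:20", diffusion=True, sinking=True,
            release_area="sites", settlement_targets="sites+areas",
            n_release_points=980, particles_per_point_per_month=1000,
            months=("jun", "jul", "aug", "sep", "oct"),
            years=tuple(range(2008, 2018)),
        )
    if experiment_id == 4:
        return ExperimentConfig(
            experiment_id=4, direction="forward",
            pld_max=30 * DAY, competency_start=10 * DAY,
            release_depth="seafloor+1", diffusion=True, sinking=True,
            release_area="primary_areas", settlement_targets="sites",
            n_release_points=200, particles_per_point_per_month=1000,
            months=("jul", "aug", "sep", "oct", "nov"),
            years=tuple(range(2008, 2018)),
        )
    raise ValueError(f"unknown experiment id {experiment_id}")


# ---------------------------------------------------------------------------
# Release scheduling
# ---------------------------------------------------------------------------

def _sample_in_polygons(polys: Sequence[tuple[object, Polygon]], n: int,
                        rng: np.random.Generator) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    """n points uniform over the union of polygons; returns x, y and the
    index of the containing polygon (rejection sampling in the joint bbox,
    area-weighted by construction)."""
    if not polys:
        raise ValueError("empty release geometry")
    geoms = [p for _, p in polys]
    xmin = min(g.bounds[0] for g in geoms); ymin = min(g.bounds[1] for g in geoms)
    xmax = max(g.bounds[2] for g in geoms); ymax = max(g.bounds[3] for g in geoms)
    import shapely
    xs = np.empty(n); ys = np.empty(n); which = np.empty(n, dtype=np.int64)
    got = 0
    tree = shapely.strtree.STRtree(geoms)
    while got < n:
        m = max(4 * (n - got), 256)
        cx = rng.uniform(xmin, xmax, m)
        cy = rng.uniform(ymin, ymax, m)
        pts = shapely.points(cx, cy)
        pi, gi = tree.query(pts, predicate="within")
        if len(pi) == 0:
            continue
        order = np.argsort(pi)
        pi, gi = pi[order], gi[order]
        first = np.concatenate([[True], np.diff(pi) != 0])
        pi, gi = pi[first], gi[first]
        take = min(n - got, len(pi))
        xs[got:got + take] = cx[pi[:take]]
        ys[got:got + take] = cy[pi[:take]]
        which[got:got + take] = gi[:take]
        got += take
    return xs, ys, which


@dataclass
class ReleaseSchedule:
    """Per-particle release table (one row per particle)."""

    table: pd.DataFrame
    released_per_source: dict      # release group id -> particle count

    def __len__(self) -> int:
        return len(self.table)


def build_release_schedule(
    config: ExperimentConfig,
    areas: Sequence[tuple[object, Polygon]],
    rng: np.random.Generator,
    field: FlowField | None = None,
    n_points: int | None = None,
    particles_per_point: int | None = None,
    months: Sequence[str] | None = None,
    beach_span_y: tuple[float, float] | None = None,
) -> ReleaseSchedule:
    """Build the release table for one experiment-year.

    ``areas`` are (group_id, polygon) pairs: the beach, the primary
    settlement areas, or the habitat sites depending on the experiment.  For
    the per-site release rule (Experiment 3) ``n_points`` counts points per
    site; otherwise points are spread uniformly over the union of areas.
    Release instants are evenly spaced within each month (the mid-points of
    equal sub-intervals, so a 30-day month with 10 particles per point gives
    3-day spacing).
    """
    if not areas:
        raise ValueError("empty release geometry")
    npts = n_points if n_points is not None else (
        config.n_release_points // len(areas) if config.release_area == "sites"
        else config.n_release_points)
    ppp = (particles_per_point if particles_per_point is not None
           else config.particles_per_point_per_month)
    use_months = tuple(months) if months is not None else config.months
    bounds = month_bounds(use_months)

    if config.release_area == "sites":
        per_area = npts
        xs, ys, which = [], [], []
        for ai, (_, poly) in enumerate(areas):
            px, py, _ = _sample_in_polygons([(None, poly)], per_area, rng)
            xs.append(px); ys.append(py)
            which.append(np.full(per_area, ai, dtype=np.int64))
        xs = np.concatenate(xs); ys = np.concatenate(ys)
        which = np.concatenate(which)
    else:
        xs, ys, which = _sample_in_polygons(list(areas), npts, rng)

    n_pts_total = len(xs)
    point_ids = np.arange(n_pts_total)
    rows_x, rows_y, rows_src, rows_t, rows_p = [], [], [], [], []
    for _, (t0, t1) in sorted(bounds.items(), key=lambda kv: kv[1][0]):
        t_rel = t0 + (np.arange(ppp) + 0.5) * (t1 - t0) / ppp
        for trel in t_rel:
            rows_x.append(xs); rows_y.append(ys); rows_src.append(which)
            rows_t.append(np.full(n_pts_total, trel)); rows_p.append(point_ids)
    x = np.concatenate(rows_x); y = np.concatenate(rows_y)
    src = np.concatenate(rows_src); t = np.concatenate(rows_t)
    pid = np.concatenate(rows_p)

    # depth rule
    if config.release_depth.startswith("uniform"):
        _, a, b = config.release_depth.split(":")
        z = rng.uniform(float(a), float(b), len(x))
    elif config.release_depth == "seafloor+1":
        if field is None:
            raise ValueError("seafloor release depth needs the flow field")
        depth = lc.FieldSampler(field).seafloor_depth(x, y)
        z = np.where(depth >= 2.0, depth - 1.0, depth / 2.0)
    else:
        raise ValueError(f"unknown release depth rule {config.release_depth}")

    lag = np.zeros(len(x))
    if config.lag_max > 0:
        if beach_span_y is None:
            beach_span_y = (float(y.min()), float(y.max()))
        lag = np.array([lc.release_lag(yy, beach_span_y[0], beach_span_y[1],
                                       config.lag_max) for yy in y])

    group_ids = [areas[i][0] for i in src]
    table = pd.DataFrame({
        "particle_id": np.arange(len(x)),
        "release_point_id": pid,
        "release_group": group_ids,
        "x": x, "y": y, "z": z,
        "release_time": t, "lag": lag,
    })
    counts = table.groupby("release_group", sort=False).size().to_dict()
    return ReleaseSchedule(table=table, released_per_source=counts)


# ---------------------------------------------------------------------------
# Experiment driver
# ---------------------------------------------------------------------------

def settlement_target_polygons(
    config: ExperimentConfig,
    sites: Sequence[HabitatSite],
    primary_areas: Sequence[tuple[object, Polygon]] | None = None,
) -> list[tuple[object, Polygon]] | None:
    """Polygons a particle may settle on, labelled by target id.

    Population targets are labelled ``("pop", population_id)``, site targets
    ``("site", site_id)``, primary areas ``("area", label)``.
    """
    kind = config.settlement_targets
    if kind == "none":
        return None
    targets: list[tuple[object, Polygon]] = []
    if kind == "populations":
        by_pop: dict[int, list[Polygon]] = {}
        for s in sites:
            by_pop.setdefault(s.population_id, []).append(s.polygon)
        from shapely.ops import unary_union
        for pid in sorted(by_pop):
            targets.append((("pop", pid), unary_union(by_pop[pid])))
        return targets
    if kind in ("sites", "sites+areas"):
        targets.extend((("site", s.site_id), s.polygon) for s in sites)
    if kind == "sites+areas":
        for label, poly in (primary_areas or []):
            targets.append((("area", label), poly))
    return targets


@dataclass
class ExperimentResult:
    config: ExperimentConfig
    records: pd.DataFrame            # settlement records, all years, + year col
    released_per_source: dict        # release group -> count per year
    trajectories: dict               # year -> TrajectoryEnsemble (Experiment 1)


def run_experiment(
    config: ExperimentConfig,
    field: FlowField,
    sites: Sequence[HabitatSite],
    seed: int,
    beach: Polygon | None = None,
    primary_areas: Sequence[tuple[object, Polygon]] | None = None,
    n_points: int | None = None,
    particles_per_point: int | None = None,
    months: Sequence[str] | None = None,
    years: Sequence[int] | None = None,
    save_every: int = 4,
) -> ExperimentResult:
    """Run one experiment over its years (each year re-seeded from ``seed``).

    On a steady synthetic field the "years" are replicate seasons that differ
    only through the seeded randomness of release positions, depths and
    turbulence.
    """
    use_years = tuple(years) if years is not None else config.years
    if config.release_area == "beach":
        if beach is None:
            raise ValueError("experiment releases from the beach; pass its polygon")
        areas = [("beach", beach)]
    elif config.release_area == "primary_areas":
        if not primary_areas:
            raise ValueError("experiment releases from primary settlement "
                             "areas; none provided")
        areas = list(primary_areas)
    else:
        areas = [(s.site_id, s.polygon) for s in sites]

    targets = settlement_target_polygons(config, sites, primary_areas)
    site_index = lc.SiteIndex(targets) if targets is not None else None

    beach_span = None
    if config.release_area == "beach" and beach is not None:
        _, ymin, _, ymax = beach.bounds
        beach_span = (ymin, ymax)

    ss = np.random.SeedSequence(seed)
    year_seeds = {y: int(s.generate_state(1)[0] % (2**31 - 1))
                  for y, s in zip(use_years, ss.spawn(len(use_years)))}

    all_records = []
    trajectories = {}
    released = {}
    for year in use_years:
        yseed = year_seeds[year]
        rng = np.random.default_rng(yseed)
        sched = build_release_schedule(
            config, areas, rng, field=field,
            n_points=n_points, particles_per_point=particles_per_point,
            months=months, beach_span_y=beach_span,
        )
        icfg = lc.IntegrationConfig(
            pld_max=config.pld_max,
            competency_start=config.competency_start,
            direction=config.direction,
            diffusion=config.diffusion,
            sinking=config.sinking,
            sinking_velocity=config.sinking_velocity,
            seed=yseed,
            store_trajectories=(config.settlement_targets == "none"),
            save_every=save_every,
        )
        traj, records = lc.integrate(sched.table, field, site_index, icfg)
        records = records.merge(
            sched.table[["particle_id", "release_group"]], on="particle_id")
        records["year"] = year
        all_records.append(records)
        if traj is not None:
            trajectories[year] = traj
        for gid, cnt in sched.released_per_source.items():
            released.setdefault(gid, {})[year] = cnt

    return ExperimentResult(
        config=config,
        records=pd.concat(all_records, ignore_index=True),
        released_per_source=released,
        trajectories=trajectories,
    )


# ---------------------------------------------------------------------------
# Source contributions and their ANOVA
# ---------------------------------------------------------------------------

def source_contributions(
    records: pd.DataFrame,
    populations: dict[int, float] | Sequence[HabitatSite],
    per_area: bool = False,
) -> pd.DataFrame:
    """Percent contribution of each source population to total settlement.

    ``populations`` maps population_id -> area_km2 (or pass the habitat site
    list).  Rows: population_id, settled, percent, per-year percents and
    their standard deviation; with ``per_area`` the percents are divided by
    population area and renormalised to 100.
    """
    if not isinstance(populations, dict):
        populations = population_areas(populations)
    settled = records[records["status"] == "settled"].copy()
    if len(settled) == 0:
        import warnings
        warnings.warn("no settlers: empty contribution table", stacklevel=2)
        return pd.DataFrame(columns=["population_id", "settled", "percent"])
    settled["population_id"] = settled["settlement_site_id"].map(
        lambda t: t[1] if isinstance(t, tuple) and t[0] == "pop" else t)
    years = sorted(settled["year"].unique()) if "year" in settled else [None]

    def percents(df):
        counts = df.groupby("population_id").size()
        vals = counts.astype(float)
        if per_area:
            vals = vals / vals.index.map(lambda p: populations[p]).astype(float)
        return 100.0 * vals / vals.sum()

    total = percents(settled).rename("percent")
    out = pd.DataFrame({"population_id": total.index, "percent": total.values})
    out["settled"] = out["population_id"].map(
        settled.groupby("population_id").size()).astype(int)
    per_year = {}
    for y in years:
        sub = settled if y is None else settled[settled["year"] == y]
        p = percents(sub) if len(sub) else pd.Series(dtype=float)
        per_year[y] = out["population_id"].map(p).fillna(0.0)
        out[f"percent_{y}"] = per_year[y]
    if len(years) > 1:
        out["percent_std"] = np.std(
            np.column_stack([per_year[y] for y in years]), axis=1, ddof=1)
    out["area_km2"] = out["population_id"].map(populations)
    return out.sort_values("population_id").reset_index(drop=True)


def yearly_contribution_groups(contrib: pd.DataFrame) -> list[np.ndarray]:
    """Per-population arrays of yearly percent contributions (ANOVA groups)."""
    ycols = [c for c in contrib.columns if c.startswith("percent_")
             and c != "percent_std"]
    return [contrib.loc[i, ycols].to_numpy(dtype=float)
            for i in contrib.index]


def one_way_anova(groups: Sequence[np.ndarray]) -> tuple[float, int, int, float]:
    """Classical one-way ANOVA: (F, df_between, df_within, p).

    Degenerate input with zero between- and within-group variance returns
    F = 0, p = 1.
    """
    groups = [np.asarray(g, dtype=float) for g in groups]
    if len(groups) < 2 or any(len(g) < 2 for g in groups):
        raise ValueError("need >= 2 groups with >= 2 observations each")
    df1 = len(groups) - 1
    df2 = sum(len(g) for g in groups) - len(groups)
    allv = np.concatenate(groups)
    if np.ptp(allv) == 0:
        return 0.0, df1, df2, 1.0
    f, p = stats.f_oneway(*groups)
    if not np.isfinite(f):  # zero within-group variance only
        f, p = np.inf, 0.0
    return float(f), df1, df2, float(p)
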