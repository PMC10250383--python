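"""Particle kernel: interpolation, RK4, diffusion, boundaries, settlement."""

import numpy as np
import pandas as pd
import pytest

import musselflow as mf
from musselflow.lagrangian_core import (
    FieldSampler, IntegrationConfig, SiteIndex, _step_normals, integrate,
)

DAY = 86400.0


class TestInterpolation:
    def test_linear_in_x_field_interpolates_exactly(self, small_grid):
        # value at the midpoint of two nodes equals the mean of node values
        g = small_grid
        X, _ = np.meshgrid(g.x_centers, g.y_centers)
        u = 1e-6 * X
        f = mf.FlowField(grid=g, u=np.broadcast_to(u, (1, 3, g.ny, g.nx)).copy(),
                         v=np.zeros((1, 3, g.ny, g.nx)),
                         w=np.zeros((1, 3, g.ny, g.nx)),
                         mask=np.ones((g.ny, g.nx), bool),
                         bathymetry=np.full((g.ny, g.nx), 100.0))
        xm = 0.5 * (g.x_centers[3] + g.x_centers[4])
        u_mid, _, _ = mf.interpolate_velocity(f, (xm, 100e3, 5.0), 0.0)
        assert u_mid == pytest.approx(1e-6 * xm, rel=1e-12)

    def test_out_of_domain_raises(self, small_grid):
        f = mf.uniform_flow(small_grid, 0.1, 0.0)
        with pytest.raises(mf.OutOfDomainError):
            mf.interpolate_velocity(f, (-1.0, 100e3, 5.0), 0.0)

    def test_unsteady_field_linear_in_time(self):
        g = mf.build_grid((50e3, 50e3), (5e3, 5e3), time_axis=(0.0, 3600.0, 3))
        shp = (3, 1, g.ny, g.nx)
        u = np.zeros(shp)
        u[1] = 1.0
        u[2] = 2.0
        f = mf.FlowField(grid=g, u=u, v=np.zeros(shp), w=np.zeros(shp),
                         mask=np.ones((g.ny, g.nx), bool),
                         bathymetry=np.full((g.ny, g.nx), 50.0))
        uu, _, _ = mf.interpolate_velocity(f, (25e3, 25e3, 0.0), 1800.0)
        assert uu == pytest.approx(0.5)


class TestRK4:
    def test_exact_for_constant_field(self, small_grid):
        f = mf.uniform_flow(small_grid, 0.1, 0.0)
        p = mf.rk4_step((100e3, 100e3, 5.0), 0.0, 900.0, f)
        assert p == (100e3 + 90.0, 100e3, 5.0)

    def test_one_period_radial_drift_below_0p1_percent(self, solid_body):
        from conftest import rk4_orbit
        T = 2 * np.pi / 1e-4
        x, y, _ = rk4_orbit(solid_body, (310e3, 150e3, 0.0), 900.0, T)
        r = np.hypot(x - 300e3, y - 150e3)
        assert abs(r - 10e3) / 10e3 < 1e-3

    def test_fourth_order_convergence(self, solid_body):
        from conftest import rk4_orbit
        T = 2 * np.pi / 1e-4
        errs = []
        for dt in (900.0, 450.0):
            x, y, _ = rk4_orbit(solid_body, (310e3, 150e3, 0.0), dt, T)
            errs.append(np.hypot(x - 310e3, y - 150e3))
        assert 12.0 < errs[0] / errs[1] < 20.0

    def test_local_reversibility(self, solid_body):
        p = (310e3, 150e3, 0.0)
        q = mf.rk4_step(p, 0.0, 900.0, solid_body)
        r = mf.rk4_step(q, 900.0, -900.0, solid_body)
        assert np.hypot(r[0] - p[0], r[1] - p[1]) < 1e-3

    def test_out_of_domain_stage_raises(self, small_grid):
        f = mf.uniform_flow(small_grid, -10.0, 0.0)
        with pytest.raises(mf.OutOfDomainError):
            mf.rk4_step((100.0, 100e3, 5.0), 0.0, 900.0, f)


class TestDiffusion:
    def test_zero_diffusivity_is_identity(self):
        rng = np.random.default_rng(0)
        p = mf.diffusion_step((1.0, 2.0, 3.0), 0.0, 0.0, 900.0, 90.0, rng)
        assert p == (1.0, 2.0, 3.0)

    def test_horizontal_variance_matches_2kt(self):
        rng = np.random.default_rng(1)
        K, dt = 0.1176, 900.0
        n = 20000
        dx = np.array([mf.diffusion_step((0, 0, 0), K, 0.0, dt, 90.0, rng)[0]
                       for _ in range(n)])
        assert dx.var() == pytest.approx(2 * K * dt, rel=0.05)

    def test_vertical_variance_independent_of_substep_count(self):
        # sum of n independent increments has variance 2*Kv*dt exactly
        K, dt = 0.01, 900.0
        for sub in (90.0, 450.0, 900.0):
            rng = np.random.default_rng(2)
            dz = np.array([mf.diffusion_step((0, 0, 0), 0.0, K, dt, sub, rng)[2]
                           for _ in range(20000)])
            assert dz.var() == pytest.approx(2 * K * dt, rel=0.05)

    def test_counter_based_draws_partition_independent(self):
        full = _step_normals(42, 7, 100, 4)
        again = _step_normals(42, 7, 100, 4)
        assert np.array_equal(full, again)
        assert not np.array_equal(full, _step_normals(42, 8, 100, 4))


class TestSinkingAndBoundary:
    @pytest.mark.parametrize("w_s,dt,expected",
                             [(0.001, 900.0, 0.9), (0.0, 900.0, 0.0),
                              (0.001, 10000.0, 10.0)])
    def test_sinking_deepens_linearly(self, w_s, dt, expected):
        _, _, z = mf.sinking_step((0.0, 0.0, 5.0), w_s, dt)
        assert z - 5.0 == pytest.approx(expected)

    def test_land_move_rejected(self, coastal):
        _, field, _ = coastal
        prev = (78e3, 100e3, 5.0)
        hit_land = (95e3, 100e3, 5.0)
        assert mf.apply_boundary(prev, hit_land, field) == prev

    def test_open_water_move_accepted(self, coastal):
        _, field, _ = coastal
        prev = (50e3, 100e3, 5.0)
        prop = (51e3, 101e3, 6.0)
        assert mf.apply_boundary(prev, prop, field) == prop

    def test_surface_breach_clamps_to_zero(self, coastal):
        _, field, _ = coastal
        out = mf.apply_boundary((50e3, 100e3, 1.0), (50e3, 100e3, -2.0), field)
        assert out[2] == 0.0

    def test_closed_basin_contains_particles_30_days(self):
        # still water, land ring, strong random walk: nothing ever leaves
        g = mf.build_grid((50e3, 50e3), (5e3, 5e3), z_levels=(0.0, 10.0))
        mask = np.zeros((g.ny, g.nx), bool)
        mask[1:-1, 1:-1] = True
        bathy = np.where(mask, 20.0, 0.0)
        f = mf.FlowField(grid=g, u=np.zeros((1, 2, g.ny, g.nx)),
                         v=np.zeros((1, 2, g.ny, g.nx)),
                         w=np.zeros((1, 2, g.ny, g.nx)),
                         mask=mask, bathymetry=bathy)
        parts = pd.DataFrame({"particle_id": np.arange(20),
                              "release_time": 0.0,
                              "x": 25e3, "y": 25e3, "z": 5.0})
        cfg = IntegrationConfig(pld_max=30 * DAY, competency_start=30 * DAY,
                                horizontal_diffusivity=50.0, sinking=False,
                                seed=3)
        _, rec = integrate(parts, f, None, cfg)
        assert (rec["status"] == "expired").all()  # never removed
        assert rec["final_x"].between(5e3, 45e3).all()
        assert rec["final_y"].between(5e3, 45e3).all()


@pytest.fixture(scope="module")
def sites():
    return mf.generate_habitat([(10e3, 0), (10e3, 20e3)], 1, 4, 5000.0)


class TestSettlement:
    def test_precompetent_inside_site_is_ignored(self, sites):
        assert mf.check_settlement((7.5e3, 2.5e3, 5.0), 20 * DAY, sites,
                                   21 * DAY, 35 * DAY) is None

    def test_competent_inside_site_settles(self, sites):
        sid = mf.check_settlement((7.5e3, 2.5e3, 5.0), 25 * DAY, sites,
                                  21 * DAY, 35 * DAY)
        assert sid == sites[0].site_id

    def test_one_meter_outside_polygon_misses(self, sites):
        assert mf.check_settlement((4999.0, 2.5e3, 5.0), 25 * DAY, sites,
                                   21 * DAY, 35 * DAY) is None

    def test_site_index_prefers_first_polygon(self, sites):
        idx = SiteIndex(sites)
        hits = idx.locate(np.array([7.5e3]), np.array([2.5e3]))
        assert idx.ids[hits[0]] == sites[0].site_id


class TestReleaseLag:
    def test_linear_south_to_north(self):
        assert mf.release_lag(0.0, 0.0, 88e3) == 0.0
        assert mf.release_lag(88e3, 0.0, 88e3) == pytest.approx(5.5 * DAY)
        assert mf.release_lag(44e3, 0.0, 88e3) == pytest.approx(2.75 * DAY)

    def test_outside_beach_rejected(self):
        with pytest.raises(ValueError):
            mf.release_lag(-1.0, 0.0, 88e3)


class TestIntegrate:
    def test_null_dynamics_constant_trajectories(self, small_grid):
        f = mf.uniform_flow(small_grid, 0.0, 0.0)
        parts = pd.DataFrame({"particle_id": [0, 1], "release_time": 0.0,
                              "x": [100e3, 200e3], "y": 100e3, "z": 5.0})
        cfg = IntegrationConfig(pld_max=2 * DAY, competency_start=DAY,
                                diffusion=False, sinking=False,
                                store_trajectories=True, seed=0)
        traj, rec = integrate(parts, f, None, cfg)
        assert np.nanstd(traj.positions[:, :, 0], axis=1).max() == 0.0
        assert (rec["status"] == "expired").all()

    def test_forward_backward_round_trip(self, coastal):
        # deterministic advection retraces itself when reversed; released
        # offshore so the (irreversible) coastline rule never triggers
        _, field, _ = coastal
        rng = np.random.default_rng(5)
        n = 20
        parts = pd.DataFrame({
            "particle_id": np.arange(n), "release_time": 0.0,
            "x": rng.uniform(10e3, 55e3, n),
            "y": rng.uniform(100e3, 500e3, n), "z": 5.0})
        fwd_cfg = IntegrationConfig(pld_max=5 * DAY, competency_start=5 * DAY,
                                    diffusion=False, sinking=False, seed=0)
        _, fwd = integrate(parts, field, None, fwd_cfg)
        back = pd.DataFrame({
            "particle_id": np.arange(n), "release_time": 5 * DAY,
            "x": fwd["final_x"], "y": fwd["final_y"], "z": fwd["final_z"]})
        bwd_cfg = IntegrationConfig(pld_max=5 * DAY, competency_start=5 * DAY,
                                    direction="backward",
                                    diffusion=False, sinking=False, seed=0)
        _, bwd = integrate(back, field, None, bwd_cfg)
        disp = np.hypot(bwd["final_x"] - parts["x"], bwd["final_y"] - parts["y"])
        assert disp.max() < 1.0

    def test_trajectory_sample_count_bounded(self, small_grid):
        f = mf.uniform_flow(small_grid, 0.0, 0.0)
        parts = pd.DataFrame({"particle_id": [0], "release_time": 0.0,
                              "x": 100e3, "y": 100e3, "z": 5.0})
        cfg = IntegrationConfig(pld_max=35 * DAY, competency_start=21 * DAY,
                                diffusion=False, sinking=False,
                                store_trajectories=True, seed=0)
        traj, _ = integrate(parts, f, None, cfg)
        assert traj.positions.shape[1] <= 35 * DAY / 900 + 1 == 3361

    def test_conservation_and_competency_window(self, coastal):
        _, field, sites = coastal
        rng = np.random.default_rng(6)
        n = 200
        parts = pd.DataFrame({
            "particle_id": np.arange(n), "release_time": 0.0,
            "x": rng.uniform(74e3, 79e3, n),
            "y": rng.uniform(280e3, 360e3, n), "z": 5.0})
        cfg = IntegrationConfig(pld_max=35 * DAY, competency_start=21 * DAY,
                                seed=1)
        _, rec = integrate(parts, field, sites, cfg)
        counts = rec["status"].value_counts()
        assert counts.sum() == n
        settled = rec[rec["status"] == "settled"]
        assert (settled["age_final"] >= 21 * DAY).all()
        assert (settled["age_final"] <= 35 * DAY).all()
        assert settled["settlement_site_id"].notna().all()

    def test_fixed_seed_bit_identical(self, coastal):
        _, field, sites = coastal
        parts = pd.DataFrame({"particle_id": np.arange(50), "release_time": 0.0,
                              "x": 76e3, "y": np.linspace(280e3, 350e3, 50),
                              "z": 5.0})
        cfg = IntegrationConfig(pld_max=25 * DAY, competency_start=21 * DAY,
                                seed=9)
        _, r1 = integrate(parts, field, sites, cfg)
        _, r2 = integrate(parts, field, sites, cfg)
        pd.testing.assert_frame_equal(r1, r2)

    def test_backward_with_diffusion_warns(self, small_grid):
        f = mf.uniform_flow(small_grid, 0.0, 0.0)
        parts = pd.DataFrame({"particle_id": [0], "release_time": DAY,
                              "x": 100e3, "y": 100e3, "z": 5.0})
        cfg = IntegrationConfig(pld_max=DAY, competency_start=DAY,
                                direction="backward", diffusion=True,
                                sinking=False, seed=0)
        with pytest.warns(UserWarning, match="backward"):
            integrate(parts, f, None, cfg)

    def test_unsteady_field_too_short_rejected(self):
        g = mf.build_grid((50e3, 50e3), (5e3, 5e3), time_axis=(0.0, 3600.0, 2))
        shp = (2, 1, g.ny, g.nx)
        f = mf.FlowField(grid=g, u=np.zeros(shp), v=np.zeros(shp),
                         w=np.zeros(shp), mask=np.ones((g.ny, g.nx), bool),
                         bathymetry=np.full((g.ny, g.nx), 50.0))
        parts = pd.DataFrame({"particle_id": [0], "release_time": 0.0,
                              "x": 25e3, "y": 25e3, "z": 5.0})
        cfg = IntegrationConfig(pld_max=DAY, competency_start=DAY,
                                diffusion=False, sinking=False, seed=0)
        with pytest.raises(ValueError, match="time axis"):
            integrate(parts, f, None, cfg)
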