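"""Ellipsoid heat budget: geometry against a numerical surface integral,
hand-computed flux terms, solver correctness against a grid-scan oracle,
and the physical monotonicity / limiting behaviour of the equilibrium."""

import numpy as np
import pandas as pd
import pytest

from ectotemp import heatbudget as hb
from ectotemp import weather

SIGMA = hb.STEFAN_BOLTZMANN


def make_env(**kwargs):
    defaults = dict(T_air_2m=15.0, T_air_ground=15.0, T_ground=15.0,
                    wind_organism=0.5, S_direct=0.0, S_diffuse=0.0,
                    e_sky=0.95)
    defaults.update(kwargs)
    return hb.Environment(**defaults)


def ellipsoid_area_numeric(a, b, c, n=2000):
    """Numerical ellipsoid surface integral (independent oracle):
    integrate |r_θ × r_φ| over the parametric sphere."""
    theta = np.linspace(0, np.pi, n)
    phi = np.linspace(0, 2 * np.pi, n)
    th, ph = np.meshgrid(theta, phi, indexing="ij")
    st, ct = np.sin(th), np.cos(th)
    sp, cp = np.sin(ph), np.cos(ph)
    # cross-product magnitude of the parametric derivatives
    integrand = st * np.sqrt((b * c * cp * st) ** 2 + (a * c * sp * st) ** 2
                             + (a * b * ct) ** 2)
    return np.trapezoid(np.trapezoid(integrand, phi, axis=1), theta)


class TestGeometry:
    def test_sphere_closed_form(self):
        params = hb.OrganismParams(mass_g=1.0, axis_ratio=(1, 1, 1))
        geom = hb.body_geometry(params)
        r = (3.0 * 1e-6 / (4.0 * np.pi)) ** (1.0 / 3.0)
        assert geom.semi_axes[0] == pytest.approx(r, rel=1e-12)
        assert geom.surface_area == pytest.approx(4 * np.pi * r**2, rel=1e-9)
        assert geom.characteristic_dimension == pytest.approx(2 * r)

    def test_area_mass_scaling_law(self):
        a1 = hb.body_geometry(hb.OrganismParams(mass_g=1.0)).surface_area
        a2 = hb.body_geometry(hb.OrganismParams(mass_g=2.0)).surface_area
        assert a2 / a1 == pytest.approx(2 ** (2 / 3), rel=1e-9)

    def test_ellipsoid_area_vs_numerical_integral(self):
        geom = hb.body_geometry(hb.OrganismParams(mass_g=1.0, axis_ratio=(3, 1, 1)))
        a, b, c = geom.semi_axes
        exact = ellipsoid_area_numeric(a, b, c)
        assert geom.surface_area == pytest.approx(exact, rel=0.011)

    def test_nonpositive_mass_rejected(self):
        with pytest.raises(ValueError):
            hb.OrganismParams(mass_g=0.0)


class TestShortwave:
    def test_zero_radiation_zero_gain(self, default_params, default_geom):
        q = hb.absorbed_shortwave(make_env(), default_geom, default_params)
        assert q == 0.0

    def test_linear_in_absorptivity(self, default_geom):
        env = make_env(S_direct=500.0, S_diffuse=120.0)
        q_full = hb.absorbed_shortwave(env, default_geom,
                                       hb.OrganismParams(solar_absorptivity=0.9))
        q_half = hb.absorbed_shortwave(env, default_geom,
                                       hb.OrganismParams(solar_absorptivity=0.45))
        assert q_half == pytest.approx(q_full / 2, rel=1e-12)

    def test_diffuse_only_hand_value(self):
        """Diffuse-only gain on a sphere with no ground reflection:
        Q = a·S_diff·(A/2)·(1 − f_c)."""
        params = hb.OrganismParams(axis_ratio=(1, 1, 1), ground_albedo=0.0)
        geom = hb.body_geometry(params)
        env = make_env(S_diffuse=100.0)
        expected = 0.9 * 100.0 * (geom.surface_area / 2) * (1 - 0.2)
        assert hb.absorbed_shortwave(env, geom, params) == pytest.approx(expected, rel=1e-12)

    def test_beam_conversion_from_horizontal(self):
        """With solar elevation given, the horizontal direct flux is
        amplified by 1/sin(elevation) on the silhouette (no ground
        reflection, so the beam term is isolated)."""
        params = hb.OrganismParams(ground_albedo=0.0)
        geom = hb.body_geometry(params)
        env_low = make_env(S_direct=500.0, solar_elevation=30.0)
        env_high = make_env(S_direct=500.0, solar_elevation=90.0)
        q_low = hb.absorbed_shortwave(env_low, geom, params)
        q_high = hb.absorbed_shortwave(env_high, geom, params)
        assert q_low == pytest.approx(q_high * 2.0, rel=1e-9)


class TestLongwave:
    def test_blackbody_equilibrium(self, default_geom):
        """T_b = T_air = T_ground under unit emissivities: gain = loss."""
        params = hb.OrganismParams(thermal_emissivity=1.0, ground_emissivity=1.0)
        geom = hb.body_geometry(params)
        env = make_env(T_air_2m=20.0, T_ground=20.0, e_sky=1.0)
        gain, loss = hb.longwave_exchange(20.0, env, geom, params)
        assert gain == pytest.approx(loss, rel=1e-12)

    def test_both_terms_linear_in_emissivity(self, default_geom):
        env = make_env(T_air_2m=10.0, T_ground=25.0)
        p1 = hb.OrganismParams(thermal_emissivity=0.9)
        p2 = hb.OrganismParams(thermal_emissivity=0.45)
        g1, l1 = hb.longwave_exchange(30.0, env, default_geom, p1)
        g2, l2 = hb.longwave_exchange(30.0, env, default_geom, p2)
        assert g2 == pytest.approx(g1 / 2, rel=1e-12)
        assert l2 == pytest.approx(l1 / 2, rel=1e-12)

    def test_emission_hand_value(self):
        """Stefan–Boltzmann emission from the free surface only."""
        params = hb.OrganismParams(thermal_emissivity=0.95,
                                   ground_contact_fraction=0.2)
        geom = hb.body_geometry(params)
        _, loss = hb.longwave_exchange(30.0, make_env(), geom, params)
        expected = 0.95 * SIGMA * 303.15**4 * geom.surface_area * 0.8
        assert loss == pytest.approx(expected, rel=1e-12)


class TestConvection:
    def test_no_gradient_no_flux(self, default_geom):
        for wind in (0.0, 0.5, 10.0):
            env = make_env(T_air_ground=25.0, wind_organism=wind)
            assert hb.convective_loss(25.0, env, default_geom) == 0.0

    def test_power_law_in_wind(self, default_geom):
        """Within one Reynolds band, h grows as u^n: quadrupling the wind
        scales the flux by 4^0.466."""
        q1 = hb.convective_loss(30.0, make_env(wind_organism=0.5), default_geom)
        q4 = hb.convective_loss(30.0, make_env(wind_organism=2.0), default_geom)
        assert q4 / q1 == pytest.approx(4 ** 0.466, rel=1e-9)

    def test_hand_computed_correlation_chain(self):
        """u = 0.5 m/s, d = 0.02 m, ΔT = 10 °C: recompute Re → Nu → h → Q
        by hand with the documented air-property fits."""
        geom = hb.Geometry(semi_axes=(0.01, 0.005, 0.005), surface_area=5e-4,
                           characteristic_dimension=0.02, silhouette_area=1e-4,
                           contact_area=1e-4, free_area=4e-4)
        env = make_env(T_air_ground=20.0, wind_organism=0.5)
        film = 25.0  # (30 + 20)/2
        nu_air = 1.338e-5 + 9.19e-8 * film
        re = 0.5 * 0.02 / nu_air
        nu = 0.615 * re**0.466  # Re ≈ 638: the 40–4000 band
        h = nu * (0.02425 + 7.038e-5 * film) / 0.02
        expected = h * 4e-4 * 10.0
        assert hb.convective_loss(30.0, env, geom) == pytest.approx(expected, rel=1e-12)

    def test_still_air_floor(self, default_geom):
        """At zero wind the transfer coefficient floors at H_MIN."""
        env = make_env(T_air_ground=20.0, wind_organism=0.0)
        q = hb.convective_loss(30.0, env, default_geom)
        assert q == pytest.approx(hb.H_MIN * default_geom.free_area * 10.0, rel=1e-12)

    def test_negative_wind_rejected(self):
        with pytest.raises(ValueError):
            make_env(wind_organism=-1.0)


class TestConduction:
    def test_zero_contact_zero_flux(self):
        params = hb.OrganismParams(ground_contact_fraction=0.0)
        geom = hb.body_geometry(params)
        env = make_env(T_ground=40.0)
        assert hb.conductive_loss(30.0, env, geom, params) == 0.0

    def test_no_gradient_no_flux(self, default_params, default_geom):
        env = make_env(T_ground=30.0)
        assert hb.conductive_loss(30.0, env, default_geom, default_params) == 0.0

    def test_hand_value(self, default_params):
        geom = hb.Geometry(semi_axes=(0.01, 0.005, 0.005), surface_area=6e-4,
                           characteristic_dimension=0.02, silhouette_area=1.5e-4,
                           contact_area=1.2e-4, free_area=4.8e-4)
        env = make_env(T_ground=15.0)
        expected = (hb.K_SUBSTRATE / hb.T_BOUNDARY) * 1.2e-4 * 15.0
        assert hb.conductive_loss(30.0, env, geom, default_params) == pytest.approx(
            expected, rel=1e-12)


def random_environments(n, seed):
    rng = np.random.default_rng(seed)
    envs = []
    for _ in range(n):
        t_air = rng.uniform(0, 35)
        s_total = rng.uniform(0, 1000)
        diffuse_frac = rng.uniform(0.15, 1.0)
        envs.append(hb.Environment(
            T_air_2m=t_air,
            T_air_ground=t_air + rng.uniform(-2, 8),
            T_ground=t_air + rng.uniform(-2, 15),
            wind_organism=rng.uniform(0.05, 8.0),
            S_direct=s_total * (1 - diffuse_frac),
            S_diffuse=s_total * diffuse_frac,
            e_sky=rng.uniform(0.6, 1.0),
            solar_elevation=rng.uniform(10, 80),
        ))
    return envs


def grid_scan_equilibrium(env, geom, params, step=0.001):
    """Brute-force oracle: finest sign change of the net flux on a
    uniform temperature grid."""
    grid = np.arange(-50.0, 80.0 + step, step)
    q_net = hb.energy_balance(grid, env, geom, params).Q_net
    i = int(np.argmax(q_net <= 0.0))  # first non-positive: root just below
    return 0.5 * (grid[i - 1] + grid[i])


class TestEnergyBalance:
    def test_flux_sum_identity(self, default_params, default_geom):
        for env in random_environments(20, seed=1):
            b = hb.energy_balance(33.0, env, default_geom, default_params)
            total = b.Q_solar + b.Q_lw_gain - b.Q_lw_loss - b.Q_conv - b.Q_cond
            assert b.Q_net == pytest.approx(total, abs=1e-9)
            assert b.Q_solar >= 0 and b.Q_lw_loss >= 0

    def test_net_flux_strictly_decreasing_in_body_temperature(
            self, default_params, default_geom):
        tb = np.linspace(-50, 80, 500)
        for env in random_environments(5, seed=2):
            q = hb.energy_balance(tb, env, default_geom, default_params).Q_net
            assert np.all(np.diff(q) < 0)

    def test_bracket_straddles_root(self, default_params, default_geom):
        for env in random_environments(50, seed=3):
            assert hb.energy_balance(-50.0, env, default_geom, default_params).Q_net > 0
            assert hb.energy_balance(80.0, env, default_geom, default_params).Q_net < 0


class TestSolveEquilibrium:
    def test_uniform_blackbody_night_returns_air_temperature(self):
        """Calm night, all environmental temperatures 15 °C, blackbody
        sky: the body equilibrates with its surroundings."""
        params = hb.OrganismParams(thermal_emissivity=1.0, ground_emissivity=1.0)
        env = make_env(wind_organism=0.0, e_sky=1.0)
        res = hb.solve_equilibrium(env, params)
        assert res.T_b == pytest.approx(15.0, abs=0.01)
        assert abs(res.residual) < 1e-6

    def test_clear_sky_radiative_cooling_below_air(self, default_params):
        """No sun and a clear sky (low sky emissivity) pull the body
        below air temperature via net thermal emission."""
        env = make_env(e_sky=0.75)
        res = hb.solve_equilibrium(env, default_params)
        assert res.T_b < 15.0

    def test_agrees_with_grid_scan_oracle(self, default_params, default_geom):
        for env in random_environments(25, seed=4):
            res = hb.solve_equilibrium(env, default_params, default_geom)
            oracle = grid_scan_equilibrium(env, default_geom, default_params)
            assert res.T_b == pytest.approx(oracle, abs=0.01)

    def test_high_wind_couples_body_to_near_ground_air(self, default_params):
        env = make_env(T_air_2m=18.0, T_air_ground=18.0, T_ground=18.0,
                       wind_organism=50.0, e_sky=1.0)
        res = hb.solve_equilibrium(env, default_params)
        assert res.T_b == pytest.approx(18.0, abs=0.1)

    def test_tiny_absorptivity_removes_sun_dependence(self):
        params = hb.OrganismParams(solar_absorptivity=1e-9)
        shaded = hb.solve_equilibrium(make_env(), params)
        sunny = hb.solve_equilibrium(
            make_env(S_direct=700.0, S_diffuse=100.0, solar_elevation=60.0), params)
        assert sunny.T_b == pytest.approx(shaded.T_b, abs=1e-3)


class TestEquilibriumMonotonicity:
    def sweep(self, default_params=None, **sweeps):
        params = hb.OrganismParams()
        base = dict(T_air_2m=20.0, T_air_ground=22.0, T_ground=26.0,
                    wind_organism=1.0, S_direct=300.0, S_diffuse=80.0,
                    e_sky=0.85, solar_elevation=50.0)
        (key, values), = sweeps.items()
        out = []
        for v in values:
            kw = dict(base)
            if key == "S_total":
                kw["S_direct"], kw["S_diffuse"] = 0.8 * v, 0.2 * v
            else:
                kw[key] = v
            out.append(hb.solve_equilibrium(hb.Environment(**kw), params).T_b)
        return np.array(out)

    def test_nondecreasing_in_radiation(self):
        tb = self.sweep(S_total=np.linspace(0, 1000, 12))
        assert np.all(np.diff(tb) > 0)

    def test_nondecreasing_in_near_ground_air(self):
        tb = self.sweep(T_air_ground=np.linspace(10, 35, 10))
        assert np.all(np.diff(tb) > 0)

    def test_nondecreasing_in_ground_temperature(self):
        tb = self.sweep(T_ground=np.linspace(10, 45, 10))
        assert np.all(np.diff(tb) > 0)

    def test_wind_cools_a_warm_body(self):
        tb = self.sweep(wind_organism=np.array([0.2, 0.5, 1, 2, 4, 8]))
        assert np.all(np.diff(tb) < 0)  # T_b > T_air_ground throughout


class TestRunSeries:
    def test_constant_environment_constant_body_temperature(self):
        frame = pd.DataFrame({
            "timestamp": pd.date_range("2019-06-01", periods=24, freq="h"),
            "T_air_2m": 18.0, "T_air_ground": 19.0, "T_ground": 21.0,
            "wind_organism": 0.8, "S_direct": 0.0, "S_diffuse": 50.0,
            "e_sky": 0.9, "precip": 0.0, "solar_elevation": np.nan,
        })
        out = hb.run_series(frame)
        assert out["T_b"].nunique() == 1

    def test_matches_scalar_solver(self, one_season, default_params):
        sample = one_season.iloc[::97].reset_index(drop=True)
        series = hb.run_series(sample, default_params)
        for i in [0, 3, 7, 11]:
            row = sample.iloc[i]
            env = hb.Environment(
                T_air_2m=row.T_air_2m, T_air_ground=row.T_air_ground,
                T_ground=row.T_ground, wind_organism=row.wind_organism,
                S_direct=row.S_direct, S_diffuse=row.S_diffuse,
                e_sky=row.e_sky, solar_elevation=row.solar_elevation)
            scalar = hb.solve_equilibrium(env, default_params)
            assert series["T_b"].iloc[i] == pytest.approx(scalar.T_b, abs=1e-6)

    def test_missing_forcing_yields_missing_body_temperature(self, one_season):
        frame = one_season.iloc[:48].copy().reset_index(drop=True)
        frame.loc[10, "wind_organism"] = np.nan
        out = hb.run_series(frame)
        assert np.isnan(out["T_b"].iloc[10])
        assert np.isfinite(out["T_b"].drop(10)).all()

    def test_flux_audit_reverifies_balance(self, one_season):
        out = hb.run_series(one_season.iloc[:72], flux_audit=True)
        residual = (out["Q_solar"] + out["Q_lw_gain"] - out["Q_lw_loss"]
                    - out["Q_conv"] - out["Q_cond"])
        assert np.nanmax(np.abs(residual)) < 1e-6

    def test_clear_day_peak_tracks_radiation_peak(self, one_season):
        s_total = one_season["S_direct"] + one_season["S_diffuse"]
        daily = s_total.groupby(np.arange(len(s_total)) // 24).max()
        day = int(daily.idxmax())  # clearest day of the season
        sl = slice(24 * day, 24 * (day + 1))
        frame = one_season.iloc[sl].reset_index(drop=True)
        tb = hb.run_series(frame)["T_b"]
        t_peak_rad = int(np.argmax(frame["S_direct"] + frame["S_diffuse"]))
        t_peak_tb = int(np.argmax(tb))
        assert abs(t_peak_tb - t_peak_rad) <= 2
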