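"""Generators: closed-form exactness, seeding, and planted ground truth."""

import numpy as np
import pytest

from memdomain.fcs import diffusion_law_from_series
from memdomain.synthetic import (ACFModelParams, GUVImageSpec, OpticsSpec,
                                 SyntheticTruth, default_lag_grid,
                                 fibonacci_sphere, gen_acf_curve,
                                 gen_brownian_trajectories,
                                 gen_diffusion_time_grid, gen_guv_stack,
                                 spherical_cap_area, spherical_stripe_area)


class TestACFCurves:
    def test_noiseless_closed_forms(self):
        # at tau = tau_d the Lorentzian factor is 1/2
        c = gen_acf_curve(ACFModelParams(10.0, [1.0]), lags=[1e-3])
        assert c.g[0] == pytest.approx(0.05, rel=1e-12)
        # amplitude 1/N at vanishing lag
        c = gen_acf_curve(ACFModelParams(10.0, [1.0, 100.0], [0.5, 0.5]),
                          lags=[1e-12])
        assert c.g[0] == pytest.approx(0.1, rel=1e-9)
        # direct evaluation: N=5, tau_d=2 ms at tau=6 ms -> (1/5)*(1/4)
        c = gen_acf_curve(ACFModelParams(5.0, [2.0]), lags=[6e-3])
        assert c.g[0] == pytest.approx(0.05, rel=1e-12)

    def test_seeded_reproducibility_and_noise(self):
        p = ACFModelParams(8.0, [2.5])
        a = gen_acf_curve(p, noise_scale=0.05, seed=42)
        b = gen_acf_curve(p, noise_scale=0.05, seed=42)
        assert np.array_equal(a.g, b.g)
        clean = gen_acf_curve(p, noise_scale=0.0)
        # multiplicative noise: relative scatter about the clean curve
        rel = a.g / clean.g - 1.0
        assert 0.02 < np.std(rel) < 0.10

    def test_invalid_inputs(self):
        with pytest.raises(ValueError):
            gen_acf_curve(ACFModelParams(10.0, [1.0]), lags=[])
        with pytest.raises(ValueError):
            gen_acf_curve(ACFModelParams(10.0, [1.0]), noise_scale=-0.1)
        with pytest.raises(ValueError):
            ACFModelParams(10.0, [2.0, 1.0], [0.5, 0.5])   # not ascending
        with pytest.raises(ValueError):
            ACFModelParams(10.0, [1.0, 2.0], [0.6, 0.6])   # fractions != 1
        with pytest.raises(ValueError):
            OpticsSpec(waist_w0=0.25, z_offsets=[0.0, 0.5, 1.0])  # < 5


class TestDiffusionTimeGrids:
    def test_focus_value_closed_form(self):
        # tau_d(0) = omega0^2/(4 D): 0.04/20 s = 2 ms
        truth = SyntheticTruth(d_eff=5.0)
        opt = OpticsSpec(waist_w0=0.2)
        series = gen_diffusion_time_grid(truth, [opt], n_vesicles=1)
        s = series[0]
        i0 = np.argmin(np.abs(s.z))
        assert s.tau_d[i0] == pytest.approx(2.0, rel=1e-12)

    def test_even_in_z(self):
        truth = SyntheticTruth(d_eff=3.0, t0=0.5, kind="domain")
        opt = OpticsSpec(waist_w0=0.3, z_offsets=[-2, -1, 0, 1, 2])
        s = gen_diffusion_time_grid(truth, [opt], n_vesicles=1)[0]
        assert np.allclose(s.tau_d, s.tau_d[::-1], rtol=1e-12)

    def test_noiseless_roundtrip_recovers_popc_diffusion_law(self):
        truth = SyntheticTruth(d_eff=6.46, t0=0.14, kind="domain")
        optics = [OpticsSpec(waist_w0=w) for w in (0.2, 0.25, 0.3, 0.35, 0.4)]
        series = gen_diffusion_time_grid(truth, optics, n_vesicles=5)
        law = diffusion_law_from_series(series)
        assert law.d_eff == pytest.approx(6.46, rel=1e-9)
        assert law.t0 == pytest.approx(0.14, abs=1e-9)

    def test_unphysical_negative_t0_rejected(self):
        truth = SyntheticTruth(d_eff=5.0, t0=-10.0, kind="meshwork")
        with pytest.raises(ValueError):
            gen_diffusion_time_grid(truth, [OpticsSpec(waist_w0=0.2)])


class TestBrownian:
    def test_zero_diffusion_is_stationary(self):
        traj = gen_brownian_trajectories(0.0, n=5, steps=20, dt=1e-3, seed=0)
        assert np.all(traj.positions == 0.0)

    def test_single_step_variance(self):
        # Var(dx) = 2 D dt = 0.002 um^2 per axis
        traj = gen_brownian_trajectories(1.0, n=100_000, steps=2, dt=1e-3,
                                         seed=7)
        step = traj.positions[:, 1, :] - traj.positions[:, 0, :]
        var = step.var(axis=0)
        se = 0.002 * np.sqrt(2 / (100_000 - 1))
        assert np.all(np.abs(var - 0.002) < 3 * se)

    def test_determinism(self):
        a = gen_brownian_trajectories(2.0, n=3, steps=50, dt=0.01, seed=9)
        b = gen_brownian_trajectories(2.0, n=3, steps=50, dt=0.01, seed=9)
        assert np.array_equal(a.positions, b.positions)


class TestGUVStacks:
    def test_planted_cap_areas_are_analytic(self):
        # 60 deg cap on R=10: 2 pi R^2 (1 - cos 60) = 100 pi
        assert spherical_cap_area(10.0, np.deg2rad(60)) == pytest.approx(
            100 * np.pi, rel=1e-12)
        # hemisphere: half the sphere
        assert spherical_cap_area(10.0, np.pi / 2) == pytest.approx(
            2 * np.pi * 100, rel=1e-12)
        spec = GUVImageSpec(radius=10.0, domain_plan=[
            ("cap", np.deg2rad(60), (0.0, 0.0, 1.0))], seed=0)
        _, truth = gen_guv_stack(spec)
        assert truth.domains[0].area == pytest.approx(100 * np.pi, rel=1e-12)

    def test_stripe_area_closed_form(self):
        width = np.deg2rad(30)
        assert spherical_stripe_area(5.0, width) == pytest.approx(
            4 * np.pi * 25 * np.sin(width / 2), rel=1e-12)

    def test_full_coverage_rejected(self):
        spec = GUVImageSpec(radius=5.0, domain_plan=[
            ("cap", np.deg2rad(179), (0.0, 0.0, 1.0)),
            ("cap", np.deg2rad(179), (0.0, 0.0, -1.0))], seed=0)
        with pytest.raises(ValueError):
            gen_guv_stack(spec)

    def test_stack_determinism_and_dtype(self):
        spec = GUVImageSpec(radius=3.0, voxel_size=(0.3, 0.3, 0.3), seed=5)
        a, _ = gen_guv_stack(spec)
        b, _ = gen_guv_stack(spec)
        assert np.array_equal(a.data, b.data)
        assert a.data.dtype == np.uint16


def test_fibonacci_sphere_is_near_uniform():
    pts = fibonacci_sphere(2000)
    assert np.allclose(np.linalg.norm(pts, axis=1), 1.0, atol=1e-12)
    # octant occupancies within 10% of each other
    counts = [np.sum((pts[:, 0] > 0) & (pts[:, 1] > 0) & (pts[:, 2] > 0))]
    assert abs(counts[0] - 250) < 25


def test_default_lag_grid_shape():
    lags = default_lag_grid()
    assert lags.size == 150 and lags[0] == pytest.approx(1e-6)
    assert np.all(np.diff(np.log(lags)) > 0)
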