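"""svzFCS analysis: ACF fits, model selection, z-scan, diffusion law."""

import numpy as np
import pytest

from memdomain.fcs import (ACFCurve, ZScanConcaveError, ZScanSeries,
                           VesicleTau, acf_model, aggregate_vesicles,
                           classify_confinement, diffusion_law_from_series,
                           fit_acf, fit_diffusion_law, fit_zscan,
                           select_population_model, DiffusionLaw)
from memdomain.synthetic import (ACFModelParams, OpticsSpec, SyntheticTruth,
                                 default_lag_grid, gen_acf_curve,
                                 gen_diffusion_time_grid)


class TestACFFitting:
    def test_noiseless_one_population_exact(self):
        curve = gen_acf_curve(ACFModelParams(10.0, [1.0]))
        fit = fit_acf(curve, 1)
        assert fit.n_particles == pytest.approx(10.0, rel=1e-6)
        assert fit.tau_d[0] == pytest.approx(1.0, rel=1e-6)
        assert fit.residual_sse < 1e-16

    def test_noiseless_two_population_recovery(self):
        # fast/slow contrast like the fluid vs gel populations
        curve = gen_acf_curve(ACFModelParams(10.0, [0.6, 94.0], [0.5, 0.5]))
        fit = fit_acf(curve, 2)
        assert fit.tau_d[0] == pytest.approx(0.6, rel=1e-4)
        assert fit.tau_d[1] == pytest.approx(94.0, rel=1e-4)
        assert fit.fractions[0] == pytest.approx(0.5, abs=1e-4)

    def test_two_population_model_with_unit_fraction_matches_one_population(self):
        lags = default_lag_grid(60)
        one = acf_model(lags, 8.0, [3.0], [1.0])
        two = acf_model(lags, 8.0, [3.0, 50.0], [1.0, 0.0])
        assert np.allclose(one, two, rtol=1e-14)

    def test_overfitting_one_population_truth_degenerates(self):
        curve = gen_acf_curve(ACFModelParams(10.0, [2.0]))
        fit2 = fit_acf(curve, 2)
        ratio = fit2.tau_d[1] / fit2.tau_d[0]
        minor = min(fit2.fractions)
        assert ratio < 5.0 or minor < 0.1 or \
            abs(fit2.tau_d[1] - fit2.tau_d[0]) < 3 * max(fit2.se_tau_d)

    def test_fit_input_guards(self):
        with pytest.raises(ValueError):
            fit_acf(ACFCurve(lags=[1e-4, 2e-4, 3e-4], g=[1, 2, 3]), 1)
        lags = default_lag_grid(20)
        with pytest.raises(ValueError):
            fit_acf(ACFCurve(lags=lags, g=np.ones_like(lags)), 1)


class TestModelSelection:
    def test_clear_two_population_curve_detected(self):
        curve = gen_acf_curve(ACFModelParams(10.0, [0.6, 94.0], [0.5, 0.5]),
                              noise_scale=0.02, seed=3)
        assert select_population_model(curve) == 2

    def test_nearby_times_merge_into_one_apparent_population(self):
        # tau ratio 1.2: indistinguishable on the autocorrelation curve
        curve = gen_acf_curve(ACFModelParams(10.0, [1.0, 1.2], [0.5, 0.5]),
                              noise_scale=0.02, seed=4)
        assert select_population_model(curve) == 1

    def test_one_population_truth_rarely_upgraded(self):
        hits = 0
        for seed in range(40):
            curve = gen_acf_curve(ACFModelParams(10.0, [2.0]),
                                  noise_scale=0.02, seed=seed)
            hits += select_population_model(curve) == 2
        assert hits <= 4    # false-positive rate compatible with alpha = 0.05


class TestZScan:
    def test_exact_symmetric_parabola(self):
        s = ZScanSeries(z=[-2, -1, 0, 1, 2], tau_d=[4.4, 4.1, 4.0, 4.1, 4.4],
                        waist=0.25)
        vt = fit_zscan(s)
        assert vt.tau_min == pytest.approx(4.0, abs=1e-12)
        assert vt.weight == 5

    def test_offset_vertex_recovered(self):
        z = np.linspace(-1.5, 1.5, 7)
        tau = 0.2 * (z - 0.3) ** 2 + 2.5
        vt = fit_zscan(ZScanSeries(z=z, tau_d=tau, waist=0.3))
        assert vt.tau_min == pytest.approx(2.5, abs=1e-10)
        assert vt.z0 == pytest.approx(0.3, abs=1e-10)

    def test_translation_invariance_in_z(self):
        z = np.linspace(-2, 2, 9)
        tau = 0.15 * (z - 0.2) ** 2 + 3.0
        a = fit_zscan(ZScanSeries(z=z, tau_d=tau, waist=0.3))
        b = fit_zscan(ZScanSeries(z=z + 5.0, tau_d=tau, waist=0.3))
        assert a.tau_min == pytest.approx(b.tau_min, abs=1e-9)
        assert b.z0 == pytest.approx(a.z0 + 5.0, abs=1e-9)

    def test_concave_series_rejected(self):
        z = np.linspace(-2, 2, 5)
        with pytest.raises(ZScanConcaveError):
            fit_zscan(ZScanSeries(z=z, tau_d=5.0 - 0.5 * z, waist=0.25))


class TestAggregation:
    def test_identical_values(self):
        taus = [VesicleTau(2.0, 5, 0.25), VesicleTau(2.0, 7, 0.25)]
        mean, sd = aggregate_vesicles(taus)
        assert (mean, sd) == (2.0, 0.0)

    def test_hand_computed_weighted_mean(self):
        taus = [VesicleTau(1.0, 1, 0.3), VesicleTau(3.0, 3, 0.3)]
        mean, _ = aggregate_vesicles(taus)
        assert mean == pytest.approx(2.5)

    def test_permutation_invariance(self):
        taus = [VesicleTau(1.5, 5, 0.3), VesicleTau(2.5, 6, 0.3),
                VesicleTau(2.0, 7, 0.3)]
        assert aggregate_vesicles(taus) == aggregate_vesicles(taus[::-1])

    def test_mixed_waists_rejected(self):
        with pytest.raises(ValueError):
            aggregate_vesicles([VesicleTau(1.0, 5, 0.2),
                                VesicleTau(1.0, 5, 0.3)])


class TestDiffusionLaw:
    def test_exact_line_inversion(self):
        pts = [(w2, 1e3 * w2 / (4 * 5.0), 0.0) for w2 in (0.04, 0.09, 0.16)]
        law = fit_diffusion_law(pts)
        assert law.d_eff == pytest.approx(5.0, rel=1e-12)
        assert law.t0 == pytest.approx(0.0, abs=1e-12)

    def test_matches_weighted_least_squares_oracle(self, rng):
        import statsmodels.api as sm
        for _ in range(10):
            x = rng.uniform(0.02, 0.3, 6)
            y = 1e3 * x / (4 * rng.uniform(2, 8)) + rng.normal(0, 0.2, 6)
            sd = rng.uniform(0.05, 0.5, 6)
            y = np.abs(y) + 0.5
            law = fit_diffusion_law(list(zip(x, y, sd)))
            res = sm.WLS(y, sm.add_constant(x), weights=1.0 / sd**2).fit()
            slope = res.params[1]
            assert 1e3 / (4 * slope) == pytest.approx(law.d_eff, rel=1e-10)
            assert res.params[0] == pytest.approx(law.t0, rel=1e-10)
            assert res.bse[0] == pytest.approx(law.se_t0, rel=1e-8)

    def test_nonpositive_slope_is_failure(self):
        pts = [(0.04, 5.0, 0.1), (0.09, 4.0, 0.1), (0.16, 3.0, 0.1)]
        with pytest.raises(ValueError):
            fit_diffusion_law(pts)

    def test_zero_sd_falls_back_to_unweighted(self):
        pts = [(0.04, 2.0, 0.0), (0.09, 4.5, 0.1), (0.16, 8.0, 0.1)]
        law = fit_diffusion_law(pts)
        assert law.d_eff > 0


class TestConfinementClassification:
    @pytest.mark.parametrize("t0, se, expected", [
        (0.14, 0.12, "free"),             # homogeneous POPC membrane
        (1.14, 0.42, "domain_confined"),  # transient trapping in nanodomains
        (-0.92, 0.23, "meshwork"),        # barrier fences between domains
    ])
    def test_reference_intercepts(self, t0, se, expected):
        law = DiffusionLaw(d_eff=5.0, t0=t0, se_d_eff=0.1, se_t0=se)
        assert classify_confinement(law, alpha=0.05) == expected

    def test_se_guard(self):
        law = DiffusionLaw(d_eff=5.0, t0=0.1, se_d_eff=0.1, se_t0=0.0)
        with pytest.raises(ValueError):
            classify_confinement(law)


def test_end_to_end_recovery_with_noise():
    """Median D within 5% and t0 within 0.2 ms at 5% diffusion-time noise."""
    truth = SyntheticTruth(d_eff=3.45, t0=1.14, kind="domain")
    optics = [OpticsSpec(waist_w0=w) for w in (0.2, 0.25, 0.3, 0.35, 0.4)]
    ds, t0s = [], []
    for seed in range(30):
        series = gen_diffusion_time_grid(truth, optics, n_vesicles=5,
                                         noise_cv=0.05, seed=seed)
        law = diffusion_law_from_series(series)
        ds.append(law.d_eff)
        t0s.append(law.t0)
    assert abs(np.median(ds) - 3.45) / 3.45 < 0.05
    assert abs(np.median(t0s) - 1.14) < 0.2
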