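"""Core CH4 fluxes and temperature/salinity response fitting."""

import datetime as dt
import math
import warnings

import numpy as np
import pytest
from scipy import constants as spc

from deltacarbon import methane


def make_core(**kw):
    defaults = dict(
        site_id="s",
        date=dt.date(2016, 6, 1),
        sediment_depth_cm=7.5,
        water_depth_cm=20.0,
        duration_d=2.0,
        ch4_ppm_start=0.0,
        ch4_ppm_end=500.0,
        incubation_temp_c=20.0,
    )
    defaults.update(kw)
    return methane.CoreIncubation(**defaults)


class TestHeadspaceVolume:
    def test_cylinder_volume(self):
        assert methane.headspace_volume(make_core()) == pytest.approx(0.2827, abs=1e-4)

    def test_alternate_geometry(self):
        core = make_core(sediment_depth_cm=5.0, water_depth_cm=25.0)
        assert methane.headspace_volume(core) == pytest.approx(0.2513, abs=1e-4)

    def test_no_headspace_rejected(self):
        with pytest.raises(ValueError):
            make_core(sediment_depth_cm=25.0, water_depth_cm=25.0)


class TestPpmToMass:
    def test_zero_ppm(self):
        assert methane.ppm_to_mass_c(0.0, 1.0, 20.0) == 0.0

    def test_molar_volume_limit(self):
        # pure CH4 filling one molar volume at STP is one mole of carbon
        mass = methane.ppm_to_mass_c(1e6, 22.414, 0.0, 1.0)
        assert mass == pytest.approx(12011.0, rel=1e-3)

    def test_against_pv_rt_oracle(self):
        """Independent PV=nRT computation in SI units via scipy constants."""
        mol = (500e-6 * spc.atm * 0.2827e-3) / (spc.R * 293.15)
        expected_mg = mol * 12.011 * 1000
        assert methane.ppm_to_mass_c(500.0, 0.2827, 20.0) == pytest.approx(
            expected_mg, rel=1e-6
        )
        assert expected_mg == pytest.approx(0.0706, abs=2e-4)


class TestCoreFlux:
    def test_zero_accumulation(self):
        assert methane.core_flux(make_core(ch4_ppm_end=0.0)) == 0.0

    def test_worked_chain(self):
        # 500 ppm into 0.2827 L at 20 degC over 2 d, footprint pi*(2 cm)^2
        flux = methane.core_flux(make_core())
        assert flux == pytest.approx(28.1, abs=0.1)

    def test_doubling_duration_halves_flux(self):
        f2 = methane.core_flux(make_core(duration_d=2.0))
        f4 = methane.core_flux(make_core(duration_d=4.0))
        assert f4 == pytest.approx(f2 / 2.0, rel=1e-12)

    def test_negative_accumulation_flagged(self):
        core = make_core(ch4_ppm_start=500.0, ch4_ppm_end=100.0)
        with pytest.warns(UserWarning, match="methanotrophy"):
            assert methane.core_flux(core) < 0

    def test_geometry_unit_consistency(self):
        """Scaling the tube diameter changes headspace and footprint consistently."""
        thin = make_core(tube_diameter_cm=4.0)
        wide = make_core(tube_diameter_cm=8.0)
        # same ppm accumulation in 4x the volume over 4x the area: equal flux
        assert methane.core_flux(wide) == pytest.approx(
            methane.core_flux(thin), rel=1e-12
        )


class TestSiteFlux:
    def test_mean_of_replicates(self):
        cores = [make_core(ch4_ppm_end=e) for e in (400.0, 500.0, 600.0)]
        rate = methane.site_flux(cores)
        fluxes = [methane.core_flux(c) for c in cores]
        assert rate.value == pytest.approx(np.mean(fluxes))
        assert rate.sd == pytest.approx(np.std(fluxes, ddof=1))
        assert rate.n_replicates == 3
        assert rate.process == "CH4"

    def test_empty_rejected(self):
        with pytest.raises(ValueError):
            methane.site_flux([])


class TestTemperatureFit:
    def test_exact_recovery_on_model_class(self):
        temps = np.repeat([14.0, 20.0, 25.0, 30.0], 3)
        fluxes = 1.0 * np.exp(0.1 * temps)
        fit = methane.fit_temperature_response(temps, fluxes)
        assert fit.a == pytest.approx(1.0, abs=1e-6)
        assert fit.b == pytest.approx(0.1, abs=1e-6)
        assert fit.r == pytest.approx(1.0, abs=1e-9)
        assert fit.p_value < 1e-6

    def test_constant_flux_gives_zero_exponent(self):
        temps = [14.0, 20.0, 25.0, 30.0]
        fit = methane.fit_temperature_response(temps, [5.0] * 4)
        assert fit.b == pytest.approx(0.0, abs=1e-8)

    def test_degenerate_temperatures_rejected(self):
        with pytest.raises(ValueError):
            methane.fit_temperature_response([20.0] * 5, [1, 2, 3, 4, 5])

    def test_noisy_recovery_median_within_ten_percent(self):
        """Simulation oracle: 100 experiments, 4 temps x 5 reps, CV 20%."""
        true_a, true_b, cv = 2.0, 0.12, 0.2
        sigma = math.sqrt(math.log(1 + cv**2))
        temps = np.repeat([14.0, 20.0, 25.0, 30.0], 5)
        estimates = []
        for seed in range(100):
            rng = np.random.default_rng(seed)
            noise = rng.lognormal(-sigma**2 / 2, sigma, temps.size)
            fit = methane.fit_temperature_response(
                temps, true_a * np.exp(true_b * temps) * noise
            )
            estimates.append(fit.b)
        assert abs(np.median(estimates) - true_b) / true_b < 0.10
        assert np.median(estimates) > 0

    def test_interval_coverage_for_exponent(self):
        """Nominal 95% intervals for b cover the truth at close-to-nominal rate."""
        from scipy import stats

        true_b, cv = 0.12, 0.2
        sigma = math.sqrt(math.log(1 + cv**2))
        temps = np.repeat([14.0, 20.0, 25.0, 30.0], 5)
        tcrit = stats.t.ppf(0.975, temps.size - 2)
        hits = 0
        for seed in range(100):
            rng = np.random.default_rng(1000 + seed)
            noise = rng.lognormal(-sigma**2 / 2, sigma, temps.size)
            fit = methane.fit_temperature_response(
                temps, 2.0 * np.exp(true_b * temps) * noise
            )
            if abs(fit.b - true_b) <= tcrit * fit.b_se:
                hits += 1
        assert 88 <= hits <= 99


class TestSalinityFit:
    def test_exact_recovery(self):
        x = np.repeat([10.0, 30.0, 60.0, 120.0], 3)
        fit = methane.fit_salinity_response(x, 100.0 * x**-0.8)
        assert fit.a == pytest.approx(100.0, rel=1e-6)
        assert fit.b == pytest.approx(-0.8, abs=1e-6)
        assert fit.r == pytest.approx(1.0, abs=1e-9)

    def test_flux_independent_of_salinity(self):
        fit = methane.fit_salinity_response([10.0, 30.0, 60.0], [7.0] * 3)
        assert fit.b == pytest.approx(0.0, abs=1e-8)

    def test_zero_conductivity_excluded_with_warning(self):
        with pytest.warns(UserWarning, match="non-positive"):
            fit = methane.fit_salinity_response(
                [0.0, 10.0, 30.0, 60.0, 120.0], [1.0, 100 * 10**-0.8, 100 * 30**-0.8, 100 * 60**-0.8, 100 * 120**-0.8]
            )
        assert fit.n_points == 4
        assert fit.b == pytest.approx(-0.8, abs=1e-6)

    def test_noisy_recovery_median_within_fifteen_percent(self):
        true_b, cv = -0.8, 0.2
        sigma = math.sqrt(math.log(1 + cv**2))
        x = np.repeat([6.0, 15.0, 31.0, 62.0], 5)
        estimates = []
        for seed in range(100):
            rng = np.random.default_rng(seed)
            noise = rng.lognormal(-sigma**2 / 2, sigma, x.size)
            fit = methane.fit_salinity_response(x, 200.0 * x**true_b * noise)
            estimates.append(fit.b)
        assert abs(np.median(estimates) - true_b) / abs(true_b) < 0.15
        assert np.median(estimates) < 0


class TestPredictResponse:
    def test_exponential_at_origin_and_e(self):
        fit = methane.ResponseFit("exponential_temperature", a=1.0, b=0.1, r=1.0, p_value=0.0, n_points=4)
        assert methane.predict_response(fit, 0.0) == pytest.approx(1.0)
        assert methane.predict_response(fit, 10.0) == pytest.approx(math.e, rel=1e-9)

    def test_power_at_unity(self):
        fit = methane.ResponseFit("power_salinity", a=42.0, b=-0.8, r=1.0, p_value=0.0, n_points=4)
        assert methane.predict_response(fit, 1.0) == pytest.approx(42.0)

    def test_monotonicity_matches_exponent_sign(self):
        exp_fit = methane.ResponseFit("exponential_temperature", 2.0, 0.12, 1.0, 0.0, 4)
        pow_fit = methane.ResponseFit("power_salinity", 100.0, -0.8, 1.0, 0.0, 4)
        t = np.linspace(5, 35, 50)
        assert np.all(np.diff(methane.predict_response(exp_fit, t)) > 0)
        x = np.linspace(1, 100, 50)
        assert np.all(np.diff(methane.predict_response(pow_fit, x)) < 0)

    def test_seasonal_prediction_peaks_in_warm_period(self):
        """The fitted exponential applied to a seasonal temperature series
        predicts its maximum flux in the warmest months."""
        from deltacarbon.synth import water_temperature

        fit = methane.ResponseFit("exponential_temperature", 2.0, 0.12, 1.0, 0.0, 4)
        dates = [dt.date(2016, 1, 1) + dt.timedelta(days=15 + 30 * m) for m in range(12)]
        fluxes = [float(methane.predict_response(fit, water_temperature(d))) for d in dates]
        assert dates[int(np.argmax(fluxes))].month in (7, 8)
        assert min(fluxes) == pytest.approx(
            float(methane.predict_response(fit, min(water_temperature(d) for d in dates))),
            rel=1e-9,
        )
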