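"""Oxygen incubation processing: rates, stoichiometry, scaling, day length."""

import datetime as dt
import math

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from deltacarbon import oxygen


def make_campaign(**kw):
    defaults = dict(
        site_id="s",
        date=dt.date(2016, 6, 1),
        daylight_h=14.0,
        water_temp_c=22.0,
        conductivity_ms_cm=30.0,
        depth_m=0.45,
    )
    defaults.update(kw)
    return oxygen.SamplingCampaign(**defaults)


def make_incubation(campaign=None, **kw):
    defaults = dict(
        campaign=campaign or make_campaign(),
        compartment="plankton",
        treatment="light",
        o2_start_mg_l=8.0,
        o2_end_mg_l=8.8,
        duration_h=4.0,
    )
    defaults.update(kw)
    return oxygen.OxygenIncubation(**defaults)


class TestBottleRate:
    @pytest.mark.parametrize(
        "start,end,hours,expected",
        [(8.0, 8.8, 4.0, 0.2), (8.0, 8.0, 2.0, 0.0), (8.0, 7.6, 4.0, -0.1)],
    )
    def test_linear_rate(self, start, end, hours, expected):
        inc = make_incubation(o2_start_mg_l=start, o2_end_mg_l=end, duration_h=hours)
        assert oxygen.bottle_rate(inc) == pytest.approx(expected)

    def test_nonpositive_duration_rejected(self):
        with pytest.raises(ValueError):
            make_incubation(duration_h=0.0)


class TestCommunityRates:
    def test_constant_replicates(self):
        comm = oxygen.community_rates([0.2] * 4, [-0.1] * 4)
        assert (comm.ncp, comm.r, comm.gpp) == pytest.approx((0.2, 0.1, 0.3))
        assert not comm.dark_production

    def test_light_equals_dark_means_no_photosynthesis(self):
        comm = oxygen.community_rates([-0.1] * 4, [-0.1] * 4)
        assert (comm.ncp, comm.r, comm.gpp) == pytest.approx((-0.1, 0.1, 0.0))

    def test_replicate_means(self):
        comm = oxygen.community_rates(
            [0.25, 0.15, 0.30, 0.10], [-0.12, -0.08, -0.10, -0.10]
        )
        assert (comm.ncp, comm.r, comm.gpp) == pytest.approx((0.2, 0.1, 0.3))
        assert comm.ncp_sd == pytest.approx(np.std([0.25, 0.15, 0.30, 0.10], ddof=1))

    def test_dark_production_clips_r(self):
        with pytest.warns(UserWarning, match="dark"):
            comm = oxygen.community_rates([0.2] * 4, [0.05] * 4)
        assert comm.r == 0.0
        assert comm.dark_production
        assert comm.gpp == pytest.approx(comm.ncp)

    def test_empty_replicates_rejected(self):
        with pytest.raises(ValueError):
            oxygen.community_rates([], [-0.1])

    @given(
        light=st.lists(st.floats(-1, 1), min_size=1, max_size=8),
        dark=st.lists(st.floats(-1, -0.001), min_size=1, max_size=8),
    )
    @settings(deadline=None)
    def test_gpp_is_ncp_plus_r(self, light, dark):
        comm = oxygen.community_rates(light, dark)
        assert comm.gpp == pytest.approx(comm.ncp + comm.r, rel=1e-9, abs=1e-12)


class TestO2ToCarbon:
    @pytest.mark.parametrize("o2,c", [(32.0, 12.0), (0.0, 0.0), (0.3, 0.1125)])
    def test_molar_conversion(self, o2, c):
        assert oxygen.o2_to_carbon(o2) == pytest.approx(c)

    @given(a=st.floats(-1e3, 1e3), b=st.floats(-1e3, 1e3), k=st.floats(-10, 10))
    @settings(deadline=None)
    def test_linearity(self, a, b, k):
        f = oxygen.o2_to_carbon
        assert f(a + b) == pytest.approx(f(a) + f(b), rel=1e-12, abs=1e-9)
        assert f(k * a) == pytest.approx(k * f(a), rel=1e-12, abs=1e-9)

    def test_quotient_scales(self):
        assert oxygen.o2_to_carbon(32.0, quotient=1.2) == pytest.approx(14.4)


class TestArealScaling:
    @pytest.mark.parametrize("rate,depth,expected", [(0.3, 0.45, 135.0), (0.1, 0.20, 20.0)])
    def test_plankton_depth_integration(self, rate, depth, expected):
        assert oxygen.plankton_areal(rate, depth) == pytest.approx(expected)

    def test_zero_depth_rejected(self):
        with pytest.raises(ValueError):
            oxygen.plankton_areal(0.3, 0.0)

    @pytest.mark.parametrize(
        "rate,vol,area,expected",
        [(0.2, 2.0, 0.02, 20.0), (0.0, 2.0, 0.02, 0.0), (0.15, 1.5, 0.0125, 18.0)],
    )
    def test_benthic_jar_geometry(self, rate, vol, area, expected):
        assert oxygen.benthic_areal(rate, vol, area) == pytest.approx(expected)

    def test_zero_area_rejected(self):
        with pytest.raises(ValueError):
            oxygen.benthic_areal(0.2, 2.0, 0.0)


class TestDielScale:
    @pytest.mark.parametrize(
        "gpp,r,day,expected",
        [
            (10.0, 5.0, 12.0, (120.0, 120.0, 0.0)),
            (10.0, 0.0, 0.0, (0.0, 0.0, 0.0)),
            (8.333, 2.5, 14.4, (119.9952, 60.0, 59.9952)),
        ],
    )
    def test_daylight_scaling(self, gpp, r, day, expected):
        assert oxygen.diel_scale(gpp, r, day) == pytest.approx(expected)

    def test_daylight_out_of_range(self):
        with pytest.raises(ValueError):
            oxygen.diel_scale(1.0, 1.0, 25.0)

    @given(
        gpp=st.floats(0, 100),
        r=st.floats(0, 100),
        day=st.floats(0, 24),
        depth=st.floats(0.05, 1.0),
    )
    @settings(deadline=None)
    def test_scaling_commutes_with_stoichiometry(self, gpp, r, day, depth):
        """C-conversion then geometric/diel scaling == the reverse order."""
        a = oxygen.diel_scale(
            oxygen.plankton_areal(float(oxygen.o2_to_carbon(gpp)), depth),
            oxygen.plankton_areal(float(oxygen.o2_to_carbon(r)), depth),
            day,
        )
        b = tuple(
            float(oxygen.o2_to_carbon(v))
            for v in oxygen.diel_scale(
                oxygen.plankton_areal(gpp, depth), oxygen.plankton_areal(r, depth), day
            )
        )
        assert a == pytest.approx(b, rel=1e-12, abs=1e-12)


class TestDaylightHours:
    def test_equinox_near_twelve_hours(self):
        assert oxygen.daylight_hours(dt.date(2016, 3, 21), 40.65) == pytest.approx(
            12.0, abs=0.2
        )

    def test_equator_always_near_twelve(self):
        assert oxygen.daylight_hours(dt.date(2016, 6, 21), 0.0) == pytest.approx(
            12.0, abs=0.1
        )

    def test_winter_solstice_matches_day_length_tables(self):
        # almanac day length at 40 deg N on the winter solstice is ~9.3 h
        hours = oxygen.daylight_hours(dt.date(2016, 12, 21), 40.65)
        assert hours < 10.0
        assert hours == pytest.approx(9.2, abs=0.4)

    def test_solstices_bracket_equinox(self):
        lat = 40.65
        assert (
            oxygen.daylight_hours(dt.date(2016, 12, 21), lat)
            < oxygen.daylight_hours(dt.date(2016, 3, 21), lat)
            < oxygen.daylight_hours(dt.date(2016, 6, 21), lat)
        )

    def test_polar_latitude_unsupported(self):
        with pytest.raises(ValueError):
            oxygen.daylight_hours(dt.date(2016, 6, 21), 70.0)


class TestCommunityDailyRates:
    def test_full_chain_on_known_rates(self):
        """Noise-free bottles constructed from known rates are recovered."""
        campaign = make_campaign(daylight_h=12.0, depth_m=0.5)
        # true: GPP 600 mg C m-2 d-1, R 300 mg C m-2 d-1
        gpp_v = 600 / 12.0 / oxygen.O2_TO_C / (1000 * 0.5)
        r_v = 300 / 24.0 / oxygen.O2_TO_C / (1000 * 0.5)
        incs = []
        for _ in range(4):
            incs.append(
                make_incubation(
                    campaign,
                    treatment="light",
                    o2_end_mg_l=8.0 + (gpp_v - r_v) * 2.0,
                    duration_h=2.0,
                )
            )
            incs.append(
                make_incubation(
                    campaign, treatment="dark", o2_end_mg_l=8.0 - r_v * 2.0, duration_h=2.0
                )
            )
        rates = {r.process: r.value for r in oxygen.community_daily_rates(incs)}
        assert rates["GPP"] == pytest.approx(600.0, rel=1e-9)
        assert rates["R"] == pytest.approx(300.0, rel=1e-9)
        assert rates["NCP"] == pytest.approx(300.0, rel=1e-9)

    def test_triple_identity(self):
        campaign = make_campaign()
        incs = [
            make_incubation(campaign, treatment=t, o2_end_mg_l=e)
            for t, e in [("light", 8.9), ("light", 8.7), ("dark", 7.7), ("dark", 7.9)]
        ]
        rates = {r.process: r.value for r in oxygen.community_daily_rates(incs)}
        assert rates["GPP"] == pytest.approx(rates["NCP"] + rates["R"], rel=1e-9)

    def test_mixed_compartments_rejected(self):
        campaign = make_campaign()
        incs = [
            make_incubation(campaign, compartment="plankton"),
            make_incubation(
                campaign, compartment="benthos", enclosed_volume_l=2.0, basal_area_m2=0.02
            ),
        ]
        with pytest.raises(ValueError):
            oxygen.community_daily_rates(incs)
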