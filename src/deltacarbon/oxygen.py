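"""Light/dark oxygen incubations to areal daily carbon rates.

Plankton metabolism is measured in paired clear ("light") and dark Winkler-type
bottles, benthic metabolism in clear and dark bell-jars staked into the
sediment.  The net O2 change in a light enclosure is net community production
(NCP: photosynthesis minus the concurrent respiration of the enclosed
community); the O2 decline in a dark enclosure is aerobic respiration (R).
Gross primary production is their sum, GPP = NCP + R.

The conversion chain implemented here is

    bottle O2 rate (mg O2 L-1 h-1)
      -> areal O2 rate (mg O2 m-2 h-1)        depth integration / jar geometry
      -> areal C rate  (mg C  m-2 h-1)        molar O2:C stoichiometry
      -> daily C rate  (mg C  m-2 d-1)        diel scaling

GPP runs only during daylight, so its diel estimate multiplies by the daytime
length of the campaign; respiration is assumed constant over 24 h.  All steps
are linear, so stoichiometric conversion and geometric scaling commute.
"""

from __future__ import annotations

import datetime as _dt
import math
import warnings
from dataclasses import dataclass, field

import numpy as np

__all__ = [
    "SamplingCampaign",
    "OxygenIncubation",
    "MetabolicRate",
    "CommunityRates",
    "O2_TO_C",
    "bottle_rate",
    "community_rates",
    "o2_to_carbon",
    "plankton_areal",
    "benthic_areal",
    "diel_scale",
    "daylight_hours",
]

#: mg C per mg O2 at a 1:1 molar O2:C exchange (12/32).  Photosynthetic and
#: respiratory quotients default to 1.0 and enter as a multiplier on this.
O2_TO_C = 12.0 / 32.0


@dataclass(frozen=True)
class SamplingCampaign:
    """One site visit: the shared environmental context of its incubations."""

    site_id: str
    date: _dt.date
    daylight_h: float
    water_temp_c: float
    conductivity_ms_cm: float
    depth_m: float

    def __post_init__(self) -> None:
        if not 0.0 <= self.daylight_h <= 24.0:
            raise ValueError(f"daylight_h must be in [0, 24], got {self.daylight_h}")
        if self.depth_m <= 0:
            raise ValueError(f"depth_m must be positive, got {self.depth_m}")
        if self.conductivity_ms_cm < 0:
            raise ValueError("conductivity_ms_cm must be non-negative")


@dataclass(frozen=True)
class OxygenIncubation:
    """A single replicate light or dark bottle/jar O2 measurement."""

    campaign: SamplingCampaign
    compartment: str  # "plankton" | "benthos"
    treatment: str  # "light" | "dark"
    o2_start_mg_l: float
    o2_end_mg_l: float
    duration_h: float
    enclosed_volume_l: float = float("nan")
    basal_area_m2: float = float("nan")

    def __post_init__(self) -> None:
        if self.compartment not in ("plankton", "benthos"):
            raise ValueError(f"unknown compartment {self.compartment!r}")
        if self.treatment not in ("light", "dark"):
            raise ValueError(f"unknown treatment {self.treatment!r}")
        if self.duration_h <= 0:
            raise ValueError("duration_h must be positive")
        if self.o2_start_mg_l < 0 or self.o2_end_mg_l < 0:
            raise ValueError("O2 concentrations must be non-negative")
        if self.compartment == "benthos" and not self.basal_area_m2 > 0:
            raise ValueError("benthic incubations need basal_area_m2 > 0")


@dataclass(frozen=True)
class MetabolicRate:
    """An areal daily rate for one site/date/compartment/process.

    ``value`` is in mg C m-2 d-1 and is stored as a non-negative magnitude for
    GPP, R and CH4; NCP may be signed (negative = net heterotrophy).
    """

    site_id: str
    date: _dt.date
    compartment: str  # plankton | benthos | vegetation | sediment
    process: str  # GPP | NCP | R | CH4 | VEG_P
    value: float
    sd: float = float("nan")
    n_replicates: int = 1
    flagged: bool = False

    def __post_init__(self) -> None:
        if self.n_replicates < 1:
            raise ValueError("n_replicates must be >= 1")


@dataclass(frozen=True)
class CommunityRates:
    """Paired light/dark replicate means in one set of units.

    ``dark_production`` marks net O2 production in the dark (mean dark rate
    > 0), in which case R is clipped to zero; ``negative_gpp`` marks a GPP
    that averaged below zero after pairing.
    """

    ncp: float
    r: float
    gpp: float
    ncp_sd: float
    r_sd: float
    n_light: int
    n_dark: int
    dark_production: bool = False
    negative_gpp: bool = False

    @property
    def gpp_sd(self) -> float:
        """sd of GPP assuming independent light and dark replicate errors."""
        return math.hypot(self.ncp_sd, self.r_sd)


def bottle_rate(incubation: OxygenIncubation) -> float:
    """Volumetric O2 change rate of one enclosure, mg O2 L-1 h-1.

    Sign is retained: a light enclosure yields an NCP-like rate, a dark one a
    (normally negative) rate whose magnitude is respiration.
    """
    if incubation.duration_h <= 0:
        raise ValueError("duration_h must be positive")
    return (incubation.o2_end_mg_l - incubation.o2_start_mg_l) / incubation.duration_h


def _mean_sd(values: list[float] | np.ndarray) -> tuple[float, float]:
    arr = np.asarray(values, dtype=float)
    sd = float(arr.std(ddof=1)) if arr.size > 1 else 0.0
    return float(arr.mean()), sd


def community_rates(
    light: list[float] | np.ndarray, dark: list[float] | np.ndarray
) -> CommunityRates:
    """Combine light and dark replicate rates into (NCP, R, GPP).

    NCP is the mean light rate; R is the magnitude of the mean dark rate;
    GPP = NCP + R.  Net O2 production in the dark is physically dubious
    (measurement noise), so a positive dark mean clips R to 0 and sets the
    ``dark_production`` flag.  Inputs may be in any consistent rate units.
    """
    light = np.asarray(light, dtype=float)
    dark = np.asarray(dark, dtype=float)
    if light.size == 0 or dark.size == 0:
        raise ValueError("need at least one light and one dark replicate")

    ncp, ncp_sd = _mean_sd(light)
    dark_mean, dark_sd = _mean_sd(dark)
    dark_production = dark_mean > 0
    if dark_production:
        warnings.warn(
            "net O2 production in the dark; respiration clipped to 0",
            stacklevel=2,
        )
        r = 0.0
    else:
        r = -dark_mean
    gpp = ncp + r
    return CommunityRates(
        ncp=ncp,
        r=r,
        gpp=gpp,
        ncp_sd=ncp_sd,
        r_sd=dark_sd,
        n_light=int(light.size),
        n_dark=int(dark.size),
        dark_production=dark_production,
        negative_gpp=gpp < 0,
    )


def o2_to_carbon(rate_o2: float | np.ndarray, quotient: float = 1.0):
    """Convert an O2-mass rate to a C-mass rate via molar stoichiometry.

    ``quotient`` is mol C exchanged per mol O2 (the inverse photosynthetic
    quotient for production, the respiratory quotient for respiration);
    the default 1.0 gives the plain 12/32 mass conversion.
    """
    return np.multiply(rate_o2, O2_TO_C * quotient)


def plankton_areal(volumetric_rate: float, depth_m: float) -> float:
    """Depth-integrate a volumetric rate (mg L-1 h-1) to mg m-2 h-1.

    Assumes a vertically well-mixed column (the studied wetlands are
    <= 0.5 m deep), so the areal rate is rate x 1000 L m-3 x depth.
    """
    if depth_m <= 0:
        raise ValueError("depth_m must be positive")
    return volumetric_rate * 1000.0 * depth_m


def benthic_areal(
    volumetric_rate: float, enclosed_volume_l: float, basal_area_m2: float
) -> float:
    """Convert a jar's volumetric rate to the rate per m2 of sediment.

    The O2 change happens in ``enclosed_volume_l`` of water sitting over
    ``basal_area_m2`` of sediment footprint.
    """
    if basal_area_m2 <= 0:
        raise ValueError("basal_area_m2 must be positive")
    return volumetric_rate * enclosed_volume_l / basal_area_m2


def diel_scale(
    gpp_hourly: float, r_hourly: float, daylight_h: float
) -> tuple[float, float, float]:
    """Scale hourly areal rates to daily: GPP by daytime length, R by 24 h.

    Returns (GPP_daily, R_daily, NCP_daily) with NCP = GPP - R, all in the
    input units per day.
    """
    if not 0.0 <= daylight_h <= 24.0:
        raise ValueError(f"daylight_h must be in [0, 24], got {daylight_h}")
    gpp_daily = gpp_hourly * daylight_h
    r_daily = r_hourly * 24.0
    return gpp_daily, r_daily, gpp_daily - r_daily


def daylight_hours(date: _dt.date, latitude_deg: float) -> float:
    """Astronomical day length from the solar-declination formula.

    Fallback for campaigns without an observed daytime length.  Uses the
    Cooper declination approximation; atmospheric refraction is ignored, so
    values run a few minutes short of almanac day lengths.  Polar latitudes
    (|lat| >= 66.5 deg), where the formula degenerates, are unsupported.
    """
    if abs(latitude_deg) >= 66.5:
        raise ValueError("polar latitudes are not supported")
    doy = date.timetuple().tm_yday
    decl = math.radians(23.45) * math.sin(2.0 * math.pi * (284 + doy) / 365.0)
    lat = math.radians(latitude_deg)
    cos_omega = -math.tan(lat) * math.tan(decl)
    cos_omega = min(1.0, max(-1.0, cos_omega))
    return 24.0 / math.pi * math.acos(cos_omega)


def incubation_to_areal_o2(incubation: OxygenIncubation) -> float:
    """Per-enclosure areal hourly O2 rate (mg O2 m-2 h-1), geometry applied."""
    vol_rate = bottle_rate(incubation)
    if incubation.compartment == "plankton":
        return plankton_areal(vol_rate, incubation.campaign.depth_m)
    return benthic_areal(
        vol_rate, incubation.enclosed_volume_l, incubation.basal_area_m2
    )


def community_daily_rates(
    incubations: list[OxygenIncubation],
    pq: float = 1.0,
    rq: float = 1.0,
) -> list[MetabolicRate]:
    """Full chain for one site/date/compartment set of incubations.

    Converts each enclosure to an areal hourly O2 rate, pairs light/dark
    replicates, applies the stoichiometric quotients (``pq`` mol O2 per mol C
    for production, ``rq`` mol CO2 per mol O2 for respiration) and the diel
    scaling, and returns GPP, NCP and R as :class:`MetabolicRate` rows in
    mg C m-2 d-1.
    """
    if not incubations:
        raise ValueError("no incubations given")
    campaigns = {id(i.campaign): i.campaign for i in incubations}
    keys = {(i.campaign.site_id, i.campaign.date, i.compartment) for i in incubations}
    if len(keys) != 1:
        raise ValueError("incubations must share site, date and compartment")
    campaign = next(iter(campaigns.values()))
    (site_id, date, compartment) = next(iter(keys))

    light = [incubation_to_areal_o2(i) for i in incubations if i.treatment == "light"]
    dark = [incubation_to_areal_o2(i) for i in incubations if i.treatment == "dark"]
    comm = community_rates(light, dark)

    gpp_c = float(o2_to_carbon(comm.gpp, 1.0 / pq))
    r_c = float(o2_to_carbon(comm.r, rq))
    gpp_d, r_d, ncp_d = diel_scale(gpp_c, r_c, campaign.daylight_h)
    flagged = comm.dark_production or comm.negative_gpp

    gpp_sd_d = float(o2_to_carbon(comm.gpp_sd, 1.0 / pq)) * campaign.daylight_h
    r_sd_d = float(o2_to_carbon(comm.r_sd, rq)) * 24.0
    ncp_sd_d = math.hypot(gpp_sd_d, r_sd_d)

    n = min(comm.n_light, comm.n_dark)
    mk = lambda process, value, sd: MetabolicRate(  # noqa: E731
        site_id=site_id,
        date=date,
        compartment=compartment,
        process=process,
        value=value,
        sd=sd,
        n_replicates=n,
        flagged=flagged,
    )
    return [mk("GPP", gpp_d, gpp_sd_d), mk("NCP", ncp_d, ncp_sd_d), mk("R", r_d, r_sd_d)]
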