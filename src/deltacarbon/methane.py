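"""Sediment-core headspace CH4 fluxes and their temperature/salinity response.

CH4 emission (the net balance of methanogenesis and methanotrophy) is measured
ex situ: intact cores — sediment plus overlying water in a closed transparent
tube with an air headspace — accumulate CH4 in the headspace over a 2-5 day
incubation.  The ppm increase is converted to mass with the ideal-gas law and
normalised by core footprint and time.

Manipulation experiments incubate replicate cores across temperature levels
(exponential response, flux = a*exp(b*T)) or salinity dilution/concentration
series (power-law inhibition, flux = a*x**b with b < 0).  Both curves are fit
by nonlinear least squares seeded from the corresponding log-space linear
regression; fit strength is reported as the Pearson correlation between
observed and fitted fluxes with a t-transform p-value on n-2 degrees of
freedom.
"""

from __future__ import annotations

import datetime as _dt
import math
import warnings
from dataclasses import dataclass

import numpy as np
from scipy import optimize, stats

from .oxygen import MetabolicRate

__all__ = [
    "CoreIncubation",
    "ResponseFit",
    "GAS_CONSTANT_L_ATM",
    "MOLAR_MASS_C",
    "headspace_volume",
    "ppm_to_mass_c",
    "core_flux",
    "site_flux",
    "fit_temperature_response",
    "fit_salinity_response",
    "predict_response",
]

#: ideal gas constant, L atm mol-1 K-1
GAS_CONSTANT_L_ATM = 0.0820573660809596
#: g mol-1
MOLAR_MASS_C = 12.011


@dataclass(frozen=True)
class CoreIncubation:
    """One sediment-core headspace incubation."""

    site_id: str
    date: _dt.date
    tube_length_cm: float = 50.0
    tube_diameter_cm: float = 4.0
    sediment_depth_cm: float = 7.5
    water_depth_cm: float = 20.0
    duration_d: float = 3.0
    ch4_ppm_start: float = 0.0
    ch4_ppm_end: float = 0.0
    incubation_temp_c: float = 20.0
    conductivity_ms_cm: float = 0.0
    pressure_atm: float = 1.0

    def __post_init__(self) -> None:
        if self.sediment_depth_cm + self.water_depth_cm >= self.tube_length_cm:
            raise ValueError("no headspace: sediment + water >= tube length")
        if self.duration_d <= 0:
            raise ValueError("duration_d must be positive")
        if self.ch4_ppm_start < 0 or self.ch4_ppm_end < 0:
            raise ValueError("ppm readings must be non-negative")
        if self.tube_diameter_cm <= 0:
            raise ValueError("tube_diameter_cm must be positive")

    @property
    def basal_area_m2(self) -> float:
        return math.pi * (self.tube_diameter_cm / 2.0 / 100.0) ** 2


@dataclass(frozen=True)
class ResponseFit:
    """Fitted flux-response curve: exponential in T or power-law in salinity.

    ``r`` is the Pearson correlation between observed and fitted fluxes (NaN
    when either side is constant); ``b_se`` the asymptotic standard error of
    the exponent from the nonlinear fit.
    """

    model: str  # "exponential_temperature" | "power_salinity"
    a: float
    b: float
    r: float
    p_value: float
    n_points: int
    a_se: float = float("nan")
    b_se: float = float("nan")


def headspace_volume(core: CoreIncubation) -> float:
    """Air volume above the water in the tube, litres."""
    head_cm = core.tube_length_cm - core.sediment_depth_cm - core.water_depth_cm
    if head_cm <= 0:
        raise ValueError("no headspace: sediment + water >= tube length")
    radius_cm = core.tube_diameter_cm / 2.0
    return math.pi * radius_cm**2 * head_cm / 1000.0


def ppm_to_mass_c(
    delta_ppm: float, volume_l: float, temp_c: float, pressure_atm: float = 1.0
) -> float:
    """CH4-C mass (mg) of a mixing-ratio change in a closed gas volume.

    Ideal gas: mol = ppm x 1e-6 x P V / (R T); mass = mol x 12.011 g/mol.
    """
    if volume_l <= 0:
        raise ValueError("volume_l must be positive")
    if temp_c <= -273.15:
        raise ValueError("temperature below absolute zero")
    temp_k = temp_c + 273.15
    mol = delta_ppm * 1e-6 * pressure_atm * volume_l / (GAS_CONSTANT_L_ATM * temp_k)
    return mol * MOLAR_MASS_C * 1000.0


def core_flux(core: CoreIncubation) -> float:
    """Areal CH4-C emission of one core, mg C m-2 d-1.

    Negative accumulation (net methanotrophy) is allowed and returned signed
    with a warning.
    """
    delta = core.ch4_ppm_end - core.ch4_ppm_start
    mass_mg = ppm_to_mass_c(
        delta, headspace_volume(core), core.incubation_temp_c, core.pressure_atm
    )
    flux = mass_mg / core.basal_area_m2 / core.duration_d
    if flux < 0:
        warnings.warn(
            f"negative CH4 accumulation ({flux:.3g} mg C m-2 d-1): net methanotrophy",
            stacklevel=2,
        )
    return flux


def site_flux(cores: list[CoreIncubation]) -> MetabolicRate:
    """Mean areal CH4 emission across a campaign's replicate cores."""
    if not cores:
        raise ValueError("no cores given")
    keys = {(c.site_id, c.date) for c in cores}
    if len(keys) != 1:
        raise ValueError("cores must share site and date")
    site_id, date = next(iter(keys))
    fluxes = np.array([core_flux(c) for c in cores])
    sd = float(fluxes.std(ddof=1)) if fluxes.size > 1 else 0.0
    return MetabolicRate(
        site_id=site_id,
        date=date,
        compartment="sediment",
        process="CH4",
        value=float(fluxes.mean()),
        sd=sd,
        n_replicates=int(fluxes.size),
        flagged=bool((fluxes < 0).any()),
    )


def _fit_correlation(observed: np.ndarray, fitted: np.ndarray) -> tuple[float, float]:
    """Pearson r between observed and fitted, with t-transform p (n-2 df)."""
    n = observed.size
    if n < 3 or np.std(observed) == 0 or np.std(fitted) == 0:
        return float("nan"), float("nan")
    r = float(np.corrcoef(observed, fitted)[0, 1])
    if abs(r) >= 1.0:
        return r, 0.0
    t = r * math.sqrt((n - 2) / (1.0 - r * r))
    p = 2.0 * stats.t.sf(abs(t), n - 2)
    return r, float(p)


def fit_temperature_response(
    temps_c: np.ndarray | list[float], fluxes: np.ndarray | list[float]
) -> ResponseFit:
    """Fit flux = a * exp(b * T) to core fluxes across temperature levels.

    Initialised from the linear regression of log(flux) on T (non-positive
    fluxes excluded there), then refined by nonlinear least squares on all
    points.  Needs at least three distinct temperatures.
    """
    temps = np.asarray(temps_c, dtype=float)
    obs = np.asarray(fluxes, dtype=float)
    if temps.size != obs.size:
        raise ValueError("temps and fluxes must have the same length")
    if np.unique(temps).size < 3:
        raise ValueError("need at least 3 distinct temperatures")

    positive = obs > 0
    if positive.sum() < 2:
        raise ValueError("need at least 2 positive fluxes for initialization")
    slope, intercept = np.polyfit(temps[positive], np.log(obs[positive]), 1)
    p0 = (math.exp(intercept), slope)

    model = lambda t, a, b: a * np.exp(b * t)  # noqa: E731
    popt, pcov = optimize.curve_fit(model, temps, obs, p0=p0, maxfev=20000)
    fitted = model(temps, *popt)
    r, p = _fit_correlation(obs, fitted)
    se = np.sqrt(np.diag(pcov))
    return ResponseFit(
        model="exponential_temperature",
        a=float(popt[0]),
        b=float(popt[1]),
        r=r,
        p_value=p,
        n_points=int(temps.size),
        a_se=float(se[0]),
        b_se=float(se[1]),
    )


def fit_salinity_response(
    conductivities: np.ndarray | list[float], fluxes: np.ndarray | list[float]
) -> ResponseFit:
    """Fit flux = a * x**b to fluxes across a conductivity series.

    A power law is undefined at x = 0, so zero/negative conductivity points
    are dropped with a warning.  Initialised from the log-log regression,
    refined by nonlinear least squares.
    """
    x = np.asarray(conductivities, dtype=float)
    obs = np.asarray(fluxes, dtype=float)
    if x.size != obs.size:
        raise ValueError("conductivities and fluxes must have the same length")
    valid = x > 0
    if not valid.all():
        warnings.warn(
            f"excluding {int((~valid).sum())} non-positive conductivity point(s)",
            stacklevel=2,
        )
        x, obs = x[valid], obs[valid]
    if np.unique(x).size < 3:
        raise ValueError("need at least 3 distinct positive conductivities")

    positive = obs > 0
    if positive.sum() < 2:
        raise ValueError("need at least 2 positive fluxes for initialization")
    slope, intercept = np.polyfit(np.log(x[positive]), np.log(obs[positive]), 1)
    p0 = (math.exp(intercept), slope)

    model = lambda c, a, b: a * np.power(c, b)  # noqa: E731
    popt, pcov = optimize.curve_fit(model, x, obs, p0=p0, maxfev=20000)
    fitted = model(x, *popt)
    r, p = _fit_correlation(obs, fitted)
    se = np.sqrt(np.diag(pcov))
    return ResponseFit(
        model="power_salinity",
        a=float(popt[0]),
        b=float(popt[1]),
        r=r,
        p_value=p,
        n_points=int(x.size),
        a_se=float(se[0]),
        b_se=float(se[1]),
    )


def predict_response(fit: ResponseFit, x: float | np.ndarray):
    """Evaluate a fitted response curve at temperature or conductivity x."""
    if fit.model == "exponential_temperature":
        return fit.a * np.exp(fit.b * np.asarray(x, dtype=float))
    if fit.model == "power_salinity":
        return fit.a * np.power(np.asarray(x, dtype=float), fit.b)
    raise ValueError(f"unknown model {fit.model!r}")
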