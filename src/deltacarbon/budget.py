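"""Annual carbon balances, CO2-equivalent balances, and landscape totals.

Dated areal rates are integrated to annual fluxes (period-weighted trapezoid
over the sampling dates, closed to a 365-day year), weighted by the surface
fraction where each metabolism operates (open water for plankton, benthos and
sediment CH4; the vegetated belt for plant production), and combined into a
whole-wetland net C balance

    B = f_open (R_p + R_b + CH4 - GPP_p - GPP_b) - f_veg P_veg   [g C m-2 y-1]

with the convention negative = net carbon capture.  The global-warming-
potential balance expresses the same fluxes as CO2 equivalents on a gas-mass
basis: the net CO2-C flux scaled by 44/12 and the CH4-C flux by 16/12 times a
CH4/CO2 warming factor of 28 (100-year horizon).  Per-type areal balances are
extrapolated to landscape totals (Tn y-1) by the surface each wetland type
occupies.
"""

from __future__ import annotations

import datetime as _dt
import warnings
from dataclasses import dataclass, field

import numpy as np

__all__ = [
    "SiteConfig",
    "GwpConstants",
    "AnnualBudget",
    "date_balance",
    "annual_process_rate",
    "annual_budget",
    "gwp_of_budget",
    "infer_ch4_from_balance_pair",
    "extrapolate",
    "landscape_totals",
]

#: the six contributions reported in an annual budget, in output order
CONTRIBUTIONS = (
    "plankton_gpp",
    "plankton_r",
    "benthos_gpp",
    "benthos_r",
    "ch4",
    "vegetation",
)


@dataclass(frozen=True)
class SiteConfig:
    """Coverage fractions and landscape surface for one wetland site."""

    site_id: str
    wetland_type: str  # salt_marsh | brackish | freshwater
    vegetated_fraction: float
    plant_type: str  # helophyte | halophyte
    surface_ha: float
    open_water_fraction: float | None = None
    ch4_coverage: str = "open"  # weight CH4 by open-water or total surface

    def __post_init__(self) -> None:
        if self.open_water_fraction is None:
            object.__setattr__(
                self, "open_water_fraction", 1.0 - self.vegetated_fraction
            )
        if not 0.0 <= self.vegetated_fraction <= 1.0:
            raise ValueError("vegetated_fraction must be in [0, 1]")
        if self.vegetated_fraction + self.open_water_fraction > 1.0 + 1e-9:
            raise ValueError("coverage fractions must sum to at most 1")
        if self.surface_ha <= 0:
            raise ValueError("surface_ha must be positive")
        if self.ch4_coverage not in ("open", "total"):
            raise ValueError("ch4_coverage must be 'open' or 'total'")


@dataclass(frozen=True)
class GwpConstants:
    """Mass ratios and warming factor for the CO2-equivalent conversion."""

    ch4_co2_factor: float = 28.0
    co2_per_c: float = 44.0 / 12.0
    ch4_per_c: float = 16.0 / 12.0

    def __post_init__(self) -> None:
        if self.ch4_co2_factor <= 0:
            raise ValueError("ch4_co2_factor must be positive")


@dataclass(frozen=True)
class AnnualBudget:
    """Per-site annual areal budget, g C m-2 y-1, negative = sink.

    ``contributions`` holds the six coverage-weighted signed terms whose sum
    is ``c_balance`` exactly; ``gwp_balance`` is in g CO2-eq m-2 y-1.
    """

    site_id: str
    contributions: dict[str, float]
    c_balance: float
    gwp_balance: float = float("nan")


def date_balance(rates: dict[str, float]) -> float:
    """Joint plankton+benthos C balance at one sampling date, signed.

    (R_plankton + R_benthos) - (GPP_plankton + GPP_benthos), mg C m-2 d-1,
    positive = net C source.  Unweighted by coverage (an open-water quantity).
    Keys: plankton_gpp, plankton_r, benthos_gpp, benthos_r; missing processes
    count as 0 with a warning.
    """
    if not rates:
        raise ValueError("no rates given")
    needed = ("plankton_gpp", "plankton_r", "benthos_gpp", "benthos_r")
    missing = [k for k in needed if k not in rates]
    if missing:
        warnings.warn(f"missing processes treated as 0: {missing}", stacklevel=2)
    g = lambda k: rates.get(k, 0.0)  # noqa: E731
    return (g("plankton_r") + g("benthos_r")) - (g("plankton_gpp") + g("benthos_gpp"))


def annual_process_rate(
    dates: list[_dt.date], values_mg_c_m2_d: list[float] | np.ndarray
) -> float:
    """Integrate dated daily rates to an annual flux, g C m-2 y-1.

    Period-weighted trapezoid over the sampling dates; the gap from the last
    back around to the first date is closed with the mean of the two endpoint
    values so that the integral always covers a full 365-day year.  A single
    date falls back to flat extrapolation.  Dates must be strictly increasing
    and span less than 370 days.
    """
    values = np.asarray(values_mg_c_m2_d, dtype=float)
    if len(dates) != values.size or values.size == 0:
        raise ValueError("dates and values must be non-empty and equal length")
    if values.size == 1:
        return float(values[0]) * 365.0 / 1000.0

    t = np.array([(d - dates[0]).days for d in dates], dtype=float)
    if np.any(np.diff(t) <= 0):
        raise ValueError("dates must be strictly increasing with no duplicates")
    span = t[-1]
    if span >= 370:
        raise ValueError(f"dates span {span:.0f} d; split into <370-day cycles first")

    integral = float(np.trapezoid(values, t))
    gap = max(365.0 - span, 0.0)
    integral += gap * 0.5 * (values[0] + values[-1])
    mean_daily = integral / (span + gap)
    return mean_daily * 365.0 / 1000.0


def annual_budget(
    annual_rates: dict[str, float],
    config: SiteConfig,
) -> AnnualBudget:
    """Coverage-weighted whole-wetland annual C balance.

    ``annual_rates`` maps process keys (plankton_gpp, plankton_r, benthos_gpp,
    benthos_r, ch4, vegetation) to unweighted annual areal magnitudes in
    g C m-2 y-1 (per m2 of the surface where the process runs).  Missing
    processes count as 0 with a warning.  Returns the six signed weighted
    contributions and their sum (no GWP; see :func:`gwp_of_budget`).
    """
    missing = [k for k in CONTRIBUTIONS if k not in annual_rates]
    if missing:
        warnings.warn(f"missing processes treated as 0: {missing}", stacklevel=2)
    g = lambda k: annual_rates.get(k, 0.0)  # noqa: E731
    ow = config.open_water_fraction
    ch4_w = 1.0 if config.ch4_coverage == "total" else ow
    contributions = {
        "plankton_gpp": -ow * g("plankton_gpp"),
        "plankton_r": ow * g("plankton_r"),
        "benthos_gpp": -ow * g("benthos_gpp"),
        "benthos_r": ow * g("benthos_r"),
        "ch4": ch4_w * g("ch4"),
        "vegetation": -config.vegetated_fraction * g("vegetation"),
    }
    balance = sum(contributions.values())
    return AnnualBudget(
        site_id=config.site_id, contributions=contributions, c_balance=balance
    )


def gwp_of_budget(
    budget: AnnualBudget, constants: GwpConstants = GwpConstants()
) -> float:
    """CO2-equivalent balance of an annual budget, g CO2-eq m-2 y-1.

    The CH4 contribution leaves as CH4 gas (mass 16/12 per unit C) weighted by
    the warming factor; everything else is a net CO2 exchange (mass 44/12 per
    unit C).  Negative = net mitigation.
    """
    ch4_c = budget.contributions.get("ch4", 0.0)
    net_co2_c = budget.c_balance - ch4_c
    return (
        net_co2_c * constants.co2_per_c
        + ch4_c * constants.ch4_per_c * constants.ch4_co2_factor
    )


def infer_ch4_from_balance_pair(
    c_balance: float, gwp_balance: float, constants: GwpConstants = GwpConstants()
) -> float:
    """Annual CH4-C flux consistent with a printed (C, CO2-eq) balance pair.

    Exact inverse of :func:`gwp_of_budget`:
    CH4-C = (GWP - B x 44/12) / (16/12 x factor - 44/12).
    """
    denom = constants.ch4_per_c * constants.ch4_co2_factor - constants.co2_per_c
    return (gwp_balance - c_balance * constants.co2_per_c) / denom


def extrapolate(areal_balance_g_m2_y: float, surface_ha: float) -> float:
    """Scale an areal annual balance to a landscape surface, Tn y-1.

    1 ha = 1e4 m2 and 1 Tn = 1e6 g, so Tn y-1 = g m-2 y-1 x ha / 100.
    """
    if surface_ha <= 0:
        raise ValueError("surface_ha must be positive")
    return areal_balance_g_m2_y * surface_ha / 100.0


def landscape_totals(
    per_type: dict[str, tuple[float, float]],
) -> dict[str, object]:
    """Sum per-wetland-type landscape balances and compute shares.

    ``per_type`` maps wetland type to (C Tn y-1, CO2-eq Tn y-1).  Returns
    totals plus each type's share of the C total (shares sum to 1; computed
    on signed values, so they are fractions of the net balance).
    """
    if not per_type:
        raise ValueError("no wetland types given")
    total_c = sum(v[0] for v in per_type.values())
    total_gwp = sum(v[1] for v in per_type.values())
    shares = {
        k: (v[0] / total_c if total_c != 0 else float("nan"))
        for k, v in per_type.items()
    }
    return {"total_c_tn_y": total_c, "total_co2eq_tn_y": total_gwp, "shares": shares}
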