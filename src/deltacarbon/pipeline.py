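"""Dataframe-level drivers wiring the processing stages together.

Each function takes the tabular inputs (as read from the fixture CSVs or any
field dataset with the same schema) and returns tidy dataframes; the CLI and
the analysis scripts are thin wrappers over these.
"""

from __future__ import annotations

import datetime as _dt
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from . import budget as _budget
from . import methane as _methane
from . import oxygen as _oxygen
from . import vegetation as _vegetation

__all__ = [
    "compute_metabolic_rates",
    "compute_vegetation_rates",
    "compute_ch4_rates",
    "compute_date_balances",
    "fit_responses",
    "compute_annual_budgets",
    "extrapolate_budgets",
    "load_sites_yaml",
    "run_pipeline",
]

RATE_COLUMNS = [
    "site_id",
    "date",
    "compartment",
    "process",
    "value_mg_c_m2_d",
    "sd",
    "n",
]


def _date(value) -> _dt.date:
    if isinstance(value, _dt.date):
        return value
    return _dt.date.fromisoformat(str(value)[:10])


def _rates_to_frame(rates: list[_oxygen.MetabolicRate]) -> pd.DataFrame:
    return pd.DataFrame(
        [
            {
                "site_id": r.site_id,
                "date": r.date.isoformat(),
                "compartment": r.compartment,
                "process": r.process,
                "value_mg_c_m2_d": r.value,
                "sd": r.sd,
                "n": r.n_replicates,
            }
            for r in rates
        ],
        columns=RATE_COLUMNS,
    )


def compute_metabolic_rates(
    incubations: pd.DataFrame,
    campaigns: pd.DataFrame,
    pq: float = 1.0,
    rq: float = 1.0,
) -> pd.DataFrame:
    """Light/dark O2 incubations -> daily areal GPP/NCP/R rates per site/date."""
    camp_idx = campaigns.set_index(["site_id", "date"])
    out: list[_oxygen.MetabolicRate] = []
    for (site, date, compartment), group in incubations.groupby(
        ["site_id", "date", "compartment"], sort=True
    ):
        c = camp_idx.loc[(site, date)]
        campaign = _oxygen.SamplingCampaign(
            site_id=site,
            date=_date(date),
            daylight_h=float(c["daylight_h"]),
            water_temp_c=float(c["water_temp_c"]),
            conductivity_ms_cm=float(c["conductivity_ms_cm"]),
            depth_m=float(c["depth_m"]),
        )
        incs = [
            _oxygen.OxygenIncubation(
                campaign=campaign,
                compartment=compartment,
                treatment=row["treatment"],
                o2_start_mg_l=float(row["o2_start_mg_l"]),
                o2_end_mg_l=float(row["o2_end_mg_l"]),
                duration_h=float(row["duration_h"]),
                enclosed_volume_l=float(row["enclosed_volume_l"]),
                basal_area_m2=float(row["basal_area_m2"]),
            )
            for _, row in group.iterrows()
        ]
        out.extend(_oxygen.community_daily_rates(incs, pq=pq, rq=rq))
    return _rates_to_frame(out)


def compute_vegetation_rates(
    quadrats: pd.DataFrame,
    coeffs: _vegetation.CarbonCoefficients = _vegetation.CarbonCoefficients(),
    clip_negative: bool = True,
) -> pd.DataFrame:
    """Quadrat harvests -> interval net production (process VEG_P).

    The rate between two consecutive campaigns is reported at the interval's
    end date; the first campaign of a site therefore carries no row.
    """
    rows = []
    for site, site_q in quadrats.groupby("site_id", sort=True):
        stocks = []
        for date, group in site_q.groupby("date", sort=True):
            harvests = [
                _vegetation.QuadratHarvest(
                    site_id=site,
                    date=_date(date),
                    plant_type=row["plant_type"],
                    dry_weight_g=float(row["dry_weight_g"]),
                    quadrat_area_m2=float(row["quadrat_area_m2"]),
                )
                for _, row in group.iterrows()
            ]
            stocks.append(_vegetation.standing_stock(harvests, coeffs))
        stocks.sort(key=lambda s: s.date)
        for prev, cur in zip(stocks, stocks[1:]):
            days = (cur.date - prev.date).days
            rate = _vegetation.interval_production(
                prev.mean_g_c_m2, cur.mean_g_c_m2, days, clip_negative=clip_negative
            )
            sd = _vegetation.interval_production_sd(
                prev.sd_g_c_m2, cur.sd_g_c_m2, prev.n, cur.n, days
            )
            rows.append(
                {
                    "site_id": site,
                    "date": cur.date.isoformat(),
                    "compartment": "vegetation",
                    "process": "VEG_P",
                    "value_mg_c_m2_d": rate,
                    "sd": sd,
                    "n": cur.n,
                }
            )
    return pd.DataFrame(rows, columns=RATE_COLUMNS)


def _cores_from_frame(group: pd.DataFrame) -> list[_methane.CoreIncubation]:
    return [
        _methane.CoreIncubation(
            site_id=row["site_id"],
            date=_date(row["date"]),
            tube_length_cm=float(row["tube_length_cm"]),
            tube_diameter_cm=float(row["tube_diameter_cm"]),
            sediment_depth_cm=float(row["sediment_depth_cm"]),
            water_depth_cm=float(row["water_depth_cm"]),
            duration_d=float(row["duration_d"]),
            ch4_ppm_start=float(row["ch4_ppm_start"]),
            ch4_ppm_end=float(row["ch4_ppm_end"]),
            incubation_temp_c=float(row["temp_c"]),
            conductivity_ms_cm=float(row["conductivity_ms_cm"]),
            pressure_atm=float(row.get("pressure_atm", 1.0)),
        )
        for _, row in group.iterrows()
    ]


def compute_ch4_rates(cores: pd.DataFrame) -> pd.DataFrame:
    """Core incubations -> mean areal CH4 emission per site/date."""
    out = []
    for (_site, _date_), group in cores.groupby(["site_id", "date"], sort=True):
        out.append(_methane.site_flux(_cores_from_frame(group)))
    return _rates_to_frame(out)


def compute_date_balances(rates: pd.DataFrame) -> pd.DataFrame:
    """Per-date joint plankton+benthos C balance (positive = source)."""
    rows = []
    open_water = rates[rates["compartment"].isin(["plankton", "benthos"])]
    for (site, date), group in open_water.groupby(["site_id", "date"], sort=True):
        keyed = {
            f"{row['compartment']}_{row['process'].lower()}": row["value_mg_c_m2_d"]
            for _, row in group.iterrows()
        }
        rows.append(
            {
                "site_id": site,
                "date": date,
                "balance_mg_c_m2_d": _budget.date_balance(keyed),
            }
        )
    return pd.DataFrame(rows)


def fit_responses(cores: pd.DataFrame, model: str) -> pd.DataFrame:
    """Fit the manipulation-experiment response curve per site.

    ``model`` is "temperature" (exponential) or "salinity" (power law).
    """
    rows = []
    for site, group in cores.groupby("site_id", sort=True):
        core_objs = _cores_from_frame(group)
        fluxes = [_methane.core_flux(c) for c in core_objs]
        if model == "temperature":
            fit = _methane.fit_temperature_response(
                [c.incubation_temp_c for c in core_objs], fluxes
            )
        elif model == "salinity":
            fit = _methane.fit_salinity_response(
                [c.conductivity_ms_cm for c in core_objs], fluxes
            )
        else:
            raise ValueError(f"unknown model {model!r}")
        rows.append(
            {
                "site_id": site,
                "model": fit.model,
                "a": fit.a,
                "b": fit.b,
                "r": fit.r,
                "p": fit.p_value,
                "n": fit.n_points,
            }
        )
    return pd.DataFrame(rows)


PROCESS_KEYS = {
    ("plankton", "GPP"): "plankton_gpp",
    ("plankton", "R"): "plankton_r",
    ("benthos", "GPP"): "benthos_gpp",
    ("benthos", "R"): "benthos_r",
    ("sediment", "CH4"): "ch4",
    ("vegetation", "VEG_P"): "vegetation",
}


def _annual_rate_multi_cycle(dates: list[_dt.date], values: np.ndarray, anchor: _dt.date) -> float:
    """Average the annual integral over 365-day cycles anchored at ``anchor``."""
    cycles: dict[int, tuple[list[_dt.date], list[float]]] = {}
    for d, v in zip(dates, values):
        k = (d - anchor).days // 365
        cycles.setdefault(k, ([], []))[0].append(d)
        cycles[k][1].append(float(v))
    annual = [
        _budget.annual_process_rate(ds, vs) for ds, vs in cycles.values()
    ]
    return float(np.mean(annual))


def compute_annual_budgets(
    rates: pd.DataFrame,
    site_configs: dict[str, _budget.SiteConfig],
    constants: _budget.GwpConstants = _budget.GwpConstants(),
) -> pd.DataFrame:
    """Dated rates -> per-site annual areal C and CO2-eq balances.

    Records spanning more than one year are split into 365-day hydrological
    cycles (anchored at the site's first sampling date) and the per-cycle
    annual rates averaged before coverage weighting.
    """
    rows = []
    for site, site_rates in rates.groupby("site_id", sort=True):
        config = site_configs[site]
        anchor = min(_date(d) for d in site_rates["date"])
        annual: dict[str, float] = {}
        for (compartment, process), key in PROCESS_KEYS.items():
            sel = site_rates[
                (site_rates["compartment"] == compartment)
                & (site_rates["process"] == process)
            ].sort_values("date")
            if sel.empty:
                continue
            dates = [_date(d) for d in sel["date"]]
            annual[key] = _annual_rate_multi_cycle(
                dates, sel["value_mg_c_m2_d"].to_numpy(), anchor
            )
        result = _budget.annual_budget(annual, config)
        gwp = _budget.gwp_of_budget(result, constants)
        row = {"site_id": site}
        row.update({k: result.contributions[k] for k in _budget.CONTRIBUTIONS})
        row["c_balance_g_c_m2_y"] = result.c_balance
        row["gwp_g_co2eq_m2_y"] = gwp
        rows.append(row)
    return pd.DataFrame(rows)


def extrapolate_budgets(
    budgets: pd.DataFrame, site_configs: dict[str, _budget.SiteConfig]
) -> pd.DataFrame:
    """Areal balances -> landscape totals per wetland type (Tn y-1)."""
    rows = []
    for _, row in budgets.iterrows():
        config = site_configs[row["site_id"]]
        rows.append(
            {
                "wetland_type": config.wetland_type,
                "site_id": row["site_id"],
                "surface_ha": config.surface_ha,
                "c_tn_y": _budget.extrapolate(
                    row["c_balance_g_c_m2_y"], config.surface_ha
                ),
                "co2eq_tn_y": _budget.extrapolate(
                    row["gwp_g_co2eq_m2_y"], config.surface_ha
                ),
            }
        )
    frame = pd.DataFrame(rows)
    totals = _budget.landscape_totals(
        {r["wetland_type"]: (r["c_tn_y"], r["co2eq_tn_y"]) for r in rows}
    )
    frame["share"] = frame["wetland_type"].map(totals["shares"])
    return frame


def load_sites_yaml(
    path: str | Path,
) -> tuple[dict[str, _budget.SiteConfig], _budget.GwpConstants, dict[str, float]]:
    """Read the per-site configuration file (coverage, surfaces, constants)."""
    with open(path) as fh:
        raw = yaml.safe_load(fh)
    configs = {
        site: _budget.SiteConfig(
            site_id=site,
            wetland_type=cfg["wetland_type"],
            vegetated_fraction=float(cfg["vegetated_fraction"]),
            plant_type=cfg["plant_type"],
            surface_ha=float(cfg["surface_ha"]),
            ch4_coverage=cfg.get("ch4_coverage", "open"),
        )
        for site, cfg in raw["sites"].items()
    }
    constants = _budget.GwpConstants(
        ch4_co2_factor=float(raw.get("gwp", {}).get("ch4_co2_factor", 28.0))
    )
    quotients = raw.get("quotients", {"photosynthetic": 1.0, "respiratory": 1.0})
    return configs, constants, quotients


def run_pipeline(fixture_dir: str | Path) -> dict[str, pd.DataFrame]:
    """End-to-end run on a fixture directory; returns all result frames."""
    fixture_dir = Path(fixture_dir)
    campaigns = pd.read_csv(fixture_dir / "campaigns.csv")
    incubations = pd.read_csv(fixture_dir / "oxygen_incubations.csv")
    quadrats = pd.read_csv(fixture_dir / "quadrats.csv")
    cores = pd.read_csv(fixture_dir / "cores.csv")
    configs, constants, quotients = load_sites_yaml(fixture_dir / "sites.yaml")

    rates = pd.concat(
        [
            compute_metabolic_rates(
                incubations,
                campaigns,
                pq=quotients["photosynthetic"],
                rq=quotients["respiratory"],
            ),
            compute_vegetation_rates(quadrats),
            compute_ch4_rates(cores),
        ],
        ignore_index=True,
    )
    budgets = compute_annual_budgets(rates, configs, constants)
    landscape = extrapolate_budgets(budgets, configs)
    return {
        "rates": rates,
        "date_balances": compute_date_balances(rates),
        "budgets": budgets,
        "landscape": landscape,
    }
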