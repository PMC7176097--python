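"""Synthetic field campaigns for the three deltaic wetland archetypes.

Generates input datasets with the statistical structure the pipeline assumes:
three sites along a salinity gradient (a Salicornia salt marsh at ~57
mS cm-1, a brackish lagoon at ~31, a reed-covered freshwater wetland at ~2),
sampled bi-monthly over two hydrological cycles, with seasonal temperature
forcing, exponential temperature dependence of the metabolic rates, power-law
salinity inhibition of CH4 emission, and multiplicative lognormal replicate
noise at the bottle/jar/core/quadrat level.

The generator *inverts* the measurement model: it draws true areal daily
rates, then back-computes the raw observations (bottle O2 concentrations,
quadrat dry weights, headspace ppm readings) that would produce those rates
through the pipeline's forward chain.  Generator and pipeline share no
forward code path, so a zero-noise round trip is a genuine identity check.
True values are written alongside the fixtures (``truth.csv``).

Rate magnitudes are calibrated to the seasonal ranges observed in the Ebro
Delta sites (brackish plankton GPP peaking in the thousands of mg C m-2 d-1,
salt-marsh rates near 100 off-season, CH4 highest in the freshwater site);
they emulate ranges and orderings, not any site's exact annual numbers.
"""

from __future__ import annotations

import datetime as _dt
import math
import zlib
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from .methane import GAS_CONSTANT_L_ATM, MOLAR_MASS_C
from .oxygen import O2_TO_C, daylight_hours
from .reference import SURFACES_HA

__all__ = [
    "SiteArchetype",
    "GeneratorConfig",
    "ARCHETYPES",
    "simulate_environment",
    "simulate_oxygen_incubations",
    "simulate_quadrats",
    "simulate_cores",
    "write_fixture_set",
]

LATITUDE_DEG = 40.65  # Ebro Delta
REFERENCE_TEMP_C = 18.0


@dataclass(frozen=True)
class SiteArchetype:
    """Parameters of one wetland-type archetype.

    Baseline rates are true areal daily magnitudes (mg C m-2 d-1) at the
    18 degC reference temperature; rates scale as exp(b_temp (T - 18)) and,
    for respiration and CH4, by (conductivity / site mean)**b_salinity.
    """

    name: str
    wetland_type: str
    conductivity_ms_cm: float
    conductivity_jitter_sd: float
    depth_m: float
    vegetated_fraction: float
    plant_type: str
    gpp_plankton: float
    r_plankton: float
    gpp_benthos: float
    r_benthos: float
    ch4_base: float
    b_temp: float = 0.10
    b_temp_ch4: float = 0.12
    b_salinity: float = -0.8
    peak_biomass_g_dw_m2: float = 300.0
    winter_biomass_g_dw_m2: float = 30.0
    cv: float = 0.2


#: the three study-condition archetypes along the salinity gradient
ARCHETYPES: dict[str, SiteArchetype] = {
    "salt_marsh": SiteArchetype(
        name="salt_marsh",
        wetland_type="salt_marsh",
        conductivity_ms_cm=56.6,
        conductivity_jitter_sd=6.0,
        depth_m=0.45,
        vegetated_fraction=0.37,
        plant_type="halophyte",
        gpp_plankton=350.0,
        r_plankton=330.0,
        gpp_benthos=250.0,
        r_benthos=240.0,
        ch4_base=4.0,
        peak_biomass_g_dw_m2=450.0,
        winter_biomass_g_dw_m2=40.0,
    ),
    "brackish": SiteArchetype(
        name="brackish",
        wetland_type="brackish",
        conductivity_ms_cm=31.3,
        conductivity_jitter_sd=5.0,
        depth_m=0.20,
        vegetated_fraction=0.37,
        plant_type="halophyte",
        gpp_plankton=2500.0,
        r_plankton=1600.0,
        gpp_benthos=300.0,
        r_benthos=450.0,
        ch4_base=30.0,
        peak_biomass_g_dw_m2=300.0,
        winter_biomass_g_dw_m2=30.0,
    ),
    "freshwater": SiteArchetype(
        name="freshwater",
        wetland_type="freshwater",
        conductivity_ms_cm=2.0,
        conductivity_jitter_sd=0.2,
        depth_m=0.50,
        vegetated_fraction=0.50,
        plant_type="helophyte",
        gpp_plankton=700.0,
        r_plankton=650.0,
        gpp_benthos=150.0,
        r_benthos=250.0,
        ch4_base=40.0,
        peak_biomass_g_dw_m2=1400.0,
        winter_biomass_g_dw_m2=100.0,
    ),
}


def _default_dates() -> tuple[_dt.date, ...]:
    start = _dt.date(2015, 7, 15)
    return tuple(start + _dt.timedelta(days=73 * i) for i in range(10))


@dataclass(frozen=True)
class GeneratorConfig:
    """Campaign structure, replicate counts and noise level."""

    seed: int = 0
    dates: tuple[_dt.date, ...] = field(default_factory=_default_dates)
    n_bottles: int = 4  # per light/dark treatment
    n_cores: int = 12
    n_quadrats: int = 15
    cv: float | None = None  # overrides the archetype CV when set

    def __post_init__(self) -> None:
        if min(self.n_bottles, self.n_cores, self.n_quadrats) < 1:
            raise ValueError("replicate counts must be >= 1")
        if any(b <= a for a, b in zip(self.dates, self.dates[1:])):
            raise ValueError("dates must be strictly increasing")


def _rng(config: GeneratorConfig, archetype: SiteArchetype, stream: str) -> np.random.Generator:
    # crc32 gives a process-independent stream key (str hash() is salted)
    return np.random.default_rng(
        np.random.SeedSequence(
            entropy=config.seed % (2**31),
            spawn_key=(
                zlib.crc32(archetype.name.encode()),
                zlib.crc32(stream.encode()),
            ),
        )
    )


def _lognormal_noise(rng: np.random.Generator, cv: float, size) -> np.ndarray:
    """Unit-mean multiplicative lognormal noise with the given CV."""
    if cv == 0:
        return np.ones(size)
    sigma2 = math.log(1.0 + cv * cv)
    return rng.lognormal(mean=-sigma2 / 2.0, sigma=math.sqrt(sigma2), size=size)


def water_temperature(date: _dt.date) -> float:
    """Seasonal water temperature: mean 18 degC, amplitude 10, peak 1 Aug."""
    doy = date.timetuple().tm_yday
    return 18.0 + 10.0 * math.cos(2.0 * math.pi * (doy - 213) / 365.0)


def _seasonal_factor(archetype: SiteArchetype, temp_c: float, ch4: bool = False) -> float:
    b = archetype.b_temp_ch4 if ch4 else archetype.b_temp
    return math.exp(b * (temp_c - REFERENCE_TEMP_C))


def _salinity_factor(archetype: SiteArchetype, conductivity: float) -> float:
    return (conductivity / archetype.conductivity_ms_cm) ** archetype.b_salinity


def simulate_environment(
    archetype: SiteArchetype, config: GeneratorConfig
) -> pd.DataFrame:
    """Campaign series: date, daylight, temperature, conductivity, depth."""
    rng = _rng(config, archetype, "environment")
    rows = []
    for date in config.dates:
        cond = -1.0
        while cond <= 0:
            cond = rng.normal(archetype.conductivity_ms_cm, archetype.conductivity_jitter_sd)
        rows.append(
            {
                "site_id": archetype.name,
                "date": date.isoformat(),
                "daylight_h": round(daylight_hours(date, LATITUDE_DEG), 4),
                "water_temp_c": round(water_temperature(date), 3),
                "conductivity_ms_cm": round(cond, 3),
                "depth_m": archetype.depth_m,
            }
        )
    return pd.DataFrame(rows)


def true_daily_rates(
    archetype: SiteArchetype, campaigns: pd.DataFrame
) -> pd.DataFrame:
    """True areal daily rates per campaign (the generator's ground truth)."""
    rows = []
    for _, c in campaigns.iterrows():
        temp = float(c["water_temp_c"])
        cond = float(c["conductivity_ms_cm"])
        f = _seasonal_factor(archetype, temp)
        fs = _salinity_factor(archetype, cond)
        fm = _seasonal_factor(archetype, temp, ch4=True)
        truth = {
            ("plankton", "GPP"): archetype.gpp_plankton * f,
            ("plankton", "R"): archetype.r_plankton * f * fs,
            ("benthos", "GPP"): archetype.gpp_benthos * f,
            ("benthos", "R"): archetype.r_benthos * f * fs,
            ("sediment", "CH4"): archetype.ch4_base * fm * fs,
        }
        for (compartment, process), value in truth.items():
            rows.append(
                {
                    "site_id": archetype.name,
                    "date": c["date"],
                    "compartment": compartment,
                    "process": process,
                    "true_value_mg_c_m2_d": value,
                }
            )
    return pd.DataFrame(rows)


# jar geometry defaults (unreported in the field protocol; plausible values)
BOTTLE_DURATION_H = 2.0
O2_START_MG_L = 8.0
JAR_VOLUME_L = 2.0
JAR_AREA_M2 = 0.02


def simulate_oxygen_incubations(
    archetype: SiteArchetype, campaigns: pd.DataFrame, config: GeneratorConfig
) -> pd.DataFrame:
    """Bottle/jar O2 records whose forward processing recovers the true rates.

    True daily GPP and R are converted back through diel scaling, geometry and
    O2:C stoichiometry into per-enclosure start/end O2 concentrations; noise
    multiplies the per-enclosure GPP and R components independently.
    """
    rng = _rng(config, archetype, "oxygen")
    cv = archetype.cv if config.cv is None else config.cv
    truth = true_daily_rates(archetype, campaigns).set_index(
        ["date", "compartment", "process"]
    )["true_value_mg_c_m2_d"]

    rows = []
    for _, c in campaigns.iterrows():
        date = c["date"]
        daylight = float(c["daylight_h"])
        depth = float(c["depth_m"])
        for compartment in ("plankton", "benthos"):
            gpp_d = truth[(date, compartment, "GPP")]
            r_d = truth[(date, compartment, "R")]
            # daily C -> hourly C -> hourly O2 -> volumetric O2
            gpp_h_o2 = gpp_d / daylight / O2_TO_C
            r_h_o2 = r_d / 24.0 / O2_TO_C
            if compartment == "plankton":
                to_vol = 1.0 / (1000.0 * depth)
                vol_l, area = float("nan"), float("nan")
            else:
                to_vol = JAR_AREA_M2 / JAR_VOLUME_L
                vol_l, area = JAR_VOLUME_L, JAR_AREA_M2
            gpp_v = gpp_h_o2 * to_vol
            r_v = r_h_o2 * to_vol
            noise_g = _lognormal_noise(rng, cv, 2 * config.n_bottles)
            noise_r = _lognormal_noise(rng, cv, 2 * config.n_bottles)
            for k in range(2 * config.n_bottles):
                light = k < config.n_bottles
                if light:
                    rate = gpp_v * noise_g[k] - r_v * noise_r[k]
                else:
                    rate = -r_v * noise_r[k]
                o2_end = O2_START_MG_L + rate * BOTTLE_DURATION_H
                rows.append(
                    {
                        "site_id": archetype.name,
                        "date": date,
                        "compartment": compartment,
                        "treatment": "light" if light else "dark",
                        "replicate": (k % config.n_bottles) + 1,
                        "o2_start_mg_l": O2_START_MG_L,
                        "o2_end_mg_l": max(o2_end, 0.0),
                        "duration_h": BOTTLE_DURATION_H,
                        "enclosed_volume_l": vol_l,
                        "basal_area_m2": area,
                    }
                )
    return pd.DataFrame(rows)


def biomass_g_dw_m2(archetype: SiteArchetype, date: _dt.date) -> float:
    """Seasonal above-ground biomass trajectory, g dry weight m-2.

    Logistic green-up through spring/summer (inflection late June), then a
    linear dieback after late September to the winter standing minimum.
    """
    doy = date.timetuple().tm_yday
    if doy <= 270:
        frac = 1.0 / (1.0 + math.exp(-(doy - 180) / 20.0))
        if doy < 90:  # late-winter remnant of last year's dieback
            frac = 1.0 / (1.0 + math.exp(-(90 - 180) / 20.0)) * max(0.0, 1.0 - (90 - doy) / 60.0)
    else:
        f270 = 1.0 / (1.0 + math.exp(-(270 - 180) / 20.0))
        frac = f270 * max(0.0, 1.0 - (doy - 270) / 75.0)
    span = archetype.peak_biomass_g_dw_m2 - archetype.winter_biomass_g_dw_m2
    return archetype.winter_biomass_g_dw_m2 + span * frac


QUADRAT_AREA_M2 = 0.25


def simulate_quadrats(
    archetype: SiteArchetype, campaigns: pd.DataFrame, config: GeneratorConfig
) -> pd.DataFrame:
    """Quadrat dry-weight records following the seasonal biomass trajectory."""
    rng = _rng(config, archetype, "quadrats")
    cv = archetype.cv if config.cv is None else config.cv
    rows = []
    for _, c in campaigns.iterrows():
        date = _dt.date.fromisoformat(c["date"])
        biomass = biomass_g_dw_m2(archetype, date)
        noise = _lognormal_noise(rng, cv, config.n_quadrats)
        for k in range(config.n_quadrats):
            rows.append(
                {
                    "site_id": archetype.name,
                    "date": c["date"],
                    "plant_type": archetype.plant_type,
                    "replicate": k + 1,
                    "dry_weight_g": biomass * QUADRAT_AREA_M2 * noise[k],
                    "quadrat_area_m2": QUADRAT_AREA_M2,
                }
            )
    return pd.DataFrame(rows)


# core geometry defaults
CORE_LENGTH_CM = 50.0
CORE_DIAMETER_CM = 4.0
CORE_SEDIMENT_CM = 7.5
CORE_WATER_CM = 20.0
CORE_DURATION_D = 3.0
AMBIENT_CH4_PPM = 1.9
TEMPERATURE_LEVELS_C = (14.0, 20.0, 25.0, 30.0)
#: salinity manipulation factor series by wetland type
SALINITY_FACTORS = {
    "salt_marsh": (0.2, 0.5, 1.0, 2.0),
    "brackish": (0.2, 0.5, 1.0, 2.0),
    "freshwater": (0.5, 1.0, 2.0, 5.0),
}
MANIPULATION_REPLICATES = 5
MANIPULATION_TEMP_C = 20.0  # acclimation temperature of the salinity series


def _flux_to_ppm(flux_mg_c_m2_d: float, temp_c: float) -> float:
    """Headspace ppm increase produced by a given flux over the default core."""
    area_m2 = math.pi * (CORE_DIAMETER_CM / 2.0 / 100.0) ** 2
    head_l = (
        math.pi
        * (CORE_DIAMETER_CM / 2.0) ** 2
        * (CORE_LENGTH_CM - CORE_SEDIMENT_CM - CORE_WATER_CM)
        / 1000.0
    )
    mass_mg = flux_mg_c_m2_d * area_m2 * CORE_DURATION_D
    mol = mass_mg / 1000.0 / MOLAR_MASS_C
    return mol * GAS_CONSTANT_L_ATM * (temp_c + 273.15) / (1.0 * head_l) * 1e6


def _core_row(
    archetype: SiteArchetype, date: str, replicate: int, flux: float,
    temp_c: float, conductivity: float,
) -> dict:
    return {
        "site_id": archetype.name,
        "date": date,
        "replicate": replicate,
        "tube_length_cm": CORE_LENGTH_CM,
        "tube_diameter_cm": CORE_DIAMETER_CM,
        "sediment_depth_cm": CORE_SEDIMENT_CM,
        "water_depth_cm": CORE_WATER_CM,
        "duration_d": CORE_DURATION_D,
        "ch4_ppm_start": AMBIENT_CH4_PPM,
        "ch4_ppm_end": AMBIENT_CH4_PPM + _flux_to_ppm(flux, temp_c),
        "temp_c": temp_c,
        "conductivity_ms_cm": conductivity,
        "pressure_atm": 1.0,
    }


def simulate_cores(
    archetype: SiteArchetype,
    campaigns: pd.DataFrame,
    config: GeneratorConfig,
    manipulation: str | None = None,
) -> pd.DataFrame:
    """Sediment-core headspace records.

    Field mode (default): replicate cores per campaign at field temperature
    and conductivity.  ``manipulation="temperature"`` emits the four-level
    factorial temperature design at site conductivity;
    ``manipulation="salinity"`` the dilution/concentration series at 20 degC.
    The true flux a exp(b_T T) cond**b_S is inverted through the ideal-gas
    headspace model into ppm readings.
    """
    rng = _rng(config, archetype, f"cores:{manipulation}")
    cv = archetype.cv if config.cv is None else config.cv
    rows: list[dict] = []

    if manipulation is None:
        for _, c in campaigns.iterrows():
            temp = float(c["water_temp_c"])
            cond = float(c["conductivity_ms_cm"])
            true_flux = (
                archetype.ch4_base
                * _seasonal_factor(archetype, temp, ch4=True)
                * _salinity_factor(archetype, cond)
            )
            noise = _lognormal_noise(rng, cv, config.n_cores)
            for k in range(config.n_cores):
                rows.append(
                    _core_row(archetype, c["date"], k + 1, true_flux * noise[k], temp, cond)
                )
    elif manipulation == "temperature":
        date = campaigns["date"].iloc[-1]
        cond = archetype.conductivity_ms_cm
        for temp in TEMPERATURE_LEVELS_C:
            true_flux = archetype.ch4_base * _seasonal_factor(archetype, temp, ch4=True)
            noise = _lognormal_noise(rng, cv, MANIPULATION_REPLICATES)
            for k in range(MANIPULATION_REPLICATES):
                rows.append(
                    _core_row(archetype, date, k + 1, true_flux * noise[k], temp, cond)
                )
    elif manipulation == "salinity":
        date = campaigns["date"].iloc[-1]
        temp = MANIPULATION_TEMP_C
        for factor in SALINITY_FACTORS[archetype.wetland_type]:
            cond = factor * archetype.conductivity_ms_cm
            true_flux = (
                archetype.ch4_base
                * _seasonal_factor(archetype, temp, ch4=True)
                * _salinity_factor(archetype, cond)
            )
            noise = _lognormal_noise(rng, cv, MANIPULATION_REPLICATES)
            for k in range(MANIPULATION_REPLICATES):
                rows.append(
                    _core_row(archetype, date, k + 1, true_flux * noise[k], temp, cond)
                )
    else:
        raise ValueError(f"unknown manipulation {manipulation!r}")
    return pd.DataFrame(rows)


def true_vegetation_stocks(
    archetype: SiteArchetype, campaigns: pd.DataFrame
) -> pd.DataFrame:
    """True standing biomass per campaign date (g DW m-2), for truth output."""
    rows = [
        {
            "site_id": archetype.name,
            "date": c["date"],
            "compartment": "vegetation",
            "process": "BIOMASS_DW",
            "true_value_mg_c_m2_d": biomass_g_dw_m2(
                archetype, _dt.date.fromisoformat(c["date"])
            ),
        }
        for _, c in campaigns.iterrows()
    ]
    return pd.DataFrame(rows)


def write_fixture_set(
    outdir: str | Path, config: GeneratorConfig, archetypes: dict[str, SiteArchetype] | None = None
) -> dict[str, Path]:
    """Write the full fixture file set for all archetypes.

    Emits campaigns.csv, oxygen_incubations.csv, quadrats.csv, cores.csv,
    sites.yaml and truth.csv; byte-identical across reruns with the same
    config.
    """
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    archetypes = archetypes or ARCHETYPES

    campaigns, oxygen, quadrats, cores, truth = [], [], [], [], []
    sites_cfg: dict[str, dict] = {}
    for name, arch in archetypes.items():
        camp = simulate_environment(arch, config)
        campaigns.append(camp)
        oxygen.append(simulate_oxygen_incubations(arch, camp, config))
        quadrats.append(simulate_quadrats(arch, camp, config))
        cores.append(simulate_cores(arch, camp, config))
        truth.append(true_daily_rates(arch, camp))
        truth.append(true_vegetation_stocks(arch, camp))
        sites_cfg[name] = {
            "wetland_type": arch.wetland_type,
            "vegetated_fraction": arch.vegetated_fraction,
            "plant_type": arch.plant_type,
            "surface_ha": SURFACES_HA[arch.wetland_type],
            "ch4_coverage": "open",
        }

    paths = {}
    frames = {
        "campaigns.csv": pd.concat(campaigns, ignore_index=True),
        "oxygen_incubations.csv": pd.concat(oxygen, ignore_index=True),
        "quadrats.csv": pd.concat(quadrats, ignore_index=True),
        "cores.csv": pd.concat(cores, ignore_index=True),
        "truth.csv": pd.concat(truth, ignore_index=True),
    }
    for fname, frame in frames.items():
        path = outdir / fname
        frame.to_csv(path, index=False)
        paths[fname] = path

    sites_path = outdir / "sites.yaml"
    with open(sites_path, "w") as fh:
        yaml.safe_dump(
            {
                "sites": sites_cfg,
                "gwp": {"ch4_co2_factor": 28.0},
                "quotients": {"photosynthetic": 1.0, "respiratory": 1.0},
            },
            fh,
            sort_keys=True,
        )
    paths["sites.yaml"] = sites_path
    return paths
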