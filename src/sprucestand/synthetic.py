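"""Synthetic inputs emulating an upland UK spruce plantation site.

Every input the analysis needs can be generated here, with the statistical
structure of the Harwood-like study site: a cool maritime climate (mean
annual temperature 7.8 degC, mean precipitation 1352 mm yr^-1, latitude
~55 degrees), ten 200 m^2 survey plots with integer dbh recorded above
7 cm and an even-aged unimodal size structure, a seasonal-diurnal GPP
cycle, sparse soil-respiration chamber visits, and a Woodland-Carbon-Code
style five-year yield table.  Column schemas match the package readers so
real site files can be dropped in later.

All generators are deterministic under a fixed seed.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .evaluation import SurveyData
from .productivity import (
    DEFAULT_PRODUCTIVITY,
    ProductivityParams,
    gpp_step,
)
from .simulate import saturation_vapour_pressure_hpa

__all__ = [
    "SiteClimate",
    "DEFAULT_SITE",
    "gen_weather",
    "gen_co2_series",
    "gen_survey",
    "gen_flux_series",
    "gen_wcc_table",
]

SOLAR_CONSTANT_WM2 = 1361.0
STEFAN_BOLTZMANN = 5.670374e-8
DAYS_PER_YEAR = 365.25


@dataclass(frozen=True)
class SiteClimate:
    """Climatological parameters of the emulated site.

    The precipitation gamma scale is derived so the expected annual total
    equals ``annual_precip`` exactly given the wet-day probability and gamma
    shape; wet/dry days follow a two-state Markov chain started from its
    stationary distribution, so the expectation holds from day one.
    """

    mean_annual_t: float = 7.8        # degC
    annual_precip: float = 1352.0     # mm yr^-1
    latitude: float = 55.2            # degrees north
    t_seasonal_amplitude: float = 5.5  # degC, winter-summer half-range
    diurnal_amplitude: float = 3.5    # degC (half-hourly cadence only)
    ar1_rho: float = 0.8              # day-to-day persistence of T anomalies
    t_noise_sd: float = 2.5           # degC, stationary anomaly s.d.
    precip_wet_prob: float = 0.5625   # stationary wet-day probability
    precip_wet_persist: float = 0.65  # P(wet | wet)
    precip_gamma_shape: float = 0.8
    mean_pressure_hpa: float = 978.0  # ~290 m elevation
    mean_cloud: float = 0.6

    def __post_init__(self) -> None:
        if self.annual_precip <= 0:
            raise ValueError("annual precipitation must be positive")
        if not 0 <= self.ar1_rho < 1:
            raise ValueError("ar1_rho must lie in [0, 1)")
        if not 0 < self.precip_wet_prob < 1:
            raise ValueError("wet-day probability must lie in (0, 1)")

    @property
    def precip_gamma_scale(self) -> float:
        """Gamma scale (mm) making E[annual total] = annual_precip."""
        wet_days = self.precip_wet_prob * DAYS_PER_YEAR
        return self.annual_precip / (wet_days * self.precip_gamma_shape)


DEFAULT_SITE = SiteClimate()


def _ar1(rng: np.random.Generator, n: int, rho: float, sd: float) -> np.ndarray:
    """Stationary zero-mean AR(1) path of length n."""
    z = rng.standard_normal(n)
    out = np.empty(n)
    out[0] = z[0] * sd
    innov_sd = sd * np.sqrt(1.0 - rho**2)
    for i in range(1, n):
        out[i] = rho * out[i - 1] + innov_sd * z[i]
    return out


def _solar_declination(doy: np.ndarray) -> np.ndarray:
    return 0.409 * np.sin(2 * np.pi * doy / 365.0 - 1.39)


def _daily_extraterrestrial_wm2(doy: np.ndarray, lat_deg: float) -> np.ndarray:
    """Daily-mean top-of-atmosphere shortwave (W m^-2), FAO-style geometry."""
    phi = np.radians(lat_deg)
    delta = _solar_declination(doy)
    dr = 1.0 + 0.033 * np.cos(2 * np.pi * doy / 365.0)
    x = np.clip(-np.tan(phi) * np.tan(delta), -1.0, 1.0)
    ws = np.arccos(x)
    ra_mj = (
        (24 * 60 / np.pi)
        * 0.0820
        * dr
        * (ws * np.sin(phi) * np.sin(delta) + np.cos(phi) * np.cos(delta) * np.sin(ws))
    )
    return ra_mj * 1e6 / 86400.0


def _markov_wet(rng: np.random.Generator, n: int, pi_wet: float, p_ww: float) -> np.ndarray:
    """Two-state wet/dry chain, stationary start."""
    p_dw = pi_wet * (1.0 - p_ww) / (1.0 - pi_wet)  # P(wet | dry)
    if not 0 <= p_dw <= 1:
        raise ValueError("inconsistent wet-day probability and persistence")
    u = rng.random(n)
    wet = np.empty(n, dtype=bool)
    wet[0] = u[0] < pi_wet
    for i in range(1, n):
        wet[i] = u[i] < (p_ww if wet[i - 1] else p_dw)
    return wet


def gen_weather(
    site: SiteClimate = DEFAULT_SITE,
    years: int = 1,
    cadence: str = "daily",
    seed: int = 0,
    start_year: int = 2015,
) -> pd.DataFrame:
    """Generate a driver series for the site.

    cadence='daily' gives one row per day (gridded-product style);
    cadence='half-hourly' gives 48 rows per day (flux-tower style) with a
    diurnal temperature cycle and solar-geometry shortwave that is zero at
    night.  Columns: tair_c, rh_pct, pressure_hpa, wind_ms, sw_down_wm2,
    lw_down_wm2, precip_mm (per row).  Deterministic under ``seed``.
    """
    if years < 1:
        raise ValueError("need at least one year")
    if cadence not in ("daily", "half-hourly"):
        raise ValueError("cadence must be 'daily' or 'half-hourly'")
    rng = np.random.default_rng(seed)
    days = pd.date_range(
        f"{start_year}-01-01", f"{start_year + years - 1}-12-31", freq="D"
    )
    n_days = len(days)
    t_elapsed = np.arange(n_days, dtype=float)

    # temperature: seasonal cycle peaking late July + persistent anomalies
    season = -site.t_seasonal_amplitude * np.cos(
        2 * np.pi * (t_elapsed - 28.0) / DAYS_PER_YEAR
    )
    anomaly = _ar1(rng, n_days, site.ar1_rho, site.t_noise_sd)
    t_daily = site.mean_annual_t + season + anomaly

    # cloudiness: persistent, bounded
    cloud = np.clip(site.mean_cloud + _ar1(rng, n_days, 0.7, 0.25), 0.02, 1.0)

    # precipitation: Markov occurrence x gamma amounts, wetter under cloud
    doy = days.dayofyear.to_numpy()
    wet = _markov_wet(rng, n_days, site.precip_wet_prob, site.precip_wet_persist)
    amounts = rng.gamma(site.precip_gamma_shape, site.precip_gamma_scale, n_days)
    precip_daily = np.where(wet, amounts, 0.0)

    rh_daily = np.clip(80.0 + 8.0 * (cloud - site.mean_cloud) / 0.25
                       + rng.normal(0.0, 4.0, n_days), 40.0, 100.0)
    pressure_daily = site.mean_pressure_hpa + _ar1(rng, n_days, 0.85, 6.0)
    wind_daily = rng.gamma(2.5, 1.6, n_days)

    if cadence == "daily":
        sw = _daily_extraterrestrial_wm2(doy, site.latitude) * (
            0.25 + 0.50 * (1.0 - cloud)
        )
        t_k = t_daily + 273.15
        lw = (0.70 + 0.22 * cloud) * STEFAN_BOLTZMANN * t_k**4
        return pd.DataFrame(
            {
                "tair_c": t_daily,
                "rh_pct": rh_daily,
                "pressure_hpa": pressure_daily,
                "wind_ms": wind_daily,
                "sw_down_wm2": sw,
                "lw_down_wm2": lw,
                "precip_mm": precip_daily,
            },
            index=days,
        )

    # half-hourly cadence
    stamps = pd.date_range(
        days[0], periods=n_days * 48, freq="30min"
    )
    hour = stamps.hour.to_numpy() + stamps.minute.to_numpy() / 60.0
    day_ix = np.repeat(np.arange(n_days), 48)
    doy_hh = doy[day_ix]
    diurnal = -site.diurnal_amplitude * np.cos(2 * np.pi * (hour - 15.0) / 24.0)
    t_hh = t_daily[day_ix] + diurnal + rng.normal(0.0, 0.4, len(stamps))

    phi = np.radians(site.latitude)
    delta = _solar_declination(doy_hh)
    hour_angle = np.pi / 12.0 * (hour - 12.0)
    cosz = np.maximum(
        np.sin(phi) * np.sin(delta) + np.cos(phi) * np.cos(delta) * np.cos(hour_angle),
        0.0,
    )
    sw_hh = SOLAR_CONSTANT_WM2 * 0.75 * cosz * (1.0 - 0.7 * cloud[day_ix])
    t_k = t_hh + 273.15
    lw_hh = (0.70 + 0.22 * cloud[day_ix]) * STEFAN_BOLTZMANN * t_k**4
    rh_hh = np.clip(rh_daily[day_ix] + rng.normal(0.0, 2.0, len(stamps)), 40.0, 100.0)
    pressure_hh = pressure_daily[day_ix] + rng.normal(0.0, 0.5, len(stamps))
    wind_hh = np.maximum(wind_daily[day_ix] + rng.normal(0.0, 0.6, len(stamps)), 0.0)
    precip_hh = np.repeat(precip_daily / 48.0, 48)
    return pd.DataFrame(
        {
            "tair_c": t_hh,
            "rh_pct": rh_hh,
            "pressure_hpa": pressure_hh,
            "wind_ms": wind_hh,
            "sw_down_wm2": sw_hh,
            "lw_down_wm2": lw_hh,
            "precip_mm": precip_hh,
        },
        index=stamps,
    )


def gen_co2_series(
    start_year: int = 1973,
    end_year: int = 2018,
    mode: str = "ramp",
    c0: float = 330.0,
    ramp: float = 1.756,
) -> pd.Series:
    """Annual-mean CO2 series (ppm): constant ('fixed') or linear ('ramp').

    The default ramp of 1.756 ppm yr^-1 from 330 ppm reproduces the observed
    ~79 ppm rise between the early 1970s and 2018.
    """
    if end_year < start_year:
        raise ValueError("end_year must not precede start_year")
    years = np.arange(start_year, end_year + 1)
    if mode == "fixed":
        values = np.full(len(years), float(c0))
    elif mode == "ramp":
        values = c0 + ramp * (years - start_year)
    else:
        raise ValueError("mode must be 'fixed' or 'ramp'")
    return pd.Series(values, index=pd.Index(years, name="year"), name="co2_ppm")


def gen_survey(
    n_plots: int = 10,
    plot_area_m2: float = 200.0,
    target_density_ha: float = 1348.0,
    dbh_lognormal_mu: float = 3.135,
    dbh_lognormal_sigma: float = 0.22,
    dbh_min_cm: int = 7,
    seed: int = 0,
) -> SurveyData:
    """Generate an even-aged plot survey.

    Per-plot tree counts are Poisson at the target density; dbh is lognormal
    (defaults emulate a mature ~45-year stand: ~1350 trees ha^-1, mean
    height ~17-18 m), rounded to the nearest cm and resampled below the
    survey minimum so the unimodal shape and the density are both kept.
    """
    rng = np.random.default_rng(seed)
    mean_count = target_density_ha * plot_area_m2 / 10_000.0
    plots = []
    for _ in range(n_plots):
        k = rng.poisson(mean_count)
        dbh = np.empty(0, dtype=int)
        while len(dbh) < k:
            draw = np.rint(
                rng.lognormal(dbh_lognormal_mu, dbh_lognormal_sigma, k - len(dbh))
            ).astype(int)
            dbh = np.concatenate([dbh, draw[draw >= dbh_min_cm]])
        plots.append(tuple(int(d) for d in dbh))
    return SurveyData(tuple(plots), plot_area_m2=plot_area_m2, dbh_min_cm=dbh_min_cm)


def gen_flux_series(
    drivers: pd.DataFrame,
    lai: float = 5.5,
    ca_ppm: float = 400.0,
    f_root: float = 0.42,
    q10_soil: float = 2.0,
    soil_resp_rate_10: float = 1.2,     # kgC m^-2 yr^-1 at 10 degC
    above_resp_rate_10: float = 0.5,    # kgC m^-2 yr^-1 at 10 degC
    chamber_every_days: int = 14,
    gap_fraction: float = 0.02,
    prod: ProductivityParams = DEFAULT_PRODUCTIVITY,
    seed: int = 0,
) -> tuple[pd.DataFrame, pd.DataFrame, pd.DataFrame]:
    """Generate a self-consistent tower flux record with known truth.

    From half-hourly drivers: GPP follows the light-use-efficiency model at
    fixed LAI and CO2; soil respiration is an exact Q10 response of air
    temperature; above-ground respiration likewise; tree respiration is the
    root share of soil respiration plus the above-ground component; Reco is
    soil plus above-ground respiration; NEE = Reco - GPP.  Soil respiration
    is thinned to chamber visits every ``chamber_every_days`` at noon, and
    random gaps are injected into pressure, wind and humidity.

    Returns (tower, chambers, truth): the tower frame carries met columns
    plus gpp/reco/nee (kgC m^-2 per half hour); chambers has columns
    value/t_mean; truth additionally holds soil_resp, tree_resp and npp.
    The inference chain run with the same f_root and q10 recovers the truth
    to floating-point precision.
    """
    idx = drivers.index
    if len(idx) > 1 and (idx[1] - idx[0]) != pd.Timedelta("30min"):
        raise ValueError("flux generation needs half-hourly drivers")
    rng = np.random.default_rng(seed)
    t = drivers["tair_c"].to_numpy()
    e_s = saturation_vapour_pressure_hpa(t)
    vpd = e_s * (1.0 - drivers["rh_pct"].to_numpy() / 100.0)
    step_days = 1.0 / 48.0
    gpp = gpp_step(
        drivers["sw_down_wm2"].to_numpy(), t, vpd,
        lai=lai, ca_ppm=ca_ppm, dt_days=step_days, params=prod,
    )
    q10_fac = q10_soil ** ((t - 10.0) / 10.0)
    steps_per_year = DAYS_PER_YEAR * 48.0
    soil = soil_resp_rate_10 / steps_per_year * q10_fac
    above = above_resp_rate_10 / steps_per_year * q10_fac
    tree = f_root * soil + above
    reco = soil + above            # == tree + (1 - f_root) * soil
    nee = reco - gpp

    truth = pd.DataFrame(
        {"gpp": gpp, "soil_resp": soil, "tree_resp": tree, "reco": reco,
         "nee": nee, "npp": gpp - tree},
        index=idx,
    )

    tower = drivers.copy()
    tower["gpp"] = gpp
    tower["reco"] = reco
    tower["nee"] = nee
    for col in ("pressure_hpa", "wind_ms", "rh_pct"):
        gaps = rng.random(len(idx)) < gap_fraction
        tower.loc[gaps, col] = np.nan

    noon = (idx.hour == 12) & (idx.minute == 0)
    day_number = (idx - idx[0]).days
    visit = noon & (day_number % chamber_every_days == 0)
    chambers = pd.DataFrame(
        {"value": truth.loc[visit, "soil_resp"],
         "t_mean": tower.loc[visit, "tair_c"]}
    )
    return tower, chambers, truth


def gen_wcc_table(
    max_age: int = 60,
    period_years: int = 5,
    standing_max_tc: float = 260.0,
    growth_rate: float = 0.12,
    age_mid: float = 22.0,
    thinned: bool = True,
    thin_start_age: int = 15,
    thin_per_period_tc: float = 6.0,
) -> pd.DataFrame:
    """A WCC-style per-period yield table (synthetic stand-in).

    Standing-carbon increments follow a logistic stand-growth curve typical
    of a high-yield-class spruce plantation; the thinned variant removes a
    fixed carbon amount every period from ``thin_start_age`` and grows a
    correspondingly reduced standing stock.  Values in tCO2 ha^-1 per
    period, matching the reader schema (age_from, age_to,
    carbon_standing_tCO2, removed_tCO2, variant).
    """
    ages = np.arange(0, max_age + 1, period_years, dtype=float)

    def logistic(a: np.ndarray) -> np.ndarray:
        return standing_max_tc / (1.0 + np.exp(-growth_rate * (a - age_mid)))

    cum = logistic(ages) - logistic(np.zeros_like(ages))
    inc_tc = np.diff(cum)
    removed_tc = np.zeros_like(inc_tc)
    if thinned:
        thinning = ages[:-1] >= thin_start_age
        removed_tc[thinning] = thin_per_period_tc
        inc_tc = np.maximum(inc_tc * 0.82, 0.0)  # thinned stands carry less stock
    co2 = 44.0 / 12.0
    return pd.DataFrame(
        {
            "age_from": ages[:-1].astype(int),
            "age_to": ages[1:].astype(int),
            "carbon_standing_tCO2": inc_tc * co2,
            "removed_tCO2": removed_tc * co2,
            "variant": "thinned" if thinned else "unthinned",
        }
    )
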