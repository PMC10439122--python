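"""End-to-end stand simulation: weather + CO2 in, demographic trajectory out.

Productivity is evaluated at the driver resolution (daily rows of a
DriverSeries-style DataFrame) and aggregated onto monthly demographic steps
(dt = 1/12 yr).  Within each month the leaf area index is held at its
start-of-month value; GPP is summed over the month's driver rows, the
biomass-dependent maintenance respiration uses the month's temperatures,
and the resulting NPP rate feeds one demography step.  A thinning event,
if configured, fires at the first step boundary where the stand age reaches
its trigger.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .demography import (
    DEFAULT_PFT,
    MassClassGrid,
    PFTParams,
    StandState,
    stand_aggregates,
    step_demography,
)
from .management import ThinningEvent, ThinningYield, apply_thinning, total_sequestration
from .productivity import (
    DEFAULT_PRODUCTIVITY,
    ProductivityParams,
    gpp_step,
    npp_step,
)

__all__ = ["RunResult", "run_simulation", "saturation_vapour_pressure_hpa"]

DT_DEMOGRAPHY = 1.0 / 12.0


def saturation_vapour_pressure_hpa(t_air_c):
    """August-Roche-Magnus saturation vapour pressure (hPa)."""
    t = np.asarray(t_air_c, dtype=float)
    out = 6.1094 * np.exp(17.625 * t / (t + 243.04))
    return float(out) if out.ndim == 0 else out


def _vpd_hpa(t_air_c, rh_pct):
    return saturation_vapour_pressure_hpa(t_air_c) * (
        1.0 - np.clip(np.asarray(rh_pct, float), 0.0, 100.0) / 100.0
    )


@dataclass
class RunResult:
    """Annual trajectory plus event log of one simulation.

    ``annual`` has one row per simulated year: stand age, number density
    (trees ha^-1), live carbon (tC ha^-1), LAI, product pool and total
    sequestration (tC ha^-1), annual GPP and NPP (kgC m^-2 yr^-1).
    ``thinning`` records the single event, if it fired.
    """

    annual: pd.DataFrame
    final_state: StandState
    thinning: ThinningYield | None = None
    monthly_npp: list = field(default_factory=list)


def run_simulation(
    drivers: pd.DataFrame,
    co2_by_year: pd.Series,
    grid: MassClassGrid,
    initial_state: StandState,
    pft: PFTParams = DEFAULT_PFT,
    prod: ProductivityParams = DEFAULT_PRODUCTIVITY,
    years: int | None = None,
    thinning: ThinningEvent | None = None,
) -> RunResult:
    """Run the coupled productivity-demography model over daily drivers.

    ``drivers`` needs a DatetimeIndex (daily cadence) and columns
    ``tair_c``, ``rh_pct``, ``sw_down_wm2``.  ``co2_by_year`` maps calendar
    year to annual-mean CO2 (ppm); years absent from the series reuse its
    last value.  The driver years are recycled if the run is longer than the
    driver record.
    """
    for col in ("tair_c", "rh_pct", "sw_down_wm2"):
        if col not in drivers.columns:
            raise ValueError(f"drivers missing required column {col!r}")
    idx = drivers.index
    if not isinstance(idx, pd.DatetimeIndex):
        raise ValueError("drivers must carry a DatetimeIndex")
    driver_years = sorted(idx.year.unique())
    start_year = driver_years[0]
    if years is None:
        years = len(driver_years)

    # pre-split driver rows by (year, month) once
    by_ym = {
        ym: sub for ym, sub in drivers.groupby([idx.year, idx.month], sort=True)
    }

    state = initial_state.copy()
    records = []
    monthly_npp: list[float] = []
    thin_yield: ThinningYield | None = None

    for step_year in range(years):
        sim_year = start_year + step_year
        drv_year = driver_years[step_year % len(driver_years)]
        ca = float(
            co2_by_year.get(sim_year, co2_by_year.iloc[-1])
        )
        gpp_year = 0.0
        npp_year = 0.0
        for month in range(1, 13):
            sub = by_ym[(drv_year, month)]
            agg = stand_aggregates(state, grid, m_trunc=0.0, pft=pft)
            biomass = state.biomass(grid)
            vpd = _vpd_hpa(sub["tair_c"].to_numpy(), sub["rh_pct"].to_numpy())
            gpp_days = gpp_step(
                sub["sw_down_wm2"].to_numpy(),
                sub["tair_c"].to_numpy(),
                vpd,
                lai=agg.lai,
                ca_ppm=ca,
                dt_days=1.0,
                params=prod,
            )
            npp_days = npp_step(
                gpp_days, biomass, sub["tair_c"].to_numpy(), dt_days=1.0, params=prod
            )
            gpp_month = float(np.sum(gpp_days))
            npp_month = float(np.sum(npp_days))
            gpp_year += gpp_month
            npp_year += npp_month
            monthly_npp.append(npp_month)
            state = step_demography(
                state, grid, pft, npp=npp_month / DT_DEMOGRAPHY, dt=DT_DEMOGRAPHY
            )
            if thinning is not None and thinning.due(state):
                state, thin_yield = apply_thinning(state, grid, pft, thinning)
        agg = stand_aggregates(state, grid, m_trunc=0.0, pft=pft)
        records.append(
            {
                "year": sim_year,
                "stand_age": state.stand_age,
                "n_density_ha": agg.n_density_ha,
                "c_density_tc_ha": agg.c_density_tc_ha,
                "lai": agg.lai,
                "product_pool_tc_ha": state.product_pool * 10.0,
                "total_sequestration_tc_ha": total_sequestration(state, grid) * 10.0,
                "gpp_kgc_m2_yr": gpp_year,
                "npp_kgc_m2_yr": npp_year,
            }
        )
    return RunResult(
        annual=pd.DataFrame.from_records(records).set_index("year"),
        final_state=state,
        thinning=thin_yield,
        monthly_npp=monthly_npp,
    )
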