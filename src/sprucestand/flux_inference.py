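"""Observation-side flux processing for an eddy-covariance site.

Given tower GPP and ecosystem respiration plus intermittent soil-respiration
chamber measurements, tree respiration and NPP are inferred in four steps:

1. interpolate the sparse chamber points to the tower timestep with a Q10
   temperature-respiration function anchored at the nearest chamber point;
2. assume a root contribution to soil respiration (42%, range 30-50%);
3. tree respiration = ecosystem respiration minus the non-root share of
   soil respiration;
4. NPP = GPP minus tree respiration.

The root-fraction range propagates to (low, mid, high) uncertainty bands:
tree respiration increases with the root fraction, so the NPP band is the
mirror image.  Driver-cleaning utilities (linear gap fill, specific humidity
from relative humidity via the August-Roche-Magnus formula, radiation
clean-up) live here too.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .simulate import saturation_vapour_pressure_hpa

__all__ = [
    "RootFraction",
    "FluxBands",
    "interpolate_soil_resp_q10",
    "infer_tree_respiration",
    "infer_npp",
    "gapfill_linear",
    "specific_humidity_from_rh",
    "clean_radiation",
    "umol_to_kgc",
]

#: kg of carbon per µmol of CO2.
KG_C_PER_UMOL_CO2 = 12.011e-9


def umol_to_kgc(flux_umol_m2_s, step_seconds: float = 1800.0):
    """Convert a CO2 flux from µmol m^-2 s^-1 to kgC m^-2 per step."""
    out = np.asarray(flux_umol_m2_s, dtype=float) * KG_C_PER_UMOL_CO2 * step_seconds
    return float(out) if out.ndim == 0 else out


@dataclass(frozen=True)
class RootFraction:
    """Root contribution to total soil respiration, with uncertainty range."""

    mid: float = 0.42
    low: float = 0.30
    high: float = 0.50

    def __post_init__(self) -> None:
        if not 0 < self.low <= self.mid <= self.high < 1:
            raise ValueError("need 0 < low <= mid <= high < 1")


@dataclass
class FluxBands:
    """A derived flux with (low, mid, high) uncertainty bands, time-aligned."""

    low: pd.Series
    mid: pd.Series
    high: pd.Series

    def __post_init__(self) -> None:
        if not (self.low.index.equals(self.mid.index) and self.mid.index.equals(self.high.index)):
            raise ValueError("band series must share one time index")
        if not ((self.low <= self.mid + 1e-12).all() and (self.mid <= self.high + 1e-12).all()):
            raise ValueError("band ordering low <= mid <= high violated")


def interpolate_soil_resp_q10(
    chamber_points: pd.DataFrame,
    halfhourly_t: pd.Series,
    q10: float = 2.0,
) -> pd.Series:
    """Fill soil respiration to the tower timestep with a Q10 response.

    ``chamber_points`` needs columns ``value`` (respiration at the chamber
    visit) and ``t_mean`` (mean temperature of the chamber interval), indexed
    by time.  Each tower timestamp uses its nearest-in-time chamber point
    (ties towards the earlier point):
    ``R(t) = R_obs * q10 ** ((T(t) - T_obs) / 10)``.
    Exact at chamber timestamps by construction.
    """
    if len(chamber_points) == 0:
        raise ValueError("need at least one chamber point")
    if q10 <= 0:
        raise ValueError("q10 must be positive")
    ch = chamber_points.sort_index()
    t_target = halfhourly_t.index
    ch_times = ch.index.asi8.astype(float)
    tgt_times = t_target.asi8.astype(float)
    # nearest chamber point, ties to the earlier one
    pos = np.searchsorted(ch_times, tgt_times)
    pos_lo = np.clip(pos - 1, 0, len(ch_times) - 1)
    pos_hi = np.clip(pos, 0, len(ch_times) - 1)
    d_lo = np.abs(tgt_times - ch_times[pos_lo])
    d_hi = np.abs(tgt_times - ch_times[pos_hi])
    nearest = np.where(d_lo <= d_hi, pos_lo, pos_hi)
    r_obs = ch["value"].to_numpy()[nearest]
    t_obs = ch["t_mean"].to_numpy()[nearest]
    values = r_obs * q10 ** ((halfhourly_t.to_numpy() - t_obs) / 10.0)
    return pd.Series(values, index=t_target, name="soil_resp")


def _require_aligned(*series: pd.Series) -> None:
    first = series[0].index
    for s in series[1:]:
        if not s.index.equals(first):
            raise ValueError("flux series must share one time index")


def infer_tree_respiration(
    reco: pd.Series,
    soil_resp: pd.Series,
    f: RootFraction = RootFraction(),
) -> FluxBands:
    """Tree (autotrophic, incl. root) respiration bands by differencing.

    tree_resp(f_root) = Reco - (1 - f_root) * soil_resp: roots belong to the
    trees, so only the non-root share of soil respiration is subtracted.
    The band increases with the assumed root fraction.
    """
    _require_aligned(reco, soil_resp)
    def at(fr: float) -> pd.Series:
        return reco - (1.0 - fr) * soil_resp
    return FluxBands(low=at(f.low), mid=at(f.mid), high=at(f.high))


def infer_npp(gpp: pd.Series, tree_resp: FluxBands) -> FluxBands:
    """NPP bands: GPP minus tree respiration, with the band order flipped.

    A larger root fraction means more tree respiration and hence less NPP,
    so the NPP low band comes from the tree-respiration high band.
    """
    _require_aligned(gpp, tree_resp.mid)
    return FluxBands(
        low=gpp - tree_resp.high,
        mid=gpp - tree_resp.mid,
        high=gpp - tree_resp.low,
    )


def gapfill_linear(series: pd.Series) -> pd.Series:
    """Linearly interpolate interior gaps; pad leading/trailing gaps with the
    nearest observed value."""
    if series.notna().sum() == 0:
        raise ValueError("cannot gap-fill an all-missing series")
    filled = series.interpolate(method="linear", limit_direction="both")
    return filled


def specific_humidity_from_rh(t_air_c, rh_pct, pressure_hpa):
    """Specific humidity (kg kg^-1) from T (degC), RH (%) and pressure (hPa).

    Saturation vapour pressure from the August-Roche-Magnus formula
    (6.1094 hPa, 17.625, 243.04 degC), then
    q = 0.622 e / (p - 0.378 e).
    """
    rh = np.asarray(rh_pct, dtype=float)
    p = np.asarray(pressure_hpa, dtype=float)
    if np.any((rh < 0) | (rh > 100)):
        raise ValueError("relative humidity must lie in [0, 100] %")
    if np.any(p <= 0):
        raise ValueError("pressure must be positive")
    e = rh / 100.0 * saturation_vapour_pressure_hpa(t_air_c)
    if np.any(p <= e):
        raise ValueError("pressure must exceed vapour pressure")
    out = 0.622 * e / (p - 0.378 * e)
    return float(out) if out.ndim == 0 else out


def clean_radiation(
    sw_down: pd.Series,
    lw_down: pd.Series | None = None,
    lw_substitute: pd.Series | None = None,
) -> tuple[pd.Series, pd.Series | None]:
    """Clean the radiation drivers.

    Shortwave is truncated at zero (instrument noise at night produces small
    negative values).  If a longwave substitute is supplied, longwave is taken
    from it wherever it covers the record, and from its mean seasonal cycle
    (day-of-year means) elsewhere — the longwave sensor is assumed
    systematically biased, so the observed longwave is never used.
    """
    sw_clean = sw_down.clip(lower=0.0)
    if lw_substitute is None:
        return sw_clean, lw_down
    target_index = lw_down.index if lw_down is not None else sw_down.index
    lw_clean = lw_substitute.reindex(target_index)
    missing = lw_clean.isna()
    if missing.any():
        doy = lw_substitute.index.dayofyear
        cycle = lw_substitute.groupby(doy).mean()
        # clip to the cycle's coverage (e.g. day 366 outside a non-leap record)
        query = np.clip(
            target_index.dayofyear[missing], cycle.index.min(), cycle.index.max()
        )
        fill = pd.Series(cycle.reindex(query).to_numpy(), index=target_index[missing])
        lw_clean.loc[missing] = fill
    return sw_clean, lw_clean
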