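"""Light-use-efficiency stand productivity.

A parsimonious productivity engine drives the demography: GPP is absorbed
photosynthetically active radiation times a maximum light-use efficiency,
modulated by temperature (Gaussian around an optimum), vapour-pressure
deficit (hyperbolic) and atmospheric CO2 (Michaelis-like saturating response
normalised to a reference concentration).  Maintenance respiration scales
with live biomass through a Q10 temperature response; NPP applies a fixed
growth-respiration fraction to the residual.

All functions accept scalars or numpy arrays and are vectorised over time.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

__all__ = [
    "ProductivityParams",
    "co2_factor",
    "temperature_factor",
    "vpd_factor",
    "fapar",
    "gpp_step",
    "maintenance_respiration",
    "npp_step",
    "DEFAULT_PRODUCTIVITY",
]

SECONDS_PER_DAY = 86_400.0
PAR_FRACTION = 0.5          # fraction of shortwave that is PAR
CANOPY_EXTINCTION = 0.5     # Beer's-law extinction coefficient


@dataclass(frozen=True)
class ProductivityParams:
    """Constants of the light-use-efficiency model.

    lue_max is kgC per MJ of absorbed PAR; t_opt/t_width define the Gaussian
    temperature response (degC); vpd_half is the VPD (hPa) at which the VPD
    factor halves; gamma_star and ca_ref (ppm) shape and normalise the CO2
    response; resp_rate_ref is the maintenance respiration rate per unit
    biomass (yr^-1) at 10 degC with sensitivity q10_plant; growth_resp_frac
    is the fraction of net assimilate lost to growth respiration.
    """

    lue_max: float = 0.0020        # kgC MJ^-1 APAR
    t_opt: float = 16.0            # degC
    t_width: float = 11.0          # degC
    vpd_half: float = 12.0         # hPa
    gamma_star: float = 40.0       # ppm
    ca_ref: float = 330.0          # ppm (early-1970s atmosphere)
    resp_rate_ref: float = 0.055   # yr^-1 per unit biomass at 10 degC
    q10_plant: float = 2.0
    growth_resp_frac: float = 0.25

    def __post_init__(self) -> None:
        if not 0 <= self.growth_resp_frac < 1:
            raise ValueError("growth_resp_frac must lie in [0, 1)")
        if min(self.lue_max, self.t_width, self.vpd_half, self.gamma_star,
               self.ca_ref, self.resp_rate_ref, self.q10_plant) <= 0:
            raise ValueError("productivity constants must be positive")


DEFAULT_PRODUCTIVITY = ProductivityParams()


def co2_factor(ca, params: ProductivityParams = DEFAULT_PRODUCTIVITY):
    """CO2 fertilisation multiplier, equal to 1 at the reference concentration.

    f(ca) = [(ca - G) / (ca + 2G)] / [(ca_ref - G) / (ca_ref + 2G)] with
    G = gamma_star: strictly increasing and saturating in ca.
    """
    ca = np.asarray(ca, dtype=float)
    if np.any(ca <= params.gamma_star):
        raise ValueError("CO2 concentration must exceed gamma_star")
    g = params.gamma_star
    ref = (params.ca_ref - g) / (params.ca_ref + 2 * g)
    out = ((ca - g) / (ca + 2 * g)) / ref
    return float(out) if out.ndim == 0 else out


def temperature_factor(t_air, params: ProductivityParams = DEFAULT_PRODUCTIVITY):
    """Gaussian temperature response centred on t_opt."""
    t_air = np.asarray(t_air, dtype=float)
    out = np.exp(-(((t_air - params.t_opt) / params.t_width) ** 2))
    return float(out) if out.ndim == 0 else out


def vpd_factor(vpd_hpa, params: ProductivityParams = DEFAULT_PRODUCTIVITY):
    """Hyperbolic vapour-pressure-deficit limitation, 1 at VPD = 0."""
    vpd_hpa = np.asarray(vpd_hpa, dtype=float)
    out = 1.0 / (1.0 + np.maximum(vpd_hpa, 0.0) / params.vpd_half)
    return float(out) if out.ndim == 0 else out


def fapar(lai):
    """Fraction of PAR absorbed by a canopy of the given leaf area index."""
    lai = np.asarray(lai, dtype=float)
    out = 1.0 - np.exp(-CANOPY_EXTINCTION * lai)
    return float(out) if out.ndim == 0 else out


def gpp_step(
    sw_down_wm2,
    t_air_c,
    vpd_hpa,
    lai: float,
    ca_ppm: float,
    dt_days: float = 1.0,
    params: ProductivityParams = DEFAULT_PRODUCTIVITY,
):
    """GPP (kgC m^-2 per driver step) from mean shortwave, T, VPD, LAI and CO2.

    APAR = SW * PAR_FRACTION * fAPAR(LAI), integrated over the step length;
    zero shortwave (night) or zero LAI gives zero GPP.  Negative shortwave is
    rejected (the radiation cleaner should have truncated it).
    """
    sw = np.asarray(sw_down_wm2, dtype=float)
    if np.any(sw < 0):
        raise ValueError("negative shortwave radiation: clean drivers first")
    if lai < 0:
        raise ValueError("LAI must be non-negative")
    apar_mj = sw * SECONDS_PER_DAY * dt_days / 1e6 * PAR_FRACTION * fapar(lai)
    out = (
        params.lue_max
        * temperature_factor(t_air_c, params)
        * vpd_factor(vpd_hpa, params)
        * co2_factor(ca_ppm, params)
        * apar_mj
    )
    return float(out) if np.ndim(out) == 0 else out


def maintenance_respiration(
    biomass_kgc_m2: float,
    t_air_c,
    dt_days: float = 1.0,
    params: ProductivityParams = DEFAULT_PRODUCTIVITY,
):
    """Maintenance respiration (kgC m^-2 per step): Q10 response of a
    biomass-proportional base rate referenced to 10 degC."""
    if biomass_kgc_m2 < 0:
        raise ValueError("biomass must be non-negative")
    t_air = np.asarray(t_air_c, dtype=float)
    rate = params.resp_rate_ref * biomass_kgc_m2 * params.q10_plant ** (
        (t_air - 10.0) / 10.0
    )
    out = rate * dt_days / 365.25
    return float(out) if out.ndim == 0 else out


def npp_step(
    gpp_kgc_m2,
    biomass_kgc_m2: float,
    t_air_c,
    dt_days: float = 1.0,
    params: ProductivityParams = DEFAULT_PRODUCTIVITY,
):
    """NPP (kgC m^-2 per step): growth-respiration-discounted GPP minus
    maintenance respiration.  May be negative in cold, dark intervals."""
    rm = maintenance_respiration(biomass_kgc_m2, t_air_c, dt_days, params)
    out = (1.0 - params.growth_resp_frac) * (np.asarray(gpp_kgc_m2, dtype=float) - rm)
    return float(out) if np.ndim(out) == 0 else out
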