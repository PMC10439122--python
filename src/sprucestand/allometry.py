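"""Allometric relationships for an even-aged Sitka spruce (NET) stand.

Two deterministic curves tie the whole package together:

* a uniform height curve for even-aged stands,
  ``h(dbh) = h_offset + exp(a - dbh_scale / dbh)``, with the intercept
  ``a`` chosen so that the curve saturates at the maximum observed stand
  height ``h_max`` (``a = ln(h_max - h_offset)``), and
* a stem carbon-mass allometry,
  ``m(dbh) = carbon_fraction * mass_coeff * (dbh * h)**mass_exp``,
  where ``carbon_fraction`` converts dry mass to carbon mass.

Units throughout: dbh in cm, height in m, per-tree mass in kgC.  Stand-level
densities use kgC m^-2 internally; the tC ha^-1 conversion factor lives here
so every module agrees on it.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

from scipy.optimize import brentq

__all__ = [
    "AllometryParams",
    "height_from_dbh",
    "mass_from_dbh",
    "dbh_from_mass",
    "truncation_mass",
    "kgc_m2_to_tc_ha",
    "tc_ha_to_kgc_m2",
    "KGC_M2_PER_TC_HA",
]

#: 1 kgC m^-2 equals 10 tC ha^-1.
KGC_M2_PER_TC_HA = 0.1


def kgc_m2_to_tc_ha(x: float) -> float:
    """Convert an areal carbon density from kgC m^-2 to tC ha^-1."""
    return x * 10.0


def tc_ha_to_kgc_m2(x: float) -> float:
    """Convert an areal carbon density from tC ha^-1 to kgC m^-2."""
    return x * 0.1


@dataclass(frozen=True)
class AllometryParams:
    """Parameters of the height and stem-mass curves.

    The height-curve intercept ``a`` is derived from the asymptotic stand
    height ``h_max`` as ``a = ln(h_max - h_offset)``; storing ``h_max``
    rather than a rounded ``a`` keeps the derived truncation mass
    reproducible to the hundredth of a kgC.
    """

    h_max: float = 25.0          # m, asymptotic (maximum observed) height
    h_offset: float = 1.3        # m, breast height
    dbh_scale: float = 7.55      # cm, curvature constant of the height curve
    mass_coeff: float = 0.286    # dry-mass allometry coefficient
    mass_exp: float = 1.138      # dry-mass allometry exponent
    carbon_fraction: float = 0.5  # kgC per kg dry mass

    def __post_init__(self) -> None:
        if self.h_offset <= 0:
            raise ValueError("h_offset must be positive")
        if self.h_max <= self.h_offset:
            raise ValueError("h_max must exceed h_offset")
        if self.mass_exp <= 1:
            raise ValueError("mass_exp must exceed 1")
        if not 0 < self.carbon_fraction <= 1:
            raise ValueError("carbon_fraction must lie in (0, 1]")

    @property
    def a(self) -> float:
        """Height-curve intercept, ln(h_max - h_offset)."""
        return math.log(self.h_max - self.h_offset)


DEFAULT_ALLOMETRY = AllometryParams()


def height_from_dbh(dbh: float, params: AllometryParams = DEFAULT_ALLOMETRY) -> float:
    """Tree height (m) from diameter at breast height (cm).

    Strictly increasing in dbh, tending to ``h_offset`` as dbh -> 0 and
    saturating at ``h_max`` for very large trees.
    """
    if dbh <= 0:
        raise ValueError("dbh must be positive")
    return params.h_offset + math.exp(params.a - params.dbh_scale / dbh)


def mass_from_dbh(dbh: float, params: AllometryParams = DEFAULT_ALLOMETRY) -> float:
    """Per-tree carbon mass (kgC) from dbh (cm), via the height curve."""
    if dbh <= 0:
        raise ValueError("dbh must be positive")
    h = height_from_dbh(dbh, params)
    return params.carbon_fraction * params.mass_coeff * (dbh * h) ** params.mass_exp


_DBH_BRACKET = (0.1, 500.0)  # cm; covers ~1e-4 to ~1e5 kgC


def dbh_from_mass(mass: float, params: AllometryParams = DEFAULT_ALLOMETRY) -> float:
    """Invert the mass allometry numerically (dbh in cm from mass in kgC).

    The mass curve is strictly increasing, so the bracketed root is unique.
    Resolved to 1e-8 relative tolerance.
    """
    if mass <= 0:
        raise ValueError("mass must be positive")
    lo, hi = _DBH_BRACKET
    if not mass_from_dbh(lo, params) <= mass <= mass_from_dbh(hi, params):
        raise ArithmeticError(
            f"mass {mass} kgC outside the invertible dbh bracket {_DBH_BRACKET} cm"
        )
    return brentq(
        lambda d: mass_from_dbh(d, params) - mass, lo, hi, rtol=1e-10, xtol=1e-12
    )


def truncation_mass(dbh_min: float, params: AllometryParams = DEFAULT_ALLOMETRY) -> float:
    """Carbon mass (kgC) of the smallest surveyable tree.

    Surveys record dbh above a minimum (7 cm here); structure statistics are
    computed above the corresponding per-tree mass.
    """
    return mass_from_dbh(dbh_min, params)
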