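"""Woodland-Carbon-Code-style yield-table comparison.

The WCC publishes per-period (five-year) lookup tables of standing and
removed carbon for UK species / yield-class / spacing / management
combinations, in tCO2 ha^-1.  This module reads tables with that schema,
converts them to tC ha^-1 (factor 12/44), accumulates them into standing
biomass and removed-carbon curves against stand age, and differences them
against simulator output on a shared age axis.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd

__all__ = [
    "WCCTable",
    "convert_co2_to_c",
    "read_wcc_csv",
    "cumulative_curves",
    "sequestration_rates",
    "paired_difference",
]

C_PER_CO2 = 12.0 / 44.0


def convert_co2_to_c(x):
    """Convert tCO2 ha^-1 to tC ha^-1 (molar-mass factor 12/44)."""
    arr = np.asarray(x, dtype=float)
    if np.any(arr < 0):
        raise ValueError("carbon quantities must be non-negative")
    out = arr * C_PER_CO2
    return float(out) if out.ndim == 0 else out


@dataclass(frozen=True)
class WCCTable:
    """Per-period standing and removed carbon (tCO2 ha^-1 per period)."""

    age_from: np.ndarray
    age_to: np.ndarray
    carbon_standing_tco2: np.ndarray   # per-period increment
    removed_tco2: np.ndarray           # per-period removal
    variant: str = "thinned"

    def __post_init__(self) -> None:
        if np.any(self.age_to <= self.age_from):
            raise ValueError("periods must have positive duration")
        if not np.allclose(self.age_from[1:], self.age_to[:-1]):
            raise ValueError("periods must be contiguous and non-overlapping")
        if np.any(self.carbon_standing_tco2 < 0) or np.any(self.removed_tco2 < 0):
            raise ValueError("table values must be non-negative")


def read_wcc_csv(path) -> dict[str, WCCTable]:
    """Read a WCC-style CSV (columns: age_from, age_to, carbon_standing_tCO2,
    removed_tCO2, variant) into one table per variant."""
    frame = pd.read_csv(path)
    required = {"age_from", "age_to", "carbon_standing_tCO2", "removed_tCO2", "variant"}
    missing = required - set(frame.columns)
    if missing:
        raise ValueError(f"WCC table missing columns {sorted(missing)}")
    tables = {}
    for variant, sub in frame.groupby("variant"):
        sub = sub.sort_values("age_from")
        tables[variant] = WCCTable(
            age_from=sub["age_from"].to_numpy(float),
            age_to=sub["age_to"].to_numpy(float),
            carbon_standing_tco2=sub["carbon_standing_tCO2"].to_numpy(float),
            removed_tco2=sub["removed_tCO2"].to_numpy(float),
            variant=str(variant),
        )
    return tables


def cumulative_curves(table: WCCTable) -> pd.DataFrame:
    """Cumulative standing-biomass and removed-carbon curves (tC ha^-1).

    Per-period increments are converted to carbon and summed; the curves are
    evaluated at period boundaries (piecewise linear in between), starting
    from zero at the first period's opening age.
    """
    ages = np.concatenate([[table.age_from[0]], table.age_to])
    standing = np.concatenate([[0.0], np.cumsum(convert_co2_to_c(table.carbon_standing_tco2))])
    removed = np.concatenate([[0.0], np.cumsum(convert_co2_to_c(table.removed_tco2))])
    return pd.DataFrame(
        {"stand_biomass_tc_ha": standing, "thinned_cum_tc_ha": removed},
        index=pd.Index(ages, name="stand_age"),
    )


def sequestration_rates(curves: pd.DataFrame) -> pd.DataFrame:
    """Per-period sequestration rates (tC ha^-1 yr^-1) from cumulative curves.

    Finite differences of each cumulative column over the age axis; the rate
    for a period is indexed by the period's closing age.
    """
    ages = curves.index.to_numpy(float)
    d_age = np.diff(ages)
    if np.any(d_age <= 0):
        raise ValueError("age axis must be strictly increasing")
    rates = curves.diff().iloc[1:].div(d_age, axis=0)
    return rates


def paired_difference(a: pd.DataFrame, b: pd.DataFrame) -> pd.DataFrame:
    """Difference two curves (a - b) on a common age axis.

    Mismatched age grids are linearly resampled onto the coarser grid, with
    a warning.
    """
    if not a.index.equals(b.index):
        warnings.warn("age grids differ: resampling onto the coarser grid")
        target = a.index if len(a.index) <= len(b.index) else b.index
        def on(frame: pd.DataFrame) -> pd.DataFrame:
            out = {}
            for col in frame.columns:
                out[col] = np.interp(
                    target.to_numpy(float),
                    frame.index.to_numpy(float),
                    frame[col].to_numpy(float),
                )
            return pd.DataFrame(out, index=target)
        a, b = on(a), on(b)
    common = [c for c in a.columns if c in b.columns]
    return a[common] - b[common]
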