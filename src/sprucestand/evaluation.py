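"""Demographic and flux evaluation statistics.

Survey plots of dbh are mapped to per-tree carbon masses and an areal
density scale; a Gaussian kernel density estimate in log-mass projects the
observed masses onto the simulator's mass classes; stand structure is then
compared through the biomass Gini coefficient (Lorenz curve of cumulative
biomass against cumulative tree count, trees ranked by size), a Pearson
chi-squared statistic over the mass classes above the truncation mass, and
a Kolmogorov-Smirnov statistic on the mass CDFs.  Flux series are compared
with RMSE and squared Pearson correlation at sub-daily or monthly cadence,
and summarised as month-by-hour seasonal-diurnal matrices.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats

from .allometry import AllometryParams, DEFAULT_ALLOMETRY, mass_from_dbh
from .demography import MassClassGrid

__all__ = [
    "SurveyData",
    "EvaluationReport",
    "survey_to_masses",
    "fit_kde_to_classes",
    "gini_biomass",
    "gini_from_classes",
    "chi_squared_classes",
    "ks_statistic",
    "flux_error_stats",
    "seasonal_diurnal_matrix",
    "evaluate_stand",
]

M2_PER_HA = 10_000.0


@dataclass(frozen=True)
class SurveyData:
    """A plot survey: per-plot integer dbh lists (cm), plot area and count."""

    dbh_by_plot: tuple[tuple[int, ...], ...]
    plot_area_m2: float = 200.0
    dbh_min_cm: float = 7.0

    @property
    def n_plots(self) -> int:
        return len(self.dbh_by_plot)

    @property
    def all_dbh(self) -> np.ndarray:
        return np.concatenate([np.asarray(p, dtype=float) for p in self.dbh_by_plot])

    @classmethod
    def from_frame(cls, frame: pd.DataFrame, plot_area_m2: float = 200.0,
                   dbh_min_cm: float = 7.0) -> "SurveyData":
        """Build from a tidy table with columns ``plot_id`` and ``dbh_cm``."""
        plots = tuple(
            tuple(int(d) for d in sub["dbh_cm"])
            for _, sub in frame.groupby("plot_id", sort=True)
        )
        return cls(plots, plot_area_m2=plot_area_m2, dbh_min_cm=dbh_min_cm)


def survey_to_masses(
    survey: SurveyData,
    allom: AllometryParams = DEFAULT_ALLOMETRY,
) -> tuple[np.ndarray, float]:
    """Per-tree carbon masses (kgC) and the per-tree density scale.

    Each surveyed tree represents 10000 / (n_plots * plot_area) trees ha^-1.
    Trees below the survey minimum dbh are dropped with a warning.
    """
    dbh = survey.all_dbh
    below = dbh < survey.dbh_min_cm
    if below.any():
        warnings.warn(
            f"dropping {int(below.sum())} trees below the {survey.dbh_min_cm} cm "
            "survey minimum"
        )
        dbh = dbh[~below]
    masses = np.array([mass_from_dbh(d, allom) for d in dbh])
    scale = M2_PER_HA / (survey.n_plots * survey.plot_area_m2)
    return masses, scale


def fit_kde_to_classes(
    masses: np.ndarray,
    weights: np.ndarray | float,
    grid: MassClassGrid,
) -> np.ndarray:
    """Project observed per-tree masses onto the mass classes with a KDE.

    A Gaussian kernel density estimate in log-mass (Scott's-rule bandwidth)
    is integrated over the class edges, then renormalised so the total
    density equals the survey total exactly.  A single observed mass (or
    coincident masses, for which the KDE is degenerate) falls back to direct
    binning.
    """
    masses = np.asarray(masses, dtype=float)
    if np.any(masses <= 0):
        raise ValueError("masses must be positive")
    w = np.broadcast_to(np.asarray(weights, dtype=float), masses.shape).copy()
    total = float(w.sum())
    log_m = np.log(masses)
    log_edges = np.log(grid.class_edges)

    def direct_bin() -> np.ndarray:
        hist, _ = np.histogram(log_m, bins=log_edges, weights=w)
        # clip out-of-range mass into the end classes
        hist[0] += w[log_m < log_edges[0]].sum()
        hist[-1] += w[log_m > log_edges[-1]].sum()
        return hist

    if len(masses) < 2 or np.ptp(log_m) == 0.0:
        warnings.warn("degenerate mass sample: falling back to direct binning")
        return direct_bin()
    kde = stats.gaussian_kde(log_m, weights=w)
    per_class = np.array(
        [kde.integrate_box_1d(lo, hi) for lo, hi in zip(log_edges[:-1], log_edges[1:])]
    )
    mass_in = per_class.sum()
    if mass_in <= 0:
        warnings.warn("KDE mass fell outside the grid: falling back to direct binning")
        return direct_bin()
    return per_class * (total / mass_in)


def gini_biomass(masses: np.ndarray, weights: np.ndarray | float = 1.0) -> float:
    """Biomass Gini coefficient of a stand from per-tree masses.

    Trees are ranked by size; the Lorenz curve plots cumulative biomass share
    against cumulative tree-count share.  0 means every tree carries the same
    biomass; values toward 1 mean the stand biomass is concentrated in a few
    large trees.  ``weights`` are per-tree multiplicities (densities).
    """
    m = np.asarray(masses, dtype=float)
    if m.size == 0:
        raise ValueError("need at least one tree")
    w = np.broadcast_to(np.asarray(weights, dtype=float), m.shape).astype(float)
    if np.any(w < 0) or w.sum() <= 0:
        raise ValueError("weights must be non-negative with positive total")
    biomass = float(m @ w)
    if biomass <= 0:
        raise ValueError("total biomass must be positive")
    order = np.argsort(m, kind="stable")
    m, w = m[order], w[order]
    cum_n = np.concatenate([[0.0], np.cumsum(w)]) / w.sum()
    cum_b = np.concatenate([[0.0], np.cumsum(m * w)]) / biomass
    # Gini = 1 - 2 * area under the Lorenz curve (trapezoid over the steps)
    area = float(np.sum(np.diff(cum_n) * (cum_b[:-1] + cum_b[1:]) / 2.0))
    return 1.0 - 2.0 * area


def gini_from_classes(grid: MassClassGrid, per_class_density: np.ndarray) -> float:
    """Biomass Gini from a class-resolved stand (weighted form)."""
    dens = np.asarray(per_class_density, dtype=float)
    keep = dens > 0
    return gini_biomass(grid.class_masses[keep], dens[keep])


def chi_squared_classes(
    obs_density: np.ndarray,
    sim_density: np.ndarray,
    grid: MassClassGrid,
    m_trunc: float = 0.0,
    n_obs_trees: float | None = None,
) -> tuple[float, int, float]:
    """Pearson chi-squared between observed and simulated class densities.

    Classes with centre mass below the truncation mass are discarded; both
    distributions are scaled to the observed total tree count; cells with
    zero expected count are pooled into their upper neighbour (logged with a
    warning).  Returns (chi2, dof, p) with dof = cells - 1.
    """
    obs = np.asarray(obs_density, dtype=float)
    sim = np.asarray(sim_density, dtype=float)
    mask = grid.class_masses >= m_trunc
    obs, sim = obs[mask], sim[mask]
    if obs.sum() <= 0 or sim.sum() <= 0:
        raise ValueError("no trees above the truncation mass")
    n_tot = float(obs.sum()) if n_obs_trees is None else float(n_obs_trees)
    o = obs / obs.sum() * n_tot
    e = sim / sim.sum() * n_tot
    # pool zero-expected cells upward so every retained cell has E > 0
    cells_o, cells_e = [], []
    carry_o = carry_e = 0.0
    for oi, ei in zip(o, e):
        carry_o += oi
        carry_e += ei
        if carry_e > 0:
            cells_o.append(carry_o)
            cells_e.append(carry_e)
            carry_o = carry_e = 0.0
    if carry_e > 0 or carry_o > 0:
        if not cells_e:
            raise ValueError("all expected counts are zero")
        warnings.warn("pooling trailing zero-expected cells into the last cell")
        cells_o[-1] += carry_o
        cells_e[-1] += carry_e
    o = np.asarray(cells_o)
    e = np.asarray(cells_e)
    if len(o) < len(obs):
        warnings.warn(f"pooled {len(obs) - len(o)} zero-expected cells")
    chi2 = float(np.sum((o - e) ** 2 / e))
    dof = len(o) - 1
    p = float(stats.chi2.sf(chi2, dof)) if dof > 0 else float("nan")
    return chi2, dof, p


def ks_statistic(
    obs_masses: np.ndarray,
    obs_weights: np.ndarray | float,
    grid: MassClassGrid,
    sim_density: np.ndarray,
    m_trunc: float = 0.0,
    n_eff: float | None = None,
) -> tuple[float, float]:
    """Kolmogorov-Smirnov distance between observed and simulated mass CDFs.

    The observed CDF is the weighted empirical CDF of per-tree masses above
    the truncation mass; the simulated CDF steps at the class centres above
    truncation.  D is the supremum over all step points (both one-sided
    limits); the p-value uses the asymptotic KS distribution with effective
    sample size ``n_eff`` (the observed tree count by default).
    """
    m = np.asarray(obs_masses, dtype=float)
    w = np.broadcast_to(np.asarray(obs_weights, dtype=float), m.shape).astype(float)
    keep = m >= m_trunc
    m, w = m[keep], w[keep]
    sim_mask = grid.class_masses >= m_trunc
    sm = grid.class_masses[sim_mask]
    sw = np.asarray(sim_density, dtype=float)[sim_mask]
    if m.size == 0 or sw.sum() <= 0:
        raise ValueError("empty distribution above the truncation mass")

    order = np.argsort(m, kind="stable")
    m, w = m[order], w[order]
    obs_cdf_vals = np.cumsum(w) / w.sum()
    # collapse duplicate masses onto the last cumulative value at each mass
    uniq, idx_last = np.unique(m[::-1], return_index=True)
    cdf_at_uniq = obs_cdf_vals[len(m) - 1 - idx_last]

    sim_cdf_vals = np.cumsum(sw) / sw.sum()

    def cdf(xq: np.ndarray, xs: np.ndarray, cs: np.ndarray) -> np.ndarray:
        pos = np.searchsorted(xs, xq, side="right")
        out = np.zeros_like(xq, dtype=float)
        nz = pos > 0
        out[nz] = cs[pos[nz] - 1]
        return out

    points = np.unique(np.concatenate([uniq, sm]))
    eps = 1e-9
    queries = np.concatenate([points, points * (1 - eps)])
    d = np.max(np.abs(cdf(queries, uniq, cdf_at_uniq) - cdf(queries, sm, sim_cdf_vals)))
    n = float(w.sum()) if n_eff is None else float(n_eff)
    p = float(stats.kstwobign.sf(d * np.sqrt(n)))
    return float(d), p


def flux_error_stats(
    sim: pd.Series,
    obs: pd.Series,
    cadence: str = "sub-daily",
) -> dict:
    """RMSE, squared Pearson correlation and means of two aligned flux series.

    ``cadence='monthly'`` aggregates both series to calendar-month means
    first.  Only the overlapping, jointly observed timestamps are compared.
    A zero-variance series leaves r2 undefined (NaN).
    """
    joined = pd.concat([sim.rename("sim"), obs.rename("obs")], axis=1).dropna()
    if joined.empty:
        raise ValueError("no overlap between simulated and observed series")
    if cadence == "monthly":
        joined = joined.resample("MS").mean().dropna()
    elif cadence != "sub-daily":
        raise ValueError("cadence must be 'sub-daily' or 'monthly'")
    diff = joined["sim"] - joined["obs"]
    rmse = float(np.sqrt(np.mean(diff**2)))
    if joined["sim"].std() == 0 or joined["obs"].std() == 0:
        r2 = float("nan")
    else:
        r2 = float(joined["sim"].corr(joined["obs"]) ** 2)
    return {
        "rmse": rmse,
        "r2": r2,
        "mean_sim": float(joined["sim"].mean()),
        "mean_obs": float(joined["obs"].mean()),
        "n": int(len(joined)),
    }


def seasonal_diurnal_matrix(
    series: pd.Series,
    other: pd.Series | None = None,
) -> pd.DataFrame:
    """Month-by-time-of-day means of a sub-daily series (12 x 48 for
    half-hourly input).  With ``other`` given, returns the cellwise
    difference ``series - other``.  Cells with no data are NaN."""
    def matrix(s: pd.Series) -> pd.DataFrame:
        idx = s.index
        halfhour = idx.hour * 2 + idx.minute // 30
        out = s.groupby([idx.month, halfhour]).mean().unstack()
        return out.reindex(index=range(1, 13), columns=sorted(out.columns))
    m = matrix(series)
    if other is not None:
        m = m - matrix(other)
    m.index.name = "month"
    m.columns.name = "halfhour"
    return m


@dataclass(frozen=True)
class EvaluationReport:
    """Table of stand structure aggregates and goodness-of-fit statistics."""

    n_density_ha: float
    c_density_tc_ha: float
    mean_height_m: float
    lai: float
    gini: float
    chi2: float
    chi2_dof: int
    chi2_p: float
    ks_d: float
    ks_p: float

    def to_dict(self) -> dict:
        return {
            "n_density_ha": self.n_density_ha,
            "c_density_tc_ha": self.c_density_tc_ha,
            "mean_height_m": self.mean_height_m,
            "lai": self.lai,
            "gini": self.gini,
            "chi2": self.chi2,
            "chi2_dof": self.chi2_dof,
            "chi2_p": self.chi2_p,
            "ks_d": self.ks_d,
            "ks_p": self.ks_p,
        }


def evaluate_stand(
    survey: SurveyData,
    sim_per_class_density_ha: np.ndarray,
    grid: MassClassGrid,
    sim_aggregates,
    allom: AllometryParams = DEFAULT_ALLOMETRY,
    m_trunc: float | None = None,
) -> EvaluationReport:
    """Compare a simulated stand snapshot against a plot survey.

    Returns the simulated aggregates alongside distributional fit statistics
    (Gini of the simulated stand, chi-squared and KS against the survey)
    computed above the truncation mass implied by the survey's minimum dbh.
    """
    masses, scale = survey_to_masses(survey, allom)
    if m_trunc is None:
        m_trunc = mass_from_dbh(survey.dbh_min_cm, allom)
    obs_per_class = fit_kde_to_classes(masses, scale, grid)
    sim_dens = np.asarray(sim_per_class_density_ha, dtype=float)
    chi2, dof, chi2_p = chi_squared_classes(
        obs_per_class, sim_dens, grid, m_trunc, n_obs_trees=len(masses)
    )
    ks_d, ks_p = ks_statistic(
        masses, scale, grid, sim_dens, m_trunc, n_eff=len(masses)
    )
    gini = gini_from_classes(grid, sim_dens)
    return EvaluationReport(
        n_density_ha=sim_aggregates.n_density_ha,
        c_density_tc_ha=sim_aggregates.c_density_tc_ha,
        mean_height_m=sim_aggregates.mean_height_m,
        lai=sim_aggregates.lai,
        gini=gini,
        chi2=chi2,
        chi2_dof=dof,
        chi2_p=chi2_p,
        ks_d=ks_d,
        ks_p=ks_p,
    )
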