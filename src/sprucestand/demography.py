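"""Size-structured stand demography on a geometric ladder of mass classes.

The state is the number density of trees per carbon-mass class (trees m^-2).
Each step distributes net primary productivity over the classes as growth,
moves trees up the ladder with an upwind number flux, applies exponential
baseline mortality, and recruits new trees into the seed class at a rate
suppressed by canopy closure.  The discretisation follows the published
RED (Robust Ecosystem Demography) v1.0 structure: geometric mass classes,
growth scaling as m^phi_g shaded by larger trees, and recruitment scaled
by the open fraction of the canopy.

Carbon bookkeeping closes exactly: every kgC of allocated NPP ends up in
either live structure or the litter accumulator, and the top class retains
growth that would leave the ladder as an explicit mass-excess pool.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

import numpy as np

from .allometry import AllometryParams, DEFAULT_ALLOMETRY, dbh_from_mass, height_from_dbh

__all__ = [
    "PFTParams",
    "MassClassGrid",
    "StandState",
    "StandAggregates",
    "build_mass_grid",
    "initialise_planting",
    "initialise_from_distribution",
    "canopy_cover",
    "step_demography",
    "stand_aggregates",
    "planting_density_from_spacing",
    "DEFAULT_PFT",
]

M2_PER_HA = 10_000.0


def planting_density_from_spacing(spacing_m: float) -> float:
    """Planting density (trees ha^-1) for square spacing (m).

    Standard UK conifer establishment at 2.0 m spacing gives
    10000 / 2.0^2 = 2500 trees ha^-1.
    """
    if spacing_m <= 0:
        raise ValueError("spacing must be positive")
    return M2_PER_HA / spacing_m**2


@dataclass(frozen=True)
class PFTParams:
    """Plant-functional-type parameters for the needle-leaved evergreen tree.

    gamma_base is an instantaneous baseline mortality rate (yr^-1) applied
    as exponential decay; alpha_repro is the fraction of positive NPP routed
    to reproduction; phi_g is the growth-scaling exponent of per-tree growth
    with mass.  crown_area_coeff and leaf_mass_coeff scale the m^(2/3)
    crown-area and leaf-carbon laws; sla converts leaf carbon to leaf area.
    The leaf/root/wood fractions partition removed-tree carbon at thinning.
    """

    gamma_base: float = 0.01        # yr^-1 baseline mortality
    alpha_repro: float = 0.05       # fraction of NPP to reproduction
    phi_g: float = 0.75             # growth ~ m^phi_g
    m_seed: float = 1.0             # kgC, mass of the lowest class
    sla: float = 8.0                # m^2 leaf area per kgC leaf
    crown_area_coeff: float = 0.27  # m^2 kgC^(-2/3)
    leaf_mass_coeff: float = 0.177  # kgC leaf per kgC^(2/3) tree mass
    leaf_frac: float = 0.05
    root_frac: float = 0.15
    wood_frac: float = 0.80

    def __post_init__(self) -> None:
        if self.gamma_base < 0:
            raise ValueError("gamma_base must be non-negative")
        if not 0 <= self.alpha_repro < 1:
            raise ValueError("alpha_repro must lie in [0, 1)")
        if abs(self.leaf_frac + self.root_frac + self.wood_frac - 1.0) > 1e-9:
            raise ValueError("leaf_frac + root_frac + wood_frac must sum to 1")


DEFAULT_PFT = PFTParams()


@dataclass(frozen=True)
class MassClassGrid:
    """Geometric ladder of per-tree carbon-mass classes with allometric attributes.

    class_masses are the class centres (kgC, strictly increasing); class_edges
    bracket them at geometric midpoints.  Per-class dbh, height, crown area
    and leaf carbon are evaluated once from the centre masses.
    """

    class_masses: np.ndarray   # (K,) kgC
    class_edges: np.ndarray    # (K+1,) kgC
    dbh: np.ndarray            # (K,) cm
    height: np.ndarray         # (K,) m
    crown_area: np.ndarray     # (K,) m^2
    leaf_carbon: np.ndarray    # (K,) kgC

    @property
    def n_classes(self) -> int:
        return len(self.class_masses)

    def class_of_mass(self, mass: float) -> int:
        """Index of the class whose edges bracket ``mass``."""
        k = int(np.searchsorted(self.class_edges, mass, side="right")) - 1
        return min(max(k, 0), self.n_classes - 1)


def build_mass_grid(
    K: int = 10,
    m_seed: float = 1.0,
    ratio: float = 2.0,
    allom: AllometryParams = DEFAULT_ALLOMETRY,
    pft: PFTParams = DEFAULT_PFT,
) -> MassClassGrid:
    """Build a K-class geometric mass ladder with allometric attributes.

    Class centres are m_seed * ratio**i; edges sit at geometric midpoints,
    extended by sqrt(ratio) beyond the outermost centres.
    """
    if K < 4:
        raise ValueError("need at least 4 mass classes")
    if ratio <= 1:
        raise ValueError("class ratio must exceed 1")
    masses = m_seed * ratio ** np.arange(K)
    edges = np.empty(K + 1)
    edges[1:-1] = np.sqrt(masses[:-1] * masses[1:])
    edges[0] = masses[0] / np.sqrt(ratio)
    edges[-1] = masses[-1] * np.sqrt(ratio)
    dbh = np.array([dbh_from_mass(m, allom) for m in masses])
    height = np.array([height_from_dbh(d, allom) for d in dbh])
    crown = pft.crown_area_coeff * masses ** (2.0 / 3.0)
    leaf = pft.leaf_mass_coeff * masses ** (2.0 / 3.0)
    return MassClassGrid(masses, edges, dbh, height, crown, leaf)


@dataclass
class StandState:
    """Simulator state: per-class number density plus pools and clocks.

    number_density is trees m^-2 per class.  top_mass_excess holds carbon
    grown by top-class trees beyond the top class centre, so the ladder never
    loses trees or carbon at its upper end.  product_pool is harvested woody
    carbon (kgC m^-2, non-decaying by default); litter_flux_accum integrates
    carbon routed to litter.
    """

    number_density: np.ndarray          # (K,) trees m^-2
    stand_age: float = 0.0              # yr
    top_mass_excess: float = 0.0        # kgC m^-2
    product_pool: float = 0.0           # kgC m^-2
    litter_flux_accum: float = 0.0      # kgC m^-2
    thinning_fired: bool = False

    def __post_init__(self) -> None:
        self.number_density = np.asarray(self.number_density, dtype=float)
        if np.any(self.number_density < 0):
            raise ValueError("number densities must be non-negative")

    def copy(self) -> "StandState":
        return replace(self, number_density=self.number_density.copy())

    def total_density(self) -> float:
        """Total tree number density, trees m^-2."""
        return float(self.number_density.sum())

    def biomass(self, grid: MassClassGrid) -> float:
        """Live stand biomass, kgC m^-2 (includes top-class mass excess)."""
        return float(self.number_density @ grid.class_masses) + self.top_mass_excess


def initialise_planting(grid: MassClassGrid, density_per_ha: float) -> StandState:
    """Even-aged planting: all trees in the lowest mass class at age 0."""
    if density_per_ha < 0:
        raise ValueError("planting density must be non-negative")
    n = np.zeros(grid.n_classes)
    n[0] = density_per_ha / M2_PER_HA
    return StandState(number_density=n)


def initialise_from_distribution(
    grid: MassClassGrid,
    per_class_density_per_ha: np.ndarray,
    stand_age: float = 0.0,
) -> StandState:
    """Initialise from a fitted per-class density (trees ha^-1 per class)."""
    dens = np.asarray(per_class_density_per_ha, dtype=float)
    if dens.shape != (grid.n_classes,):
        raise ValueError(
            f"expected {grid.n_classes} per-class densities, got {dens.shape}"
        )
    return StandState(number_density=dens / M2_PER_HA, stand_age=stand_age)


def canopy_cover(state: StandState, grid: MassClassGrid) -> tuple[float, np.ndarray]:
    """Total canopy cover and the cover shading each class from above.

    nu_above[i] is the crown cover of classes strictly larger than i (larger
    trees shade smaller ones, never themselves); nu_total is the whole-stand
    cover.  Both are capped at 1 (closed canopy).
    """
    per_class = state.number_density * grid.crown_area
    nu_total = min(1.0, float(per_class.sum()))
    above = np.concatenate([np.cumsum(per_class[::-1])[::-1][1:], [0.0]])
    nu_above = np.minimum(1.0, above)
    return nu_total, nu_above


def step_demography(
    state: StandState,
    grid: MassClassGrid,
    pft: PFTParams = DEFAULT_PFT,
    npp: float = 0.0,
    dt: float = 1.0 / 12.0,
) -> StandState:
    """Advance the stand by one demographic step.

    npp is the stand NPP rate in kgC m^-2 yr^-1 (may be negative on cold,
    dark intervals).  Positive NPP is split into a reproduction share
    alpha_repro and a growth share 1 - alpha_repro; growth is distributed
    over trees in proportion to m^phi_g * (1 - nu_above) and moved up the
    ladder with an upwind number flux; mortality is exponential at
    gamma_base; recruitment into the seed class scales with the open canopy
    fraction 1 - nu_total.  Reproduction carbon that finds no open ground is
    routed to litter, and negative NPP is drawn from the litter accumulator
    rather than from live structure, so the step conserves carbon exactly.
    """
    if dt <= 0 or dt > 1.0:
        raise ValueError("dt must lie in (0, 1] years")
    n = state.number_density.copy()
    K = grid.n_classes
    masses = grid.class_masses
    litter = state.litter_flux_accum
    top_excess = state.top_mass_excess

    nu_total, nu_above = canopy_cover(state, grid)
    npp_pos = max(npp, 0.0)
    if npp < 0:
        # cold-period deficit: drawn from litter bookkeeping, structure untouched
        litter += npp * dt

    # --- growth: allocate (1 - alpha) * NPP over trees ~ m^phi_g * light ---
    if npp_pos > 0.0:
        growth_carbon = (1.0 - pft.alpha_repro) * npp_pos * dt  # kgC m^-2
        weight = n * masses**pft.phi_g * (1.0 - nu_above)
        wsum = float(weight.sum())
        if wsum > 0.0:
            # per-tree growth rate g_i (kgC tree^-1 per step)
            g = growth_carbon * masses**pft.phi_g * (1.0 - nu_above) / wsum
            # upwind number flux between adjacent classes
            flux = np.zeros(K)  # flux[i]: trees m^-2 moved i -> i+1 this step
            flux[:-1] = n[:-1] * g[:-1] / (masses[1:] - masses[:-1])
            moved = np.minimum(flux[:-1], n[:-1])  # cannot move more than present
            n[:-1] -= moved
            n[1:] += moved
            # carbon actually moved up the ladder
            carbon_moved = float(moved @ (masses[1:] - masses[:-1]))
            # top class is absorbing: its growth stays as mass excess;
            # any clipped flux below also stays put as excess of its class —
            # book it against the top pool so carbon never leaks.
            top_excess += growth_carbon - carbon_moved
        else:
            litter += growth_carbon  # no live trees to grow
    # --- mortality: exponential decay, dead carbon to litter ---
    if pft.gamma_base > 0.0:
        surv = np.exp(-pft.gamma_base * dt)
        dead = n * (1.0 - surv)
        litter += float(dead @ masses) + top_excess * (1.0 - surv)
        n *= surv
        top_excess *= surv

    # --- recruitment into the seed class, suppressed by canopy closure ---
    if npp_pos > 0.0:
        repro_carbon = pft.alpha_repro * npp_pos * dt
        recruited = repro_carbon * (1.0 - nu_total)
        n[0] += recruited / pft.m_seed
        litter += repro_carbon - recruited  # failed seeds on closed ground

    if np.any(n < -1e-12):
        raise ArithmeticError("negative number density: reduce the time step")
    n = np.maximum(n, 0.0)
    new = state.copy()
    new.number_density = n
    new.stand_age = state.stand_age + dt
    new.top_mass_excess = top_excess
    new.litter_flux_accum = litter
    return new


@dataclass(frozen=True)
class StandAggregates:
    """Stand structure summary above a truncation mass.

    N, C and mean_height are computed over classes whose centre mass is at
    least m_trunc (the surveyable part of the stand); LAI uses all classes.
    """

    n_density_ha: float      # trees ha^-1
    c_density_tc_ha: float   # tC ha^-1
    mean_height_m: float
    lai: float               # m^2 m^-2
    per_class_density_ha: np.ndarray


def stand_aggregates(
    state: StandState,
    grid: MassClassGrid,
    m_trunc: float = 0.0,
    pft: PFTParams = DEFAULT_PFT,
) -> StandAggregates:
    """Aggregate the stand above a truncation mass (kgC).

    Number density, carbon density and number-weighted mean height are taken
    over classes with centre mass >= m_trunc; the leaf area index is a
    whole-stand quantity and always sums over every class.
    """
    if m_trunc < 0:
        raise ValueError("truncation mass must be non-negative")
    n = state.number_density
    mask = grid.class_masses >= m_trunc
    n_sel = n[mask]
    n_total = float(n_sel.sum())
    carbon = float(n_sel @ grid.class_masses[mask])
    if mask[-1]:
        carbon += state.top_mass_excess
    mean_h = float(n_sel @ grid.height[mask] / n_total) if n_total > 0 else 0.0
    lai = float(n @ grid.leaf_carbon) * pft.sla
    return StandAggregates(
        n_density_ha=n_total * M2_PER_HA,
        c_density_tc_ha=carbon * 10.0,
        mean_height_m=mean_h,
        lai=lai,
        per_class_density_ha=n * M2_PER_HA,
    )
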