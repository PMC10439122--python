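"""Thinning operator and harvest bookkeeping.

A single thinning event removes a fixed fraction of trees uniformly across
the size structure once the stand reaches a trigger age.  The woody carbon
of the removed trees goes to a non-decaying harvested-products pool; their
leaf and root carbon joins the local litter flux.  Uniform removal leaves
the normalised size distribution (and hence the biomass Gini coefficient)
unchanged at the event instant.
"""

from __future__ import annotations

from dataclasses import dataclass

from .demography import M2_PER_HA, MassClassGrid, PFTParams, StandState, DEFAULT_PFT

__all__ = ["ThinningEvent", "ThinningYield", "apply_thinning", "total_sequestration"]


@dataclass(frozen=True)
class ThinningEvent:
    """A one-off uniform thinning: remove ``fraction`` of trees at ``trigger_age``."""

    trigger_age: float = 25.0   # yr
    fraction: float = 1.0 / 3.0

    def __post_init__(self) -> None:
        if not 0 < self.fraction < 1:
            raise ValueError("thinning fraction must lie in (0, 1)")

    def due(self, state: StandState) -> bool:
        return (not state.thinning_fired) and state.stand_age >= self.trigger_age


@dataclass(frozen=True)
class ThinningYield:
    """Carbon and tree removals of one thinning event."""

    wood_to_products: float      # kgC m^-2
    leaf_root_to_litter: float   # kgC m^-2
    trees_removed_ha: float      # trees ha^-1
    n_before_ha: float
    n_after_ha: float


def apply_thinning(
    state: StandState,
    grid: MassClassGrid,
    pft: PFTParams = DEFAULT_PFT,
    event: ThinningEvent = ThinningEvent(),
) -> tuple[StandState, ThinningYield]:
    """Remove a uniform fraction of trees from every mass class.

    Woody carbon (wood_frac of the removed biomass) moves to the product
    pool; leaf and root carbon move to litter.  Carbon is conserved exactly:
    the drop in live biomass equals products plus litter gains.
    """
    if state.thinning_fired:
        raise RuntimeError("thinning has already fired for this stand")
    f = event.fraction
    n_before = state.total_density()
    removed_carbon = f * state.biomass(grid)
    wood = pft.wood_frac * removed_carbon
    leaf_root = (pft.leaf_frac + pft.root_frac) * removed_carbon

    new = state.copy()
    new.number_density = state.number_density * (1.0 - f)
    new.top_mass_excess = state.top_mass_excess * (1.0 - f)
    new.product_pool = state.product_pool + wood
    new.litter_flux_accum = state.litter_flux_accum + leaf_root
    new.thinning_fired = True
    yield_ = ThinningYield(
        wood_to_products=wood,
        leaf_root_to_litter=leaf_root,
        trees_removed_ha=f * n_before * M2_PER_HA,
        n_before_ha=n_before * M2_PER_HA,
        n_after_ha=(1.0 - f) * n_before * M2_PER_HA,
    )
    return new, yield_


def total_sequestration(state: StandState, grid: MassClassGrid) -> float:
    """Cumulative sequestered carbon, kgC m^-2: live stand plus products.

    The harvested-products pool is non-decaying, so immediately across a
    thinning event only the litter share of the removed carbon leaves this
    total.
    """
    return state.biomass(grid) + state.product_pool
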