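"""Available-habitat maps: range x suitable land cover, under no dispersal.

A cell is available habitat for a species iff its land-cover class is
strongly or moderately associated with the species (the two levels are
pooled, unweighted) and the cell lies inside the species' *present-day*
breeding range. The same range mask is applied to every future scenario:
with no species-specific dispersal data the analysis conservatively assumes
no range expansion, so scenario habitat can shrink or shift within the
current range but never extends beyond it.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .errors import AlignmentError
from .landcover import LandCoverGrid
from .synthetic import SpeciesHabitatModel

__all__ = ["HabitatMap", "suitable_habitat", "habitat_areas_by_scenario", "T0"]

#: Scenario label of the present-day land cover.
T0 = "t0"


@dataclass
class HabitatMap:
    species_id: str
    suitable: np.ndarray
    area_km2: float
    scenario_id: str = T0

    def __post_init__(self) -> None:
        self.suitable = np.asarray(self.suitable, dtype=bool)


def suitable_habitat(
    species: SpeciesHabitatModel,
    landcover: LandCoverGrid,
    current_range: np.ndarray | None = None,
    scenario_id: str = T0,
) -> HabitatMap:
    """Overlay associations and the present-day range on one land-cover state.

    ``current_range`` defaults to the species' own range mask; pass it
    explicitly when evaluating scenario grids so the no-dispersal constraint
    is always anchored at the present-day range.
    """
    rng_mask = species.range_mask if current_range is None else np.asarray(current_range, bool)
    if rng_mask.shape != landcover.shape:
        raise AlignmentError(
            f"range mask {rng_mask.shape} does not match land cover {landcover.shape}"
        )
    suitable = landcover.class_mask(species.suitable_codes()) & rng_mask
    return HabitatMap(
        species_id=species.species_id,
        suitable=suitable,
        area_km2=float(suitable.sum()) * landcover.cell_area,
        scenario_id=scenario_id,
    )


def habitat_areas_by_scenario(
    species_set: list[SpeciesHabitatModel],
    scenario_grids: dict[str, LandCoverGrid],
) -> pd.DataFrame:
    """Species x scenario table of available-habitat areas (km^2).

    ``scenario_grids`` must include the present-day grid under the key
    ``"t0"``; every scenario column applies the no-dispersal constraint
    (the species' present-day range).
    """
    if T0 not in scenario_grids:
        raise ValueError("scenario_grids must include the present-day grid under 't0'")
    shapes = {g.shape for g in scenario_grids.values()}
    if len(shapes) != 1:
        raise AlignmentError(f"scenario grids have mismatched shapes: {shapes}")
    cols = [T0] + [s for s in scenario_grids if s != T0]
    data = {
        sid: [
            suitable_habitat(sp, scenario_grids[sid], sp.range_mask, sid).area_km2
            for sp in species_set
        ]
        for sid in cols
    }
    return pd.DataFrame(data, index=[sp.species_id for sp in species_set], columns=cols)
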