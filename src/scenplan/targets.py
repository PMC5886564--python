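"""Area-based representation targets.

The representation target is the area of a species' available habitat that
a reserve system must contain for the species to count as covered. It is
set from the present-day habitat area A (km^2):

* A < 100 km^2 (range-restricted): target = 100% of A;
* A > 1,000 km^2 (widespread): target = 10% of A;
* 100 <= A <= 1,000: linear interpolation, by default in *percent* space
  along the line through (100 km^2, 100%) and (1,000 km^2, 10%), i.e.
  ``percent = 100 - 0.1 * (A - 100)``.

The interpolation wording admits a second reading — interpolating the
target *area*, which is constant at 100 km^2 on [100, 1,000] — exposed as
``mode="area"``. Both modes agree at the two thresholds.

For each future scenario, targets are capped at the habitat remaining in
that scenario so they stay achievable.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import pandas as pd

__all__ = [
    "representation_target",
    "target_area",
    "achievable_target",
    "RepresentationTarget",
    "build_targets",
]


def representation_target(area_km2: float, mode: str = "percent") -> float:
    """Target as a percentage of present-day habitat area."""
    if area_km2 <= 0:
        raise ValueError(f"habitat area must be positive (got {area_km2})")
    if mode not in ("percent", "area"):
        raise ValueError(f"unknown interpolation mode {mode!r}")
    if area_km2 < 100.0:
        return 100.0
    if area_km2 > 1000.0:
        return 10.0
    if mode == "percent":
        return 100.0 - 0.1 * (area_km2 - 100.0)
    return 100.0 * 100.0 / area_km2  # constant 100 km^2 target area


def target_area(area_km2: float, mode: str = "percent") -> float:
    """Target in km^2: percent target applied to the present-day area."""
    return representation_target(area_km2, mode) / 100.0 * area_km2


def achievable_target(target_area_km2: float, scenario_area_km2: float) -> float:
    """Cap the target at the habitat remaining in a scenario."""
    if target_area_km2 < 0 or scenario_area_km2 < 0:
        raise ValueError("areas must be non-negative")
    return min(target_area_km2, scenario_area_km2)


@dataclass
class RepresentationTarget:
    species_id: str
    t0_area_km2: float
    target_percent: float
    target_area_km2: float
    achievable_area_km2: dict[str, float] = field(default_factory=dict)


def build_targets(
    habitat_areas: pd.DataFrame, mode: str = "percent"
) -> dict[str, RepresentationTarget]:
    """Targets for every species from a species x scenario area table.

    ``habitat_areas`` is the output of
    :func:`scenplan.habitat.habitat_areas_by_scenario` (must contain the
    ``t0`` column). Species with zero present-day habitat get a zero target.
    """
    if "t0" not in habitat_areas.columns:
        raise ValueError("habitat area table must contain a 't0' column")
    out: dict[str, RepresentationTarget] = {}
    scen_cols = [c for c in habitat_areas.columns if c != "t0"]
    for sid, row in habitat_areas.iterrows():
        a0 = float(row["t0"])
        if a0 > 0:
            pct = representation_target(a0, mode)
            tgt = pct / 100.0 * a0
        else:
            pct, tgt = 0.0, 0.0
        out[str(sid)] = RepresentationTarget(
            species_id=str(sid),
            t0_area_km2=a0,
            target_percent=pct,
            target_area_km2=tgt,
            achievable_area_km2={
                c: achievable_target(tgt, float(row[c])) for c in scen_cols
            },
        )
    return out


def targets_table(targets: dict[str, RepresentationTarget]) -> pd.DataFrame:
    """Flat CSV-ready table: one row per species, one achievable column per scenario."""
    rows = []
    for t in targets.values():
        row = {
            "species_id": t.species_id,
            "t0_area_km2": t.t0_area_km2,
            "target_percent": t.target_percent,
            "target_area_km2": t.target_area_km2,
        }
        row.update({f"achievable_{s}": a for s, a in t.achievable_area_km2.items()})
        rows.append(row)
    return pd.DataFrame(rows)
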