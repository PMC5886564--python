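"""Portfolio performance across scenarios.

A portfolio's performance in a scenario is the number of *covered*
species: species whose (scenario-achievable) representation target is met
by the habitat the portfolio holds under that scenario's land cover.
Habitat inside locked-in (already protected) PUs counts — the portfolio is
evaluated as a future reserve system. A species whose achievable target is
zero in a scenario (habitat entirely lost) is counted as not covered.

Robustness is summarised as the mean and population standard deviation of
the covered count over scenario groups, and spatial agreement between
portfolios as cell-overlap percentages (whole-portfolio, or restricted to
stated land-cover classes under each portfolio's own scenario land cover).
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .habitat import HabitatMap
from .landcover import LandCoverGrid
from .portfolio import Portfolio
from .synthetic import PUGrid

__all__ = [
    "covered_species",
    "PerformanceTable",
    "performance_summary",
    "overlap_matrix",
    "export_coverage_dataset",
]


def _portfolio_cell_mask(portfolio: Portfolio, pu_grid: PUGrid) -> np.ndarray:
    lut = np.zeros(int(pu_grid.ids.max()) + 1, dtype=bool)
    for pu in portfolio.selected_pus:
        lut[int(pu)] = True
    return lut[pu_grid.pu_ids]


def covered_species(
    portfolio: Portfolio,
    scenario_habitat: dict[str, HabitatMap],
    achievable: dict[str, float],
    pu_grid: PUGrid,
    cell_area: float,
) -> tuple[int, dict[str, bool]]:
    """Count species whose achievable target is met inside the portfolio.

    ``scenario_habitat`` maps species_id -> habitat map under one scenario's
    land cover; ``achievable`` gives that scenario's capped targets. A
    species is covered iff its achievable target is positive and the
    suitable area inside the portfolio's PUs is >= the target (inclusive).
    """
    missing = set(scenario_habitat) - set(achievable)
    if missing:
        raise ValueError(f"missing targets for species {sorted(missing)}")
    cells = _portfolio_cell_mask(portfolio, pu_grid)
    flags: dict[str, bool] = {}
    for sid, hm in scenario_habitat.items():
        if hm.suitable.shape != pu_grid.pu_ids.shape:
            raise ValueError(f"habitat map {sid} misaligned with PU grid")
        held = float((hm.suitable & cells).sum()) * cell_area
        t = float(achievable[sid])
        flags[sid] = bool(t > 0 and held >= t - 1e-9)
    return sum(flags.values()), flags


@dataclass
class PerformanceTable:
    """Covered-species results for every portfolio x scenario.

    ``counts`` is a long table (portfolio, scenario, n_covered); ``flags``
    holds the per-species boolean outcomes keyed by (portfolio, scenario).
    """

    counts: pd.DataFrame
    flags: dict[tuple[str, str], dict[str, bool]]

    @classmethod
    def from_runs(cls, results: dict[tuple[str, str], tuple[int, dict[str, bool]]]):
        rows = [
            {"portfolio": p, "scenario": s, "n_covered": n}
            for (p, s), (n, _) in results.items()
        ]
        return cls(
            counts=pd.DataFrame(rows),
            flags={k: f for k, (_, f) in results.items()},
        )


def performance_summary(
    table: PerformanceTable, groups: dict[str, list[str]]
) -> pd.DataFrame:
    """Mean and population SD of covered counts per portfolio x scenario group."""
    rows = []
    for gname, scens in groups.items():
        sub = table.counts[table.counts["scenario"].isin(scens)]
        for pname, grp in sub.groupby("portfolio"):
            vals = grp["n_covered"].to_numpy(dtype=float)
            rows.append(
                {
                    "portfolio": pname,
                    "group": gname,
                    "mean_covered": float(vals.mean()),
                    "sd_covered": float(vals.std(ddof=0)),
                    "n_scenarios": len(vals),
                }
            )
    return pd.DataFrame(rows)


def _directional_overlap(mask_a: np.ndarray, mask_b: np.ndarray) -> float:
    denom = int(mask_a.sum())
    if denom == 0:
        raise ValueError("empty portfolio/class mask in overlap computation")
    return 100.0 * int((mask_a & mask_b).sum()) / denom


def overlap_matrix(
    portfolios: list[Portfolio],
    pu_grid: PUGrid,
    mode: str = "whole_portfolio",
    landcover_by_portfolio: dict[str, LandCoverGrid] | None = None,
    class_codes: list[int] | None = None,
    symmetrize: bool = True,
) -> pd.DataFrame:
    """Pairwise percent overlap between portfolios (diagonal 100).

    ``whole_portfolio`` compares the portfolios' cell sets; the directional
    ratio uses the row portfolio's cells as denominator, symmetrised by the
    minimum of the two directions unless ``symmetrize=False``. ``per_class``
    restricts each portfolio to cells of ``class_codes`` under that
    portfolio's own land cover (``landcover_by_portfolio``), averaging the
    overlap across the classes (classes empty in the denominator are
    skipped).
    """
    if len(portfolios) < 2:
        raise ValueError("need at least 2 portfolios")
    if mode not in ("whole_portfolio", "per_class"):
        raise ValueError(f"unknown overlap mode {mode!r}")
    names = [p.name for p in portfolios]
    cells = {p.name: _portfolio_cell_mask(p, pu_grid) for p in portfolios}
    for p in portfolios:
        if not cells[p.name].any():
            raise ValueError(f"portfolio {p.name!r} is empty")
    out = pd.DataFrame(np.full((len(names), len(names)), np.nan), index=names, columns=names)
    for a in portfolios:
        for b in portfolios:
            if a.name == b.name:
                out.loc[a.name, b.name] = 100.0
                continue
            if mode == "whole_portfolio":
                ab = _directional_overlap(cells[a.name], cells[b.name])
                if symmetrize:
                    ba = _directional_overlap(cells[b.name], cells[a.name])
                    ab = min(ab, ba)
                out.loc[a.name, b.name] = ab
            else:
                if landcover_by_portfolio is None or class_codes is None:
                    raise ValueError("per_class mode needs landcover_by_portfolio and class_codes")
                la = landcover_by_portfolio[a.name]
                lb = landcover_by_portfolio[b.name]
                vals = []
                for code in class_codes:
                    ma = cells[a.name] & (la.classes == code)
                    mb = cells[b.name] & (lb.classes == code)
                    if ma.sum() == 0:
                        continue
                    v = _directional_overlap(ma, mb)
                    if symmetrize and mb.sum() > 0:
                        v = min(v, _directional_overlap(mb, ma))
                    vals.append(v)
                out.loc[a.name, b.name] = float(np.mean(vals)) if vals else np.nan
    return out


def export_coverage_dataset(table: PerformanceTable, strategies: dict[str, str]) -> pd.DataFrame:
    """Long-format records (species, scenario, strategy, covered 0/1).

    ``strategies`` maps portfolio name -> strategy label. One row per
    species x scenario x portfolio, the shape required by a binomial
    mixed-effects model with strategy as fixed effect and species/scenario
    as random intercepts (fit externally).
    """
    rows = []
    for (pname, scen), flags in table.flags.items():
        for sid, cov in flags.items():
            rows.append(
                {
                    "species": sid,
                    "scenario": scen,
                    "portfolio": pname,
                    "strategy": strategies.get(pname, pname),
                    "covered": int(cov),
                }
            )
    return pd.DataFrame(rows)
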