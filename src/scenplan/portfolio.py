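"""Conservation-area portfolios from selection frequencies.

Three strategies are compared:

* **current** — threshold rule on the present-day problem: every PU whose
  selection frequency exceeds 0.9 (plus the already-protected, locked-in
  PUs). Its natural-cover area defines the common area budget.
* **scenario_subset** — for a chosen subset of scenarios (e.g. the six
  severe-climate ones), PUs are ranked by coefficient of variation of
  selection frequency across the subset (ascending: most *consistently*
  selected first), ties by mean frequency (descending), then PU id; the
  ranking is walked, accumulating present-day natural cover, until the
  budget is reached.
* **all_scenarios** — the same CV ranking over the full 12-scenario set.

Budgets count only *purchased* natural area: locked-in PUs are already
protected, belong to every portfolio, and consume no budget. The CV of a
never-selected PU (mean 0) is undefined; such PUs are excluded from the
ranking. The standard deviation is the population SD (n divisor) across
the subset's scenarios.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .landcover import LandCoverGrid
from .reserve import AVAILABLE, LOCKED_IN, LOCKED_OUT
from .synthetic import PUGrid

__all__ = [
    "Portfolio",
    "SelectionFrequencyStack",
    "natural_area",
    "threshold_portfolio",
    "cv_rank_aggregate",
    "build_table1_portfolios",
    "TABLE1_SUBSETS",
]

#: The nine portfolio definitions: name -> scenario-id filter (None = the
#: threshold rule on the present-day problem).
TABLE1_SUBSETS: dict[str, object] = {
    "current": None,
    "all_scenarios": lambda sid: True,
    "severe_climate": lambda sid: sid.startswith("S-"),
    "moderate_climate": lambda sid: sid.startswith("M-"),
    "regulated": lambda sid: sid.split("-")[1] == "R",
    "unregulated": lambda sid: sid.split("-")[1] == "U",
    "low_rate": lambda sid: sid.endswith("-L"),
    "moderate_rate": lambda sid: sid.endswith("-M"),
    "high_rate": lambda sid: sid.endswith("-H"),
}

_STRATEGY = {
    "current": "current",
    "all_scenarios": "all_scenarios",
}


@dataclass
class Portfolio:
    """A named set of selected PUs with provenance.

    ``natural_area_km2`` is the present-day natural cover of the *purchased*
    PUs (selected minus locked-in), the quantity equalised across portfolios.
    """

    name: str
    strategy: str  # current | scenario_subset | all_scenarios
    scenarios_used: list[str]
    selected_pus: frozenset
    natural_area_km2: float
    locked_in: frozenset = field(default_factory=frozenset)

    @property
    def purchased(self) -> frozenset:
        return self.selected_pus - self.locked_in


@dataclass
class SelectionFrequencyStack:
    """Per-scenario selection frequencies (PU x scenario) with CV summaries."""

    freq: pd.DataFrame  # index: pu id, columns: scenario_id

    def __post_init__(self) -> None:
        vals = self.freq.to_numpy()
        if ((vals < -1e-12) | (vals > 1 + 1e-12)).any():
            raise ValueError("selection frequencies must lie in [0, 1]")

    @property
    def scenarios(self) -> list[str]:
        return list(self.freq.columns)

    def summary(self) -> pd.DataFrame:
        """mean, population sd and cv per PU (cv = inf where mean = 0)."""
        mean = self.freq.mean(axis=1)
        sd = self.freq.std(axis=1, ddof=0)
        cv = np.where(mean > 0, sd / mean.replace(0, np.nan), np.inf)
        return pd.DataFrame({"mean": mean, "sd": sd, "cv": cv}, index=self.freq.index)

    def subset(self, predicate) -> "SelectionFrequencyStack":
        cols = [c for c in self.freq.columns if predicate(c)]
        return SelectionFrequencyStack(self.freq[cols])


def natural_area(pus, landcover_t0: LandCoverGrid, pu_grid: PUGrid) -> float:
    """Total present-day natural cover (km^2) inside a set of PUs."""
    if landcover_t0.shape != pu_grid.pu_ids.shape:
        raise ValueError("land cover misaligned with PU grid")
    per_pu = pu_grid.pu_area_of(landcover_t0.natural_mask())
    idx = pu_grid.index_of()
    return float(sum(per_pu[idx[int(p)]] for p in pus))


def _status_sets(pu_grid: PUGrid, status: np.ndarray) -> tuple[frozenset, frozenset]:
    locked_in = frozenset(int(p) for p in pu_grid.ids[status == LOCKED_IN])
    locked_out = frozenset(int(p) for p in pu_grid.ids[status == LOCKED_OUT])
    return locked_in, locked_out


def threshold_portfolio(
    freq: pd.Series,
    landcover_t0: LandCoverGrid,
    pu_grid: PUGrid,
    status: np.ndarray,
    threshold: float = 0.9,
    name: str = "current",
) -> Portfolio:
    """PUs selected in strictly more than ``threshold`` of restarts, plus locked-in."""
    if ((freq < -1e-12) | (freq > 1 + 1e-12)).any():
        raise ValueError("frequencies must lie in [0, 1]")
    locked_in, locked_out = _status_sets(pu_grid, status)
    picked = frozenset(int(p) for p, f in freq.items() if f > threshold) - locked_out
    selected = picked | locked_in
    return Portfolio(
        name=name,
        strategy="current",
        scenarios_used=["t0"],
        selected_pus=selected,
        natural_area_km2=natural_area(selected - locked_in, landcover_t0, pu_grid),
        locked_in=locked_in,
    )


def cv_rank_aggregate(
    stack: SelectionFrequencyStack,
    area_budget_km2: float,
    landcover_t0: LandCoverGrid,
    pu_grid: PUGrid,
    status: np.ndarray,
    name: str = "aggregate",
    strategy: str = "scenario_subset",
) -> Portfolio:
    """Rank PUs (cv asc, mean desc, id asc) and select up to the natural-area budget.

    Walks the ranking, accumulating each PU's present-day natural cover and
    skipping locked-out and never-selected (mean 0) PUs; the PU whose
    inclusion first reaches the budget is included. Raises if the budget
    exceeds the natural area attainable from the ranked PUs.
    """
    if len(stack.scenarios) < 2:
        raise ValueError("CV aggregation needs at least 2 scenarios")
    if area_budget_km2 <= 0:
        raise ValueError("area budget must be positive")
    locked_in, locked_out = _status_sets(pu_grid, status)
    summ = stack.summary()
    ranked = summ[(summ["mean"] > 0) & ~summ.index.isin(locked_in | locked_out)]
    ranked = ranked.sort_values(
        by=["cv", "mean"], ascending=[True, False], kind="stable"
    )
    # stable sort on the pre-sorted-by-id index gives the id tie-break
    per_pu = pu_grid.pu_area_of(landcover_t0.natural_mask())
    idx = pu_grid.index_of()
    picked: list[int] = []
    acc = 0.0
    for pu in ranked.index:
        picked.append(int(pu))
        acc += float(per_pu[idx[int(pu)]])
        if acc >= area_budget_km2:
            break
    else:
        raise ValueError(
            f"area budget {area_budget_km2:.1f} km^2 unreachable; "
            f"max attainable natural area is {acc:.1f} km^2"
        )
    selected = frozenset(picked) | locked_in
    return Portfolio(
        name=name,
        strategy=strategy,
        scenarios_used=stack.scenarios,
        selected_pus=selected,
        natural_area_km2=acc,
        locked_in=locked_in,
    )


def build_table1_portfolios(
    freq_by_scenario: dict[str, pd.Series],
    t0_freq: pd.Series,
    landcover_t0: LandCoverGrid,
    pu_grid: PUGrid,
    status: np.ndarray,
    threshold: float = 0.9,
) -> list[Portfolio]:
    """The nine standard portfolios at a common natural-area budget.

    The current-distributions portfolio (threshold rule on the present-day
    frequencies) sets the budget; the all-scenarios portfolio and the
    climate/policy/rate subset portfolios are CV aggregates over their
    scenario columns at that budget.
    """
    if len(freq_by_scenario) != 12:
        raise ValueError(f"expected 12 scenario frequency maps, got {len(freq_by_scenario)}")
    stack = SelectionFrequencyStack(pd.DataFrame(freq_by_scenario))
    current = threshold_portfolio(
        t0_freq, landcover_t0, pu_grid, status, threshold=threshold, name="current"
    )
    budget = current.natural_area_km2
    out = [current]
    for name, pred in TABLE1_SUBSETS.items():
        if pred is None:
            continue
        strategy = "all_scenarios" if name == "all_scenarios" else "scenario_subset"
        out.append(
            cv_rank_aggregate(
                stack.subset(pred),
                budget,
                landcover_t0,
                pu_grid,
                status,
                name=name,
                strategy=strategy,
            )
        )
    return out
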