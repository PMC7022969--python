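"""Partial-budget economics of adopting a herd management information
system.

Only the cost and income changes caused by the adoption are counted:

* extra costs dC — straight-line amortization of hardware and software
  over their service life, plus additional labor for data collection and
  for data entry/analysis (day counts per 100 cows, scaled linearly with
  herd size, priced at a daily wage);
* extra income dI — for each improved trait, annual change (units per cow
  per year) x economic value (currency per unit per cow per year) x cows,
  accrued once per year over the horizon (non-cumulative: each year
  credits one year's worth of improvement, which is what makes a 0.31
  kg/yr milk-yield gain on 100 cows over 5 years worth
  0.31 x 64.6 x 100 x 5 ~= $10k, not the ~3x larger cumulative ramp);
* gross margin GM = dI - dC and marginal return rate MRR = 100 x GM / dC.

Annual trait changes can be supplied directly or estimated as the OLS
slope of model marginal means over the first follow-up years. All
arithmetic is kept unrounded; rounding is applied only when formatting
reports. Currency is a label, not a unit the engine interprets.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd


@dataclass(frozen=True)
class TraitChange:
    """Annual change of a trait and its economic value per unit."""

    name: str
    annual_change: float   # units / cow / year
    economic_value: float  # currency / unit / cow / year

    @property
    def income_per_cow_year(self) -> float:
        return self.annual_change * self.economic_value


def default_trait_changes() -> tuple[TraitChange, ...]:
    """Base scenario: one day less open per year (roughly) and a third of
    a kg more milk per day per year, at their per-unit economic values."""
    return (
        TraitChange("DO", -1.02, -2.15),
        TraitChange("DMY", 0.31, 64.6),
    )


@dataclass(frozen=True)
class BudgetInputs:
    """Inputs of the base partial-budget scenario (100-cow herd, 5-year
    horizon, $700 hardware and software amortized over 5 years, 7.6 + 15.2
    additional labor days per year per 100 cows at $24.7/day)."""

    horizon_years: int = 5
    herd_cows: float = 100.0
    hardware_cost: float = 700.0
    hardware_life_years: float = 5.0
    software_cost: float = 700.0
    software_life_years: float = 5.0
    collection_days_per_year_per_100cows: float = 7.6
    entry_days_per_year_per_100cows: float = 15.2
    day_wage: float = 24.7
    collection_day_wage: float | None = None  # None -> day_wage
    entry_day_wage: float | None = None
    traits: tuple[TraitChange, ...] = field(default_factory=default_trait_changes)

    def __post_init__(self) -> None:
        if self.horizon_years <= 0:
            raise ValueError("horizon_years must be positive")
        if self.herd_cows <= 0:
            raise ValueError("herd_cows must be positive")
        if min(self.hardware_life_years, self.software_life_years) <= 0:
            raise ValueError("amortization life must be positive")
        if self.day_wage <= 0 or self.hardware_cost < 0 or self.software_cost < 0:
            raise ValueError("costs must be non-negative and wage positive")

    @property
    def wage_collection(self) -> float:
        return self.day_wage if self.collection_day_wage is None \
            else self.collection_day_wage

    @property
    def wage_entry(self) -> float:
        return self.day_wage if self.entry_day_wage is None else self.entry_day_wage


@dataclass(frozen=True)
class CostBreakdown:
    hardware_per_year: float
    software_per_year: float
    collection_per_year: float
    entry_per_year: float
    horizon_years: int

    @property
    def per_year(self) -> float:
        return (self.hardware_per_year + self.software_per_year
                + self.collection_per_year + self.entry_per_year)

    @property
    def total(self) -> float:
        return self.horizon_years * self.per_year


@dataclass(frozen=True)
class BudgetResult:
    delta_cost: float
    income_by_trait: dict
    costs: CostBreakdown

    @property
    def delta_income(self) -> float:
        return float(sum(self.income_by_trait.values()))

    @property
    def gross_margin(self) -> float:
        return self.delta_income - self.delta_cost

    @property
    def marginal_return_rate(self) -> float:
        """Percent; NaN when the cost increase is zero (undefined)."""
        if self.delta_cost == 0:
            return math.nan
        return 100.0 * self.gross_margin / self.delta_cost


def compute_costs(inputs: BudgetInputs) -> CostBreakdown:
    """Expected cost increase: fixed amortized investments plus labor
    lines scaling linearly with herd size."""
    scale = inputs.herd_cows / 100.0
    return CostBreakdown(
        hardware_per_year=inputs.hardware_cost / inputs.hardware_life_years,
        software_per_year=inputs.software_cost / inputs.software_life_years,
        collection_per_year=(inputs.collection_days_per_year_per_100cows
                             * inputs.wage_collection * scale),
        entry_per_year=(inputs.entry_days_per_year_per_100cows
                        * inputs.wage_entry * scale),
        horizon_years=inputs.horizon_years,
    )


def compute_income(inputs: BudgetInputs) -> dict:
    """Expected income increase per trait over the horizon."""
    return {
        t.name: t.income_per_cow_year * inputs.herd_cows * inputs.horizon_years
        for t in inputs.traits
    }


def evaluate(inputs: BudgetInputs) -> BudgetResult:
    """Assemble the full budget: dC, per-trait dI, GM and MRR."""
    costs = compute_costs(inputs)
    income = compute_income(inputs)
    return BudgetResult(delta_cost=costs.total, income_by_trait=income,
                        costs=costs)


def annual_change_from_means(means: pd.DataFrame, level: str,
                             years: range | None = None) -> float:
    """OLS slope of marginal means on follow-up year for one adoption
    level (units per year), over the first five follow-up years by
    default."""
    years = years if years is not None else range(1, 6)
    lvl_col, fy_col = means.columns[:2]
    sub = means[(means[lvl_col] == level)
                & (means[fy_col].isin(list(years)))]
    if len(sub) < 2:
        raise ValueError("need at least two marginal means to fit a slope")
    x = sub[fy_col].to_numpy(dtype=float)
    y = sub["mean"].to_numpy(dtype=float)
    return float(np.polyfit(x, y, 1)[0])


def with_annual_changes(inputs: BudgetInputs, changes: dict[str, float]
                        ) -> BudgetInputs:
    """Return inputs with selected traits' annual changes replaced."""
    traits = tuple(
        replace(t, annual_change=changes.get(t.name, t.annual_change))
        for t in inputs.traits
    )
    return replace(inputs, traits=traits)


def break_even_herd_size(inputs: BudgetInputs, max_size: int = 10_000
                         ) -> int | None:
    """Smallest integer herd size with non-negative gross margin, all
    other inputs fixed (labor and income scale with cows, hardware and
    software do not). Returns None when no size up to ``max_size``
    breaks even."""
    per_cow_income = sum(t.income_per_cow_year for t in inputs.traits)
    per_cow_cost = (inputs.collection_days_per_year_per_100cows
                    * inputs.wage_collection
                    + inputs.entry_days_per_year_per_100cows
                    * inputs.wage_entry) / 100.0
    fixed = (inputs.hardware_cost / inputs.hardware_life_years
             + inputs.software_cost / inputs.software_life_years)
    margin = per_cow_income - per_cow_cost
    if margin <= 0:
        if fixed == 0 and margin == 0:
            return 1
        return None  # income never covers the variable cost, let alone fixed
    n = math.ceil(fixed / margin - 1e-12)
    n = max(n, 1)
    return n if n <= max_size else None


def format_budget_table(result: BudgetResult, inputs: BudgetInputs) -> str:
    """Human-readable budget statement with whole-dollar line items
    (presentation only; the result object keeps full precision)."""
    c = result.costs
    rows = [
        ("Investment in hardware", "USD/year", c.hardware_per_year),
        ("Investment in software", "USD/year", c.software_per_year),
        ("Data collection", "USD/year", c.collection_per_year),
        ("Data entry and information analysis", "USD/year", c.entry_per_year),
        (f"Total increase of costs (dC)", f"USD/{c.horizon_years}yr", c.total),
    ]
    lines = ["Expected increase in costs:"]
    lines += [f"  {n:<40s} {s:<10s} ${v:,.0f}" for n, s, v in rows]
    lines.append("Expected increase in income:")
    for name, v in result.income_by_trait.items():
        lines.append(f"  {name:<40s} USD/{c.horizon_years}yr   ${v:,.0f}")
    lines.append(f"  {'Total increase of income (dI)':<40s} "
                 f"USD/{c.horizon_years}yr   ${result.delta_income:,.0f}")
    lines.append(f"Gross margin (GM = dI - dC): ${result.gross_margin:,.0f}")
    mrr = result.marginal_return_rate
    lines.append(f"Marginal return rate (MRR = 100 x GM/dC): {mrr:.1f}%")
    return "\n".join(lines)
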