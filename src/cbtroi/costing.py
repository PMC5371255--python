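"""Ingredient-based program costing: line items, ledgers, rollout schedule.

Costs are built bottom-up from line items (units x unit cost, in KES),
aggregated into category subtotals and ledger grand totals, and converted to
USD at the fixed exchange rate. Two bundled ledgers transcribe the program's
cost tables line-for-line: one-off training costs, and the annual recurring
cost of running one site.

The rollout enrolls 13,440 participants across 12 sites over five years:
160 participants per site in year 1 (two counselors, two groups/week) and
240 per site in years 2-5 (three groups/week).
"""

from __future__ import annotations

import importlib.resources
from dataclasses import dataclass, field

import pandas as pd

from .params import EconomicContext, InvalidParameterError, kes_to_usd
from .engine import CashFlowSeries

__all__ = [
    "InconsistentLineItemError",
    "CostLineItem",
    "CostLedger",
    "RolloutSchedule",
    "sum_ledger",
    "load_ledger_csv",
    "training_ledger",
    "site_ledger",
    "base_schedule",
    "cost_stream",
    "unit_cost",
    "scale_line_items",
]

#: Tolerance (KES) for a stated line-item total vs. units x unit cost.
_LINE_TOL_KES = 1.0


class InconsistentLineItemError(ValueError):
    """A provided line-item total contradicts n_units x unit_cost."""


@dataclass(frozen=True)
class CostLineItem:
    """One costed ingredient: ``total_kes = n_units * unit_cost``."""

    label: str
    category: str
    unit: str
    n_units: float
    unit_cost: float  # KES per unit
    total_kes: float | None = None

    def __post_init__(self) -> None:
        if self.unit_cost < 0 or self.n_units < 0:
            raise InvalidParameterError(f"{self.label}: negative units or unit cost")
        computed = self.n_units * self.unit_cost
        if self.total_kes is None:
            object.__setattr__(self, "total_kes", computed)
        elif abs(self.total_kes - computed) > _LINE_TOL_KES:
            raise InconsistentLineItemError(
                f"{self.label}: stated total {self.total_kes} KES differs from "
                f"{self.n_units} x {self.unit_cost} = {computed} KES"
            )


@dataclass(frozen=True)
class CostLedger:
    """A collection of line items with category subtotals and grand totals."""

    items: tuple[CostLineItem, ...]
    category_subtotals: dict[str, float]
    grand_total_kes: float
    grand_total_usd: float

    def to_frame(self) -> pd.DataFrame:
        """Line items as a DataFrame (one row per item)."""
        return pd.DataFrame(
            {
                "label": [i.label for i in self.items],
                "category": [i.category for i in self.items],
                "unit": [i.unit for i in self.items],
                "n_units": [i.n_units for i in self.items],
                "unit_cost_kes": [i.unit_cost for i in self.items],
                "total_kes": [i.total_kes for i in self.items],
            }
        )


def sum_ledger(items: list[CostLineItem] | tuple[CostLineItem, ...], ctx: EconomicContext) -> CostLedger:
    """Aggregate line items into a ledger with subtotals and USD grand total."""
    if not items:
        raise InvalidParameterError("ledger requires at least one line item")
    subtotals: dict[str, float] = {}
    for item in items:
        subtotals[item.category] = subtotals.get(item.category, 0.0) + item.total_kes
    grand_kes = sum(item.total_kes for item in items)
    return CostLedger(
        items=tuple(items),
        category_subtotals=subtotals,
        grand_total_kes=grand_kes,
        grand_total_usd=kes_to_usd(grand_kes, ctx),
    )


def load_ledger_csv(path_or_buffer, ctx: EconomicContext) -> CostLedger:
    """Read a ledger from CSV (columns label, category, unit, n_units, unit_cost_kes)."""
    df = pd.read_csv(path_or_buffer)
    required = {"label", "category", "unit", "n_units", "unit_cost_kes"}
    missing = required - set(df.columns)
    if missing:
        raise InvalidParameterError(f"ledger CSV missing columns: {sorted(missing)}")
    items = [
        CostLineItem(
            label=row.label,
            category=row.category,
            unit=row.unit,
            n_units=float(row.n_units),
            unit_cost=float(row.unit_cost_kes),
        )
        for row in df.itertuples()
    ]
    return sum_ledger(items, ctx)


def _bundled(name: str):
    return importlib.resources.files("cbtroi.data").joinpath(name)


def training_ledger(ctx: EconomicContext) -> CostLedger:
    """The bundled first-year training cost ledger (KES 4,369,168)."""
    with importlib.resources.as_file(_bundled("training_costs.csv")) as p:
        return load_ledger_csv(p, ctx)


def site_ledger(ctx: EconomicContext) -> CostLedger:
    """The bundled per-site annual scale-up cost ledger (KES 752,555)."""
    with importlib.resources.as_file(_bundled("site_costs.csv")) as p:
        return load_ledger_csv(p, ctx)


@dataclass(frozen=True)
class RolloutSchedule:
    """Sites x years x participants-per-site enrollment plan.

    The base case runs 12 sites for 5 cost years with per-site enrollment
    (160, 240, 240, 240, 240), totalling 13,440 participants. Transport
    reimbursement (200 KES x 6 visits per participant) is already a line
    item of the per-site ledger; the schedule records the rates so
    sensitivity analyses can rescale that line without double counting.
    """

    n_sites: int = 12
    participants_per_site_by_year: tuple[int, ...] = (160, 240, 240, 240, 240)
    transport_reimbursement: float = 200.0  # KES per visit
    visits_per_participant: int = 6

    def __post_init__(self) -> None:
        if self.n_sites < 0:
            raise InvalidParameterError("n_sites must be >= 0")
        if any(p < 0 for p in self.participants_per_site_by_year):
            raise InvalidParameterError("participant counts must be >= 0")

    @property
    def n_cost_years(self) -> int:
        return len(self.participants_per_site_by_year)

    @property
    def cohort_sizes(self) -> tuple[int, ...]:
        """Participants enrolled program-wide in each rollout year."""
        return tuple(self.n_sites * p for p in self.participants_per_site_by_year)

    @property
    def total_participants(self) -> int:
        return sum(self.cohort_sizes)


def base_schedule() -> RolloutSchedule:
    """The base-case rollout schedule (12 sites, 160/240, 13,440 total)."""
    return RolloutSchedule()


def cost_stream(
    training: CostLedger, per_site: CostLedger, sched: RolloutSchedule
) -> CashFlowSeries:
    """Nominal program cost by year, USD.

    Year 1 carries the training ledger plus ``n_sites`` per-site ledgers;
    years 2..n_cost_years carry the per-site ledgers only. The same per-site
    ledger recurs each year (constant-2013-USD framing, no wage inflation).
    """
    annual_sites = sched.n_sites * per_site.grand_total_usd
    amounts = [training.grand_total_usd + annual_sites]
    amounts += [annual_sites] * (sched.n_cost_years - 1)
    return CashFlowSeries(amounts=tuple(amounts))


def unit_cost(total_cost: float, sched: RolloutSchedule) -> float:
    """Cost per participant: ``total_cost`` / total projected participants.

    Pass an undiscounted or a discounted total to get the corresponding
    per-participant variant.
    """
    n = sched.total_participants
    if n == 0:
        raise InvalidParameterError("schedule has zero participants")
    return total_cost / n


def scale_line_items(
    ledger: CostLedger, label_contains: str, factor: float, ctx: EconomicContext
) -> CostLedger:
    """Rescale every line whose label contains ``label_contains`` by ``factor``.

    Used by sensitivity analyses, e.g. to vary the participant transport
    reimbursement by scaling the participant-payments line.
    """
    items = [
        CostLineItem(i.label, i.category, i.unit, i.n_units, i.unit_cost * factor)
        if label_contains.lower() in i.label.lower()
        else i
        for i in ledger.items
    ]
    return sum_ledger(items, ctx)
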