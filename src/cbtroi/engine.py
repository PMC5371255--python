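"""Discounted cash-flow engine and headline cost-benefit outputs.

Monetary flows are year-indexed series in constant 2013 USD. Flows are
deemed to occur at the end of each program year, so year 1 is undiscounted
and year t is divided by (1 + r)^(t-1).

The time horizon is never configured independently: it is derived as
``n_cost_years + effect_length - 1`` (6 years in the base case), so the
final enrollment cohort's benefits are always counted over the full
treatment-effect length.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

__all__ = ["CashFlowSeries", "CBAResult", "discount", "run_cba", "ZeroCostError"]


class ZeroCostError(ZeroDivisionError):
    """Discounted costs are zero; the benefit-to-cost ratio is undefined."""


@dataclass(frozen=True)
class CashFlowSeries:
    """A year-indexed monetary stream (USD per program year).

    ``amounts[0]`` is program year ``start_year`` (1 by convention).
    """

    amounts: tuple[float, ...]
    start_year: int = 1

    def __post_init__(self) -> None:
        if len(self.amounts) < 1:
            raise ValueError("series must have at least one year")
        if not np.all(np.isfinite(self.amounts)):
            raise ValueError("series amounts must be finite")

    @property
    def total(self) -> float:
        return float(np.sum(self.amounts))

    def padded(self, n_years: int) -> "CashFlowSeries":
        """Extend with zero years up to length ``n_years``."""
        if n_years < len(self.amounts):
            raise ValueError("cannot pad to a shorter length")
        return CashFlowSeries(
            amounts=self.amounts + (0.0,) * (n_years - len(self.amounts)),
            start_year=self.start_year,
        )

    def __add__(self, other: "CashFlowSeries") -> "CashFlowSeries":
        if self.start_year != other.start_year:
            raise ValueError("series must share a start year")
        n = max(len(self.amounts), len(other.amounts))
        a = np.asarray(self.padded(n).amounts) + np.asarray(other.padded(n).amounts)
        return CashFlowSeries(amounts=tuple(float(x) for x in a), start_year=self.start_year)


def discount(series: CashFlowSeries, rate: float) -> CashFlowSeries:
    """Discount end-of-year flows: year t divided by (1 + rate)^(t-1).

    Year 1 (the first entry) is left undiscounted; rate 0 is the identity.
    """
    if rate < 0:
        raise ValueError("discount rate must be >= 0")
    t = np.arange(len(series.amounts))
    amounts = np.asarray(series.amounts) / (1.0 + rate) ** t
    return CashFlowSeries(amounts=tuple(float(x) for x in amounts), start_year=series.start_year)


@dataclass(frozen=True)
class CBAResult:
    """Headline outputs of one deterministic cost-benefit run.

    ``bcr = total_benefit_disc / total_cost_disc``;
    ``net_benefit = total_benefit_disc - total_cost_disc``. ``unit_cost`` is
    the undiscounted cost per projected participant; ``unit_cost_disc`` the
    discounted variant.
    """

    total_cost_disc: float
    total_benefit_disc: float
    bcr: float
    net_benefit: float
    unit_cost: float
    unit_cost_disc: float
    per_year_costs_disc: CashFlowSeries
    per_year_benefits_disc: CashFlowSeries
    effect_length: int
    discount_rate: float

    def summary(self) -> dict:
        """Reporting-precision summary alongside the raw values.

        Totals are rounded to the nearest $1,000 and the benefit-to-cost
        ratio to 2 decimals; raw full-precision values are always included.
        """
        return {
            "bcr": round(self.bcr, 2),
            "total_cost_disc_thousands": round(self.total_cost_disc / 1000) * 1000,
            "total_benefit_disc_thousands": round(self.total_benefit_disc / 1000) * 1000,
            "net_benefit": round(self.net_benefit),
            "unit_cost": round(self.unit_cost),
            "effect_length": self.effect_length,
            "discount_rate": self.discount_rate,
            "raw": {
                "bcr": self.bcr,
                "total_cost_disc": self.total_cost_disc,
                "total_benefit_disc": self.total_benefit_disc,
                "net_benefit": self.net_benefit,
                "unit_cost": self.unit_cost,
                "unit_cost_disc": self.unit_cost_disc,
                "per_year_costs_disc": list(self.per_year_costs_disc.amounts),
                "per_year_benefits_disc": list(self.per_year_benefits_disc.amounts),
            },
        }


def run_cba(
    params,
    training,
    per_site,
    sched,
    ctx,
    effect_length: int | None = None,
) -> CBAResult:
    """Run the full deterministic cost-benefit analysis.

    Composes the program cost stream, the cohort benefit stream, end-of-year
    discounting at ``ctx.discount_rate`` and the headline ratio outputs over
    the derived horizon ``n_cost_years + effect_length - 1``.
    """
    from .benefits import benefit_stream
    from .costing import cost_stream, unit_cost as _unit_cost

    if effect_length is None:
        effect_length = params.effect_length
    costs = cost_stream(training, per_site, sched)
    benefits = benefit_stream(params, sched, ctx, effect_length=effect_length)
    horizon = max(len(costs.amounts), len(benefits.amounts))
    costs_disc = discount(costs.padded(horizon), ctx.discount_rate)
    benefits_disc = discount(benefits.padded(horizon), ctx.discount_rate)
    total_cost = costs_disc.total
    total_benefit = benefits_disc.total
    if total_cost == 0:
        raise ZeroCostError("discounted costs are zero; BCR undefined")
    return CBAResult(
        total_cost_disc=total_cost,
        total_benefit_disc=total_benefit,
        bcr=total_benefit / total_cost,
        net_benefit=total_benefit - total_cost,
        unit_cost=_unit_cost(costs.total, sched),
        unit_cost_disc=_unit_cost(total_cost, sched),
        per_year_costs_disc=costs_disc,
        per_year_benefits_disc=benefits_disc,
        effect_length=effect_length,
        discount_rate=ctx.discount_rate,
    )
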