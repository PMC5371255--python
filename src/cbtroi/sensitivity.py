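"""One-way (tornado) sensitivity analysis and the varied-input registry.

Every sensitivity analysis — one-way here, probabilistic in
:mod:`cbtroi.psa` — works on named inputs. A :class:`Scenario` bundles the
complete model state (parameters, ledgers, schedule, economic context,
effect length); ``Scenario.apply(name, value)`` returns a new scenario with
that single input overridden. Composite parameters (the abstinence
difference and the adherence gain) are overridden directly, because the
published ranges are stated on the composites, not their ingredients.

Beyond the tabulated inputs, three program-level knobs are varied: the
treatment-effect length (which stretches the horizon with it), the discount
rate, and the participant transport reimbursement (applied by rescaling the
participant-payments ledger line, never added on top of it). The rollout
cost per participant is varied by rescaling both ledgers so the undiscounted
unit cost hits the target value.
"""

from __future__ import annotations

from dataclasses import dataclass, replace
from typing import Callable

import pandas as pd

from .costing import RolloutSchedule, CostLedger, scale_line_items, unit_cost, cost_stream
from .engine import CBAResult, run_cba
from .params import EconomicContext, ModelParameters, ParameterSpec

__all__ = ["UnknownParameterError", "Scenario", "TornadoEntry", "tornado", "tornado_frame"]


class UnknownParameterError(KeyError):
    """A varied name does not resolve to any model input."""


@dataclass(frozen=True)
class Scenario:
    """Complete model state for one deterministic cost-benefit run."""

    params: ModelParameters
    training: CostLedger
    per_site: CostLedger
    sched: RolloutSchedule
    ctx: EconomicContext
    effect_length: int = 2

    def run(self) -> CBAResult:
        return run_cba(
            self.params, self.training, self.per_site, self.sched, self.ctx,
            effect_length=self.effect_length,
        )

    def apply(self, name: str, value: float) -> "Scenario":
        """Return a copy with the named input set to ``value``."""
        try:
            applier = _APPLIERS[name]
        except KeyError:
            raise UnknownParameterError(name) from None
        return applier(self, value)


def _param_field(field_name: str) -> Callable[[Scenario, float], Scenario]:
    def apply(s: Scenario, v: float) -> Scenario:
        return replace(s, params=s.params.with_(**{field_name: v}))

    return apply


def _nondrug_component(index: int) -> Callable[[Scenario, float], Scenario]:
    def apply(s: Scenario, v: float) -> Scenario:
        comps = list(s.params.nondrug_costs_2009)
        comps[index] = v
        return replace(s, params=s.params.with_(nondrug_costs_2009=tuple(comps)))

    return apply


def _apply_effect_length(s: Scenario, v: float) -> Scenario:
    return replace(s, effect_length=int(round(v)))


def _apply_discount_rate(s: Scenario, v: float) -> Scenario:
    return replace(s, ctx=replace(s.ctx, discount_rate=v))


def _apply_transport(s: Scenario, v: float) -> Scenario:
    factor = v / s.sched.transport_reimbursement
    per_site = scale_line_items(s.per_site, "participant payments", factor, s.ctx)
    return replace(
        s, per_site=per_site, sched=replace(s.sched, transport_reimbursement=v)
    )


def _apply_unit_cost(s: Scenario, v: float) -> Scenario:
    base_unit = unit_cost(cost_stream(s.training, s.per_site, s.sched).total, s.sched)
    factor = v / base_unit
    return replace(
        s,
        training=scale_line_items(s.training, "", factor, s.ctx),
        per_site=scale_line_items(s.per_site, "", factor, s.ctx),
    )


#: name -> applier; the single registry shared by tornado and PSA.
_APPLIERS: dict[str, Callable[[Scenario, float], Scenario]] = {
    "abstinence_difference": _param_field("delta_abstinence_override"),
    "alcohol_attributable_fraction": _param_field("alcohol_attrib_frac"),
    "adherence_gain": _param_field("adherence_gain_override"),
    "nondrug_lab": _nondrug_component(0),
    "nondrug_visits": _nondrug_component(1),
    "nondrug_support": _nondrug_component(2),
    "nondrug_fixed": _nondrug_component(3),
    "arv_drug_cost": _param_field("arv_drug_cost"),
    "monthly_min_wage": _param_field("monthly_min_wage"),
    "lfp_rise": _param_field("lfp_rise"),
    "hp_firewood_hours": _param_field("hp_hours_firewood"),
    "hp_water_hours": _param_field("hp_hours_water"),
    "house_worker_wage": _param_field("house_wage"),
    "effect_length_years": _apply_effect_length,
    "discount_rate": _apply_discount_rate,
    "transport_kes_per_visit": _apply_transport,
    "cbt_cost_per_participant": _apply_unit_cost,
}


@dataclass(frozen=True)
class TornadoEntry:
    """One-way sensitivity result for a single input."""

    parameter: str
    low_value: float
    high_value: float
    bcr_at_low: float
    bcr_at_high: float

    @property
    def spread(self) -> float:
        return abs(self.bcr_at_high - self.bcr_at_low)


def tornado(base: Scenario, vary_list: list[ParameterSpec]) -> list[TornadoEntry]:
    """One-way sensitivity: re-run the full CBA at each bound of each input.

    Every other input stays at base. Entries are sorted by spread,
    descending, with ties broken alphabetically by parameter name.
    """
    entries = []
    for spec in vary_list:
        bcr_low = base.apply(spec.name, spec.low).run().bcr
        bcr_high = base.apply(spec.name, spec.high).run().bcr
        entries.append(
            TornadoEntry(
                parameter=spec.name,
                low_value=spec.low,
                high_value=spec.high,
                bcr_at_low=bcr_low,
                bcr_at_high=bcr_high,
            )
        )
    return sorted(entries, key=lambda e: (-e.spread, e.parameter))


def tornado_frame(entries: list[TornadoEntry]) -> pd.DataFrame:
    """Tornado results as a DataFrame, one input per row, widest spread first."""
    return pd.DataFrame(
        {
            "parameter": [e.parameter for e in entries],
            "low_value": [e.low_value for e in entries],
            "high_value": [e.high_value for e in entries],
            "bcr_at_low": [e.bcr_at_low for e in entries],
            "bcr_at_high": [e.bcr_at_high for e in entries],
            "spread": [e.spread for e in entries],
        }
    )
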