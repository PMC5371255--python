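"""Configuration loading, validation and report writing.

The package ships a bundled base-case configuration (parameter YAML plus the
two cost-ledger CSVs); ``load_config()`` with no arguments loads it.
Validation failures name the offending field. Reports are written as CSV
tables (per-year streams, tornado, PSA summaries) and a JSON summary with
deterministic field ordering.
"""

from __future__ import annotations

import importlib.resources
import json
from dataclasses import dataclass
from pathlib import Path

import yaml

from .costing import (
    CostLedger,
    RolloutSchedule,
    load_ledger_csv,
    site_ledger,
    training_ledger,
)
from .engine import CBAResult
from .params import (
    EconomicContext,
    InvalidParameterError,
    ModelParameters,
    ParameterSpec,
)
from .sensitivity import Scenario

__all__ = ["ConfigError", "ModelConfig", "load_config", "write_report"]


class ConfigError(ValueError):
    """A configuration file failed to parse or validate."""


@dataclass(frozen=True)
class ModelConfig:
    """Fully validated model inputs plus the sensitivity specification."""

    params: ModelParameters
    training: CostLedger
    per_site: CostLedger
    sched: RolloutSchedule
    ctx: EconomicContext
    sensitivity: tuple[ParameterSpec, ...]
    oneway_extras: tuple[ParameterSpec, ...]

    def scenario(self, effect_length: int | None = None) -> Scenario:
        """The base-case scenario this configuration defines."""
        return Scenario(
            params=self.params,
            training=self.training,
            per_site=self.per_site,
            sched=self.sched,
            ctx=self.ctx,
            effect_length=effect_length or self.params.effect_length,
        )

    @property
    def all_oneway_specs(self) -> tuple[ParameterSpec, ...]:
        return self.sensitivity + self.oneway_extras


def _spec_from_record(record: dict) -> ParameterSpec:
    try:
        return ParameterSpec(
            name=record["name"],
            base=float(record["base"]),
            low=float(record["low"]),
            high=float(record["high"]),
            units=str(record.get("units", "")),
            distribution=str(record.get("distribution", "fixed")),
            se=float(record["se"]) if "se" in record else None,
        )
    except (KeyError, TypeError, ValueError) as exc:
        raise ConfigError(f"sensitivity record {record.get('name', record)!r}: {exc}") from exc


def load_config(
    params_path: str | Path | None = None,
    training_csv: str | Path | None = None,
    site_csv: str | Path | None = None,
) -> ModelConfig:
    """Load and validate a full model configuration.

    Any argument left as ``None`` falls back to the bundled base-case file.
    """
    if params_path is None:
        source = importlib.resources.files("cbtroi.data").joinpath("table1_params.yaml")
        raw = yaml.safe_load(source.read_text())
    else:
        try:
            raw = yaml.safe_load(Path(params_path).read_text())
        except yaml.YAMLError as exc:
            raise ConfigError(f"cannot parse {params_path}: {exc}") from exc
    for section in ("economic_context", "model", "schedule"):
        if section not in raw:
            raise ConfigError(f"missing config section {section!r}")

    econ = raw["economic_context"]
    try:
        ctx = EconomicContext(
            discount_rate=float(econ["discount_rate"]),
            exchange_rate=float(econ["exchange_rate_kes_per_usd"]),
            cpi={int(y): float(v) for y, v in econ["cpi"].items()},
            reference_year=int(econ["reference_year"]),
        )
    except (KeyError, InvalidParameterError, ValueError) as exc:
        raise ConfigError(f"economic_context: {exc}") from exc

    m = raw["model"]
    try:
        params = ModelParameters(
            p_abst_cbt=float(m["p_abst_cbt"]),
            p_abst_uc=float(m["p_abst_uc"]),
            alcohol_attrib_frac=float(m["alcohol_attrib_frac"]),
            nondrug_costs_2009=tuple(float(c) for c in m["nondrug_costs_2009"]),
            arv_drug_cost=float(m["arv_drug_cost"]),
            adherence_counts=(
                tuple(int(c) for c in m["adherence_counts"]["hazardous"]),
                tuple(int(c) for c in m["adherence_counts"]["nondrinker"]),
            ),
            lfp_rise=float(m["lfp_rise"]),
            lfp_baseline_hours=float(m["lfp_baseline_hours"]),
            lfp_se_hours=float(m["lfp_se_hours"]),
            monthly_min_wage=float(m["monthly_min_wage"]),
            hp_hours_firewood=float(m["hp_hours_firewood"]),
            hp_hours_water=float(m["hp_hours_water"]),
            house_wage=float(m["house_wage"]),
            female_fraction=float(m["female_fraction"]),
            effect_length=int(m["effect_length"]),
            annualization_weeks=float(m["annualization_weeks"]),
            months_per_year=int(m.get("months_per_year", 12)),
        )
    except (KeyError, InvalidParameterError, ValueError) as exc:
        raise ConfigError(f"model: {exc}") from exc

    s = raw["schedule"]
    try:
        sched = RolloutSchedule(
            n_sites=int(s["n_sites"]),
            participants_per_site_by_year=tuple(int(p) for p in s["participants_per_site_by_year"]),
            transport_reimbursement=float(s["transport_kes_per_visit"]),
            visits_per_participant=int(s["visits_per_participant"]),
        )
    except (KeyError, InvalidParameterError, ValueError) as exc:
        raise ConfigError(f"schedule: {exc}") from exc

    training = training_ledger(ctx) if training_csv is None else load_ledger_csv(training_csv, ctx)
    per_site = site_ledger(ctx) if site_csv is None else load_ledger_csv(site_csv, ctx)

    sensitivity = tuple(_spec_from_record(r) for r in raw.get("sensitivity", []))
    extras = tuple(_spec_from_record(r) for r in raw.get("oneway_extras", []))
    return ModelConfig(
        params=params,
        training=training,
        per_site=per_site,
        sched=sched,
        ctx=ctx,
        sensitivity=sensitivity,
        oneway_extras=extras,
    )


def write_report(result: CBAResult, out_dir: str | Path, stem: str = "cba") -> list[Path]:
    """Write a CBAResult as a JSON summary plus a per-year CSV table."""
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    paths = []
    summary_path = out / f"{stem}_summary.json"
    summary_path.write_text(json.dumps(result.summary(), indent=2, sort_keys=True))
    paths.append(summary_path)

    years = range(1, len(result.per_year_costs_disc.amounts) + 1)
    import pandas as pd

    table = pd.DataFrame(
        {
            "year": list(years),
            "cost_disc_usd": list(result.per_year_costs_disc.amounts),
            "benefit_disc_usd": list(result.per_year_benefits_disc.amounts),
        }
    )
    table_path = out / f"{stem}_per_year.csv"
    table.to_csv(table_path, index=False)
    paths.append(table_path)
    return paths
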