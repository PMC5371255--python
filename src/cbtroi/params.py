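"""Model inputs: economic context, parameter specifications, derived parameters.

Every input of the cost-benefit model lives here: the economic context
(discount rate, KES/USD exchange rate, the Kenyan consumer price index used
to express 2009-denominated treatment costs in constant 2013 USD), the base
values of the behavioural and economic parameters, and the sensitivity
specification (range + distribution family) attached to each of them.

Two composite parameters are derived rather than quoted:

* the abstinence-rate difference between the CBT arm and usual care
  (0.69 − 0.38 = 0.31), and
* the adherence gain — the excess non-adherence of hazardous drinkers over
  non-drinkers (19/69 − 112/1439 ≈ 0.19753) — i.e. the rise in the
  probability of full ARV adherence when a patient moves to abstinence.

Internal computation never rounds these composites; reporting does.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

__all__ = [
    "InvalidParameterError",
    "MissingCPIYearError",
    "EconomicContext",
    "ParameterSpec",
    "ModelParameters",
    "derive_abstinence_difference",
    "derive_adherence_gain",
    "inflate_cpi",
    "kes_to_usd",
    "usd_to_kes",
    "annual_hiv_treatment_cost",
    "base_economic_context",
    "base_model_parameters",
]


class InvalidParameterError(ValueError):
    """A model input violates its domain constraints."""


class MissingCPIYearError(KeyError):
    """A CPI conversion was requested for a year absent from the index."""


@dataclass(frozen=True)
class EconomicContext:
    """Monetary conversion context: discounting, FX and price index.

    Parameters
    ----------
    discount_rate : float
        Annual discount rate (fraction per year), default 0.03.
    exchange_rate : float
        Kenyan shillings per US dollar; a single fixed rate (84.53) is used
        for all years.
    cpi : dict[int, float]
        Calendar year -> Kenyan consumer price index value (2009 = 100).
    reference_year : int
        Year of the constant-dollar reporting basis (2013).
    """

    discount_rate: float = 0.03
    exchange_rate: float = 84.53
    cpi: dict[int, float] = field(
        default_factory=lambda: {2009: 100.0, 2010: 106.265, 2011: 121.17, 2013: 140.103}
    )
    reference_year: int = 2013

    def __post_init__(self) -> None:
        if self.discount_rate < 0:
            raise InvalidParameterError("discount_rate must be >= 0")
        if self.exchange_rate <= 0:
            raise InvalidParameterError("exchange_rate must be > 0")
        if any(v <= 0 for v in self.cpi.values()):
            raise InvalidParameterError("all CPI values must be > 0")
        if self.reference_year not in self.cpi:
            raise MissingCPIYearError(self.reference_year)


#: Distribution families recognised by the probabilistic sensitivity analysis.
DISTRIBUTIONS = ("right_skewed_cost", "normal_ci", "uniform_range", "fixed")


@dataclass(frozen=True)
class ParameterSpec:
    """One model input with its base value, sensitivity range and distribution.

    ``distribution`` is one of ``right_skewed_cost`` (log-normal, used for
    cost inputs), ``normal_ci`` (normal with sd equal to the standard error
    behind the printed confidence interval; requires ``se``),
    ``uniform_range`` or ``fixed``.
    """

    name: str
    base: float
    low: float
    high: float
    units: str = ""
    distribution: str = "fixed"
    se: float | None = None

    def __post_init__(self) -> None:
        if not (self.low <= self.base <= self.high):
            raise InvalidParameterError(
                f"{self.name}: require low <= base <= high, got "
                f"({self.low}, {self.base}, {self.high})"
            )
        if self.distribution not in DISTRIBUTIONS:
            raise InvalidParameterError(
                f"{self.name}: unknown distribution {self.distribution!r}"
            )
        if self.distribution == "normal_ci" and not (self.se and self.se > 0):
            raise InvalidParameterError(f"{self.name}: normal_ci requires se > 0")


def derive_abstinence_difference(p_cbt: float, p_uc: float) -> float:
    """Abstinence-rate difference between the CBT arm and usual care.

    Both arguments are 90-day abstinence proportions in [0, 1]; the CBT rate
    must be at least the usual-care rate (a negative treatment effect is not
    supported by the base model).
    """
    for name, p in (("p_cbt", p_cbt), ("p_uc", p_uc)):
        if not 0.0 <= p <= 1.0:
            raise InvalidParameterError(f"{name} must be in [0, 1], got {p}")
    if p_cbt < p_uc:
        raise InvalidParameterError("treatment abstinence rate below control rate")
    return p_cbt - p_uc


def derive_adherence_gain(
    nonadherent_hazardous: tuple[int, int], nonadherent_nondrinker: tuple[int, int]
) -> float:
    """Rise in the probability of full ARV adherence on moving to abstinence.

    Each argument is an ``(events, exposed)`` pair of non-adherent counts:
    the hazardous-drinker fraction minus the non-drinker fraction.
    """
    fracs = []
    for pair in (nonadherent_hazardous, nonadherent_nondrinker):
        events, exposed = pair
        if exposed <= 0:
            raise InvalidParameterError("exposed count must be > 0")
        if not 0 <= events <= exposed:
            raise InvalidParameterError(f"require 0 <= events <= exposed, got {pair}")
        fracs.append(events / exposed)
    return fracs[0] - fracs[1]


def inflate_cpi(amount: float, from_year: int, to_year: int, ctx: EconomicContext) -> float:
    """Convert ``amount`` from ``from_year`` prices to ``to_year`` prices via CPI."""
    for year in (from_year, to_year):
        if year not in ctx.cpi:
            raise MissingCPIYearError(year)
    return amount * ctx.cpi[to_year] / ctx.cpi[from_year]


def kes_to_usd(amount_kes: float, ctx: EconomicContext) -> float:
    """Convert Kenyan shillings to US dollars at the fixed exchange rate."""
    return amount_kes / ctx.exchange_rate


def usd_to_kes(amount_usd: float, ctx: EconomicContext) -> float:
    """Convert US dollars to Kenyan shillings at the fixed exchange rate."""
    return amount_usd * ctx.exchange_rate


@dataclass(frozen=True)
class ModelParameters:
    """Base-case behavioural and economic inputs of the cost-benefit model.

    Attributes
    ----------
    p_abst_cbt, p_abst_uc
        90-day abstinence proportions in the CBT and usual-care arms.
    alcohol_attrib_frac
        Fraction of new HIV infections attributable to alcohol use (0.13,
        consumed from the Braithwaite transmission model, not re-estimated).
    nondrug_costs_2009
        Annual per-patient non-drug HIV treatment cost components in 2009
        USD: lab tests, clinic visits, support services, hospital fixed
        costs (32, 24, 0.4, 32).
    arv_drug_cost
        Annual tenofovir/3TC/EFV cost, 2013 USD (145.47).
    adherence_counts
        Non-adherent (events, exposed) pairs for hazardous drinkers and
        non-drinkers, the ingredients of the adherence gain.
    lfp_rise
        Rise in weekly hours worked after consistent ARV adherence, as a
        fraction of baseline hours (0.19 = +4.6 h on 24.3 h, SE 1.88 h).
    monthly_min_wage
        Mean Kenyan monthly minimum wage, 2013 USD (76.93).
    hp_hours_firewood, hp_hours_water
        Weekly female household-production hour gains (firewood, water).
    house_wage
        Hourly minimum wage for a house worker, USD (0.85).
    female_fraction
        Share of the modelled cohort that is female (0.5); household
        productivity accrues to women only.
    effect_length
        Years the CBT treatment effect is maintained (base case 2).
    annualization_weeks
        Weeks per year used to value weekly household-production hours (48).
    """

    p_abst_cbt: float = 0.69
    p_abst_uc: float = 0.38
    alcohol_attrib_frac: float = 0.13
    nondrug_costs_2009: tuple[float, float, float, float] = (32.0, 24.0, 0.4, 32.0)
    arv_drug_cost: float = 145.47
    adherence_counts: tuple[tuple[int, int], tuple[int, int]] = ((19, 69), (112, 1439))
    lfp_rise: float = 0.19
    lfp_baseline_hours: float = 24.3
    lfp_se_hours: float = 1.88
    monthly_min_wage: float = 76.93
    hp_hours_firewood: float = 1.056
    hp_hours_water: float = 1.945
    hp_se_firewood: float = 0.461
    hp_se_water: float = 0.556
    house_wage: float = 0.85
    female_fraction: float = 0.5
    effect_length: int = 2
    annualization_weeks: float = 48.0
    months_per_year: int = 12
    # Composite overrides: sensitivity analyses vary the composites directly
    # (the ranges are stated on the composites, not their ingredients).
    delta_abstinence_override: float | None = None
    adherence_gain_override: float | None = None

    def __post_init__(self) -> None:
        fractions = {
            "p_abst_cbt": self.p_abst_cbt,
            "p_abst_uc": self.p_abst_uc,
            "alcohol_attrib_frac": self.alcohol_attrib_frac,
            "female_fraction": self.female_fraction,
        }
        for name, value in fractions.items():
            if not 0.0 <= value <= 1.0:
                raise InvalidParameterError(f"{name} must be in [0, 1], got {value}")
        nonneg = {
            "arv_drug_cost": self.arv_drug_cost,
            "lfp_rise": self.lfp_rise,
            "monthly_min_wage": self.monthly_min_wage,
            "hp_hours_firewood": self.hp_hours_firewood,
            "hp_hours_water": self.hp_hours_water,
            "house_wage": self.house_wage,
            "annualization_weeks": self.annualization_weeks,
        }
        for name, value in nonneg.items():
            if value < 0:
                raise InvalidParameterError(f"{name} must be >= 0, got {value}")
        if any(c < 0 for c in self.nondrug_costs_2009):
            raise InvalidParameterError("non-drug cost components must be >= 0")
        if self.effect_length < 1:
            raise InvalidParameterError("effect_length must be >= 1")

    @property
    def delta_abstinence(self) -> float:
        """Abstinence-rate difference (parameter of benefit chains 1 and 2)."""
        if self.delta_abstinence_override is not None:
            return self.delta_abstinence_override
        return derive_abstinence_difference(self.p_abst_cbt, self.p_abst_uc)

    @property
    def adherence_gain(self) -> float:
        """Adherence-probability gain from abstinence (full precision)."""
        if self.adherence_gain_override is not None:
            return self.adherence_gain_override
        return derive_adherence_gain(*self.adherence_counts)

    def with_(self, **changes) -> "ModelParameters":
        """Return a copy with the given fields replaced."""
        return replace(self, **changes)


def annual_hiv_treatment_cost(params: ModelParameters, ctx: EconomicContext) -> float:
    """Annual per-patient HIV treatment cost in constant 2013 USD.

    Sum of the 2009-denominated non-drug components (lab tests, clinic
    visits, support services, hospital fixed costs) inflated to 2013 with
    the Kenyan CPI, plus the 2013 ARV drug cost.
    """
    nondrug_2013 = inflate_cpi(sum(params.nondrug_costs_2009), 2009, ctx.reference_year, ctx)
    return nondrug_2013 + params.arv_drug_cost


def base_economic_context() -> EconomicContext:
    """The base-case economic context (3% discount, 84.53 KES/USD, 2013 basis)."""
    return EconomicContext()


def base_model_parameters() -> ModelParameters:
    """The base-case model parameters."""
    return ModelParameters()
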