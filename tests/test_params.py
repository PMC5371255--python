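"""Economic context, parameter derivations, CPI and currency conversion."""

import pytest
from hypothesis import given, settings, strategies as st

from cbtroi import (
    EconomicContext,
    InvalidParameterError,
    MissingCPIYearError,
    ModelParameters,
    ParameterSpec,
    annual_hiv_treatment_cost,
    base_economic_context,
    derive_abstinence_difference,
    derive_adherence_gain,
    inflate_cpi,
    kes_to_usd,
    usd_to_kes,
)


class TestAbstinenceDifference:
    @pytest.mark.parametrize(
        "p_cbt, p_uc, expected",
        [(0.69, 0.38, 0.31), (0.5, 0.5, 0.0), (1.0, 0.0, 1.0)],
    )
    def test_examples(self, p_cbt, p_uc, expected):
        assert derive_abstinence_difference(p_cbt, p_uc) == pytest.approx(expected)

    def test_negative_effect_rejected(self):
        with pytest.raises(InvalidParameterError):
            derive_abstinence_difference(0.38, 0.69)

    def test_out_of_range_rejected(self):
        with pytest.raises(InvalidParameterError):
            derive_abstinence_difference(1.2, 0.38)


class TestAdherenceGain:
    @pytest.mark.parametrize(
        "hazardous, nondrinker, expected",
        [
            ((19, 69), (112, 1439), 19 / 69 - 112 / 1439),
            ((0, 10), (0, 10), 0.0),
            ((69, 69), (0, 1439), 1.0),
        ],
    )
    def test_examples(self, hazardous, nondrinker, expected):
        assert derive_adherence_gain(hazardous, nondrinker) == pytest.approx(expected)

    def test_reproduces_printed_percentage(self):
        # 19/69 - 112/1439 rounds to the published 19.75%
        assert round(100 * derive_adherence_gain((19, 69), (112, 1439)), 2) == 19.75

    def test_zero_denominator_rejected(self):
        with pytest.raises(InvalidParameterError):
            derive_adherence_gain((19, 0), (112, 1439))


class TestCPIAndFX:
    def test_nondrug_2009_to_2013(self):
        ctx = base_economic_context()
        # 32 + 24 + 0.4 + 32 = 88.4 in 2009 USD -> 2013 USD
        value = inflate_cpi(88.4, 2009, 2013, ctx)
        assert value == pytest.approx(123.85, abs=0.01)
        assert round(value) == 124

    def test_identity_same_year(self):
        ctx = base_economic_context()
        assert inflate_cpi(57.0, 2010, 2010, ctx) == pytest.approx(57.0)

    def test_2009_to_2010(self):
        assert inflate_cpi(100, 2009, 2010, base_economic_context()) == pytest.approx(106.265)

    def test_missing_year_signalled(self):
        with pytest.raises(MissingCPIYearError):
            inflate_cpi(10.0, 2009, 2012, base_economic_context())

    @pytest.mark.parametrize(
        "kes, usd", [(752_555, 8903), (0, 0.0), (84.53, 1.0)]
    )
    def test_kes_to_usd(self, kes, usd):
        # the per-site total prints as $8,903 at the 84.53 rate
        assert kes_to_usd(kes, base_economic_context()) == pytest.approx(usd, abs=0.5)

    @given(st.floats(min_value=0, max_value=1e9, allow_nan=False))
    @settings(max_examples=50, deadline=None)
    def test_fx_round_trip(self, x):
        ctx = base_economic_context()
        assert kes_to_usd(usd_to_kes(x, ctx), ctx) == pytest.approx(x, rel=1e-12)

    @given(st.floats(min_value=0.01, max_value=1e6, allow_nan=False))
    @settings(max_examples=50, deadline=None)
    def test_cpi_multiplicative_transitivity(self, amount):
        ctx = base_economic_context()
        via_2010 = inflate_cpi(inflate_cpi(amount, 2009, 2010, ctx), 2010, 2013, ctx)
        assert via_2010 == pytest.approx(inflate_cpi(amount, 2009, 2013, ctx), rel=1e-12)

    def test_context_validation(self):
        with pytest.raises(InvalidParameterError):
            EconomicContext(discount_rate=-0.01)
        with pytest.raises(InvalidParameterError):
            EconomicContext(exchange_rate=0)
        with pytest.raises(MissingCPIYearError):
            EconomicContext(cpi={2009: 100.0}, reference_year=2013)


class TestTreatmentCost:
    def test_base_case(self):
        value = annual_hiv_treatment_cost(ModelParameters(), base_economic_context())
        assert value == pytest.approx(123.85 + 145.47, abs=0.01)

    def test_zero_drug_cost(self):
        params = ModelParameters(arv_drug_cost=0.0)
        value = annual_hiv_treatment_cost(params, base_economic_context())
        assert value == pytest.approx(123.85, abs=0.01)

    def test_fixed_cost_upper_bound(self):
        # fixed-cost component at its upper bound, used by the tornado
        params = ModelParameters(nondrug_costs_2009=(32.0, 24.0, 0.4, 46.6))
        expected = (32 + 24 + 0.4 + 46.6) * 140.103 / 100 + 145.47
        value = annual_hiv_treatment_cost(params, base_economic_context())
        assert value == pytest.approx(expected, rel=1e-12)
        assert value == pytest.approx(144.31 + 145.47, abs=0.01)


class TestModelParameters:
    def test_composites_match_stored_base_values(self):
        params = ModelParameters()
        assert params.delta_abstinence == pytest.approx(0.31)
        assert round(100 * params.adherence_gain, 2) == 19.75

    def test_composite_overrides(self):
        params = ModelParameters(delta_abstinence_override=0.21, adherence_gain_override=0.1475)
        assert params.delta_abstinence == 0.21
        assert params.adherence_gain == 0.1475

    def test_fraction_bounds_validated(self):
        with pytest.raises(InvalidParameterError):
            ModelParameters(p_abst_cbt=1.2)
        with pytest.raises(InvalidParameterError):
            ModelParameters(monthly_min_wage=-1.0)


class TestParameterSpec:
    def test_base_must_lie_in_range(self):
        with pytest.raises(InvalidParameterError):
            ParameterSpec("x", base=0.5, low=0.6, high=0.9)

    def test_normal_ci_requires_se(self):
        with pytest.raises(InvalidParameterError):
            ParameterSpec("x", base=0.5, low=0.1, high=0.9, distribution="normal_ci")

    def test_unknown_distribution_rejected(self):
        with pytest.raises(InvalidParameterError):
            ParameterSpec("x", base=0.5, low=0.1, high=0.9, distribution="triangular")
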