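"""Cost ledgers, rollout schedule, program cost stream and unit cost."""

import random

import pytest

from cbtroi import (
    CostLineItem,
    InvalidParameterError,
    RolloutSchedule,
    base_economic_context,
    cost_stream,
    scale_line_items,
    sum_ledger,
    unit_cost,
)
from cbtroi.costing import InconsistentLineItemError


@pytest.fixture(scope="module")
def ctx():
    return base_economic_context()


class TestLedgerFixtures:
    def test_training_grand_totals(self, cfg):
        assert cfg.training.grand_total_kes == pytest.approx(4_369_168)
        assert round(cfg.training.grand_total_usd) == 51_688

    def test_site_grand_totals(self, cfg):
        assert cfg.per_site.grand_total_kes == pytest.approx(752_555)
        assert round(cfg.per_site.grand_total_usd) == 8_903

    @pytest.mark.parametrize(
        "category, usd",
        [
            ("Counselor consultants", 10_146),
            ("Psychiatry", 9_701),
            ("Per diems", 16_893),
            ("Training materials", 1_739),
            ("Conference center", 6_878),
            ("Furniture", 4_912),
            ("Equipment", 1_419),
        ],
    )
    def test_training_category_subtotals(self, cfg, category, usd):
        assert round(cfg.training.category_subtotals[category] / cfg.ctx.exchange_rate) == usd

    @pytest.mark.parametrize(
        "category, usd",
        [("Personnel", 6_089), ("Supplies", 542), ("Participant payments", 2_271)],
    )
    def test_site_category_subtotals(self, cfg, category, usd):
        assert round(cfg.per_site.category_subtotals[category] / cfg.ctx.exchange_rate) == usd


class TestSumLedger:
    def test_single_item(self, ctx):
        ledger = sum_ledger([CostLineItem("pens", "supplies", "packet", 2, 500)], ctx)
        assert ledger.grand_total_kes == 1_000
        assert ledger.grand_total_usd == pytest.approx(1_000 / 84.53)

    def test_permutation_invariance(self, cfg, ctx):
        items = list(cfg.training.items)
        random.Random(7).shuffle(items)
        shuffled = sum_ledger(items, ctx)
        assert shuffled.grand_total_kes == pytest.approx(cfg.training.grand_total_kes)
        assert shuffled.category_subtotals == pytest.approx(cfg.training.category_subtotals)

    def test_inconsistent_stated_total_rejected(self):
        with pytest.raises(InconsistentLineItemError):
            CostLineItem("pens", "supplies", "packet", 2, 500, total_kes=1_100)

    def test_empty_ledger_rejected(self, ctx):
        with pytest.raises(InvalidParameterError):
            sum_ledger([], ctx)


class TestRolloutSchedule:
    def test_base_schedule_totals(self, cfg):
        assert cfg.sched.cohort_sizes == (1_920, 2_880, 2_880, 2_880, 2_880)
        assert cfg.sched.total_participants == 13_440

    def test_doubling_enrollment_halves_unit_cost(self, cfg):
        doubled = RolloutSchedule(
            participants_per_site_by_year=tuple(
                2 * p for p in cfg.sched.participants_per_site_by_year
            )
        )
        assert doubled.total_participants == 2 * cfg.sched.total_participants
        assert unit_cost(1_000_000, doubled) == pytest.approx(
            unit_cost(1_000_000, cfg.sched) / 2
        )


class TestCostStream:
    def test_year_one_includes_training(self, cfg):
        stream = cost_stream(cfg.training, cfg.per_site, cfg.sched)
        assert stream.amounts[0] == pytest.approx(158_524, abs=5)

    def test_recurring_years(self, cfg):
        stream = cost_stream(cfg.training, cfg.per_site, cfg.sched)
        assert len(stream.amounts) == 5
        for amount in stream.amounts[1:]:
            assert amount == pytest.approx(12 * 8_903, abs=5)

    def test_zero_sites_leaves_training_only(self, cfg):
        sched = RolloutSchedule(n_sites=0)
        stream = cost_stream(cfg.training, cfg.per_site, sched)
        assert stream.amounts[0] == pytest.approx(cfg.training.grand_total_usd)
        assert sum(stream.amounts[1:]) == 0


class TestUnitCost:
    def test_undiscounted_rounds_to_44(self, cfg):
        total = cost_stream(cfg.training, cfg.per_site, cfg.sched).total
        assert total == pytest.approx(585_857, abs=5)
        assert round(unit_cost(total, cfg.sched)) == 44

    def test_discounted_variant(self, base_result):
        assert base_result.unit_cost_disc == pytest.approx(41.3, abs=0.1)

    def test_zero_cost(self, cfg):
        assert unit_cost(0.0, cfg.sched) == 0.0

    def test_zero_participants_guarded(self):
        with pytest.raises(InvalidParameterError):
            unit_cost(100.0, RolloutSchedule(participants_per_site_by_year=(0,)))


class TestScaleLineItems:
    def test_transport_line_scales_proportionally(self, cfg, ctx):
        scaled = scale_line_items(cfg.per_site, "participant payments", 2.5, ctx)
        assert scaled.category_subtotals["Participant payments"] == pytest.approx(
            2.5 * cfg.per_site.category_subtotals["Participant payments"]
        )
        assert scaled.category_subtotals["Supplies"] == pytest.approx(
            cfg.per_site.category_subtotals["Supplies"]
        )

    def test_empty_needle_scales_everything(self, cfg, ctx):
        scaled = scale_line_items(cfg.training, "", 0.5, ctx)
        assert scaled.grand_total_kes == pytest.approx(0.5 * cfg.training.grand_total_kes)
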