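"""Stay-ratio capacity model and ratio-adjusted costs."""

import numpy as np
import pytest
from hypothesis import given
from hypothesis import strategies as st

import endocost as ec
from endocost.scale_model import ScaleScenario, UndefinedRatioError, results_to_frame


def _records_with_stays(stays, arm="LPS"):
    return [
        ec.PatientRecord(arm=arm, theatre_minutes=100, stay_days=d, consumables_cost=0)
        for d in stays
    ]


class TestStayRatio:
    def test_mean_stay_1p7_gives_0p59(self):
        # 10 surgeries over 17 admission days: 1/1.7 = 0.588 -> 0.59
        ratio = ec.stay_ratio(_records_with_stays([1, 1, 1, 1, 1, 1, 2, 2, 3, 4]))
        assert ratio.value == 0.59
        assert ratio.raw == pytest.approx(10 / 17)
        assert ratio.source == "computed_from_records"

    def test_all_one_day_stays_give_perfect_ratio(self):
        assert ec.stay_ratio(_records_with_stays([1] * 12)).value == 1.0

    def test_four_surgeries_ten_days(self):
        assert ec.stay_ratio(_records_with_stays([2, 3, 4, 1])).value == 0.40

    def test_order_invariance(self):
        stays = [1, 2, 1, 3, 1, 1, 4]
        a = ec.stay_ratio(_records_with_stays(stays))
        b = ec.stay_ratio(_records_with_stays(stays[::-1]))
        assert a == b

    def test_zero_total_days_is_undefined(self):
        with pytest.raises(UndefinedRatioError):
            ec.stay_ratio(_records_with_stays([0, 0]))

    @given(st.lists(st.integers(1, 30), min_size=1, max_size=50))
    def test_ratio_bounded_by_one_for_stays_of_at_least_a_day(self, stays):
        assert 0 < ec.stay_ratio(_records_with_stays(stays)).value <= 1


class TestCapacity:
    @pytest.mark.parametrize(
        "value, k, annual, total",
        [(0.59, 1, 177, 1770), (0.88, 1, 264, 2640), (1.0, 3, 900, 9000)],
    )
    def test_published_capacity_examples(self, value, k, annual, total):
        ratio = ec.StayRatio(value, "reported_override")
        scenario = ScaleScenario(procedures_per_session=k)
        assert ec.capacity(ratio, scenario) == (annual, total)

    @given(
        st.floats(0.01, 1.0),
        st.integers(1, 5),
        st.integers(1, 400),
        st.integers(1, 20),
    )
    def test_total_is_annual_times_years_and_scales_in_k(self, value, k, s, y):
        ratio = ec.StayRatio(round(value, 2), "reported_override")
        annual, total = ec.capacity(ratio, ScaleScenario(k, s, y))
        assert total == annual * y
        annual2, _ = ec.capacity(ratio, ScaleScenario(2 * k, s, y))
        assert annual2 == pytest.approx(2 * annual, abs=1)  # rounding slack


class TestRatioAdjustedCost:
    def test_reference_model1_costs(self, ref_summaries, lps_spec, rbt_spec):
        lps = ec.ratio_adjusted_cost(ref_summaries[ec.Arm.LPS], lps_spec, 1770)
        rbt = ec.ratio_adjusted_cost(ref_summaries[ec.Arm.RBT], rbt_spec, 2640)
        assert lps == pytest.approx(2356 + 1047 + 1153 + 140_000 / 1770)
        assert rbt == pytest.approx(2227 + 2057 + 768 + 2_000_000 / 2640)

    def test_infinite_capacity_asymptote(self, ref_summaries, rbt_spec):
        s = ref_summaries[ec.Arm.RBT]
        cost = ec.ratio_adjusted_cost(s, rbt_spec, 10**12)
        assert cost == pytest.approx(2227 + 2057 + 768, abs=1e-2)

    def test_fixed_one_day_policy_uses_the_daily_rate(self, ref_summaries, rbt_spec):
        s = ref_summaries[ec.Arm.RBT]
        cost = ec.ratio_adjusted_cost(
            s, rbt_spec, 2640, stay_policy="fixed_one_day", stay_rate=681.0
        )
        assert cost == pytest.approx(2227 + 2057 + 681 + 2_000_000 / 2640)

    def test_cost_strictly_decreases_with_capacity(self, ref_summaries, rbt_spec):
        s = ref_summaries[ec.Arm.RBT]
        costs = [ec.ratio_adjusted_cost(s, rbt_spec, c) for c in (1000, 2000, 5000)]
        assert costs[0] > costs[1] > costs[2]

    def test_brute_force_per_patient_oracle(self, rates, rbt_spec, small_cohort):
        """Summary-level adjusted cost equals the mean of per-patient totals
        recomputed with equipment share = price / capacity."""
        rbt = [r for r in small_cohort if r.arm == ec.Arm.RBT]
        summary = ec.summarize_arm(rbt, rates, rbt_spec)
        capacity = 5280
        adjusted = ec.ratio_adjusted_cost(summary, rbt_spec, capacity)
        per_patient = [
            ec.theatre_cost(r.theatre_minutes, rates)
            + r.consumables_cost
            + ec.stay_cost(r.stay_days, rates)
            + rbt_spec.purchase_price / capacity
            for r in rbt
        ]
        assert adjusted == pytest.approx(np.mean(per_patient))


class TestCompareModels:
    def test_published_three_model_table(
        self, ref_summaries, ref_ratios, lps_spec, rbt_spec
    ):
        results = ec.compare_models(
            ref_summaries[ec.Arm.LPS],
            ref_summaries[ec.Arm.RBT],
            lps_spec,
            rbt_spec,
            ref_ratios[ec.Arm.LPS],
            ref_ratios[ec.Arm.RBT],
        )
        m1, m2, m3 = results
        assert (m1.lps_total_capacity, m1.rbt_total_capacity) == (1770, 2640)
        assert (m2.lps_total_capacity, m2.rbt_total_capacity) == (3540, 5280)
        assert (m3.lps_total_capacity, m3.rbt_total_capacity) == (5310, 7920)
        assert m2.rbt_adjusted_cost == pytest.approx(5430.79, abs=0.01)
        assert m2.overrun == pytest.approx(835.24, abs=0.01)
        assert m2.overrun_pct == pytest.approx(15.4, abs=0.05)
        assert m3.overrun == pytest.approx(722.16, abs=0.01)
        assert m3.overrun_pct == pytest.approx(13.6, abs=0.05)
        assert m1.capacity_increase_annual == 87
        assert m3.capacity_increase_total == 2610
        # overrun shrinks as equipment dilution grows
        assert m1.overrun > m2.overrun > m3.overrun

    def test_identical_arms_have_zero_overrun(self, lps_spec):
        kwargs = dict(
            theatre=(2000, 100),
            consumables=(1000, 50),
            equipment=(140, 0),
            stay=(681, 100),
        )
        lps = ec.ArmCostSummary.from_moments("LPS", 10, **kwargs)
        rbt = ec.ArmCostSummary.from_moments("RBT", 10, **kwargs)
        ratio = ec.StayRatio(0.8, "reported_override")
        (res,) = ec.compare_models(
            lps, rbt, lps_spec, lps_spec, ratio, ratio, [ScaleScenario(1)]
        )
        assert res.overrun == 0
        assert res.overrun_pct == 0
        assert res.capacity_increase_total == 0

    def test_mismatched_arm_order_rejected(self, ref_summaries, ref_ratios, lps_spec):
        with pytest.raises(ec.InvalidInputError):
            ec.compare_models(
                ref_summaries[ec.Arm.RBT],
                ref_summaries[ec.Arm.LPS],
                lps_spec,
                lps_spec,
                ref_ratios[ec.Arm.RBT],
                ref_ratios[ec.Arm.LPS],
            )

    def test_results_frame_layout(self, ref_summaries, ref_ratios, lps_spec, rbt_spec):
        results = ec.compare_models(
            ref_summaries[ec.Arm.LPS],
            ref_summaries[ec.Arm.RBT],
            lps_spec,
            rbt_spec,
            ref_ratios[ec.Arm.LPS],
            ref_ratios[ec.Arm.RBT],
        )
        frame = results_to_frame(results)
        assert len(frame) == 6  # 3 models × 2 arms
        assert set(frame["arm"]) == {"LPS", "RBT"}
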