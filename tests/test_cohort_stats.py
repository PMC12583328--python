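"""Two-arm test routing, exact tests and perfect-separation detection."""

import math

import numpy as np
import pytest
from scipy.special import gammaln

import endocost as ec
from endocost.cohort_stats import compare_arms


class TestContinuousRouting:
    def test_normal_samples_route_to_student_t(self):
        rng = np.random.default_rng(3)
        res = ec.compare_continuous(
            rng.normal(10, 2, 60), rng.normal(11, 2, 60), variable="x"
        )
        assert res.test_used == "student_t"
        assert 0 <= res.p_value <= 1

    def test_heavily_skewed_samples_route_to_rank_test(self):
        rng = np.random.default_rng(5)
        x = rng.lognormal(0, 1.5, 200)
        y = rng.lognormal(0.5, 1.5, 200)
        res = ec.compare_continuous(x, y)
        assert res.test_used == "wilcoxon"

    def test_identical_non_normal_samples_give_p_one(self):
        x = np.repeat([1.0, 2.0, 50.0], [10, 10, 3])  # strongly non-normal
        res = ec.compare_continuous(x, x.copy())
        assert res.test_used == "wilcoxon"
        assert res.p_value == pytest.approx(1.0, abs=1e-9)
        assert res.group_summaries["A"]["mean"] == res.group_summaries["B"]["mean"]

    def test_constant_sample_is_flagged_degenerate_and_ranked(self):
        res = ec.compare_continuous([5.0] * 10, [1.0, 2.0, 3.0, 4.0, 5.0])
        assert res.degenerate
        assert res.test_used == "wilcoxon"

    def test_pooled_t_statistic_matches_hand_formula(self):
        """Pooled-variance t on a small worked pair: t = (x̄−ȳ)/(s_p·√(1/n+1/m))."""
        x = np.array([1.0, 2.0, 3.0, 4.0, 5.0])
        y = np.array([2.0, 4.0, 4.0, 5.0, 7.0])
        res = ec.compare_continuous(x, y)
        sp2 = ((len(x) - 1) * x.var(ddof=1) + (len(y) - 1) * y.var(ddof=1)) / (
            len(x) + len(y) - 2
        )
        t_hand = (x.mean() - y.mean()) / math.sqrt(sp2 * (1 / len(x) + 1 / len(y)))
        assert res.test_used == "student_t"
        assert res.statistic == pytest.approx(t_hand)

    def test_label_swap_preserves_p_value(self):
        rng = np.random.default_rng(9)
        x, y = rng.normal(0, 1, 40), rng.normal(0.7, 1, 40)
        a = ec.compare_continuous(x, y)
        b = ec.compare_continuous(y, x)
        assert a.p_value == pytest.approx(b.p_value)
        assert a.statistic == pytest.approx(-b.statistic)

    def test_tiny_arms_rejected(self):
        with pytest.raises(ec.InvalidInputError):
            ec.compare_continuous([1, 2], [1, 2, 3])


def _exact_fisher_2x2(table):
    """Enumeration oracle: sum of hypergeometric probabilities of all tables
    with the observed margins no more probable than the observed one."""
    table = np.asarray(table)
    r1, r2 = table.sum(axis=1)
    c1, c2 = table.sum(axis=0)
    n = table.sum()

    def prob(a):
        cells = np.array([[a, r1 - a], [c1 - a, r2 - (c1 - a)]])
        if (cells < 0).any():
            return 0.0
        return math.exp(
            gammaln(r1 + 1) + gammaln(r2 + 1) + gammaln(c1 + 1) + gammaln(c2 + 1)
            - gammaln(n + 1) - gammaln(cells + 1).sum()
        )

    p_obs = prob(table[0, 0])
    return sum(
        p for a in range(0, min(r1, c1) + 1) if (p := prob(a)) <= p_obs * (1 + 1e-9)
    )


class TestCategorical:
    def test_balanced_table_gives_zero_chi_square(self):
        res = ec.compare_categorical([[10, 10], [10, 10]])
        assert res.test_used == "chi_square"
        assert res.statistic == pytest.approx(0.0)
        assert res.p_value == pytest.approx(1.0)

    def test_small_expected_counts_route_to_fisher(self):
        res = ec.compare_categorical([[1, 0], [0, 2]])
        assert res.test_used == "fisher"

    @pytest.mark.parametrize(
        "table", [[[1, 4], [3, 2]], [[2, 0], [0, 3]], [[1, 6], [7, 2]], [[0, 5], [5, 0]]]
    )
    def test_fisher_2x2_matches_enumeration_oracle(self, table):
        res = ec.compare_categorical(table)
        assert res.test_used == "fisher"
        assert res.p_value == pytest.approx(_exact_fisher_2x2(table), abs=1e-10)

    def test_simulated_fisher_2x3_matches_enumeration(self):
        """The Monte-Carlo r×C Fisher agrees with full enumeration of all
        2×3 tables with the observed margins (within simulation error)."""
        table = np.array([[1, 2, 0], [2, 0, 3]])
        r1, r2 = table.sum(axis=1)
        cols = table.sum(axis=0)
        n = table.sum()

        def prob(t):
            return math.exp(
                gammaln(r1 + 1) + gammaln(r2 + 1) + gammaln(cols + 1).sum()
                - gammaln(n + 1) - gammaln(np.asarray(t) + 1).sum()
            )

        p_obs = prob(table)
        p_exact = 0.0
        for a in range(cols[0] + 1):
            for b in range(cols[1] + 1):
                c = r1 - a - b
                if 0 <= c <= cols[2]:
                    t = [[a, b, c], [cols[0] - a, cols[1] - b, cols[2] - c]]
                    p = prob(t)
                    if p <= p_obs * (1 + 1e-9):
                        p_exact += p
        res = ec.compare_categorical(table, n_simulations=20_000, seed=1)
        assert res.test_used == "fisher"
        assert res.p_value == pytest.approx(p_exact, abs=0.03)

    def test_chi_square_and_fisher_agree_on_large_balanced_tables(self):
        table = [[60, 40], [42, 58]]
        chi = ec.compare_categorical(table)
        from scipy.stats import fisher_exact

        assert chi.test_used == "chi_square"
        assert abs(chi.p_value - fisher_exact(table)[1]) < 0.02

    def test_invalid_tables_rejected(self):
        with pytest.raises(ec.InvalidInputError):
            ec.compare_categorical([[0, 0], [1, 2]])
        with pytest.raises(ec.InvalidInputError):
            ec.compare_categorical([[1, -2], [1, 2]])
        with pytest.raises(ec.InvalidInputError):
            ec.compare_categorical([[1, 2, 3]])


class TestSeparation:
    def test_disjoint_classes_are_separated_at_the_midpoint(self):
        res = ec.detect_perfect_separation([0, 0, 0, 1, 1], [1, 2, 3, 10, 11])
        assert res.separated
        assert res.threshold == 6.5

    def test_interleaved_values_are_not_separated(self):
        res = ec.detect_perfect_separation([0, 1, 0, 1], [1, 2, 3, 4])
        assert not res.separated
        assert res.threshold is None

    def test_invariant_under_strictly_monotone_transforms(self):
        outcome = [0, 0, 1, 1, 1]
        predictor = np.array([3.0, 5.0, 8.0, 9.0, 20.0])
        base = ec.detect_perfect_separation(outcome, predictor)
        for f in (np.log, np.sqrt, lambda v: 3 * v - 7):
            assert ec.detect_perfect_separation(outcome, f(predictor)).separated == base.separated

    def test_single_class_rejected(self):
        with pytest.raises(ec.InvalidInputError):
            ec.detect_perfect_separation([1, 1, 1], [1.0, 2.0, 3.0])

    def test_detector_agrees_with_range_overlap_oracle_on_synthetic_costs(self):
        """Across seeded synthetic cohorts, the detector matches a brute-force
        range-overlap check on per-procedure total costs."""
        params = ec.default_params()
        for seed in range(20):
            records = ec.generate_cohort(ec.default_config(seed=seed))
            totals, labels = [], []
            for r in records:
                arm = r.arm
                totals.append(
                    ec.procedure_cost(r, params.rates, params.equipment[arm]).total
                )
                labels.append(int(arm == ec.Arm.RBT))
            totals = np.array(totals)
            labels = np.array(labels)
            lo, hi = totals[labels == 0], totals[labels == 1]
            oracle = lo.max() < hi.min() or hi.max() < lo.min()
            assert ec.detect_perfect_separation(labels, totals).separated == oracle


def test_compare_arms_mirrors_cohort_table_layout(small_cohort):
    from endocost.cost_core import records_to_frame

    results = compare_arms(records_to_frame(small_cohort))
    variables = {r.variable for r in results}
    assert {"age", "bmi", "theatre_minutes", "stay_days", "consumables_cost"} <= variables
    assert "complexity_group" in variables
    for r in results:
        assert 0 <= r.p_value <= 1
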