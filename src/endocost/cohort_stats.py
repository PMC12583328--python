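"""Univariate two-arm comparison with explicit test routing.

Continuous variables pass through a normality gate — a one-sample
Kolmogorov–Smirnov test of each arm against a normal with the arm's sample
mean and SD — and are compared with a pooled-variance Student's t test when
both arms pass, otherwise with the two-sample Wilcoxon rank-sum test.
Categorical variables use the chi-square test without continuity correction,
falling back to Fisher's exact test when any expected cell count is below
five (exact for 2×2; Monte-Carlo over fixed-margin tables for wider tables).

Notes on the routing choices:

* The KS gate with estimated parameters is anti-conservative (the classical
  Lilliefors caveat); its alpha is configurable and the routing is reported
  alongside the p-value so it can be audited.
* "Wilcoxon" here is the two-sample rank-sum (Mann–Whitney) test — the arms
  are independent, so the paired signed-rank variant does not apply. Exact
  p-values for small tie-free samples, normal approximation with tie
  correction otherwise.
* Logistic-regression fitting is deliberately not part of this module. What
  matters for a cost predictor in such a regression is *perfect separation*
  — arm-wise predictor ranges that do not overlap make the maximum
  likelihood non-identifiable — and :func:`detect_perfect_separation` checks
  exactly that.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Literal, Mapping, Sequence

import numpy as np
import pandas as pd
from scipy import stats
from scipy.special import gammaln

from .cost_core import InvalidInputError

__all__ = [
    "ComparisonResult",
    "SeparationResult",
    "compare_continuous",
    "compare_categorical",
    "detect_perfect_separation",
    "compare_arms",
]

TestName = Literal["student_t", "wilcoxon", "chi_square", "fisher"]


@dataclass(frozen=True)
class ComparisonResult:
    """Outcome of one univariate arm comparison."""

    variable: str
    test_used: TestName
    statistic: float
    p_value: float
    group_summaries: Mapping[str, Mapping[str, float]] = field(default_factory=dict)
    degenerate: bool = False

    def __post_init__(self) -> None:
        if not (0 <= self.p_value <= 1 or np.isnan(self.p_value)):
            raise InvalidInputError(f"p_value out of [0, 1]: {self.p_value}")


@dataclass(frozen=True)
class SeparationResult:
    """Perfect-separation check: separated flag plus a midpoint threshold."""

    separated: bool
    threshold: float | None = None


def _normal_ks_pvalue(x: np.ndarray) -> float:
    """KS p-value of x against Normal(sample mean, sample SD)."""
    sd = x.std(ddof=1)
    if sd == 0:
        return 0.0  # constant sample: treat as failing the gate
    return float(stats.kstest(x, "norm", args=(x.mean(), sd)).pvalue)


def compare_continuous(
    x: Sequence[float],
    y: Sequence[float],
    alpha: float = 0.05,
    variable: str = "",
    welch: bool = False,
) -> ComparisonResult:
    """Compare a continuous variable between two independent arms.

    Both arms must pass the KS normality gate at ``alpha`` to use the
    Student's t test (pooled variance by default; ``welch=True`` drops the
    equal-variance assumption); otherwise the Wilcoxon rank-sum test is
    used. Arms with fewer than 3 observations are rejected. Constant
    (all-identical) samples are flagged degenerate and routed to the rank
    test.
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if len(x) < 3 or len(y) < 3:
        raise InvalidInputError("each arm needs at least 3 observations")

    summaries = {
        "A": {"n": len(x), "mean": float(x.mean()), "sd": float(x.std(ddof=1))},
        "B": {"n": len(y), "mean": float(y.mean()), "sd": float(y.std(ddof=1))},
    }
    degenerate = x.std() == 0 or y.std() == 0
    normal = (
        not degenerate
        and _normal_ks_pvalue(x) > alpha
        and _normal_ks_pvalue(y) > alpha
    )
    if normal:
        res = stats.ttest_ind(x, y, equal_var=not welch)
        test: TestName = "student_t"
    else:
        if np.array_equal(np.sort(x), np.sort(y)):
            # identical samples: U is exactly its null mean, p = 1
            res = stats.mannwhitneyu(x, y, alternative="two-sided", method="asymptotic")
        else:
            res = stats.mannwhitneyu(x, y, alternative="two-sided", method="auto")
        test = "wilcoxon"
    return ComparisonResult(
        variable=variable,
        test_used=test,
        statistic=float(res.statistic),
        p_value=float(res.pvalue),
        group_summaries=summaries,
        degenerate=bool(degenerate),
    )


def _log_table_prob(table: np.ndarray) -> float:
    """Log-probability of a contingency table under the fixed-margin null."""
    n = table.sum()
    return float(
        gammaln(table.sum(axis=1) + 1).sum()
        + gammaln(table.sum(axis=0) + 1).sum()
        - gammaln(n + 1)
        - gammaln(table + 1).sum()
    )


def _simulated_fisher(
    table: np.ndarray, n_simulations: int, rng: np.random.Generator
) -> float:
    """Monte-Carlo Fisher p for an r×C table: share of fixed-margin tables
    at most as probable as the observed one (add-one convention)."""
    dist = stats.random_table(table.sum(axis=1), table.sum(axis=0))
    sims = dist.rvs(n_simulations, random_state=rng)
    obs = _log_table_prob(table)
    hits = sum(_log_table_prob(np.asarray(s)) <= obs + 1e-9 for s in sims)
    return (1 + hits) / (n_simulations + 1)


def compare_categorical(
    table: Sequence[Sequence[int]] | np.ndarray,
    variable: str = "",
    n_simulations: int = 10_000,
    seed: int | None = 0,
) -> ComparisonResult:
    """Compare a categorical variable between arms from a 2×C count table.

    Chi-square without continuity correction unless any expected cell count
    is below five, in which case Fisher's exact test is used (exact for 2×2,
    Monte-Carlo over fixed-margin tables otherwise; ``seed`` controls the
    simulation stream).
    """
    table = np.asarray(table)
    if table.ndim != 2 or table.shape[0] != 2 or table.shape[1] < 2:
        raise InvalidInputError(f"need a 2×C table with C >= 2, got {table.shape}")
    if np.any(table < 0) or not np.issubdtype(table.dtype, np.integer):
        raise InvalidInputError("counts must be non-negative integers")
    if np.any(table.sum(axis=1) == 0) or np.any(table.sum(axis=0) == 0):
        raise InvalidInputError("every row and column margin must be positive")

    expected = stats.contingency.expected_freq(table)
    counts = {
        "A": {str(j): int(c) for j, c in enumerate(table[0])},
        "B": {str(j): int(c) for j, c in enumerate(table[1])},
    }
    if np.all(expected >= 5):
        chi2 = stats.chi2_contingency(table, correction=False)
        return ComparisonResult(
            variable=variable,
            test_used="chi_square",
            statistic=float(chi2.statistic),
            p_value=float(chi2.pvalue),
            group_summaries=counts,
        )
    if table.shape == (2, 2):
        odds, p = stats.fisher_exact(table)
        statistic = float(odds)
    else:
        rng = np.random.default_rng(seed)
        p = _simulated_fisher(table, n_simulations, rng)
        statistic = float("nan")
    return ComparisonResult(
        variable=variable,
        test_used="fisher",
        statistic=statistic,
        p_value=float(p),
        group_summaries=counts,
    )


def detect_perfect_separation(
    outcome: Sequence[int] | np.ndarray, predictor: Sequence[float] | np.ndarray
) -> SeparationResult:
    """Check whether a predictor perfectly separates a binary outcome.

    True iff the predictor ranges of the two classes do not overlap
    (max of one class strictly below the min of the other); the returned
    threshold is the midpoint of the gap. Invariant under strictly monotone
    transforms of the predictor. A predictor with this property makes
    logistic-regression maximum likelihood diverge, so such variables must
    be excluded from (or penalized in) a multivariate model.
    """
    outcome = np.asarray(outcome)
    predictor = np.asarray(predictor, dtype=float)
    if outcome.shape != predictor.shape:
        raise InvalidInputError("outcome and predictor lengths differ")
    classes = np.unique(outcome)
    if len(classes) != 2:
        raise InvalidInputError(f"need exactly 2 outcome classes, got {len(classes)}")
    a = predictor[outcome == classes[0]]
    b = predictor[outcome == classes[1]]
    if a.max() < b.min():
        return SeparationResult(True, float((a.max() + b.min()) / 2))
    if b.max() < a.min():
        return SeparationResult(True, float((b.max() + a.min()) / 2))
    return SeparationResult(False, None)


CONTINUOUS_VARIABLES = ("age", "bmi", "theatre_minutes", "stay_days", "consumables_cost")
CATEGORICAL_VARIABLES = ("complexity_group", "complication_flag")


def compare_arms(frame: pd.DataFrame, alpha: float = 0.05) -> list[ComparisonResult]:
    """Per-variable arm comparison over a standard cohort table.

    Continuous variables route through :func:`compare_continuous`,
    categorical ones through :func:`compare_categorical`; the result list
    mirrors the layout of a univariate clinical/economic comparison table.
    """
    arms = sorted(frame["arm"].unique())
    if len(arms) != 2:
        raise InvalidInputError(f"cohort must contain exactly 2 arms, got {arms}")
    a = frame[frame["arm"] == arms[0]]
    b = frame[frame["arm"] == arms[1]]
    results = []
    for var in CONTINUOUS_VARIABLES:
        if var not in frame.columns or frame[var].isna().all():
            continue
        results.append(
            compare_continuous(a[var].dropna(), b[var].dropna(), alpha, variable=var)
        )
    for var in CATEGORICAL_VARIABLES:
        if var not in frame.columns:
            continue
        levels = sorted(frame[var].unique())
        if len(levels) < 2:
            continue
        table = np.array(
            [[int((g[var] == lev).sum()) for lev in levels] for g in (a, b)]
        )
        results.append(compare_categorical(table, variable=var))
    return results
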