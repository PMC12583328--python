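"""Seeded two-arm synthetic cohorts with realistic cost-study structure.

Published cost comparisons report only arm-level moments (mean, SD) and
counts, never patient-level records, so pipeline testing needs a generator
that emulates those moments. Each arm draws, independently across variables:

* theatre minutes, consumables cost, age — normal truncated below at 0
  (rejection sampling; the truncation-induced mean shift is < 1% at the
  default parameter values and is accepted rather than re-centred);
* BMI — normal truncated below at 15 kg/m²;
* hospital stay — 1 + an overdispersed count: admissions last at least one
  day, and the published stay moments sit barely above one day, so the
  excess over one day is moment-matched to a negative binomial (or Poisson
  at the equidispersion boundary; see :func:`moment_match_stay`);
* complexity group — categorical over {A, B, C}; complication — Bernoulli.

The default parameters are the two study arms' published distributions
(n = 75 laparoscopic / 78 robotic; stay 1.7 ± 1.02 vs 1.12 ± 0.46 days,
duration 161 ± 60 vs 152 ± 43 min, consumables €1047 ± 314 vs €2057 ± 216).
Distributional shapes are stand-ins: only the first two moments are
published, so anything beyond mean/SD (skewness, tail weight, cross-variable
correlation) is a modelling choice, not data. Variables are uncorrelated by
default; a rank-correlation hook (Gaussian copula) exists for sensitivity
work. Arms use independent seed substreams, so cohorts are reproducible
per-arm as well as jointly.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
from scipy import stats

from .cost_core import Arm, ConfigurationError, InvalidInputError, PatientRecord

__all__ = [
    "ArmGeneratorParams",
    "CohortSeedConfig",
    "StayDistribution",
    "moment_match_stay",
    "generate_cohort",
    "lps_default_params",
    "rbt_default_params",
    "default_config",
]


@dataclass(frozen=True)
class ArmGeneratorParams:
    """Moment-level description of one arm; all (mean, sd) pairs."""

    n: int
    age: tuple[float, float]
    bmi: tuple[float, float]
    theatre_minutes: tuple[float, float]
    stay_days: tuple[float, float]
    consumables: tuple[float, float]
    complication_prob: float
    complexity_probs: tuple[float, float, float]  # over groups (A, B, C)
    rank_correlation: np.ndarray | None = None  # 3×3 over (theatre, stay, consumables)

    def __post_init__(self) -> None:
        if self.n < 1:
            raise ConfigurationError(f"n must be >= 1, got {self.n}")
        for name in ("age", "bmi", "theatre_minutes", "stay_days", "consumables"):
            mean, sd = getattr(self, name)
            if sd < 0:
                raise ConfigurationError(f"{name} sd must be >= 0, got {sd}")
        if not 0 <= self.complication_prob <= 1:
            raise ConfigurationError("complication_prob must be in [0, 1]")
        if abs(sum(self.complexity_probs) - 1) > 1e-9 or any(
            p < 0 for p in self.complexity_probs
        ):
            raise ConfigurationError("complexity_probs must be a simplex over A/B/C")
        if self.rank_correlation is not None:
            corr = np.asarray(self.rank_correlation, dtype=float)
            if corr.shape != (3, 3) or not np.allclose(corr, corr.T):
                raise ConfigurationError("rank_correlation must be symmetric 3×3")
            object.__setattr__(self, "rank_correlation", corr)


def lps_default_params() -> ArmGeneratorParams:
    """Laparoscopic arm defaults (study-arm moments, n = 75)."""
    return ArmGeneratorParams(
        n=75,
        age=(65.1, 10.5),
        bmi=(29.1, 5.6),
        theatre_minutes=(161.0, 60.0),
        stay_days=(1.7, 1.02),
        consumables=(1047.0, 314.0),
        complication_prob=4 / 75,
        complexity_probs=(14 / 75, 46 / 75, 15 / 75),
    )


def rbt_default_params() -> ArmGeneratorParams:
    """Robotic arm defaults (study-arm moments, n = 78)."""
    return ArmGeneratorParams(
        n=78,
        age=(65.4, 11.9),
        bmi=(30.5, 7.4),
        theatre_minutes=(152.0, 43.0),
        stay_days=(1.12, 0.46),
        consumables=(2057.0, 216.0),
        complication_prob=3 / 78,
        complexity_probs=(13 / 78, 52 / 78, 13 / 78),
    )


@dataclass(frozen=True)
class CohortSeedConfig:
    """Two arm parameter sets plus the master seed."""

    lps: ArmGeneratorParams = field(default_factory=lps_default_params)
    rbt: ArmGeneratorParams = field(default_factory=rbt_default_params)
    seed: int = 0


@dataclass(frozen=True)
class StayDistribution:
    """Moment-matched distribution of hospital stay (days, integer ≥ 1).

    Stay = 1 + count, where the count is negative binomial when the excess
    variance allows (sd² > mean − 1), Poisson at equidispersion, or
    degenerate at zero variance. ``kind`` ∈ {negative_binomial, poisson,
    degenerate}; ``params`` hold (r, p) for the NB (numpy convention:
    mean r(1−p)/p) or mu for the Poisson.
    """

    kind: str
    params: dict[str, float]

    def sample(self, rng: np.random.Generator, size: int) -> np.ndarray:
        if self.kind == "negative_binomial":
            counts = rng.negative_binomial(self.params["r"], self.params["p"], size)
        elif self.kind == "poisson":
            counts = rng.poisson(self.params["mu"], size)
        else:
            counts = np.zeros(size, dtype=int)
        return 1 + counts

    def ppf(self, q: np.ndarray) -> np.ndarray:
        if self.kind == "negative_binomial":
            return 1 + stats.nbinom.ppf(q, self.params["r"], self.params["p"])
        if self.kind == "poisson":
            return 1 + stats.poisson.ppf(q, self.params["mu"])
        return np.ones_like(q)


def moment_match_stay(mean: float, sd: float) -> StayDistribution:
    """Match a 1 + count distribution to published stay moments.

    The shifted mean is μ = mean − 1 and target variance σ² = sd². With
    σ² > μ the negative binomial r = μ²/(σ² − μ), p = r/(r + μ) matches both
    moments exactly; σ² = μ is the Poisson boundary; σ² < μ is infeasible
    for any mixed-Poisson count, so the Poisson(μ) variance floor is used
    and a warning reports the variance actually delivered.
    """
    if mean < 1:
        raise ConfigurationError(f"mean stay must be >= 1 day, got {mean}")
    mu = mean - 1.0
    var = sd * sd
    if mu == 0:
        if var > 0:
            warnings.warn(
                "mean stay of exactly 1 day forces zero variance; "
                f"requested sd={sd} ignored",
                stacklevel=2,
            )
        return StayDistribution("degenerate", {})
    if var > mu * (1 + 1e-12):
        r = mu * mu / (var - mu)
        return StayDistribution("negative_binomial", {"r": r, "p": r / (r + mu)})
    if var < mu * (1 - 1e-12):
        warnings.warn(
            f"stay sd²={var:.4g} below the Poisson floor (mean−1={mu:.4g}); "
            "falling back to Poisson with higher variance",
            stacklevel=2,
        )
    return StayDistribution("poisson", {"mu": mu})


_MAX_REJECTION_ROUNDS = 1000


def _truncated_normal(
    rng: np.random.Generator, mean: float, sd: float, lower: float, size: int
) -> np.ndarray:
    """Normal(mean, sd) conditioned on > lower, by rejection sampling."""
    if sd == 0:
        if mean <= lower:
            raise ConfigurationError(
                f"degenerate value {mean} at or below truncation bound {lower}"
            )
        return np.full(size, mean)
    out = np.empty(size)
    filled = 0
    for _ in range(_MAX_REJECTION_ROUNDS):
        draws = rng.normal(mean, sd, size=max(size - filled, 16))
        draws = draws[draws > lower]
        take = min(len(draws), size - filled)
        out[filled : filled + take] = draws[:take]
        filled += take
        if filled == size:
            return out
    raise ConfigurationError(
        f"truncated-normal acceptance too low for mean={mean}, sd={sd}, lower={lower}"
    )


def _truncnorm_ppf(q: np.ndarray, mean: float, sd: float, lower: float) -> np.ndarray:
    if sd == 0:
        return np.full_like(q, mean)
    a = (lower - mean) / sd
    return stats.truncnorm.ppf(q, a, np.inf, loc=mean, scale=sd)


def _generate_arm(
    arm: Arm, params: ArmGeneratorParams, rng: np.random.Generator
) -> list[PatientRecord]:
    n = params.n
    stay_dist = moment_match_stay(*params.stay_days)
    if params.rank_correlation is None:
        theatre = _truncated_normal(rng, *params.theatre_minutes, 0.0, n)
        stays = stay_dist.sample(rng, n)
        consumables = _truncated_normal(rng, *params.consumables, 0.0, n)
    else:
        # Gaussian copula over (theatre, stay, consumables) for sensitivity work
        chol = np.linalg.cholesky(params.rank_correlation)
        z = rng.standard_normal((n, 3)) @ chol.T
        u = stats.norm.cdf(z)
        theatre = _truncnorm_ppf(u[:, 0], *params.theatre_minutes, 0.0)
        stays = stay_dist.ppf(u[:, 1])
        consumables = _truncnorm_ppf(u[:, 2], *params.consumables, 0.0)
    age = _truncated_normal(rng, *params.age, 0.0, n)
    bmi = _truncated_normal(rng, *params.bmi, 15.0, n)
    groups = rng.choice(["A", "B", "C"], size=n, p=params.complexity_probs)
    complications = rng.random(n) < params.complication_prob
    return [
        PatientRecord(
            arm=arm,
            theatre_minutes=float(theatre[i]),
            stay_days=int(stays[i]),
            consumables_cost=float(consumables[i]),
            complexity_group=str(groups[i]),
            age=float(age[i]),
            bmi=float(bmi[i]),
            complication_flag=bool(complications[i]),
        )
        for i in range(n)
    ]


def generate_cohort(config: CohortSeedConfig) -> list[PatientRecord]:
    """Generate both arms, laparoscopic records first.

    Deterministic given ``config.seed``; each arm draws from its own seed
    substream, so changing one arm's size leaves the other arm's records
    unchanged.
    """
    lps_ss, rbt_ss = np.random.SeedSequence(config.seed).spawn(2)
    records = _generate_arm(Arm.LPS, config.lps, np.random.default_rng(lps_ss))
    records += _generate_arm(Arm.RBT, config.rbt, np.random.default_rng(rbt_ss))
    return records


def default_config(seed: int = 0) -> CohortSeedConfig:
    """Study-arm defaults with the given seed."""
    return CohortSeedConfig(seed=seed)
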