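# Methods

## The cost model

`endocost` performs a cost-minimization analysis: it assumes the two
approaches are clinically equivalent for early-stage endometrial cancer
(survival, complications) and asks only which is cheaper per procedure and
under what conditions the gap closes. Costs are pre-tax euros with no
inflation adjustment or discounting of future cash flows; equipment is
amortized straight-line.

Each case decomposes into four components:

* **theatre** (indirect): minutes of theatre occupation × rate. The default
  rate, €14.65/min, bundles the facility and a fixed team (2 surgeons,
  3 nurses, 1 anaesthesiologist) plus intra-operative medication, so no
  staff micro-costing exists below it. Minutes include field preparation
  and docking, since occupancy is what is billed.
* **consumables** (direct): per-procedure sum of single-use material plus
  one-use proration of limited-use instruments (unit price / certified
  uses; robotic instruments typically allow 10–18 uses). Proration is an
  ingest-time helper (`per_use_cost`); records store the prorated value.
* **equipment** (direct): purchase price / depreciation procedures.
  Defaults: €140,000 laparoscopic tower, €2,000,000 robotic platform, 1000
  procedures (10 years × 100/year). This component is constant per spec,
  hence SD 0 in arm summaries. Platform maintenance is an optional annual
  add-on defaulting to 0 — no separate figure is needed to reproduce the
  reference tables. Staff training is excluded by construction (procedures
  enter after the learning curve).
* **stay** (indirect): admission days × €681/day.

Totals are exact component sums at full floating precision; euro rounding
(half away from zero) happens only in rendered reports. The reference
cohort's printed laparoscopic total (€4698) exceeds the sum of its printed
component means (€4696) by rounding of unprinted means; this package always
reports its own sums.

## Stay-ratio economy of scale

The ratio ρ = surgeries / total admission days (equivalently 1 / mean
stay) expresses how far an arm is from the one-day-admission ideal; ρ = 1
means every patient left after one day. Capacity under a session plan is
`annual = round(S·k·ρ)`, `total = annual·Y` with S = 300 sessions/year
(holidays excluded), Y = 10 years, k ∈ {1, 2, 3} procedures per session.
ρ enters capacity rounded to 2 decimals — the convention that makes
300 × 0.59 = 177 rather than 176.5 — with full precision retained in
`StayRatio.raw`. Reported ratios can be injected as `reported_override`
(the reference robotic ratio 0.88 is slightly below 1/1.12 ≈ 0.89 from the
printed mean stay; reproduction keeps 0.88 verbatim, cohort mode computes
its own, and neither is silently corrected).

The ratio-adjusted cost swaps the fixed 1000-procedure equipment share for
price / total capacity and keeps the arm's **observed** mean theatre,
consumables and stay costs. Two deliberate choices here:

* The stay component stays at the observed mean (€1153 / €768), not a
  forced one-day €681 — only that arithmetic reproduces the reference
  adjusted costs (e.g. 2356 + 1047 + 1153 + 140000/1770 ≈ €4635). A
  `stay_policy="fixed_one_day"` flag provides the idealised variant.
* The percent overrun divides by the **robotic** cost: 1173/5810 = 20.2%,
  835/5431 = 15.4%, 722/5305 = 13.6% all match; a laparoscopic denominator
  matches none.

Theatre mean cost is held constant in k: stacking procedures in a session
does not change each procedure's billed minutes.

## Discount scenarios

The adjusted robotic cost is affine in the equipment discount d_e (applied
to the purchase price before amortization) and the consumables discount
d_c (applied to the consumables mean); theatre and stay rates are never
discounted. Default grids: d_e ∈ {0, 10, 15, 20}%, d_c ∈ {30, 35}%. The
break-even d_c at fixed d_e follows in closed form and is validated against
a 10⁻⁴ grid search; `inf` is the "unreachable" sentinel when no discount
below 100% suffices. Extending instrument lifespan from u to u′ uses is the
equivalent lever d_c = 1 − u/u′.

Under the reference inputs the default grid converges only at k = 3 (e.g.
10% + 35% gives €4559 ≤ €4582); at k = 2 the best default scenario still
sits ~€39 above the laparoscopic reference. The package reports convergence
flags rather than asserting any qualitative claim about k = 2.

## Cohort statistics

Continuous variables pass a Kolmogorov–Smirnov gate against a normal with
the sample mean/SD (gate alpha 0.05, configurable); both arms passing
routes to the pooled-variance Student t (a Welch option exists, off by
default), otherwise to the two-sample Wilcoxon rank-sum (exact for small
tie-free samples, normal approximation with tie correction otherwise).
The KS-with-estimated-parameters gate is anti-conservative (Lilliefors
caveat); it is kept because it is the conventional routing in clinical
tables, and the test actually used is always reported. Categorical tables
use chi-square without continuity correction unless an expected cell is
below 5, then Fisher's exact test (2×2) or its Monte-Carlo fixed-margin
variant (wider tables; validated against full enumeration on small
tables). Perfect separation — non-overlapping predictor ranges between
arms — is detected directly with the midpoint threshold reported;
logistic-regression coefficients are deliberately out of scope, since
separation is precisely the condition under which they are meaningless.

## Synthetic cohorts: what they do and do not show

The generator matches published arm **moments**, not distributions (none
are published): truncated normals (lower bound 0; BMI ≥ 15) for continuous
variables by rejection sampling, and stay = 1 + count with the count
moment-matched to (mean − 1, sd²) — negative binomial when overdispersed,
Poisson at the boundary, and a warned Poisson variance floor when sd² <
mean − 1 (infeasible for mixed-Poisson counts). The truncation-induced mean
shift is below 1% at the default parameters and is accepted rather than
re-centred; tests compare against the truncated distribution's exact mean.
Variables are independent by default; a Gaussian-copula rank-correlation
hook over (theatre, stay, consumables) supports sensitivity work. Arms
draw from spawned seed substreams, so cohorts are reproducible per arm.

Consequences worth stating plainly:

* Moment recovery, stay-ratio recovery (≈0.59 laparoscopic at large n) and
  the power of the stay comparison at n = 75/78 are faithfully reproduced.
* The reference cohort's **perfect separation** between arm and total cost
  is *not* reproduced: with totals ≈ €4698 ± 1121 vs €7052 ± 816, any
  marginal matched only to those moments overlaps across arms at n ≈ 75
  (a 100-seed Monte-Carlo finds 0 separated cohorts). Separation in the
  real data is a distribution-shape feature (clustered, near-deterministic
  per-procedure costs) that mean/SD emulation cannot carry. The test suite
  therefore validates the detector against a brute-force range-overlap
  oracle across seeds instead of asserting a separation rate. Passing
  tests show the pipeline is correct, not that real cohorts look normal.

## Problem sizes and numerics

Moment-recovery checks use n = 10,000 per arm (Monte-Carlo 2-SE bands);
power uses 200 cohorts at the study arm sizes; detector validation uses
100 cohorts; the break-even oracle uses a 10⁻⁴ discount grid. The full
suite runs in a few seconds. Currency comparisons in tests use the ±€3
slack implied by reproducing printed values from independently rounded
component means; everything internal is full precision. Degenerate inputs
(constant samples, empty arms, zero admission days, zero consumables
means) raise typed domain errors rather than propagating NaNs.

## Known limitations

Single-centre reference parameters (Spanish tertiary-care rates); no
queueing model of theatre sessions (capacity is a deterministic cap); no
cash-flow discounting; no complication-cascade simulation beyond a
Bernoulli flag; cost-minimization assumes clinical equivalence and cannot
surface quality-of-life differences.
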