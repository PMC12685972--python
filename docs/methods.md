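# Methods

`mhequity` measures wealth-related inequity in a binary maternal-healthcare
outcome and attributes it to observed determinants. This note records the
model, the estimators, the synthetic-data design, and the numerical and
design choices a maintainer would want to know.

## Outcome construction

The unit of analysis is a woman with a recent live birth. The outcome is
the *complete continuum of maternal healthcare services* (CMHS): at least
four antenatal visits (ANC4+), AND delivery at a health facility, AND at
least one postnatal check (PNC, any check before or after discharge, or
after a home birth — timing is deliberately not used, since postnatal-check
timing is not consistently collected across survey rounds). Eligibility
filters run in a fixed order — (1) ever gave birth, (2) at least one ANC
visit, (3) complete case (no missing or "don't know" required fields),
(4) de jure resident — and each step's removal count is logged. The
at-least-one-ANC condition can be expressed as a yes/no item or a visit
count (> 0); which rule was used is recorded in the filter log.

## Ranks and concentration indices

Records are ranked poorest to richest by household wealth with the weighted
fractional (midpoint) rank

    r_i = (W_{<i} + w_i/2) / W,

where `W_{<i}` is the cumulative survey weight of strictly poorer records
and `W` the total weight. The weighted mean rank is exactly 1/2. Ranking is
invariant to any strictly increasing transform of the wealth score; when
only quintiles are available, ties are broken by stable input order (the
resulting index perturbation is mean-zero pairing noise of order
`1/sqrt(n)`, about 8e-4 at n = 100,000 — a regression test bounds it at 1%
of the index).

For an outcome `y` with weighted mean `mu`, the relative concentration
index is the "convenient covariance" form

    CI = 2 * cov_w(y, r) / mu,

positive when the outcome concentrates among the rich. A binary outcome
confines CI to [mu − 1, 1 − mu], so cross-survey comparison uses the
Erreygers-corrected index

    ECI = 4 * mu * CI,

which spans [−1, 1] and satisfies the mirror property
ECI(1 − y) = −ECI(y). The identity ECI = 4·mu·CI is asserted in the result
constructor at 1e−10. An independent weighted-sum form,
CI = (2/mu)·Σ ŵ_i y_i r_i − 1, is kept as a test oracle only.

**Standard errors.** se(CI) is the heteroskedasticity-robust (HC1) slope SE
from the "convenient regression" of `2·var_w(r)·y/mu` on `r` (whose WLS
slope equals CI exactly); se(ECI) = 4·mu·se(CI), treating `mu` as fixed.
Weights are treated as precision weights throughout; design-based
(cluster/stratum linearised) variances are out of scope, so SEs understate
design effects of a multi-stage survey. With n ≤ 2 the SE is undefined and
reported as NaN.

**Degenerate inputs.** mu = 0 raises (the index is undefined); a binary
outcome with mu = 1 returns CI = ECI = 0 with a degeneracy warning; all
wealth values identical warns and falls back to input-order ranks.

## Concentration curves

The curve is the cumulative weighted outcome share `L` against the
cumulative weighted population share `p`, poorest to richest, from (0,0) to
(1,1); below the diagonal means pro-rich. Classification
(pro-rich / pro-poor / crossing / on-diagonal) compares `L − p` at a fixed
19-point interior grid of population shares (linear interpolation), with
tolerance 1e−12 for the on-diagonal case. The grid is used because
per-record ordinates in the extreme tails flip the class on single-record
noise: in a clearly pro-rich sample the curve rises above the diagonal
whenever one of the few poorest records happens to have the outcome.
`curve_position(..., at=None)` compares at every interior sample ordinate
instead.

## Decomposition

The outcome is modelled with a survey-weighted binomial GLM with logit
link, fitted by IRLS (coefficient tolerance 1e−8, at most 100 iterations).
Categorical determinants enter as dummies against a declared reference
level. Three failure modes are distinguished: zero-weighted-variance
dummies, rank-deficient (collinear) dummy sets — detected by pivoted QR of
the weighted design, naming the offending columns — and perfect separation
(divergent coefficients, |coef| > 15, alongside a separation warning or
non-convergence).

Because the model is nonlinear, the effect entering each elasticity is the
**average marginal effect** (AME): the weighted mean discrete change in
predicted probability moving the determinant from its reference level to
the level in question, other covariates at observed values. Logit
coefficients are not marginal effects on the probability scale; AME is the
standard resolution and is used openly. Then, per dummy k:

- elasticity       `eta_k = AME_k * mean(X_k) / mu`
- determinant index `C_k` = Erreygers index of the dummy over the same
  ranks (default; the standard relative index is available as a variant —
  the product `eta_k * C_k` is the quantity the decomposition pins down)
- contribution     `eta_k * C_k`, also expressed as a percent of the
  outcome ECI
- residual = outcome ECI − Σ contributions (defined as the remainder, so
  additivity holds to machine precision by construction).

**On residual size.** With `C_k` measured on the Erreygers scale, a
determinant that fully mediates the wealth gradient contributes
approximately `ECI_y · mean(X_k)/mu`, so contributions over- or under-shoot
whenever the determinant's prevalence differs from the outcome's, and the
remainder absorbs the difference. Large residuals (tens of percent, either
sign) are therefore an expected feature of this decomposition, not a
defect; the recovery test for a single known driver is calibrated to the
regime (determinant prevalence ≈ outcome prevalence) where the remainder is
genuinely small. All means, ranks and indices in one decomposition come
from a single pass over a single filtered dataset.

## Synthetic data

The generator emulates a weighted cross-sectional household survey:

- **wealth**: lognormal score, sigma = 0.9 by default (right-skewed, as
  asset indices are); quintiles are weighted fifths of the rank.
- **weights**: uniform on [0.5, 1.5] by default, independent of everything
  else (ignorable weighting); a correlation flag couples weights to wealth
  rank to stress-test the weighted estimators.
- **covariates**: Bernoulli with logit-linear prevalence in the wealth
  *rank*, so wealth gradients are monotone by construction.
- **outcome**: Bernoulli from a logit on the covariates and the wealth
  rank. Wealth enters through the rank, matching the estimators'
  rank-invariance and keeping calibration stable.
- **components**: ANC4+/facility/PNC are drawn from their own rank trends
  and then made consistent with the drawn outcome (all yes iff the
  continuum is complete; when the three draws are all yes but the outcome
  is no, the postnatal check is set to no). Component marginals are
  therefore approximate — the PNC margin is slightly depressed — but the
  logical-AND identity holds exactly.

Because the rank is uniform, the implied population mean and ECI have a
closed form up to 1-D quadrature: `mu = ∫ p(r) dr`,
`ECI = 8 ∫ p(r)(r − 1/2) dr`, with `p(r)` evaluated by exact enumeration
over covariate combinations and 96-node Gauss–Legendre quadrature. These
expected values are the generator's stored ground truth and are never
re-estimated from a sample they validate. Calibration of the wealth-rank
coefficient to a target ECI scans a coefficient grid and refines the first
bracketing interval by Brent's method (the expected ECI is not globally
monotone in the coefficient: for extreme values the probability curve
saturates and the index decays back toward zero); unreachable targets
report the achievable range.

The packaged `cmhs_scenario` (n = 50,000 default) fixes covariate
prevalences (rural 0.70, secondary education 0.16, first-trimester ANC
0.37, blood-pressure check 0.88, television 0.22) and outcome coefficients
in the range reported for such settings, with the intercept and wealth-rank
coefficient solved jointly by quadrature for an overall prevalence of 0.299
and an ECI of 0.311. The implied quintile gradient
(13.4 / 19.4 / 27.6 / 38.3 / 50.7%) is monotone and close to, though
flatter in the middle than, the survey gradient it emulates — a limit of
the single logit-in-rank family. `null_scenario` keeps informative
covariates but removes every wealth gradient, making the expected ECI and
all contributions exactly zero.

**What passing tests do not show.** The generator has no cluster/stratum
geometry, no spatial structure, no non-ignorable missingness, and
covariates are conditionally independent given the rank; recovery on this
generator validates the estimators' arithmetic and statistical behaviour
under ignorable weighting, not robustness to design effects or informative
missingness in real survey data.

## Problem sizes and tolerances

Identity assertions hold at 1e−10 (additivity of the decomposition at
1e−12, by construction); oracle equivalence at 1e−10; comparisons against
3-dp printed values at ±0.002. Monte-Carlo recovery tests use n = 50,000
per draw (20 seeds for the null-recovery check), sizes at which binomial
noise in the ECI is ≈ 0.005 — small relative to the effects of interest
while keeping the full suite around ten seconds.

## Known limitations

- SEs ignore the multi-stage sampling design (precision-weight treatment).
- No dominance hypothesis testing for curves; classification is pointwise.
- The decomposition residual conflates omitted factors with the scale
  mismatch discussed above; contribution uncertainty (bootstrap) is not
  implemented.
- Native survey-recode file formats are not parsed; input is CSV plus an
  explicit schema mapping.
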