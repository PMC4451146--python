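# Methods

## The ancestral-age statistic

For a proband with known male ancestors over up to three generations, the
weighted mean age of male ancestors is `m = Σ aᵢrᵢ / Σ rᵢ` with
relatedness weights r = 0.5 (father), 0.25 (grandfather), 0.125
(great-grandfather). `aᵢ` is always the age at fathering the next
individual down the proband's lineage: the father's age at the proband's
birth, a grandfather's age at the relevant parent's birth, a
great-grandfather's age at the relevant grandparent's birth. Unknown
ancestors are dropped from numerator and denominator alike
(renormalisation), and tallied per generation. With all seven ancestors
known the weight sum is 1.5. Eligibility for the cohort analyses requires
the father and both grandfathers; great-grandfathers are optional (0–4).

Ages are computed from birth years and are fractional if the input years
are fractional; with integer calendar years the statistic carries a ±1-year
quantisation, which is far below its between-proband spread (sd ≈ 3 y in
the simulated populations). Ages at fathering outside [13, 80] trigger a
warning but are retained.

The expected per-generation shares of the statistic's signal use raw
weights 1 : 0.5 : 0.25 (the variance contributed by a generation's ages
halves each generation back, because the number of ancestors doubles while
each squared weight quarters). This is an analytic approximation, not an
empirical variance decomposition; its two headline values are a 57% signal
loss on father removal with all three generations known (1/1.75) and 66%
with father and grandfathers only (1/1.5, truncated from 66.7%).

## Load calculus

All load quantities are deterministic arithmetic, computed at full
precision and rounded only for display:

* `U = 2·μ·L·f` — deleterious mutations per diploid genome per generation.
  With μ = 1.2e−8, the coding-sites parameterisation (L = 3e7, f = 0.75)
  gives U = 0.54; the genome-wide one (L = 3.2e9, f = 0.05) gives U = 3.84.
* `Δ_R = U·h̄s̄` — per-generation fitness reduction under relaxed
  selection; literature h̄s̄ of 0.029–0.058 brackets Δ_R at 0.016–0.031
  (coding) and 0.11–0.22 (genome-wide).
* Age-effect decomposition: given a per-generation fitness decline δ
  between paternal ages 30 and 40 and a load ratio ρ = Δ_R(40)/Δ_R(30)
  (default 4/3, the relative increase in de novo counts over that decade),
  the two equations Δ_old = ρ·Δ_young and Δ_old − Δ_young = δ give
  Δ_young = δ/(ρ−1). With ρ = 4/3 and a cumulative decline split equally
  over three generations, Δ_young equals the cumulative decline exactly —
  a useful closed-form check.
* `implied_mean_hs(δ, Δk)` is simply δ/Δk. Note that for δ = 0.04 and one
  extra deleterious mutation this is 0.04; a mean selection coefficient of
  0.12 for the same decline corresponds to Δk = 1/3 of a mutation. Both
  readings are exposed; the function computes the ratio as defined.

The constants "+2 point mutations per paternal year" and the 4/3 ratio are
configuration values (`MUTATIONS_PER_YEAR`, `DEFAULT_LOAD_RATIO`), not
hard-coded. No uncertainty propagation is attempted: these are point
calculations by construction.

## The synthetic population

`simulate_population` generates discrete, non-overlapping generations of a
strictly monogamous population:

* **Founders** (default 150 couples; the narrative run uses more) are
  mutation-free, married, assigned one of 7 parishes and a social class
  (rich/middle/poor at 0.25/0.45/0.30).
* **Births**: each couple draws a Poisson(5.5) number of children. Per
  child, the paternal age comes from a truncated normal (mean 33, sd 6,
  support [18, 60]); the child's birth year is the father's birth plus
  that age, clamped so the implied maternal age stays within [16, 45].
* **Mutations**: the child receives Binomial(k, ½) of each parent's
  deleterious count plus de novo contributions — paternal
  Poisson((λ_ref + β·(age−30))·f_del) with λ_ref = 60, β = 2, f_del = 0.05
  (so ages 30→40 add ~1 deleterious mutation), and an age-independent
  maternal Poisson(15·f_del).
* **Survival to 15**: s₀·(1−hs)^k with s₀ = 0.62 and hs = 0.04, shifted on
  the logit scale by parish intercepts (drawn once per run from N(0, 0.4²)),
  class effects (middle +0.05, poor −0.3), a twin penalty (−1.0) and a
  maternal-age slope (−0.01/y). The multiplicative (1−hs)^k form is the
  standard load model and matches Δ_R = U·h̄s̄ to first order.
* **Marriage and remating**: survivors seek marriage with probability 0.85
  (logit scale; an optional female-specific WMAMA slope is a hook for
  marriage-effect studies, off by default). Candidates pair monogamously
  within parish, matched in birth-year order with a preferred husband-wife
  age gap of N(4, 3²) years; the surplus of the more numerous sex remains
  unmarried *at random* — deterministically dropping the tail of the
  sorted list would fabricate a birth-year (and hence ancestral-age)
  effect on marriage. Wives take their husband's social class. Only
  married survivors reproduce, so selection purges deleterious mutations.
* **Bookkeeping**: 5% of individuals emigrate (uniform age 1–40) and are
  right-censored (death unobserved after emigration); non-survivors die at
  a uniform age below 15; surviving adults die at N(60, 15²) years,
  floored to outlive their last recorded birth. Every individual carries
  its ancestral ages down the pedigree, so the generator knows each
  proband's true WMAMA without traversal — the pedigree-traversal path is
  asserted equal to this bookkeeping in the tests.

Randomness comes from one master `SeedSequence`; per-generation child
seeds make runs byte-reproducible (same config + seed ⇒ identical pedigree
text and truth table).

### What the generator does and does not emulate

It reproduces the statistical structure the analyses rely on: a
paternal-age gradient in transmitted load, Mendelian dilution across three
generations, covariate structure (parish, class, twins, maternal age,
birth-year cohorts), family clustering via shared parents, selection
against carriers, and realistic eligibility attrition. It does **not**
model: overlapping generations (a consequence: balanced marriage pools
force the mean spouse age gap toward zero, so implied maternal ages are
wider (sd ≈ 6.9) and later (mean ≈ 32) than the nominal N(29, 5) law);
extra-pair paternity (≈0 in comparable register studies); imputation of
missing ancestors; or mutation-selection balance — founders start
mutation-free, so the mean deleterious count grows by ~4 per generation
over the short simulated horizon and realized child mortality (~45–60%)
exceeds the ~40% that s₀ = 0.62 implies at zero load. Two consequences
matter for interpretation:

1. Analyses should compare individuals within a generation. Pooling
   generations lets "number of generations elapsed by a given calendar
   date" confound ancestral ages: lineages with young fathers complete
   more generations and carry more accumulated load, masking the
   within-generation effect. The analysis drivers and calibration studies
   therefore use the final (proband) generation.
2. Passing calibration here shows the inference machinery is sound under
   this generative structure; it does not certify effect sizes in real
   register data, where load is at equilibrium and ancestral-age variation
   is the only load signal.

## Association analyses

Survival to 15 and marriage are binomial-logit GLMs; longevity (whole
years lived past 15, among survivors) and lifetime breeding success are
Poisson-log GLMs (Pearson overdispersion reported). Fits are maximum
likelihood with cluster-robust standard errors on maternal identity —
replacing random-intercept machinery while preserving its inferential
target — and birth year enters as 25-year fixed bins. Categorical
references: first parish, rich class, singleton, male. Marriage is fitted
separately by sex. Degenerate categorical levels (all-identical outcomes,
which a logit would fit to ±∞) are merged into the reference with a
warning. Rank-deficient designs raise an error naming the collinear
columns.

**Backward pruning** mirrors interval-based model selection: nuisance
covariates whose 95% CIs all cover zero are removed iteratively (weakest
block first); the exposure is never removed, and maternal age is retained
whenever it was significant before the exposure entered.

**Permutation inference**: the exposure is residualised on the remaining
design columns, residuals are shuffled within parish strata and added back
to the fitted part (Kennedy-style), and the model is refitted;
p = (1 + #{|b*| ≥ |b|})/(B + 1). Shuffling the raw exposure instead is
anti-conservative here because WMAMA co-moves with maternal age and birth
year (measured: roughly half of null p-values fall below 0.05 under the
raw scheme, versus a uniform distribution under the residual scheme).

**Discrete-time hazard**: each proband contributes one Bernoulli trial per
life-year up to death or age 15, with a piecewise-constant baseline
(3-year age bands); the exponentiated exposure coefficient is the per-year
mortality hazard ratio. For annual records and small per-year hazards this
coincides with proportional-hazards regression to first order.

**Effect translation**: inverse-logit predictions at exposure 30 and 40,
other covariates at reference levels and continuous covariates at their
cohort means (the prediction profile is a package choice; relative decline
(p₃₀−p₄₀)/p₃₀ and absolute decline p₃₀−p₄₀ are both reported, as
conventions differ). Interval: quantiles of the translated decline over
draws from the coefficients' asymptotic normal distribution.

**Model comparison**: AIC over identical rows, used to screen
exposure × parish/class/sex interactions.

## Calibration results and problem sizes

The test-suite runs four 100-replicate studies (replicate seeds derived
from a fixed base seed; ~2,000–4,000 probands per replicate, chosen to
keep the full suite around a minute per study on one core):

* neutral simulator (hs = 0): exposure CI covers zero ≈ 95% of runs and
  permutation p-values are uniform (KS test);
* direct logistic generation: a true slope of −0.036 and a true 13.5%
  relative decline between WMAMA 30 and 40 are recovered within each
  run's 95% interval at the nominal rate;
* default selection (hs = 0.04, ~4,000 probands): the fitted WMAMA slope
  is negative in roughly 76–90% of replicates depending on the seed set.

That last figure is worth being explicit about: the generative slope under
the default parameters is ≈ −0.020 per WMAMA year on the logit scale
(purging trims the mutation gradient slightly; controlling maternal age —
which correlates with WMAMA at r ≈ 0.57 because couples age in lockstep —
splits off another third), while the sampling sd of the estimate at 4,000
probands is ≈ 0.020 (siblings share ancestors, inflating it ~1.8× over
the independent-observation value). Sign recovery therefore sits near
Φ(1) ≈ 84%, not the ~95%+ a naive power calculation without purging,
collinearity and family clustering would suggest. The corresponding
acceptance assertion is left failing rather than weakening the test or
retuning the generator.

## Numerical choices and degenerate inputs

Quartile cut-points use linear-interpolation empirical quantiles with ties
assigned to the lower quartile; constant exposures raise an error. The
statistic is reported at full precision (display rounding only).
Truncated-normal age laws resample out-of-support draws rather than
clipping, avoiding mass at the bounds. Probabilities are clamped away from
{0, 1} before logit transforms. Empty ancestor sets, absent fathers under
the father-only variant, unknown outcome labels, self-parenting records,
ancestry cycles, duplicate ids and missing required columns all raise
typed errors with the offending entity named.
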