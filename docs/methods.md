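# Methods

## The phenotypes

Egg production (EP) of caged laying hens is recorded as egg counts over
collection spans of one to four days (occasionally longer, when staff
merged or back-filled records; such spans are flagged *imputed* but kept,
since they are kept in practice too). Span counts divided by span length
give average daily EP. A hen can show two eggs on one day — an egg laid
after collection on day 1 plus one laid before collection on day 2 — so
daily rates up to 2 are biologically possible; any hen with a span
averaging *strictly more* than 2 eggs/day is removed outright (exactly
2.0 is retained; the rule in words is "more than two").

Span rates are apportioned into non-overlapping intervals of 1, 2 or 3
weeks anchored exactly at day 175 (25 weeks of age), proportionally to
days of overlap, which conserves egg totals. Two life periods are
analysed: 25–83 weeks (the traditional selection window) and 83 weeks to
death/censoring. Trailing partial intervals are kept when at least one
day is covered, because late-life series must accommodate death at
arbitrary ages. The expected EP is either

* the **batch average**: the unweighted mean of contemporaries' interval
  values, focal hen included (no exclusion is stated in the field's
  convention, and at ~200+ hens per batch the difference is negligible);
  any bird contributing at least one covered day is included; or
* the **individual curve**: a 4th-order polynomial in centered/scaled
  age fitted per hen to her 1-week series from 25 weeks to end by
  quantile regression at τ = 0.7, so that transient drops in lay barely
  move the expectation. The fit is the exact linear-programming solution
  of the pinball-loss problem (HiGHS); a hen needs at least 9 weekly
  points (parameters + 4) to avoid quasi-rank-deficient fits, otherwise
  she is excluded from individual-reference indicators. Predictions are
  evaluated at interval midpoints and are deliberately not clamped to
  [0, 2]. Individual-reference indicators are computed for the 1-week
  interval only; longer intervals use the batch reference.

## Resilience indicators

For each hen and each (period × interval × reference) variant with at
least five interval observations:

* ln(variance): natural log of the sample variance (denominator n−1, the
  R `var` convention); undefined (missing) when the variance is zero.
* skewness: `b₁ = g₁·((n−1)/n)^{3/2}` with `g₁ = m₃/m₂^{3/2}` on
  denominator-n central moments — the default (type 3) of the R package
  commonly used for this statistic.
* lag-one autocorrelation: centered cross-product of consecutive
  deviations over the full centered sum of squares. Only pairs of
  *adjacent interval indices* enter the numerator — a missing interval
  breaks the pair — while the denominator uses all entries, which by
  Cauchy–Schwarz keeps the estimate inside [−1, 1].

Per variant, values more than four population SDs from the population
mean are discarded in a single non-iterated pass (mean and SD from the
untrimmed values); trimming one variant never removes the hen from
another. The full design yields 24 variants: 3 statistics × 2 periods ×
(3 intervals, batch reference) plus 3 × 2 × (1-week, individual
reference).

Survival enters the fixed part of the genetic model as the **maximum
age-class**: class 1 for death before 30 weeks, then 4-week bins
(30–34 → 2, 34–38 → 3, …; censoring at 105 weeks → class 20). Birds
leaving before 25 weeks never enter the analysis.

## The animal model and REML

Variance components come from the linear animal model with fixed batch,
location × row*level and maximum-age-class effects (plate, sex and an
age covariate for the antibody traits), a random additive genetic effect
with covariance `A σ²ₐ`, an optional maternal environmental (dam) effect
`I σ²ₘ`, and residual `I σ²ₑ`. The numerator relationship matrix never
materializes: its sparse inverse is assembled from per-animal
Mendelian-sampling variances `b_i = 0.5 − 0.25(F_s + F_d)` (terms
dropped for unknown parents, treated as unrelated founders — no genetic
groups), with inbreeding F from a memoized kinship recursion whose
output equals the tabular method exactly. `log|A| = Σ log b_i` falls out
of the same quantities.

The restricted log-likelihood is evaluated through
`−2ℓ_R = log|R| + log|G| + log|C| + y'Py` on the sparse mixed-model
equations (`log|C|` from a sparse LU with the symmetric MMD ordering,
which avoids the catastrophic fill-in a nonsymmetric column ordering
produces on these systems). Two maximizers are provided:

* **EM-REML** — the classical monotone updates; each step needs blocks
  of `C⁻¹`, computed densely, so this path is for small/medium systems
  and serves as the reference in tests (the likelihood trace is checked
  to be non-decreasing).
* **Direct search** (default) — σ²ₑ is profiled out analytically
  (`σ̂²ₑ = y'Py σ²ₑ/(n−p)`), leaving the variance *ratios*: a scalar
  coarse-grid + Brent search for the additive-only model, Nelder-Mead
  with simplex restarts over two ratios when the maternal term is
  present, and over up to six transformed parameters (log variances,
  atanh correlations) for bivariate models. Restarting the simplex at
  the incumbent escapes the narrow curved valleys of jointly drifting
  genetic/residual correlations. The residual correlation is capped at
  |r_e| ≤ 0.999 because the likelihood of duplicated traits is unbounded
  as the residual covariance degenerates.

Variances are floored at `1e-8 × var(y)`; whether a component is "zero"
is judged by the likelihood-ratio test, not the floor. LRTs for one
variance component use `2(ℓ₁−ℓ₀)` floored at zero against χ²₁
(deliberately not the ½χ²₀+½χ²₁ boundary mixture — the conventional,
conservative choice in this literature), significance at p ≤ 0.05 and a
tendency at p ≤ 0.10. Fixed-effect columns are intercept +
drop-first dummies; pivoted QR detects confounded factors (batch is
nested in location, so batch + location·row*level is rank-deficient by
construction) and by default drops redundant columns as mixed-model
software does, with a strict mode that raises instead. Bivariate models
estimate the residual covariance from animals measured for both traits
and fix it at zero when the measurement sets are disjoint (traits then
connected only through the pedigree).

Standard errors come from a central finite-difference observed-
information matrix at the optimum (step 1e-3 relative); SEs of h² and
r_a use the first-order delta method. Starting values are 0.1 of the
phenotypic variance for each non-residual component; bivariate
correlation searches warm-start from the phenotypic correlation of
doubly-measured animals.

Derived parameters: `h² = σ²ₐ/σ²ₚ` with `σ²ₚ = σ²ₐ + σ²ₑ (+ σ²ₘ when the
maternal LRT keeps it)`; `GCV = |√σ²ₐ/μ|` with μ the post-trim mean of
the records entering the fit, except for ln(variance) where the ln
transform already implies a multiplicative model and `GCV = √σ²ₐ`
without the mean. The genetic-correlation denominator is the *product of
genetic standard deviations* — a variance product cannot yield a
bounded correlation. Report tables round to two decimals (three where
values live at the 0.003 scale).

## The synthetic-data generator

The generator emulates the structure the analysis assumes rather than
any particular farm. Discrete generations of a hierarchical design
(default 25 sires × 4 dams × 14 offspring × 3 generations ≈ 2,100 hens,
a deliberate ~15× scale-down of a real nucleus population that preserves
all algorithmic content while keeping replicate-level experiments fast);
locations × batches (default 3 × 3 per generation) and a cage
(row*level) per hen. Breeding values for three traits — logit-scale lay
level, log disturbance-sensitivity, antibody titer — follow the additive
recursion: founders N(0, G₀), offspring mid-parent plus a Mendelian
deviation with covariance `b_i G₀`. Maternal environmental effects are
one draw per dam, shared by her offspring.

Daily laying is Bernoulli with

`logit p_i(t) = base(t) + bv_level_i + mat_i + cage + batch − D(t)·exp(bv_env_i)`

where `base` rises from onset of lay (N(20, 1.2²) weeks, clipped to
18–25) to a plateau of 0.95 by 30 weeks and declines linearly on the
logit scale (0.045/week) after 60 weeks. Disturbances are of two kinds:
batch-wide events (Poisson, 9 per 100 batch-weeks; Gamma(2) depth with
mean 2.2 logits; exponential duration, mean 2 weeks) and individual
events (10 per 100 hen-weeks, mean depth 2.2, mean duration 1.25 weeks).
Both act through the hen's multiplicative sensitivity `exp(bv_env)`, so
the within-hen deviation variance is heritable on the log scale without
forcing heritable mean differences. The individual events matter: under
a batch-average reference, purely batch-wide events make deviation
variance a U-shaped function of sensitivity (the batch mean moves with
the event, and both unusually sensitive *and* unusually insensitive hens
deviate from it), which destroys the linear additive signal; individual
events restore it.

Recording: per batch, collection spans drawn from {1,2,3,4} days
(p = .2/.3/.3/.2), a 2% chance of merging adjacent spans into a longer
flagged-imputed span, and a 3% chance that an egg is booked on the
following day (producing genuine 0-then-2 day patterns). Mortality is a
weekly hazard of 0.0012 from caging; batches are emptied at a uniform
age in 91–105 weeks. The default genetic variances
(σ²ₐ,level = 0.03, σ²ₐ,env = 0.08, σ²ₘ = 0.015) were calibrated once so
the ln(variance) indicator (1-week, 25–83, batch reference) has a
generative heritability of ≈ 0.10 at the default scale — the regime the
recovery experiments are designed around — with the qualitative sign
structure of real data (skewness predominantly negative, laying-period
autocorrelation predominantly positive, EP–ln(variance) genetic
correlation negative).

What the generator does **not** emulate: seasonal/structural production
waves, disease epidemiology (disturbances are anonymous intensity
events), non-Bernoulli within-day biology (double-egg days are a
recording artifact, as in reality), selection across generations
(parents are sampled at random), or crossbred production. Passing
recovery tests therefore show that *given* data of the assumed
structure, the pipeline estimates what it should — not that real farms
satisfy the assumptions.

## Recovery truth and problem sizes

For derived traits like ln(variance) there is no closed-form generative
additive variance, so recovery experiments define truth per replicate as
the variance of the best linear genetic predictor: regress the trait on
the known (bv_level, bv_env) and take `β₁²σ²ₐ,level + β₂²σ²ₐ,env`. The
mean REML estimate over 10 replicate seeds at the default scale is
required to sit within ±0.05 of the mean truth (h² scale), and the mean
bivariate r̂_a for traits simulated at r_a = 0.8 (n = 2,000 phenotyped
birds, heritability 0.5 per trait) within two Monte-Carlo standard
errors. The per-trait heritability of 0.5 is a deliberate design
choice: at low heritability the correlation estimator shows the
familiar away-from-zero ratio bias of normalized covariance ratios,
which would swamp the Monte-Carlo standard error and test the
estimator's small-sample bias rather than the implementation. Oracle suites pin the
numerics: tabular A vs sparse A⁻¹ to ‖AA⁻¹−I‖max < 1e-8 at 500 animals,
quantile fits within 1e-6 pinball loss of an independent IRLS solver,
REML equal to the balanced half-sib ANOVA closed form to ~1e-4 relative,
and MME solutions within 1e-8 of dense GLS.

## Known limitations

* EM-REML is quadratic-memory in the equation count (dense trace path)
  and intentionally not the default at scale.
* The additive-LRT reduced model pins the additive ratio at the floor
  rather than re-deriving a no-animal model, which is the same
  likelihood to within the floor tolerance.
* Finite-difference observed information can fail near boundaries; SEs
  are then omitted rather than extrapolated.
* Quantile-regression monotonicity in τ holds only up to degenerate-tie
  tolerance for polynomial fits at training points.
* The simulated antibody isotypes share one genetic factor (their
  genetic correlation is 1 by construction); the analysis layer treats
  them as separate traits regardless.
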