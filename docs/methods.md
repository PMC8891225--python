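# Methods

This note documents the models implemented in `soyphen`, their assumptions,
the defaults of the synthetic trial generator, and the numerical choices a
maintainer would need to reason about results.

## Trial design

`design.build_design` constructs an augmented row–column layout: replicated
check genotypes connect blocks, unreplicated entries fill the remaining
cells.  The reference replication scheme (3 checks × 9 replicates, 9 × 6,
13 × 3, 334 unreplicated) yields 454 plots and 359 genotypes per field.
The block count and block grid are not part of that scheme, so they are
configuration: the default is 9 blocks of 6 rows × 9 columns, enough to
hold 454 plots with check connectivity (each check's replicates are spread
over distinct blocks via a seeded permutation).  Row and column indices are
1-based within block; the "crossed" row/column factors of the analysis
model treat the same within-block index as one level across blocks, while
the nested versions (`row_in_block`, `column_in_block`) give every
block × index combination its own level.

Plot geometry follows the growth-group scheme: late groups GP1/GP2 use a
0.40 m row distance on 1.20 × 0.75 m plots and are thinned to 60% of the
45/55 seeds m⁻² sowing density (27 and 33 plants m⁻²); early groups
GP3/GP4 use 0.25 m rows on 0.75 × 1.20 m plots at 65/75 seeds m⁻² without
thinning.  Growth groups are sown on staggered dates to synchronise the
developmental stage at drought onset.

## Growth curves and derived traits

All plot responses on the thermal-time axis are fitted with the beta
growth function

    w(t) = wmax · (1 + (te − t)/(te − tm)) · (t/te)^(te/(te−tm)),  0 ≤ t ≤ te,

constant at `wmax` beyond `te`.  One family serves canopy height, canopy
cover and the reproductive-stage score; using a single family keeps every
derived trait a deterministic function of `(wmax, tm, te)` and makes the
generator exactly invertible by the fitter.

* Fitting is bounded trust-region least squares in the parameterisation
  `(wmax, tm, te − tm)` (which enforces `tm < te`), with an analytic
  Jacobian, from three starts (`tm` at 0.3/0.5/0.7 of the observed time
  range, `te` at 1.2× the last observation, `wmax` at the observed
  maximum); the lowest-RSS solution wins.  A fit that fails on every start
  — or a flat/zero response — is flagged non-convergent and the plot's
  curve traits are left missing; missing values are later removed with the
  other missing data, never imputed.
* AGRmax uses the closed form `wmax (2te−tm)/(te(te−tm)) (tm/te)^(tm/(te−tm))`,
  verified in the tests against dense numerical differentiation, and is
  reported × 100 (cm per 100 GDD), the conventional unit.
* CC75 and the stage crossings R1/R2/R5 are bracketed Brent roots on
  `[0, te]` (the curve is strictly increasing there); a crossing above the
  fitted asymptote is missing rather than extrapolated.
* R-stage fitting uses only observations with scores in [1, 6] — the
  visually reliable early phase of the double-sigmoid development pattern —
  with a free asymptote bounded by 10.
* The cover series is truncated one point past its running maximum before
  the CC75 fit, because late senescent observations would bias the
  (monotone) asymptote; SNC is computed from the raw series instead: after
  a 3-point running median, SNC = smoothed maximum − mean of the `k_tail`
  (default 2) lowest smoothed values after the maximum, clamped to [0, 1].
  The median step exists because an "average lowest cover" of a noisy
  series is otherwise noise-dominated.
* DET = `te(height) − R1` is left unclamped: a strongly determinate plot
  that stops elongating before flowering legitimately scores ≤ 0.  R1 is
  taken from the fitted stage curve, not from field notes.
* Phase durations are reported at two levels: plot-level differences in the
  trait table, and — for the summary statistics — differences of the
  spatially adjusted stage BLUPs (R2R5 = BLUP(R5) − BLUP(R2), etc.), which
  is why no variance components or H² exist for durations.

## Environment indices

Daily GDD uses the capped-average rule
`max(0, (min(tmax, tcap) + min(tmin, tcap))/2 − tbase)` with soybean
conventions `tbase = 10 °C`, `tcap = 30 °C` (both configurable; all
thermal-time outputs are relative to this choice, and the cumulative axis
starts at 0 on each cohort's sowing date).

ET0 implements the FAO-56 Penman–Monteith daily equation with soil heat
flux G = 0, vapour pressure from Tmin/Tmax and mean RH, and net longwave
radiation whose cloudiness factor `1.35·Rs/Rso − 0.35` is clipped to
[0, 1] (relative shortwave capped at 1), so a dark, calm, saturated day
evaporates nothing.  The test suite checks it against an independently
coded scalar walk-through of the same standard to 0.05 mm.

CWD accumulates `ET0 − P` from a fixed start of season (default 1 April)
and may go negative in wet spells.

CWSI rescales the canopy-air temperature difference between a lower
(non-stressed) and upper (non-transpiring) baseline and is clamped to
[0, 1] as its definition requires.  Published baseline procedures vary;
here baselines are empirical per flight: the 5th percentile of dT among
well-watered plots (lower) and the 95th percentile over all plots plus a
configurable margin (upper), with an explicit manual override and a
degenerate-spread error.  On the generator's linear stress model this
estimator recovers stress levels with a mean absolute error of ~0.02–0.03;
with the true baselines the inversion is exact.

## Mixed models, BLUP, heritability

Each trait × treatment × season is analysed with the intercept-only linear
mixed model `y = μ + genotype + (spatial terms) + e`, all terms random
Gaussian intercepts.  Because columns and rows are physically nested in
blocks, six candidate spatial structures are fitted — genotype plus
{block}, {block, row}, {block, column-in-block}, {block, row,
column-in-block}, {row, column}, {block, row-in-block, column-in-block} —
and the lowest-AIC fit is selected (ties: fewest parameters, then
declaration order).  The six structures are a configurable default
covering the plausible nesting lattice.

REML details: variance components are optimised on the log scale (hence
non-negative; a component may converge to the zero boundary, where it is
reported as 0), with the analytic REML gradient, L-BFGS-B, starting values
`var(y)/k` for all k components, and tolerances tight enough that on
balanced one-way designs the estimates match the closed-form ANOVA
estimators to 10⁻⁶ and the BLUPs match the closed-form shrinkage formula
to 10⁻⁸ (tested).  The response is centred internally — REML is invariant
to this, and it removes precision loss for traits with large means.  AIC
is `−2·loglik_REML + 2k` with `k` = number of variance components
(including residual) + 1 for the intercept; the fixed part is identical
across candidates, so REML likelihoods are comparable and the counting
rule only needs to be consistent.

BLUPs are reported as intercept + predicted genotype effect, on the
analysis scale (no back-transformation).  Broad-sense heritability is
`H² = σ²_G/(σ²_G + σ²_e)` — spatial variance excluded from both numerator
and denominator — classed low/medium/high at 0.30 and 0.60.

Data cleaning before fitting: plots with emergence below 30% are removed
(exactly 30% is kept); Tukey's rule flags values outside 1.5 IQR beyond
the quartiles (linear-interpolation quartiles), applied per
trait × treatment × season; a response with |sample skewness| > 1 is
log1p-transformed when its minimum exceeds −1 (a computable stand-in for
visual Q-Q inspection), and the flag is recorded.  Every removal is logged
with plot id and reason.

## Drought response

`Yr = (Control − Drought)/Control` on genotype BLUPs, for genotypes present
in both treatments (inner join; the common count is reported).  Yr is not
computed for PLV and CC75 (determined before drought onset) nor for DET (a
growth-habit trait).  Because the ratio is undefined at zero, |control
BLUP| below 10⁻⁶ × trait sd yields a missing Yr with a warning.  The CV of
Yr values is `100·sd/|mean|` on raw Yr (an optional min–max normalisation
flag exists but is not the default).

Correlation families (between seasons under control, control vs drought,
Yr vs control, between measurement dates for repeated scores) use
pairwise-complete Pearson r with a 3-pair minimum.

The multi-trait PCA standardises each column to zero mean and unit
variance (correlation scaling — the natural choice for traits on different
scales) on complete-case genotypes, after a greedy within-subset reduction
that drops a variable whose |r| with an already-retained variable of the
same subset (developmental, growth, resistance, yield) reaches 0.8, in
declared order.  Repeated scores enter as the maximum over dates (CW,
LSEN) and CWSI as Yr at the last measurement date.  Constant-on-complete-
case columns are dropped with a log entry before standardisation.

## Synthetic generator: what it emulates, and what not

The generator is the generative twin of the analysis chain: plot values
follow exactly the additive random-effects decomposition the mixed model
assumes (centred Gaussians for genotype, block, row, column, residual;
genotype effects shared between the paired control/drought fields);
series are sampled from the beta family the fitter uses; canopy
temperature follows the linear stress model the CWSI inverts.  Drought
scales the genotype-level height asymptote multiplicatively (0.89 for the
short-drought season, 0.71 for the long-drought season, i.e. −11% and
−29%), shifts curve timing, accelerates the post-peak cover decline, and
scales the manual yield traits; the cover asymptote feels only 25% of the
height reduction and the R-stage asymptote none (it is a developmental
scale, not a growth amplitude).  Emergence failures (default 7% of plots
below the 30% threshold) and two weather archetypes (hot/dry vs
cool/humid seasons with AR(1)-persistent anomalies) complete the design.

Thermal-time magnitudes are calibrated to what a base-10 °C Belgian season
actually accumulates (height `te` ≈ 780–900 GDD, stage asymptote reached
at ≈ 860–980 GDD), so curves complete within the simulated season in both
archetypes.  Field-observed maturity (R8) is drawn as a plot-level trait
rather than derived from weather, a deliberate simplification.

What passing tests therefore show: the pipeline recovers what it assumes —
unbiased variance components and H² at trial scale, exact curve-parameter
recovery without noise, calibrated Yr under uniform multiplicative
drought.  What they do not show: robustness to model misspecification in
real data (spatially correlated residuals, non-Gaussian effects,
genotype × treatment interaction in the spatial strata, scoring artefacts,
image-extraction errors), none of which the generator produces.

## Problem sizes and seeds

Every stochastic component derives a child seed from one master seed (an
FNV-style hash of the purpose tag), so a single integer reproduces all
CSVs byte for byte.  The validation experiments use the full 454-plot /
359-genotype field: heritability recovery averages 50 seeded replicates
per true H² ∈ {0.2, 0.5, 0.8}; the drought-index calibration runs 50
replicate seasons of paired fields (≈ 90,000 curve fits) through
extraction, BLUP and Yr; the variance-component duality check uses an
8 × 7 block grid (more row/column levels than the default layout, for
identifiability at the tested precision) over 50 seeds; model-selection
consistency and the end-to-end pipeline tests run on a structurally
identical 34-plot scenario.

## Known limitations

* Residuals are i.i.d.; no AR1×AR1 or other spatially correlated error
  models, no fixed covariates, no multi-environment models.
* The R-stage fit covers only the rising phase (scores 1–6); R8 must be
  observed.  Plots whose season ends before the curve plateaus can lose
  R5/CC75 to the missing-value path.
* CWSI baselines are empirical quantiles, not energy-balance limits; the
  upper baseline is biased low when no plot approaches full stomatal
  closure.
* The skewness-threshold transform rule is a proxy for judgement; borderline
  distributions (|skew| ≈ 1) may be treated differently than a human
  analyst would.
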