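# Methods

This note documents the models implemented in `seedphys`, the parameter
choices that matter, the design decisions taken where the published
description of the analysis was ambiguous, and what the synthetic-data
generators do and do not emulate.

## Photo-thermal product

Daily photosynthetically active radiation is taken as 0.5 × global solar
radiation.  The cumulative photo-thermal product over a window of the
seed-growth period is PTP = Σ PARᵢ·RTEᵢ (MJ m⁻²), with the daily thermal
effectiveness RTEᵢ = 0.5·RTE(T_avg) + 0.25·RTE(T_max) + 0.25·RTE(T_min).

The single-temperature response uses cardinal temperatures T_b = 15 °C,
T_O = 30 °C, T_c = 35 °C (base/optimum/ceiling for cottonseed development)
and, with u = (T−T_b)/(T_O−T_b), v = (T_c−T)/(T_c−T_O) and
q = (T_c−T_O)/(T_c−T_b):

* T_b ≤ T ≤ T_O:  RTE = u^(1+(T_O−T)/(T_O−T_b)) · v^q
* T_O ≤ T ≤ T_c:  RTE = u · v^q
* zero outside [T_b, T_c].

Typeset versions of this family of response functions are frequently
garbled (stacked exponents collapse into the base); the form above is the
reconstruction that is continuous at the optimum with RTE(T_O) = 1 and zero
at both cardinals, which is what a relative effectiveness requires.  The
upper branch exceeds 1 by at most ≈0.9 % just above the optimum, so the
response is clamped at 1.  Note the ceiling approach is steep (a quartic-root
modulus of continuity, since q = ¼ at the defaults): RTE still falls
continuously to 0 at T_c, but most of the drop happens in the last ~0.1 °C.

Conventions: date windows include both endpoints; a missing calendar day
inside a window is an error, never silently skipped; a missing daily mean
temperature is imputed as the tmax/tmin midpoint with a logged warning.

## Logistic growth traits

Weight vs days after anthesis is fitted by least squares with
W(t) = W_a/(1+e^(−k(t−t_m))) (`scipy.optimize.curve_fit`, positivity bounds).
Start values are data-driven — W_a at 1.05 × the observed maximum, t_m at the
steepest observed rise, k from a logit-linearised slope — followed by at most
five deterministically jittered restarts; the best (lowest-SSE) converged
start wins, which also makes the fit invariant to observation order up to
solver tolerance.  R² is 1 − SSE/SST on the raw observations, not on
time-point means.

The rapid-accumulation phase is delimited by the roots of d³W/dt³ = 0,
t_m ± ln(2+√3)/k.  This is the standard convention for "start" and "end" of
rapid accumulation: between those points the growth rate stays above ~75 % of
its peak and the curve accumulates ~57.7 % of W_a.  It implies the exact
identity duration × peak rate = (ln(2+√3)/2)·W_a ≈ 0.65848·W_a, which the
test suite asserts on every fit and which is consistent with the bundled
growth-trait table (e.g. the high-fertility CM 2012 row back-solves an
asymptote of 5.74 g, above the observed final weight of 5.18 g, as an
asymptote must be).

Seed volume implements V = ⅓π(W/2)²L + ⁴⁄₃π(W/2)³.  The geometry is usually
described verbally as "a cone and a half sphere", which would give ⅔π(W/2)³
for the cap; the full-sphere form above is the convention this field's
published formula uses, so it is implemented as such and the discrepancy
flagged here rather than resolved.

## Yield and composition arithmetic

Seed weight is carried as g per 100 seeds (field convention) and converted
internally.  Oil/protein yields partition the seed yield through the embryo
fraction and the embryo contents; nitrogen converts to protein with the
Kjeldahl factor 6.25.  Treatment contrasts are computed under *both*
denominator conventions — increase over CM (÷CM) and changing amplitude
(÷IMS) — because published tables of this kind mix them; the two are never
interchangeable and are always reported side by side.  Full precision is kept
internally; presentation rounds half-away-from-zero.

Treatment means are unweighted arithmetic means per factor combination with
the cell count reported; an empty cell in a crossed design is an error naming
the missing combination, not a silent NaN.

## Node significance

Continuous variables are discretized into equal-frequency bins (default 3)
with stable-rank tie-breaking, so every bin is non-empty and permutations of
the input produce the same label multiset.  Three bins are the default
because the published table's constant G/NMI ratio (≈2.0853 across all 8
rows) back-solves a target entropy of ≈1.567 bits, just under log₂3 — i.e. a
near-equal tertile split of the target at n = 96.

Mutual information is the plug-in estimate from the empirical joint.  NMI is
normalized by the entropy of the *target* (not joint or min entropy): the
single per-table normalizer is the only convention consistent with a constant
G/NMI ratio across rows.  Relative significance divides by the maximum NMI,
so the top node scores exactly 1.  The G-test uses the natural-log form with
marginal expectations, df = (r−1)(c−1) and a χ² upper tail; zero observed
cells contribute 0, and a zero marginal is an error.  G = 2N·MI_nats holds
algebraically for plug-in estimates and is asserted to 1e-9 against
brute-force cell summation.

Only pairwise node-target scores are computed; no Bayesian-network structure
learning is attempted.

## Factorial ANOVA and LSD

The balanced, fully crossed Year × Fertility × Management design is
decomposed with the classical orthogonal sums of squares computed directly
from marginal means by inclusion-exclusion (all factors fixed).  Unbalanced
data are rejected rather than approximated — no Type-II/III fallback.  A
zero-variance response reports F = 0, p = 1 by convention so trivial fixtures
run end-to-end.  The implementation is cross-checked in the test suite
against two independent oracles: explicit design-matrix nested regression and
`statsmodels` `anova_lm`.

Fisher's LSD for a factor is t(1−α/2, df_err)·√(2·MS_err/n); compact letters
come from the descending-mean sweep in which each maximal run of means
spanning less than the LSD shares a letter (for a threshold relation on
sorted means this reproduces all-pairs grouping exactly, which the suite
verifies by brute force).  The factor to compare and the grouping scope are
explicit arguments — nothing is pooled implicitly across years.

## Synthetic data

The generators replace the unpublished raw field records.  Defaults describe
the study conditions the pipeline assumes; all draws come from a seeded
`numpy` Generator (per-generator streams derived by CRC of the stream name),
and truncation at physical bounds resamples rather than clips, avoiding point
masses at the bound.

* **Weather** — seasonal cosine for daily mean temperature (annual mean
  15.5 °C, amplitude 12 °C, warmest day ≈ DOY 200, day-to-day sd 1.8 °C) and
  solar radiation (mean 14, amplitude 7 MJ m⁻² d⁻¹, sd 3, truncated ≥ 0),
  with tmax/tmin a fixed 9 °C diurnal range around the mean — a temperate
  coastal cotton site.  Not emulated: rainfall, autocorrelated weather
  spells, hourly structure.
* **Growth** — logistic truth (W_a = 6 g, k = 0.2 d⁻¹, t_m = 27 d) sampled
  every 7 d from 10 to 45 DAA, 3 replicates, additive Gaussian noise with
  sd 0.3 g (5 % of the asymptote).  Not emulated: heteroscedasticity,
  within-plot correlation.
* **Plots** — the full 2 × 2 × 3 × 3 factorial around configured
  treatment-mean yields (the bundled trial means by default), with boll
  density back-solved so each plot's component product reproduces its
  treatment mean, then perturbed at a 5 % replicate CV.  Composition columns
  carry the bundled per-treatment contents with a constant embryo fraction
  of 0.58 (the value the bundled yield and composition tables jointly
  imply).  Not emulated: spatial blocking, component covariance.
* **Biochemistry** — n = 96 samples with a latent developmental stage,
  exactly balanced over three stages.  Each node reports the stage with a
  node-specific *fidelity* (the strictly decreasing effect ladder; defaults
  1.00 → 0.00 across the eight nodes in the published significance order,
  sucrose-synthase strongest), and the 100-seed-weight target is the
  weighted sum of the node signals plus Gaussian noise, weights concentrated
  on the top node.  Corruption is assigned by a single sample order shared by
  all nodes and stratified over (stage, decoy) combinations — the assays are
  taken on the same physical samples, and the stratification is a
  variance-reduction device (in the spirit of Latin-hypercube sampling) that
  keeps every corruption prefix balanced.  This is what makes the generating
  information ladder identifiable from a single n = 96 table: with
  independent per-node corruption the sampling noise of the plug-in NMI
  estimator (several percentage points at this n) would swamp the adjacent
  ladder gaps and no strictly ordered 8-node ladder could be recovered
  reliably.  The node values are monotone (log-scale) transforms of the
  stage signals onto plausible assay units, which leaves equal-frequency
  discretization and MI unchanged.  Not emulated: assay-specific error
  distributions, node-node causal structure beyond the shared stage.

Because the generators are idealisations, green tests certify the *methods*
(estimator identities, calibration, recovery under the stated noise), not
field performance on real data with correlated errors, missing days or
unbalanced designs.

## Numerical choices and degenerate inputs

* Logistic fitting requires ≥ 4 distinct time points and a non-constant
  response; failure after the bounded restarts raises a fit-failure error
  carrying the starts tried.
* Equal-frequency binning requires at least `bins` distinct values; node
  ranking requires n ≥ 3·bins².
* MI is clamped at 0 against floating-point cancellation (the plug-in
  estimate is analytically non-negative).
* ANOVA treats a response with SST ≤ 1e-12·N·max(1, mean²) as degenerate
  (F = 0, p = 1); the SS decomposition identity is asserted at 1e-8 relative
  on every call.
* LSD ties in means are broken by the stable descending sort; letters are
  assigned from maximal windows only.

## Problem sizes used in validation

The repeated-simulation checks use 200 replicates for logistic parameter
recovery, 200 random contingency tables for the MI/G identity, 500 pure-noise
datasets (36 observations each) for the ANOVA null calibration, and 100
seeded tables for effect-ladder order recovery — sizes at which the binomial
noise of the measured rates is small relative to the acceptance bands.

## Known limitations

* The thermal response is evaluated at three daily temperature summaries; no
  hourly interpolation.
* Only the logistic sigmoid is offered (no Gompertz/Richards alternatives).
* The ANOVA stage is strictly for balanced designs with fixed effects.
* The node-significance stage quantifies pairwise dependence only; it cannot
  separate direct from stage-mediated association.
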