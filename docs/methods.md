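# Methods

## The problem

In 16S rRNA amplicon surveys, the number of distinct sub-genus read
clusters (OTUs/ASVs) recovered for a genus grows with the genus's total
read count, largely because amplification and sequencing errors spawn
spurious clusters at a rate that increases with the source sequence's
recovered abundance.  Consequently, a between-group change in a genus's
*abundance* masquerades as a change in its *richness* whenever richness is
compared naively — including via asymptotic estimators such as Chao1 and
ACE, which inherit the spurious clusters through their singleton and
doubleton counts.  `richtrend` estimates this technical accumulation trend
from within-genus data and uses it as a covariate (or offset) inside count
regressions, so that group contrasts on richness are read off *after* the
abundance-driven component has been absorbed.

## Trend model

For detected (genus g, sample j) cells, let n_gj be the observed sub-genus
richness and y_gj the recovered genus abundance.  The trend model is

    z_gj = log n_gj = kappa + f_R(log y_gj) + f_G(g) + eps_gj,
    eps_gj ~ N(0, sigma^2),

with:

* f_R — a cubic B-spline smooth of log abundance (interior knots at
  quantiles of the observed log y, at most 30), penalised by the exact
  integrated squared second derivative.  The basis is constrained to have
  zero mean over the data so kappa is identified.
* f_G — unpenalised per-genus offsets under a sum-to-zero constraint;
  genera with fewer than `min_points_per_genus` (default 3) detected cells
  contribute to f_R but receive no effect.
* lambda — chosen by generalized cross-validation over 40 log-spaced
  values spanning 1e-4–1e4 times a data-driven scale (trace ratio of the
  spline block's Gram matrix to the penalty); ties break toward the
  smoother fit.  Bootstrap refits freeze knots and lambda from the
  original fit and re-estimate coefficients only.

Genus effects are Wald-tested against zero using the sandwich covariance
with lambda treated as fixed, Benjamini–Hochberg adjusted, and *zeroed*
unless significant at `alpha_G` (default 0.05).  The fitted control is

    f_t(g, log y) = kappa + f_R(log y) + f_G(g) * retained(g),

evaluable at any genus (unseen genera get effect 0) and any abundance
(inputs are clamped to the observed log-y range; unpenalised polynomial
extrapolation of a B-spline outside its knots is numerically unsafe and no
observed data exists there anyway).  Cells with n_gj = 0 are excluded (log
of zero); no pseudo-count is added.  Natural logarithms are used
throughout.

A loess alternative pools all cells into a single `lowess` smooth (span
0.75 by default) with no genus effects and the same clamped evaluation
surface.  On simulated surveys without systematic genus effects the two
agree to < 0.1 RMS on the interior of the abundance range.

An interaction between genus and abundance (per-genus slopes) is
deliberately not part of the control; it is identifiable only for very
deeply sampled genera and the control's purpose is a shared technical
trend.

## Differential richness regressions

All models are log-link count regressions fitted by iteratively
reweighted least squares (deviance tolerance 1e-8, max 50 iterations;
convergence is typically reached within ten).

* **Genus-specific**: Poisson regression of n_gj on the design X plus the
  covariate f_t(g, log y_gj) with coefficient nu_g, over the samples where
  the genus is detected.
* **Sample-wide**: negative-binomial (NB2) regression of n_+j on X plus
  gamma * log Σ_{g detected} exp(f_t(g, log y_gj)); the technical term is
  the log of the summed per-genus technical contributions, which
  emphasises the dominant (abundant) genera.
* **Collections**: the same with the sum restricted to an arbitrary genus
  set; with the full set it reproduces the sample-wide model exactly.

NB dispersion is profiled by maximum likelihood on log-alpha (bounded
1e-8–10, method-of-moments start); when the profile hits the lower
boundary the fit falls back to Poisson.  Poisson variance is used for
genus-specific fits and NB for sample-wide/collection fits, reflecting
that sample-wide accumulations behave like continuous Poisson mixtures.

### The trend coefficient and collinearity (`nu_mode`)

nu_g (and gamma) are free coefficients in the model as written, and
`nu_mode='free'` fits them so.  However, the trend covariate is a
monotone function of log y_gj alone: in designs where recovered abundance
differs systematically between groups but varies little within groups
(e.g., equal sequencing depth everywhere), it is nearly collinear with the
group indicator, nu_g is unidentified, and the group contrast becomes
arbitrarily noisy.  The default `nu_mode='auto'` therefore computes the
covariate's variance inflation factor against the design and pins nu_g = 1
(offset mode) when VIF > 10, the standard collinearity rule of thumb.
Empirically nu_g ≈ 1 wherever it is well identified, so the offset is the
natural fallback.  `nu_mode='offset'` forces it.  The sample-wide and
collection models apply the same rule to gamma through their
`trend_mode` argument.

### Inference

Wald per-coefficient tests and normal 95% CIs are standard output, with BH
adjustment across genera in the all-genus tables.  For sample-wide and
collection models, bootstrap-t intervals are available: samples are
resampled with replacement stratified by design cell, the trend and the
GLM are refitted per resample, and the studentized pivot
(b* − b̂)/SE* supplies the interval endpoints.  The default interval is
the *symmetric* bootstrap-t (quantile of |t*|), which has better
finite-sample coverage than the equal-tailed construction at the modest
sample sizes typical of these designs; the equal-tailed variant is an
option.  More than 10% resample failures aborts with an error.  Fixed
seeds give bit-identical intervals.

### Asymptotic-estimator route

For comparison, the same contrasts can be run on Chao1/ACE estimates via
inverse-variance weighted least squares of log(estimate) with delta-method
standard errors (SE/estimate), so coefficients share the GLM fold-change
scale.  Zero and undefined estimator cells are dropped and counted.  Chao1
uses the classic form S_obs + f1²/(2 f2) with its asymptotic variance when
doubletons exist and the bias-corrected form otherwise; ACE uses the
standard coverage/CV construction (rare cutoff 10) with a delta-method SE
over the rare frequency counts.  ACE point estimates agree exactly with
R vegan's `estimateR`; the SE approximation differs from vegan's.

## Synthetic surveys

The simulator draws, per sample: a multinomial of size tau_j over all true
taxa (between-genus composition × within-genus profile, group-adjusted by
per-genus abundance and richness log-fold-changes); then per genus a
Poisson(alpha·y^beta) number of false taxa, identities uniform without
replacement from a per-genus pool of size M_g, each with one read plus a
small binomial extra, the reads being *moved off* the genus's true taxa
(multivariate hypergeometric) so sample depth and genus totals are
conserved exactly.  A creation mode that adds reads instead exists for
sensitivity analysis.  False counts therefore concentrate in the
low-frequency regime, per-genus false-taxon replicability falls as M_g
grows, and apparent within-genus accumulation steepens with alpha.

Default study conditions (chosen once): 60 genera, 30+30 samples, mean
depth 5e4 (fixed unless `depth_sigma` > 0), lognormal between-genus base
composition (sigma 1), geometric within-genus profiles (ratio 0.7), true
richness uniform on 8–25, alpha = 0.01, beta = 1, M_g = 200.  These
produce mean false-taxon counts of a few per genus per sample — enough to
confound naive comparisons strongly while keeping observed richness in a
realistic range.

What the simulator does **not** emulate: per-nucleotide error chemistry,
chimeras, taxonomy misannotation, compositional correlations between
genera, or overdispersed (e.g., Dirichlet-multinomial) biological
replicate variation.  Passing tests therefore demonstrate that the method
removes *abundance-driven spurious-taxa confounding under multinomial
sampling*, not that it is robust to every feature of real surveys.

## Verification study designs and sizes

The test suite's end-to-end checks use these sizes, chosen to give stable
Monte-Carlo estimates at desk scale:

* Confounding: 50 null-richness surveys at the default conditions with
  per-genus abundance LFCs uniform on ±ln 4; the naive Chao1 route's
  genus DR-vs-DA Pearson r exceeds 0.5 (observed ≈ 0.9) while the
  trend-controlled route stays below 0.2 in absolute value.
* Type-I error: 200 genus fits from the same generator; trend-controlled
  rejections at alpha 0.05 vs the naive route.
* Recovery: ln 2 richness spikes in 5 of 30 genera (even profiles, 40 true
  taxa per genus, alpha 2e-3, depth 3e4).  With additive false taxa the
  observed-richness fold change equals the true-richness fold change only
  when false counts are small relative to richness, which these conditions
  ensure; mean absolute bias ≈ 0.03–0.09.  Wald CI coverage is assessed on
  richness drawn from the genus model itself (200 fits), since
  mechanistically simulated richness is under-dispersed relative to
  Poisson (detection is a sum of near-degenerate Bernoullis) and Wald
  intervals are then conservative by construction.
* Bootstrap-t: 200 outer surveys (12 genera, 10+10 samples, depth 4000,
  B=199) under a true null sample-wide effect; empirical coverage ≈ 0.93.

`scripts/acceptance.py` re-runs the same computations at reduced replicate
counts and writes the numbers as JSON.

## Degenerate inputs and numerical choices

* Counts must be non-negative integers; relative abundances are rejected.
* Sample depth tau_j is computed from the full table before any filtering
  and frozen.
* Taxa without genus annotation are pooled into one pseudo-genus per
  parent family ("unassigned@Family") so depth conservation holds; a flag
  drops them instead.
* "Detected" means count > 0 exactly; no minimum-count filter.
* Trend fitting requires ≥ 10 detected cells with ≥ 10 distinct log-y
  values; genus models require detection in ≥ 5 samples.
* Genus models exclude samples where the genus is undetected; sample-wide
  models use all samples, with undetected genera simply absent from the
  per-sample technical sum.
* Separation in differential-abundance fits (a genus absent from an entire
  design level) is flagged, not estimated.

## Known limitations

* The trend control is shared across genera up to additive offsets; genera
  with genuinely different accumulation *shapes* are not separately
  modelled.
* The ACE standard error is a first-order approximation and can differ
  appreciably from other implementations when singletons dominate.
* The weighted regression on asymptotic estimates treats estimator SEs as
  known, ignoring their own sampling error.
* Tree-structured multiple testing across the taxonomy is not provided;
  BH within each coefficient family is.
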