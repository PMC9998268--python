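# Methods

## Data model

The unit of analysis is a per-transect presence-absence table per region
and survey wave. Occurrence records (one row per species × plot × year)
are collapsed so that a species recorded in any of a transect's plots
(roadside, 50 m, 100 m) counts as one presence there; a species' occurrence
frequency is its number of occupied transects. Distance-class subsetting
(e.g. roadside plots only) is available but the default pools all plots,
matching the main analysis setting.

Frequency filters use strict inequalities: the singleton filter removes
species recorded once in a region over all years; filters `f1`/`f2` keep
species with more than 5 / more than 10 occurrences per region over all
years; `f3` keeps species with more than 10 occurrences per region in both
the first and last survey year ("per region and year" is read as a
per-year requirement, and a species must satisfy it in the two years that
enter the shift computation). Regions retaining fewer than five species
after filtering are excluded and reported. Filter frequencies count
transect-level presences, consistent with the presence-absence collapse.

## Upper range limits and shifts

A species' upper elevational limit in a wave is the 90th percentile of its
occupied-transect elevations, computed by linear interpolation between
order statistics (R type-7, numpy `linear`). The convention matters — the
alternatives move limits by up to one inter-transect spacing — so it is
fixed and tested against independent rank arithmetic. With a single
occupied transect the limit is that elevation. The percentile tracks the
highest occurrence for scarce species while damping single outlier
occurrences for common ones, making shift estimates conservative.

The shift is `limit(t_last) − limit(t_1)` (positive = upslope), computed
only for species present in both waves; division by the interval gives
annual shifts. Regions surveyed three times use first vs last by default,
with a flag for the 5-year (second-wave) comparison. Each species carries a
regression weight equal to its summed occupied-transect count over the two
waves (minimum 2): limits of frequent species are less outlier-driven, so
they get more weight.

For cross-region models, elevations are centred and scaled (mean 0,
s.d. 1) within regions. The moments are taken from the region's surveyed
transect elevations — a design-based choice that is identical for every
species and wave; standardized shifts are then raw shifts divided by the
region scale.

## Shift models

* **Grand mean per region** — intercept-only weighted least squares on the
  shifts; the intercept is the frequency-weighted mean shift, with a
  t-based 95% confidence interval (residual variance `RSS_w/(n−1)`).
* **Elevation dependence per region** — weighted least squares of shift on
  initial limit. The *elevation-corrected* mean shift is this fit's mean
  response at the median of the region's surveyed elevations (a flag
  switches to the median of the species' initial limits); a value above
  zero means upslope shifts across most of the gradient.
* **Cross-region models** — random-intercept linear mixed models on
  standardized data, weighted by frequency: an intercept-only model for
  the overall (grand mean) shift, and a model with standardized initial
  limit as the only fixed effect for the elevation dependence.

The weighted least squares is implemented in closed form from the weighted
normal equations, because the null model refits the same two-parameter
regression 10,000 times per region and the batched form vectorizes across
replicates; statsmodels' WLS is used as an independent cross-check in the
test suite, never as the implementation.

The mixed models use the residual-variance weighting convention of
`lmer(weights=)` — observation *i* has residual variance `sigma^2 / w_i` —
which statsmodels' MixedLM does not expose, so the fitter is implemented
directly: the likelihood is profiled down to the single variance ratio
`tau^2/sigma^2`, each per-group solve uses the Sherman–Morrison identity,
and the ratio is optimized by a log-grid plus bounded scalar search with an
explicit boundary check at zero (singular fits are flagged, not hidden).
REML is used for reported estimates, plain ML when nested models are
compared by likelihood ratio. Degrees of freedom for t/F statistics are
Satterthwaite approximations computed from the finite-difference
information matrix of the restricted likelihood; the test suite verifies
estimates, standard errors, variances and df against lme4/lmerTest via
Rscript and against MixedLM in the unweighted case. Confidence intervals
on fixed effects are Wald-type with Satterthwaite df.

## Richness trends

Richness per region and wave is counted from singleton-filtered tables
(the filter is applied per region across all years before counting).
The trend over years since first survey uses
`richness ~ year + (1 | region)` vs `richness ~ 1 + (1 | region)`
(Gaussian, ML likelihood-ratio test, 1 d.f.; slope and s.e. reported from
the REML fit). Percentage change relative to the first wave is modelled
with the fixed intercept omitted — percent change is structurally zero at
year 0 — while keeping the region random intercept; its null model has no
fixed effects at all.

## The geometric-constraint null model

Given a region's observed `(initial limit, shift, weight)` triples and
gradient bounds `[min, max]`:

1. build a candidate vector of initial elevations — the surveyed transect
   elevations (default), 200 equally spaced values, or the observed
   initial limits;
2. for each species, truncate the candidates to the feasible set
   `{e : min ≤ e + shift ≤ max}` (for upward shifts this removes the top
   of the gradient, for downward shifts the bottom — the constraint is
   applied symmetrically);
3. draw each species' new initial elevation uniformly with replacement
   from its truncated set, keeping its shift and weight attached;
4. fit the same weighted regression of shift on (randomized) initial
   elevation and evaluate its fitted values on a fixed 100-point equally
   spaced grid spanning the gradient;
5. repeat `n_boot` times (default 10,000) and take pointwise 2.5%/97.5%
   quantiles as the 95% envelope.

The observed regression is evaluated on the same grid; the reported
quantities are the fractions of grid points above/below the envelope and
the elevation ranges where exceedance occurs. Any non-zero fraction is
flagged significant. This decision rule is pointwise and therefore
anticonservative as a familywise test; the output labels it as such, and
the calibration test targets the well-defined single-point coverage (the
fitted value at the gradient median escapes the pointwise 95% interval in
~5% of true-null datasets).

Two structural facts are worth knowing when reading the output. First,
because only initial elevations are randomized, every replicate's fitted
line passes through (replicate mean x, fixed weighted mean shift), so the
envelope pinches to near-zero width near the expected weighted centroid of
the feasible candidates and is widest at the gradient ends: the test is
most sensitive near mid-gradient. Second, under the constraint the
expected replicate slope is negative even for purely random shifts —
regression toward the mean plus the bounded domain — so a negative
observed slope alone is not evidence of elevation-dependent spread; only
the envelope comparison is.

Per-region RNG substreams are derived from the master seed and a CRC of
the region name, so adding or removing a region never changes another
region's draws.

## Synthetic data generator

The generator emulates the survey protocol: per region, 3 roads × 20
transects evenly stratified over a 500–2,000 m gradient (jitter 20% of the
spacing by default; 0 gives exact stratification), 2–3 waves 5 years
apart, ~40 species per region.

* **Introductions** are concentrated toward the gradient base (truncated
  exponential with scale 0.25 × extent); a species' initial upper boundary
  is its introduction elevation plus a Beta(2,2) fraction of the headroom,
  producing the nested pattern in which range size shrinks with
  introduction elevation.
* **Spread**: the true (continuous) upper boundary advances at
  `spread_rate` m/yr (a scalar, or a function of introduction elevation),
  clipped at the gradient top.
* **Occupancy** lives on the transect lattice: transects inside a species'
  band are occupied with probability 0.6 at first census; newly in-range
  transects are colonized with the same probability, and per-wave
  colonization (0.02) and extinction (0.05) probabilities add turnover.
  The minimal detectable limit shift therefore equals the inter-transect
  spacing, mirroring real surveys where large spacing blurs small shifts.

The ground-truth table records both the continuous boundary
(`true_shift`) and the 90th percentile of the continuously occupied band
(`true_q90_shift`). The two differ systematically: for base-anchored
ranges the q90 limit moves by 0.9 × the boundary shift, a bias the
estimator inherits by construction and which the recorded dual truth makes
quantifiable. A second generator places user-supplied shift vectors at
random constraint-respecting initial elevations with exact translation of
the occupied set, so realized shifts equal the supplied ones — the
construction used for null-model calibration.

What the generator does not emulate: observer error and taxonomic
turnover, spatial autocorrelation among neighbouring transects, dispersal
kernels beyond the occupied band, abundance dynamics, and climate-driven
range dynamics. Passing tests therefore demonstrate the statistical
machinery's correctness under the stated mechanism, not the ecological
fidelity of any particular field dataset.

## Numerical choices and degenerate inputs

* Quantiles: numpy `linear` interpolation everywhere (limits and envelope
  bounds alike).
* Weighted fits require positive finite weights, n ≥ 2 (intercept-only) or
  n ≥ 3 (slope); degenerate predictors (all x equal) are an error.
* Standardization refuses zero variance; the standardizer round-trips to
  1e-10.
* Truncation uses a 1e-9 tolerance at the bounds so candidates sitting
  exactly on a bound survive floating-point arithmetic.
* An empty feasible candidate set is an error — impossible for shifts that
  were observed within the same gradient.
* Null envelopes with fewer than 100 replicates trigger a warning
  (unstable quantiles); zero-shift inputs collapse the envelope onto the
  zero line.
* Mixed-model variance ratios are searched on log lambda in [-12, 8] and
  compared against the lambda = 0 boundary; Satterthwaite df fall back to
  the residual df if the information matrix is unusable (boundary fits).
* All file writes in the pipeline are atomic (temp file + rename);
  per-region analysis failures are isolated, reported in `failures.csv`,
  and do not abort other regions.

## Problem sizes in the validation suite

The statistical checks run at sizes chosen to make their assertions
meaningful while staying lightweight: 1,000 random instances for the
regression oracle; 500 constrained-random datasets (50 species, 60
transects, shifts N(0, 150 m), 1,000 replicates each) for envelope
calibration and the regression-toward-the-mean signature; 100 datasets for
the power analysis of low-elevation spread; 100 simulations for each
parameter-recovery check; an 11-region × 40-species survey for the
end-to-end run. Envelope replicate counts in validation use 1,000 rather
than the 10,000 production default; the pointwise quantiles they feed are
stable well below that.

## Known limitations

* The significance rule ("any non-zero fraction outside the envelope") is
  anticonservative; a familywise-corrected simultaneous band would be the
  principled extension and is deliberately out of scope.
* The q90 upper limit under-measures boundary shifts of base-anchored
  ranges by a factor ~0.9; with coarse lattices the combined quantile
  interpolation and contraction error can slightly exceed one
  inter-transect spacing for individual species.
* Abundance classes are carried through but unused beyond presence.
* Species names are opaque labels; no taxonomic reconciliation.
* Lower range limits and range sizes are not analysed (upper limits only).
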