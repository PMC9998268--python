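# upslope

Analysis pipeline for repeated surveys of non-native plant distributions
along mountain-road elevational gradients (MIREN-style resurveys: a few
roads per region, each stratified by elevation into ~20 transects of three
plots, recensused every 5 years).

The package answers two questions about such data:

1. **Is non-native species richness increasing?** Regional richness per
   survey wave is modelled with a random-intercept linear mixed model,
   `richness ~ years_since_first_survey + (1 | region)`, tested against the
   intercept-only model by likelihood ratio; the same on percentage change
   in richness with the fixed intercept constrained to zero.
2. **Are upper elevational range limits moving upslope — and faster than
   chance allows?** A species' upper limit in a wave is the 90th percentile
   of its occupied-transect elevations; its shift is `limit(t_last) −
   limit(t_1)`. Shifts are summarized per region by frequency-weighted
   regressions (intercept-only for the grand mean; `shift ~ initial_limit`
   for elevation dependence, evaluated at the gradient median), and across
   regions with weighted random-intercept mixed models on within-region
   standardized elevations.

The central methodological piece is a **geometric-constraint null model**.
On a gradient surveyed between `min` and `max`, a shift `d` is observable
only from initial limits `e` with `min ≤ e + d ≤ max`, and regression
toward the mean alone makes a negative shift-vs-initial-limit relationship
the default expectation. The null model keeps each species' observed
(shift, weight) pair, re-places it at an initial elevation drawn uniformly
(with replacement) from a candidate vector truncated to that feasible set,
refits the weighted regression, and repeats this 10,000 times; the
pointwise 2.5–97.5% quantiles of the replicate fitted values on a fixed
elevation grid form a 95% envelope. Observed fitted values outside the
envelope indicate elevation-dependent range shifts beyond the geometric
constraint. Three candidate-vector variants are provided: the surveyed
transect elevations (default), a 200-point equally spaced grid (less
conservative) and the species' own observed initial limits (more
conservative).

A synthetic survey generator with known ground truth (nested low-elevation
introductions, lattice occupancy, configurable upward spread and
colonization/extinction noise) serves as the test bed for every component.

## Worked example

Simulate one region (3 roads × 20 transects, 30 species, 20 m/yr upward
spread, three waves 2008–2018) and run the full analysis:

```sh
upslope simulate --seed 7 --out demo --n-species 30
upslope all --input demo/occurrences.csv --seed 7 --n-boot 2000 --out demo_out
```

prints the per-region shift table

```
region  n_species  interval_years  mean_shift  mean_shift_lo  mean_shift_hi  corrected_shift  ...      x_eval    slope
   R01         30              10  203.544143     178.111527     228.976758       208.606192  ... 1249.944972 -0.05499
```

and `demo_out/null_comparison.csv` holds the null-model verdict:

```
region,variant,n_boot,seed,prop_above,prop_below,significant,above_ranges,below_ranges
R01,surveyed,2000,7,0.21,0.0,True,911.4-1213.8,
```

Reading: species shifted their upper limits upslope by 203.5 m on average
over the 10-year interval (95% CI 178.1–229.0 m); corrected for elevation
dependence and evaluated at the gradient median (1250 m) the mean shift is
208.6 m. The observed regression lies above the null envelope over 21% of
the gradient (elevations 911–1214 m), so shifts at low-to-mid elevation
exceed what random shift placement under the geometric constraint can
produce — as expected, since this dataset was simulated with genuine
upward spread.

Every table is also written as CSV (richness, trend tests, per-species
shift records, cross-region mixed models, filter exclusions, and a run
manifest with seed and config hash). A YAML config file can replace the
flags (`upslope all --config analysis.yml`); CLI flags take precedence.

## Layout

| module | contents |
| --- | --- |
| `upslope.survey` | occurrence CSV reader, presence-absence collapse, frequency filters, survey designs |
| `upslope.limits` | 90th-percentile upper limits, shifts, within-region standardization |
| `upslope.wls` | closed-form weighted least squares (vectorized across bootstrap replicates) |
| `upslope.lmm` | weighted random-intercept mixed models (profiled REML/ML, Satterthwaite df) |
| `upslope.models` | grand-mean / elevation-corrected / cross-region shift models |
| `upslope.nullmodel` | constrained randomization, null envelopes, observed-vs-null comparison |
| `upslope.richness` | richness tables and trend tests |
| `upslope.simulate` | synthetic survey generator with ground truth |
| `upslope.pipeline`, `upslope.cli` | orchestration, config handling, `upslope` command |

See `docs/methods.md` for the statistical details and design choices.
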