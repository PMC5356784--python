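# Methods

## Partition model and concentration estimation

Digital PCR distributes template molecules across `n` droplets at limiting
dilution. Under ideal Poisson partitioning the number of copies in a droplet
is Poisson(λ), a droplet is positive iff it holds ≥ 1 copy, and the positive
count is Binomial(n, 1 − e^−λ). The maximum-likelihood inversion is
λ̂ = −ln((n − k)/n) for k positives; the concentration is λ̂ / V with V the
droplet volume in µl (default 1 nL per droplet, configurable because
instrument calibrations differ and the 5 copies/µl floor scales with it).

Counts are taken as the reader software exports them ("accepted" droplets,
treated as post-quality-filter); fluorescence gating, rain and volume
variability are upstream of this package and out of scope.

### Confidence interval

The vendor software reports a "Poisson-based 95% CI" without publishing its
formula. We use the delta-method normal interval on the log of λ̂:

    var(λ̂) = (1 − p̂_neg) / (n · p̂_neg),  p̂_neg = (n − k)/n
    CI = λ̂ · exp(±z_{0.975} · sd(λ̂)/λ̂)

The log transform keeps bounds strictly positive and geometric about λ̂,
which matters at the low concentrations typical of FFPE extractions. The
test suite validates the interval two ways: against a parametric-bootstrap
percentile interval at (n, k) = (15000, 74), and by empirical coverage —
over 2,000 simulated wells at 50 copies/µl the interval covers the truth at
95.1% (long-run value estimated at 4·10⁵ wells; a 2,000-well run has a
binomial standard error of ±0.5%).

### Degenerate wells

A well with zero positives carries only an upper bound; we report
concentration 0 with the exact one-sided bound from P(no positives | λ) = α
and a `zero_positive` flag. An all-positive well is `saturated`: the point
estimate is unbounded and only the analogous lower bound is reported.
Neither is a hard error because pooling additional wells can rescue such
samples. `estimate_lambda`/`lambda_ci` themselves raise on degenerate input
so that silent misuse is impossible.

### Well merging

Replicate wells of one sample and channel are pooled by summing counts —
exact under the Poisson model (a merged well is one well with more
droplets) — shrinking interval widths as 1/√(total droplets). Merging
across samples or channels is an error.

## CNV and the duplication call

CNV = 2 · c_target / c_reference (diploid normalization). For the interval
we treat the channels as independent and add delta-method variances on the
log scale: var(ln ratio) = var(ln λ̂_t) + var(ln λ̂_r), CNVmin/max =
CNV · exp(∓z·sd). A conservative alternative — dividing opposite
per-channel CI bounds (`ci_method="bound_ratio"`) — is provided since the
original instrument's propagation is unpublished; the log-delta method is
the default because it has the nominal, not inflated, coverage (verified by
the fraction-recovery test).

Calling rules, in priority order:

1. Saturated channel → inconclusive, `saturated_well`.
2. Either channel < 5 copies/µl → inconclusive, `low_target_conc` /
   `low_reference_conc`. The floor is applied to both channels (the ratio
   is meaningless if the reference fails to amplify).
3. CNV > 2.25 **and** CNVmin > 2 → duplicated. Both inequalities are
   strict, matching the published wording ("above").
4. Exactly one cutoff passed → inconclusive with `borderline` — never
   non-duplicated, since the published workflow re-tested such samples with
   more material.
5. Otherwise non-duplicated; CNVmax < 2 with adequate DNA adds
   `possible_deletion` (with inadequate DNA nothing is claimed about
   deletion), CNVmax < 1.5 adds `low_cnv_artefact` (low CNVmax was shown by
   RNA-seq to be an artefact rather than a fusion signature).

The tumor-fraction inverse assumes a single monoallelic-duplication clone:
target copies per cell 2 + f against a diploid reference, so f =
clamp(CNV − 2, 0, 1). Multi-allelic or subclonal mixtures are out of scope.

## Synthetic data generator

The study's per-well counts are not publicly deposited, so the generator
stands in for them with known ground truth. It emulates:

* **Partitioning**: positives ~ Binomial(n, 1 − e^(−cV)) — pure binomial
  thinning, no droplet-volume CV (the quantification model itself assumes
  ideal partitioning).
* **Droplet counts**: drawn log-uniformly over the instrument's observed
  range 7,177–47,840 per well unless fixed; only the range and median of
  the real distribution are known, so nothing finer is claimed. Both
  channels of a well share one droplet count (one emulsion, two colors).
* **Biology**: target concentration = reference · (2 + f)/2, with f = 0
  for non-duplicated samples and f ~ U(0.75, 1) for duplicated ones,
  matching the observed duplicated CNV band (2.75–3) versus the
  non-duplicated band (1.75–2.25).
* **FFPE effects**: a shared `degradation` factor in (0, 1] scales both
  channels (amplifiable-fraction loss — moves samples across the
  conclusiveness floor but leaves CNV unbiased), and a target-only
  `channel_imbalance` factor injects the low-CNV artefact; it defaults to 1
  and exists to exercise the deletion/artefact flags.
* **Cohort**: 12 DNT, 2 PTO, 3 PDA, 14 GG, 5 PA with duplication confined
  to DNT at prevalence 5/12. The duplicated count per group is
  deterministic (round(prevalence·n); assignment randomized) so the default
  cohort has exactly 5 duplicated samples. Reference concentrations are
  log-uniform over 2–200 copies/µl, spanning sub-threshold to
  well-amplifying FFPE extractions — chosen so a realistic minority of
  samples lands below the 5 copies/µl floor.

What passing simulator-based tests does **not** show: robustness to droplet
volume variation, PCR inhibition, rain/threshold misgating, reference-region
CNVs, or inter-assay drift — none of which the generator models.

## Cohort analysis

The packaged `table1.csv` transcribes the 36-sample clinical series.
Summaries are pure functions of it: per-diagnosis duplication counts (the
one inconclusive DNT counts in the denominator, not the numerator, giving
5/12 = 41.7%), BRAF V600E carriers, FGFR1 missense carriers (point
mutations are parsed from free text; same-residue substitutions such as
L548L are silent and never counted as alterations), the MAPK-alteration
fraction (union of BRAF V600E, duplication, and missense mutation), and
the BRAF/FGFR1 exclusivity overlap.

Association testing uses Fisher's exact test on the 2×2 DNT-vs-rest table
and the chi-square test on the 5×2 per-diagnosis table, each with the
inconclusive sample either excluded (default, n = 35) or counted as
non-duplicated — the original analysis does not record which convention
produced its p-value, so both are exposed rather than asserting one. No
multiple-testing correction is applied (two planned tests, reported
unadjusted). The suite cross-checks Fisher p-values against a full
hypergeometric enumeration oracle.

## Numerical and interface choices

* All computation in double precision; CSV serialization at 6 significant
  digits so identical runs are byte-identical (write→read→write is a
  fixpoint; the read-back values, not the full-precision ones, are the
  published artifact).
* z-quantiles from scipy; α ∈ (0, 1], with α = 1 degenerating to a
  zero-width interval.
* Problem sizes in the test and acceptance runs — 2,000 wells for CI
  coverage, 500 replicates per setting for fraction recovery and interval
  shrinkage, 200 instances for the likelihood-oracle grid — are sized to
  give standard errors comfortably inside the asserted tolerances while
  keeping the whole suite in the seconds-to-minutes range.
* The sklearn-estimator surface (`PoissonQuantifier`, `DuplicationCaller`)
  has no learned state; `fit` validates inputs and freezes the threshold
  configuration. It exists for composability (get_params/clone/pipelines),
  while the underlying functions remain directly importable.

## Known limitations

* The CI and CNV-propagation formulas are principled stand-ins for the
  instrument vendor's unpublished ones; absolute agreement with vendor
  output is expected only to delta-method accuracy.
* Calls at concentrations just above the 5 copies/µl floor have wide
  intervals and will frequently be borderline; the package reports them as
  inconclusive rather than guessing.
* The exact criterion that left the single published inconclusive sample
  unresolved is not recoverable; the borderline rule is an inference
  consistent with its description.
* Duplex only (two channels); higher-order multiplexing and
  fusion-detection are out of scope.
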