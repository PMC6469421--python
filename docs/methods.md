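# Methods

This note documents the statistical machinery, the numerical choices, and
what the synthetic trials do and do not emulate.

## Stage-wise pipeline

The package works in two stages, as multi-environment trial analyses
usually do.

**Stage one** operates within a site-year (one breeding cycle × one managed
treatment). Each agronomic trait and each hyperspectral band is adjusted
for the α-lattice design by the linear mixed model with fixed genotype and
random trial / replicate-in-trial / block-in-replicate effects, all i.i.d.
with scalar variances. Sum-to-zero genotype coding is used, and BLUEs are
reported as intercept + genotype effect so they stay on the trait scale.
Traits scored in a single replicate (days to heading and maturity) drop the
replicate and block terms; with one plot per line the model is nearly
saturated, and the engine falls back to ordinary least squares if the
residual degrees of freedom vanish. A lodging covariate (the ordinal 0–5
score entered linearly) is added only in site-years where lodging was
actually observed. Validation BLUPs come from the same model with genotype
random, optionally with the line-level heading date as a fixed covariate
("heading-corrected" validation); models are trained on uncorrected BLUEs
in either case, and a corrected-training mode is available by passing the
covariate to the BLUE fit.

Band means pooled over several phenotyping dates (a growth stage, or ALL
dates) add a random time-point effect, with trial/replicate/block labels
nested inside the date. Growth stages are defined from the site-year's own
phenology: a date is VEG while fewer than half of the lines have headed,
HEAD until all have headed, GF until all have matured. Fractions are
computed over lines (phenology is scored on one replicate, i.e. one plot
per line). Dates after full maturity raise an error in strict mode and are
labelled GF with a warning otherwise.

**Stage two** predicts the per-site-year GY BLUEs from kernels. Fixed
effects are an intercept plus drop-first site-year means (omitted when a
single site-year is analysed — the parameterization does not affect
predictions). Random terms are built by expanding a genotype-level kernel
to the record level: `main` (Z K Z′), `gxe` (Hadamard with the site-year
indicator, giving exact zeros between site-years), or `block_h`
(block-diagonal assembly of per-site-year spectral kernels).

## Kernels

* **G** — VanRaden method 1 on post-QC, mean-imputed dosages; allele
  frequencies are taken from the observed post-QC data. QC removes markers
  with more than 70% missing calls, then markers with minor allele
  frequency below 0.05; each marker is counted under exactly one removal
  reason. Imputed values are real numbers, never re-rounded.
* **A** — numerator relationship by the tabular method over the
  topologically sorted pedigree. Founder diagonals are 1 + f₀ with
  configurable founder inbreeding f₀ (0 by default; 1 for fully inbred
  lines, giving the diagonal of 2 expected for inbred wheat). Unknown
  parents contribute zero.
* **H** — SS′/nbands per site-year, with each band column centred and
  scaled to unit *sample* standard deviation (n−1). The divisor is the
  count of retained bands; constant bands are dropped with a warning
  rather than producing division by zero. The n−1 choice only rescales H
  globally (prediction ranks are invariant) and is configurable (ddof=0).
  With all bands retained, trace(H) = n − 1 and H·1 = 0 exactly.

## REML engine

One engine backs everything: `y = Xb + Σ Z_m u_m + e` with `u_m ~ N(0,
σ²_m I)`. Arbitrary PSD kernels enter through the factorisation
`Z = U D^{1/2}` from a truncated eigendecomposition (eigenvalues below
1e-10 of the largest are discarded), which also handles rank-deficient
spectral kernels (nbands ≪ n). All per-iteration quantities — solutions,
log-likelihood, score, average-information matrix, EM updates — are
computed from Henderson's mixed-model equations, so the iteration cost is
O((p+q)³) rather than O(n³); the design cross-products are computed once
and shared across the 62 bands of a site-year, with warm-started variance
components from band to band.

Updates are average-information steps with step-halving, falling back to
the (guaranteed-ascent) EM update whenever the AI candidate leaves the
parameter space or lowers the restricted likelihood. Components that reach
the zero boundary with a negative score are pinned there and dropped from
the AI system, and candidates are projected into a box with ceiling
1e3 × var(y) to stop drift along flat likelihood ridges (an unidentifiable
component otherwise wanders; with the study design, trial variance is only
identifiable because repeated checks link trials). Convergence requires a
relative log-likelihood change below 1e-8 and a maximum component change
below 1e-6 × var(y); boundary components are reported and flagged.

## Gibbs sampler

The Bayesian back end samples each kernel term in its eigenbasis: with
C = U D U′ and effects a ~ N(0, σ²_m D), the full conditional of a is
diagonal, so a sweep costs one matrix-vector product per term. Variances
get scaled-inverse-χ² updates with 5 prior degrees of freedom and scales
set so each term's prior mode equals var(y_train)/(number of variance
terms) — the common default convention of the Bayesian GBLUP software
family. Fixed effects use a flat prior; missing responses are imputed from
their conditional distribution each sweep, which keeps the eigenbasis
orthogonal. Defaults are 10,000 iterations, 2,000 burn-in, thinning 5, and
a fixed seed; the batteries in the test-suite and acceptance script use
shorter, validated chains (≈2,000/500) because their record counts are
small and posterior means stabilise quickly — chain settings are reported
alongside every result. Predictions are posterior means of the systematic
part μ + E_i + Σ u. A zero kernel contributes nothing (its variance reverts
to the prior); non-PSD kernels (beyond 1e-6 relative jitter) are rejected.

Gibbs and REML predictions agree to r > 0.99 on single-kernel data; the
REML path is also used where closed-form checks matter (fixed-variance
fits match a dense Henderson solve to 1e-8).

## Cross-validation

Partitions are deterministic functions of (scheme, focal unit, replicate,
master seed), derived through CRC-hashed `SeedSequence`s, and are reused
across every model in a battery so comparisons are paired. Training
fractions use floor(p·n) (with an epsilon guard against binary-float
artefacts of 1 − 0.8). Check lines recur across cycles and would leak
across-cycle information, so they stay in the training set and are never
sampled into the test set (configurable). Undefined correlations (constant
test predictions) are recorded as missing, not zero. Model/unit
combinations that lack a required spectral stage are reported absent with
a reason rather than failing the battery.

## Synthetic trials

The generator emulates: biparental full-sib families (2 sibs/family) of
partially inbred lines (4 selfing generations) from a founder pool; an
α-lattice layout with 3 replicates and 6 blocks per replicate and two
repeated check lines in every replicate of every trial (the checks provide
the across-trial connectivity the real design relies on); additive
breeding values from marker effects, rescaled to σ²_g = 0.2 (t/ha)²;
marker-driven, treatment-correlated G×E deviations (so interaction effects
are themselves heritable — an i.i.d. deviation would make interaction
kernels uninformative by construction); treatment-specific mean yields and
heading dates with a configurable heading–yield genetic correlation; and
multi-date band reflectances composed of a smooth spectral baseline, date
offsets, stage-weighted loadings on breeding value and interaction
deviation (later stages carry more yield signal), a heading-date loading,
small design effects, band-correlated plot noise, and a persistent
line-level spectral deviation. That last term is essential: plot noise
averages out over replicates and dates, so without a line-level component
the spectra become a near-perfect oracle for genetic merit, which real
reflectance data are not.

Default variances (σ²_t = 0.10, σ²_r = 0.05, σ²_b = 0.05, σ²_e = 0.257
giving entry-mean H² ≈ 0.7 at 3 replicates; treatment means 2–6 t/ha,
heading means 62–80 days) are chosen to sit inside the ranges typical of
irrigated/stress wheat trials. Named scenarios fix the study conditions
used by the tests: `baseline` (4 cycles × 5 treatments, 100 lines/cycle),
`strong_gxe` and `phenology_confounded` (2 cycles × 3 treatments,
300 lines, inflated interaction or heading loadings), and `missing_stage`
(one cycle lacks all vegetative-stage dates). Problem sizes in the tests
and the acceptance script (e.g. 12 lines/trial in the design-variance
recovery, 5 partitions in the batteries) are desk-scale choices that keep
the full pipeline re-runnable in minutes while leaving every estimate
comfortably identified.

What passing tests do **not** show about real data: the generator has no
spatial field trend, no lodging events, no atmospheric or calibration
artefacts in the spectra, no dominance or epistasis, and its pedigree is
exactly two generations deep. Accuracy levels on synthetic data therefore
calibrate the machinery, not the agronomy; only the qualitative contrasts
(multi-kernel > single-kernel, spectral G×E > genomic G×E under strong
interaction, heading-correction drop for spectral models) are designed to
transfer.

## Known limitations

* No spatial (row–column / AR1) adjustment at the plot level.
* Single-trait models only; bands are fitted independently.
* The record-level kernels are dense; thousands of site-year × genotype
  records are fine, hundreds of thousands are not.
* EM-REML on multi-kernel models can be slow when two kernels are nearly
  proportional (a flat ridge); the sampler is the more robust default
  there.
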