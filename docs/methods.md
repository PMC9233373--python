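# Methods

This note records the statistical models the package implements, the
defaults and why they were chosen, what the synthetic cohort generator does
and does not emulate, and the numerical conventions a maintainer would
otherwise have to reverse-engineer.

## Scales and transforms

Methylation is carried as beta values β ∈ [0, 1] (fraction methylated) for
reporting, region summaries, deconvolution and the risk score, and as
M-values `M = log2(β/(1−β))` for modelling, where the variance is closer to
constant across the range. Betas are clipped to `[ε, 1−ε]` with ε = 1e-3
before the log transform so M stays finite at β ∈ {0, 1}; within that range
the round trip is exact. Missing measurements propagate as missing and are
excluded per-CpG from fits; a CpG with fewer than two usable samples in
either timepoint is skipped with a logged reason.

## Preprocessing

* **Detection filter.** A measurement fails when its detection p ≥ 0.05; a
  site is removed iff strictly more than 75% of its measurements fail.
  Both knobs are exposed because the underlying rule is stated ambiguously
  in the array literature; the strict-inequality reading is implemented.
* **Type-II peak correction.** Per sample, the unmethylated (M < 0) and
  methylated (M > 0) density modes of each probe chemistry are located by
  Gaussian KDE (Silverman bandwidth, 512-point grid on [−8, 8]) and type-II
  M-values are rescaled by peakI/peakII on each side of zero. M = 0 is a
  fixed point and type-I probes are untouched, bit for bit.
* **Quantile normalization.** Every column is mapped onto the across-sample
  mean quantile function (ties receive the mean of the tied reference
  values; missing values rank among the non-missing, with interpolation
  between quantile grids of unequal length). The operation is idempotent.
* **Order of operations**: detection filter (β) → peak correction (M) →
  quantile normalization (β) → M for modelling. The source protocols list
  the steps but not the scale of each; these choices are the package's.

## Differential methylation

The two-timepoint design with partially paired patients is handled by the
consensus-correlation approximation rather than a per-CpG mixed model:

1. Per CpG, the intra-patient correlation is estimated by REML — the
   profile restricted likelihood over ρ is evaluated on a 0.01-step grid
   (blocks have size ≤ 2, so the whitening algebra is closed-form and fully
   vectorized across CpGs) — and pooled as `tanh(trim_mean(atanh(ρ_g), 0.15))`.
   The 15% trim is the convention of the standard array tooling.
2. Each CpG is fit by GLS with correlation ρ inside patient blocks and 0
   elsewhere. Unpaired samples are singleton blocks, which is how the
   partially paired cohort gains power over a paired-only analysis. The
   solution agrees with an explicit dense-covariance solve to 1e-8.
3. Empirical-Bayes moderation: the prior (d₀, s₀²) is fit by matching the
   mean and variance of log s_g² to the scaled-F model
   (digamma/trigamma moment equations, Newton inversion of the trigamma).
   If the observed spread does not exceed chi-square sampling noise, d₀ = ∞
   and the prior is the pooled df-weighted variance, so identical input
   variances are returned unchanged. Moderated t uses d_g + d₀ degrees of
   freedom.
4. BH step-up adjustment; sites with adjusted p < α (default 0.01) are
   called, with direction gain/loss by the sign of Δ = post − pre. That
   sign convention holds everywhere in the package: "loss after treatment"
   is a negative effect.

Covariates (age, treatment arm) are deliberately not in the model; the
design has timepoint only, with patient as the random effect, and subgroup
analyses re-run the full pipeline inside each subgroup.

## Region context and the toward-normal statistic

Regions are the cross of genomic context (promoter, gene body, intergenic)
and island status (CGI, non-CGI); proportions divide significant gain/loss
counts by *all* array sites in the region. The toward-normal statistic
compares group-mean betas: a significant site counts toward normal iff
|mean_post − μ_normal| < |mean_pre − μ_normal|, with ties counting as
not-toward (conservative) and group means taken over the same subgroup the
significant set came from. Mean-level rather than per-sample distances are
used; the alternative is not identifiable from the source description.

## Enrichment

A gene is significant when ≥ 1 of its CpGs is significant in the given
region × direction stratum. The probe-count bias — genes with more probes
are more likely to be hit by chance — is estimated by isotonic regression
of the significance indicator on log probe count; weights are the fitted
probabilities normalized to mean 1 and floored at 1e-3. The null resamples
significant-gene sets of the observed size without replacement with
probability ∝ weight (Gumbel top-k, vectorized), and
p = (1 + #{null ≥ obs}) / (1 + n_perm), which can never be zero. With
uniform weights this converges to the hypergeometric tail, which is the
test-suite oracle. FDR is per analysis panel (one region × direction),
matching "each analysis" semantics; top-k terms are sorted by
(fdr, p, name) for a deterministic tie order.

## Deconvolution

Fractions solve min Σ|β − S f| s.t. f ≥ 0, Σf ≤ 1 (least absolute
deviations, matching the reference-based methylation deconvolution family),
as a linear program, then are renormalized to relative fractions f/Σf. The
pre/post comparison is an *unpaired* Wilcoxon rank-sum per cell type — a
faithful-reproduction choice even though the design is partially paired —
with exact enumeration up to 12 pooled observations (correct under ties)
and the tie-/continuity-corrected normal approximation beyond.

## Risk score

Predictors are Δβ = β_post − β_pre for the 47 fully paired patients over
the significant survivor-comparison sites; the outcome is death within five
years. Per left-out patient, an L1-penalized logistic regression is fit
with columns standardized inside the training fold (coefficients mapped
back to the raw Δβ scale so frozen models transfer), penalty chosen on a
17-point grid by inner 5-fold stratified CV deviance under the
one-standard-error rule. CV-minimum was tried first and systematically
overselects — the classic prediction/selection tradeoff — so the sparser
1-SE convention is used. The final model keeps CpGs nonzero in > 80% of
the leave-one-out fits with the mean of their nonzero coefficients;
discovery risk groups are the held-out predicted class at probability 0.5
(ties high), external cohorts split at the median score (ties low; an
all-identical score vector is an error, not a silent split). The logistic
family is a choice — the binary 5-year outcome admits it naturally and the
source is silent.

Two structural facts about stability selection at this scale, found during
development and verifiable with the generator: (i) leave-one-out training
sets share 46/47 samples, so a noise column whose spurious correlation with
the outcome is a property of the *dataset* is selected stably — no
stability threshold can remove it while keeping true sites; at 1,000
candidates and n = 47 the expected maximal spurious correlation is ≈ 0.55,
so exact support recovery requires per-site true associations well above
that. (ii) Sites whose prognostic signal is a shared latent factor are
collinear in Δβ, and the LASSO splits selection among them. The generator's
causal-site design (below) reflects both.

## The synthetic cohort generator

Defaults reproduce the study conditions: 83 patients (47 paired, 8
pre-only, 28 post-only → 55 pre / 75 post samples), 2,000 CpGs, α = 0.01.

* **Methylation model.** Baseline M per CpG is bimodal by island status
  (CGI ≈ N(−2.5, 0.7), non-CGI ≈ N(2.0, 0.7)). Each (CpG, patient) has a
  random intercept with variance share `intra_patient_correlation`
  (default 0.5) of the total noise `noise_sd_m` (default 0.5 M-units);
  residual noise fills the rest. Betas are the inverse-M transform, so the
  planted M-values are recoverable exactly.
* **Treatment effect.** `n_affected_cpgs` (default 300) sites shift in
  survivors' post samples only: negative at CGI sites, positive at non-CGI
  sites. Magnitudes are folded-normal with mean `effect_size_m` (default
  1.0) — or all equal to it with `effect_distribution="fixed"`, the setting
  used by recovery tests, since a folded normal places mass near zero and
  caps attainable sensitivity. Non-survivors receive no group-level shift.
* **Survival and causal sites.** Each patient carries one latent component
  per causal CpG; components share a common factor
  (`causal_component_correlation`, default 0.5) with unique variance, and
  the standardized mean is the latent risk u. Survival is exponential with
  log-hazard `hazard_coefficient`·u (default 1.2) over baseline 0.06/year,
  administratively censored at 10 years; death before 5 years defines the
  non-survivor group. Causal CpGs (default 4, drawn from the affected set,
  given mid-range baselines so a beta shift is expressible) shift each
  patient's post sample by their own component — zero-mean across patients,
  so they do not create a group-level pre/post change in non-survivors.
  Cohorts sharing a `structure_seed` share the planted structure (probe
  annotation, affected/causal identities, directions, magnitudes) while
  drawing new patients — that is how an independent validation cohort from
  the same generative law is produced.
* **Normal reference.** μ_normal is placed relative to the *observed*
  survivor group means: beyond the post mean in the direction of change for
  exactly `round(toward_normal_fraction × n_affected)` sites, mirrored on
  the far side of the pre mean for the rest. Clipping to [0, 1] cannot flip
  the classification, so the toward-normal statistic recovers the
  configured fraction exactly, noise and all.
* **Immune mixtures.** Per-patient Dirichlet fractions over seven cell
  types (regulatory-T mean ≈ 0.08); survivors' post samples have the
  regulatory-T fraction reduced by `treg_shift` (default 0.05) with the
  rest rescaled, so the noise-free survivor pre−post difference is exactly
  the shift. Mixture betas are the fraction-weighted signature plus
  truncated Gaussian noise (sd 0.02).

**What the generator does not emulate** — and hence what passing tests do
not show about real data: probe-specific chemistry artifacts beyond a
single multiplicative type-II mode compression; between-sample intensity
and batch effects (consequently, quantile-normalizing the artifact-free
synthetic data *injects* compensation artifacts when a sizable fraction of
sites truly shifts — the acceptance run therefore analyzes
detection-filtered betas, and the normalization steps are verified by their
own dedicated checks); tumor purity and copy number; correlated CpG blocks
(real 450k neighborhoods are strongly autocorrelated, which changes
multiplicity behavior); response-linked (as opposed to survival-linked)
effects; and non-exponential survival shapes.

## Problem sizes

The test suite and acceptance script run the differential engine at 2,000
CpGs × 83 (or 40) patients, risk-model recovery at 1,000 candidates × 47
patients, replicate-based survival checks at 300 CpGs × 10 replicates, and
enrichment oracles at 50,000 permutations on a 100-gene universe — sizes at
which every statistical behavior of interest (calibration, recovery,
separation) is already expressed.

## Known limitations

* The consensus-correlation GLS is an approximation to a per-CpG mixed
  model; it matches the behavior of the standard array tooling, not a full
  REML per site at test time.
* The final risk model may contain a few stable non-causal sites alongside
  the causal ones (see the stability-selection analysis above); the
  selection *frequencies* of planted causal sites, not set equality, are
  the tested guarantee.
* The rank-sum exact branch enumerates up to 12 pooled observations;
  beyond that the normal approximation is used even under heavy ties.
* `survival_at` extrapolates beyond the last observed time by carrying the
  last estimate forward, flagged as extrapolation.
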