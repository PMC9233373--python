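# nactmeth

DNA-methylation change in breast tumors during neoadjuvant chemotherapy
(NACT), and what it says about survival.

Locally advanced breast cancer is often treated with chemotherapy before
surgery, so paired biopsies — one before treatment, one at surgery — bracket
the therapy. `nactmeth` is a tested re-implementation of the analysis such a
paired 450k-array study requires, for epigenomics analysts who want each
stage as a reusable, validated library function rather than a one-off
script:

* **Paired differential methylation** on M-values,
  `M = log2(β/(1−β))`, with a *consensus intra-patient correlation*: a
  single correlation ρ shared across CpGs is estimated by per-CpG REML and
  pooled by a trimmed mean on the atanh scale, then each CpG is fit by
  generalized least squares with block-equicorrelated covariance (paired
  samples correlate at ρ, unpaired samples are singleton blocks — every
  sample contributes). Per-CpG variances are shrunk by empirical Bayes
  (moderated t with augmented degrees of freedom d_g + d₀), and
  Benjamini–Hochberg control calls sites at adjusted p < 0.01.
* **Genomic-region characterization**: gain/loss proportions across the six
  regions promoter/gene-body/intergenic × CpG-island/non-island, and a
  *toward-normal* statistic — the fraction of changed sites whose
  post-treatment group mean moved closer to a normal-tissue reference mean.
* **Gene-set overrepresentation** of significant CpGs, split by direction
  and region, with the per-gene probe-count bias corrected by a weighted
  permutation null (isotonic bias fit; exact-hypergeometric limit under
  uniform weights).
* **Reference-based immune deconvolution** by least-absolute-deviation
  regression of each sample onto a cell-type signature (linear program,
  f ≥ 0, Σf ≤ 1), with pre/post Wilcoxon rank-sum comparisons per cell
  type — including the regulatory-T-cell fraction.
* **A Δβ risk score**: for the patients with both timepoints, Δβ =
  β_post − β_pre over the significant sites enters a leave-one-out LASSO
  logistic regression on 5-year survival; CpGs with a nonzero coefficient
  in >80% of the leave-one-out fits form the final score
  R = Σⱼ wⱼ·Δβⱼ (wⱼ = mean nonzero coefficient). Discovery risk groups are
  the held-out class predictions; external cohorts are split at the median
  score.
* **Survival evaluation**: Kaplan–Meier product-limit curves, median
  survival (smallest t with S(t) ≤ 0.5), and the 1-df log-rank test.

Because the motivating study's patient data are not public, the package
ships a first-class **synthetic cohort generator** that reproduces the
study design — 83 patients, 55 pre- and 75 post-treatment samples, 47
complete pairs — with planted structure for every downstream claim:
survivor-specific island loss / non-island gain, a configurable
toward-normal fraction, survival times coupled to Δβ at a small causal CpG
set, and immune mixtures with a post-treatment regulatory-T decrease in
survivors. Every stage is tested against that ground truth or an
independent oracle.

## Worked example

```python
from nactmeth.synthetic_cohort import SimulationConfig, generate_cohort, generate_normal_reference
from nactmeth import preprocess, diffmeth, genome_context, risk_model, survival

cfg = SimulationConfig(n_cpg=500, n_affected_cpgs=80, effect_distribution="fixed", seed=43)
beta, detp, sheet, annot, truth = generate_cohort(cfg)

m = preprocess.beta_to_m(beta)
results = diffmeth.run_group_comparisons(m, sheet, beta=beta)
for name, table in results.items():
    print(f"{name}: {int(table['significant'].sum())} significant CpGs")

surv = results["survivor"]
sig = surv.index[surv["significant"]]
normal = generate_normal_reference(cfg, truth)
surv_ids = sheet.data.loc[sheet.data["survival_group"] == "survivor", "sample_id"]
toward = genome_context.toward_normal_fraction(beta, sheet.subset(surv_ids), sig, normal)
print(f"toward normal: {toward.n_toward}/{toward.n_evaluated} = {toward.fraction_toward:.3f}")

x = risk_model.build_delta_beta(beta, sheet, sig)
y = risk_model.build_outcome(sheet, x.index)
model, loo = risk_model.loo_lasso_select(x, y, seed=1)
print(f"risk score: {len(model.coefficients)} CpGs selected from {x.shape[1]} candidates")

groups = risk_model.assign_groups_loo(loo)
per_pat = sheet.data.drop_duplicates("patient_id").set_index("patient_id")
merged = groups.join(per_pat[["survival_time", "event"]])
hi, lo = merged[merged.group == "high"], merged[merged.group == "low"]
lr = survival.logrank_test((hi.survival_time, hi.event), (lo.survival_time, lo.event))
print(f"log-rank: chi2 = {lr.statistic:.1f}, p = {lr.p:.2e} ({len(hi)} high / {len(lo)} low risk)")
```

prints

```
survivor: 79 significant CpGs
non_survivor: 3 significant CpGs
partial_response: 78 significant CpGs
stable_disease: 63 significant CpGs
toward normal: 71/79 = 0.899
risk score: 31 CpGs selected from 79 candidates
log-rank: chi2 = 62.0, p = 3.49e-15 (19 high / 28 low risk)
```

Methylation change is found in 5-year survivors (79 of the 80 planted
sites; the 3 non-survivor calls sit at the risk-coupled causal sites),
~90% of changed sites moved toward the normal-tissue mean (the planted
fraction), and the Δβ risk score separates the leave-one-out risk groups'
survival decisively. The response-group comparisons reach significance here
only because survivors sit inside both response groups and the generator's
effect is survival-linked, not response-linked.

The same pipeline is scriptable from a shell:

```bash
nactmeth simulate --seed 1 --outdir cohort/
nactmeth run-all --seed 1 --outdir run/
nactmeth summary --samples cohort/samples.csv
```

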