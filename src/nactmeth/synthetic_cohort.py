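"""Synthetic cohorts with the statistical structure of a pre/post NACT
methylation study.

The generator emulates a design of 83 breast-cancer patients sampled before
and/or after neoadjuvant chemotherapy (47 complete pairs, 8 pre-only, 28
post-only → 55 pre- and 75 post-treatment samples), with:

* M-values drawn per CpG with a patient random intercept (variance share
  ``intra_patient_correlation``) plus residual noise, betas by inverse-M;
* a survivor-specific treatment effect at a planted set of "affected" CpGs
  — methylation loss at CpG-island sites, gain at non-island sites;
* a small set of "causal" CpGs whose post-treatment shift is proportional
  to a latent per-patient log-hazard, so the pre→post beta change carries
  prognostic signal;
* exponential survival times with log-hazard proportional to that latent
  risk, administratively censored at ``censor_time`` years (the study had
  ten years of follow-up); death within five years defines the
  non-survivor group;
* a normal-tissue reference mean placed so that an exact, configurable
  fraction of the affected CpGs moved *toward* normal during treatment;
* immune-cell mixtures over a reference signature with a post-treatment
  regulatory-T-cell decrease in survivors.

Everything is reproducible from ``SimulationConfig.seed``.  Ground truth
(planted directions, causal weights, latent risks, true fractions) is
returned alongside the data so every downstream stage can be tested.
"""

from __future__ import annotations

import dataclasses
import json
from dataclasses import dataclass, field
from typing import NamedTuple

import numpy as np
import pandas as pd

from .io_model import BetaMatrix, CpGAnnotation, DetectionPMatrix, SampleSheet
from .preprocess import m_to_beta

__all__ = [
    "SimulationConfig",
    "GroundTruth",
    "SyntheticCohort",
    "generate_cohort",
    "generate_normal_reference",
    "generate_immune_mixtures",
    "CELL_TYPES",
]

CELL_TYPES = (
    "B_cell",
    "CD4_T",
    "CD8_T",
    "NK",
    "monocyte",
    "neutrophil",
    "regulatory_T",
)
# Dirichlet concentration for per-patient immune mixtures; regulatory_T mean
# ≈ 0.08, in the range reported for solid-tumor infiltrates.
_IMMUNE_ALPHA = np.array([3.0, 5.0, 4.0, 2.0, 4.0, 3.0, 1.7])


@dataclass(frozen=True)
class SimulationConfig:
    """Parameters of the synthetic cohort.

    Defaults reproduce the study design: 83 patients of whom 47 are fully
    paired, 8 have only a pre-treatment and 28 only a post-treatment sample
    (55 pre / 75 post).  Effect sizes are on the M scale; ``effect_size_m``
    is the mean |ΔM| of the survivor-specific treatment effect (magnitudes
    follow a folded normal with that mean).
    """

    n_patients: int = 83
    n_pre_only: int = 8
    n_post_only: int = 28
    n_cpg: int = 2000
    fraction_cgi: float = 0.5
    n_affected_cpgs: int = 300
    effect_size_m: float = 1.0
    effect_distribution: str = "folded_normal"  # or "fixed" (all |ΔM| equal)
    noise_sd_m: float = 0.5
    intra_patient_correlation: float = 0.5
    n_causal_cpgs: int = 4
    causal_effect_m: float = 1.5
    causal_component_correlation: float = 0.5
    hazard_coefficient: float = 1.2
    baseline_hazard: float = 0.06
    censor_time: float = 10.0
    toward_normal_fraction: float = 0.9
    treg_shift: float = 0.05
    detection_fail_rate: float = 0.005
    type2_shrink: float = 1.0
    n_signature_cpgs: int = 200
    immune_noise_sd: float = 0.02
    seed: int = 0
    # cohorts sharing a structure_seed share the planted structure (probe
    # annotation, affected/causal CpG identities, directions, magnitudes)
    # while drawing new patients and noise from `seed` — this is how an
    # independent validation cohort from the same generative law is made
    structure_seed: int | None = None

    def __post_init__(self) -> None:
        if self.n_patients <= 0 or self.n_cpg <= 0:
            raise ValueError("n_patients and n_cpg must be positive")
        if self.n_pre_only < 0 or self.n_post_only < 0:
            raise ValueError("n_pre_only / n_post_only must be non-negative")
        if self.n_paired <= 0:
            raise ValueError("configuration leaves no paired patients")
        for name in ("fraction_cgi", "toward_normal_fraction"):
            v = getattr(self, name)
            if not 0 <= v <= 1:
                raise ValueError(f"{name} must be in [0, 1], got {v}")
        if not 0 <= self.intra_patient_correlation < 1:
            raise ValueError("intra_patient_correlation must be in [0, 1)")
        if not 0 < self.n_affected_cpgs <= self.n_cpg:
            raise ValueError("n_affected_cpgs must be in (0, n_cpg]")
        if self.n_causal_cpgs > self.n_affected_cpgs:
            raise ValueError("n_causal_cpgs must be ≤ n_affected_cpgs")
        if self.noise_sd_m <= 0:
            raise ValueError("noise_sd_m must be positive")
        if self.effect_distribution not in ("folded_normal", "fixed"):
            raise ValueError("effect_distribution must be 'folded_normal' or 'fixed'")
        if not 0 <= self.causal_component_correlation < 1:
            raise ValueError("causal_component_correlation must be in [0, 1)")
        if self.censor_time <= 0 or self.baseline_hazard <= 0:
            raise ValueError("censor_time and baseline_hazard must be positive")

    @property
    def n_paired(self) -> int:
        return self.n_patients - self.n_pre_only - self.n_post_only

    @property
    def pair_fraction(self) -> float:
        return self.n_paired / self.n_patients

    def to_dict(self) -> dict:
        return dataclasses.asdict(self)


@dataclass
class GroundTruth:
    """Planted structure of a generated cohort."""

    affected_direction: pd.Series  # cpg_id → ±1 (gain/loss in survivors)
    affected_magnitude: pd.Series  # cpg_id → |ΔM|
    causal_weights: pd.Series  # cpg_id → M-shift per unit risk component (signed)
    causal_components: pd.DataFrame  # patient × causal cpg_id latent components
    true_risk: pd.Series  # patient_id → latent log-hazard scale risk
    survival_time_uncensored: pd.Series  # patient_id → time before censoring
    survivor_mean_beta_pre: pd.Series  # affected cpg_id → survivor-group mean
    survivor_mean_beta_post: pd.Series
    normal_means: pd.Series | None = None
    immune_fractions: pd.DataFrame | None = None  # sample × cell type

    def to_json(self, path) -> None:
        out = {
            "affected_direction": self.affected_direction.to_dict(),
            "affected_magnitude": self.affected_magnitude.to_dict(),
            "causal_weights": self.causal_weights.to_dict(),
            "true_risk": self.true_risk.to_dict(),
            "survival_time_uncensored": self.survival_time_uncensored.to_dict(),
        }
        if self.normal_means is not None:
            out["normal_means"] = self.normal_means.to_dict()
        with open(path, "w") as fh:
            json.dump(out, fh, indent=1)


class SyntheticCohort(NamedTuple):
    beta: BetaMatrix
    detection_p: DetectionPMatrix
    sheet: SampleSheet
    annotation: CpGAnnotation
    truth: GroundTruth


def _make_annotation(cfg: SimulationConfig, rng: np.random.Generator) -> pd.DataFrame:
    n = cfg.n_cpg
    cpg_ids = [f"cg{i:07d}" for i in range(1, n + 1)]
    island = np.where(rng.random(n) < cfg.fraction_cgi, "CGI", "nonCGI")
    context = rng.choice(
        ["promoter", "gene_body", "intergenic"], size=n, p=[0.30, 0.45, 0.25]
    )
    n_genes = max(10, n // 6)
    gene_pool = np.array([f"GENE{i:05d}" for i in range(1, n_genes + 1)])
    gene = gene_pool[rng.integers(0, n_genes, size=n)]
    gene = np.where(context == "intergenic", "", gene)
    probe_type = np.where(rng.random(n) < 0.8, "II", "I")
    return pd.DataFrame(
        {
            "cpg_id": cpg_ids,
            "gene": gene,
            "genomic_context": context,
            "island": island,
            "probe_type": probe_type,
        }
    )


def _make_patients(cfg: SimulationConfig, rng: np.random.Generator):
    n = cfg.n_patients
    pids = [f"P{i:03d}" for i in range(1, n + 1)]
    design = np.array(
        ["paired"] * cfg.n_paired
        + ["pre_only"] * cfg.n_pre_only
        + ["post_only"] * cfg.n_post_only
    )
    rng.shuffle(design)

    # Latent risk is the standardized mean of one component per causal CpG.
    # Components share a common factor (correlation a) but each keeps unique
    # variance 1-a, so every causal site is individually prognostic and none
    # is a linear function of the others.
    k = cfg.n_causal_cpgs
    a = cfg.causal_component_correlation
    shared = rng.normal(size=n)
    v = np.sqrt(a) * shared[:, None] + np.sqrt(1.0 - a) * rng.normal(size=(n, k))
    u = v.mean(axis=1) / np.sqrt(a + (1.0 - a) / k)  # N(0,1) latent risk
    rate = cfg.baseline_hazard * np.exp(cfg.hazard_coefficient * u)
    t_true = rng.exponential(1.0 / rate)
    time = np.minimum(t_true, cfg.censor_time)
    event = (t_true <= cfg.censor_time).astype(int)
    group = np.where(t_true >= 5.0, "survivor", "non_survivor")

    # clinical covariates, rates from the published cohort table
    is_surv = group == "survivor"
    response = np.where(
        rng.random(n) < np.where(is_surv, 0.695, 0.458),
        "partial_response",
        "stable_disease",
    )
    treatment = np.empty(n, dtype=object)
    for idx in range(n):
        p = (0.42, 0.41, 0.17) if is_surv[idx] else (0.33, 0.25, 0.42)
        treatment[idx] = rng.choice(["epirubicin", "paclitaxel", "epitax"], p=p)

    patients = pd.DataFrame(
        {
            "patient_id": pids,
            "design": design,
            "true_risk": u,
            "t_true": t_true,
            "survival_time": time,
            "event": event,
            "survival_group": group,
            "response": response,
            "treatment": treatment,
        }
    )
    return patients, v


def generate_cohort(cfg: SimulationConfig) -> SyntheticCohort:
    """Generate (beta, detection-p, sample sheet, annotation, ground truth)."""
    rng = np.random.default_rng(cfg.seed)
    struct_seed = cfg.seed if cfg.structure_seed is None else cfg.structure_seed
    rng_struct = np.random.default_rng(np.random.SeedSequence([int(struct_seed), 331]))
    ann_df = _make_annotation(cfg, rng_struct)
    patients, causal_components = _make_patients(cfg, rng)

    # sample layout
    rows = []
    for _, p in patients.iterrows():
        tps = {"paired": ("pre", "post"), "pre_only": ("pre",), "post_only": ("post",)}[
            p["design"]
        ]
        for tp in tps:
            rows.append(
                {
                    "sample_id": f"{p['patient_id']}_{tp}",
                    "patient_id": p["patient_id"],
                    "timepoint": tp,
                    "survival_group": p["survival_group"],
                    "response": p["response"],
                    "treatment": p["treatment"],
                    "survival_time": p["survival_time"],
                    "event": p["event"],
                }
            )
    sheet_df = pd.DataFrame(rows)
    n_samples = len(sheet_df)
    n_cpg = cfg.n_cpg

    # baseline M per CpG: islands unmethylated, non-islands methylated
    is_cgi = (ann_df["island"] == "CGI").to_numpy()
    mu = np.where(
        is_cgi,
        rng_struct.normal(-2.5, 0.7, n_cpg),
        rng_struct.normal(2.0, 0.7, n_cpg),
    )

    # planted sites chosen up front; causal sites get mid-range baselines so
    # a treatment-induced shift is expressible on the beta scale (prognostic
    # delta-beta markers are by necessity in the dynamic range)
    affected_pos = rng_struct.choice(n_cpg, cfg.n_affected_cpgs, replace=False)
    causal_pos = rng_struct.choice(affected_pos, cfg.n_causal_cpgs, replace=False)
    causal_sign = rng_struct.choice([-1.0, 1.0], cfg.n_causal_cpgs)
    mu[causal_pos] = rng_struct.normal(0.0, 0.5, cfg.n_causal_cpgs)

    sd_b = cfg.noise_sd_m * np.sqrt(cfg.intra_patient_correlation)
    sd_e = cfg.noise_sd_m * np.sqrt(1.0 - cfg.intra_patient_correlation)
    pat_index = {pid: k for k, pid in enumerate(patients["patient_id"])}
    b = rng.normal(0.0, sd_b, size=(n_cpg, cfg.n_patients))
    m = mu[:, None] + b[:, [pat_index[p] for p in sheet_df["patient_id"]]]
    m = m + rng.normal(0.0, sd_e, size=(n_cpg, n_samples))

    # planted survivor-specific treatment effect: CGI loss, non-CGI gain
    direction = np.where(is_cgi[affected_pos], -1.0, 1.0)
    if cfg.effect_distribution == "fixed":
        magnitude = np.full(cfg.n_affected_cpgs, cfg.effect_size_m)
    else:  # folded normal with mean effect_size_m
        magnitude = np.abs(
            rng_struct.normal(
                0.0, cfg.effect_size_m * np.sqrt(np.pi / 2.0), cfg.n_affected_cpgs
            )
        )
    surv_post = (
        (sheet_df["survival_group"] == "survivor") & (sheet_df["timepoint"] == "post")
    ).to_numpy()
    m[np.ix_(affected_pos, surv_post)] += (direction * magnitude)[:, None]

    # causal CpGs: post-treatment shift proportional to that CpG's own
    # latent-risk component for the patient
    is_post = (sheet_df["timepoint"] == "post").to_numpy()
    pat_of_sample = np.array([pat_index[p] for p in sheet_df["patient_id"]])
    v_per_sample = causal_components[pat_of_sample, :]  # n_samples × k
    m[np.ix_(causal_pos, is_post)] += (
        causal_sign[:, None] * cfg.causal_effect_m * v_per_sample[is_post, :].T
    )

    if cfg.type2_shrink != 1.0:
        is_t2 = (ann_df["probe_type"] == "II").to_numpy()
        m[is_t2, :] *= cfg.type2_shrink

    m = np.clip(m, -9.0, 9.0)  # keeps betas invertible at epsilon = 1e-3

    cpg_ids = pd.Index(ann_df["cpg_id"], name="cpg_id")
    sample_ids = pd.Index(sheet_df["sample_id"])
    from .io_model import MValueMatrix

    beta = m_to_beta(MValueMatrix(pd.DataFrame(m, index=cpg_ids, columns=sample_ids)))

    # detection p: mostly well below 0.05, a small failing fraction
    detp = rng.uniform(0.0, 0.01, size=(n_cpg, n_samples))
    failing = rng.random((n_cpg, n_samples)) < cfg.detection_fail_rate
    detp[failing] = rng.uniform(0.05, 1.0, size=int(failing.sum()))
    detp_m = DetectionPMatrix(pd.DataFrame(detp, index=cpg_ids, columns=sample_ids))

    sheet = SampleSheet(sheet_df)
    annotation = CpGAnnotation(ann_df)

    affected_ids = cpg_ids[affected_pos]
    surv_ids = sheet_df.loc[
        (sheet_df["survival_group"] == "survivor"), ["sample_id", "timepoint"]
    ]
    bvals = beta.values
    mean_pre = bvals.loc[
        affected_ids, surv_ids.loc[surv_ids["timepoint"] == "pre", "sample_id"]
    ].mean(axis=1)
    mean_post = bvals.loc[
        affected_ids, surv_ids.loc[surv_ids["timepoint"] == "post", "sample_id"]
    ].mean(axis=1)

    truth = GroundTruth(
        affected_direction=pd.Series(direction, index=affected_ids),
        affected_magnitude=pd.Series(magnitude, index=affected_ids),
        causal_weights=pd.Series(
            causal_sign * cfg.causal_effect_m, index=cpg_ids[causal_pos]
        ),
        causal_components=pd.DataFrame(
            causal_components,
            index=patients["patient_id"],
            columns=cpg_ids[causal_pos],
        ),
        true_risk=patients.set_index("patient_id")["true_risk"],
        survival_time_uncensored=patients.set_index("patient_id")["t_true"],
        survivor_mean_beta_pre=mean_pre,
        survivor_mean_beta_post=mean_post,
    )
    return SyntheticCohort(beta, detp_m, sheet, annotation, truth)


def generate_normal_reference(
    cfg: SimulationConfig, truth: GroundTruth, all_cpg_ids=None
) -> pd.Series:
    """Place per-CpG normal-tissue means so that exactly
    ``round(toward_normal_fraction × n_affected)`` affected CpGs moved
    toward normal during treatment.

    "Toward" placement puts the normal mean beyond the survivor post-mean in
    the direction of change (|post − μ| = 0.5|Δ| < |pre − μ|); "away"
    placement mirrors it on the other side of the pre-mean.  Clipping to
    [0, 1] cannot flip the classification.  The result is stored on
    ``truth.normal_means`` and returned.
    """
    rng = np.random.default_rng(np.random.SeedSequence([int(cfg.seed), 104729]))
    pre = truth.survivor_mean_beta_pre
    post = truth.survivor_mean_beta_post
    n_aff = len(pre)
    n_toward = int(round(cfg.toward_normal_fraction * n_aff))
    toward_idx = rng.choice(n_aff, n_toward, replace=False)
    is_toward = np.zeros(n_aff, dtype=bool)
    is_toward[toward_idx] = True

    delta = post.to_numpy() - pre.to_numpy()
    mu = np.where(
        is_toward,
        post.to_numpy() + 0.5 * delta,
        pre.to_numpy() - 0.5 * delta,
    )
    mu = np.clip(mu, 0.0, 1.0)
    normal = pd.Series(mu, index=pre.index)

    if all_cpg_ids is not None:
        rest = pd.Index(all_cpg_ids).difference(pre.index)
        filler = np.clip(rng.uniform(0.05, 0.95, len(rest)), 0.0, 1.0)
        normal = pd.concat([normal, pd.Series(filler, index=rest)])
        normal = normal.loc[pd.Index(all_cpg_ids)]
    truth.normal_means = normal
    return normal


def generate_immune_mixtures(cfg: SimulationConfig, sheet: SampleSheet):
    """Immune reference signature, mixture betas, and true fractions.

    Per patient a base fraction vector is drawn from a Dirichlet; the
    survivor post-treatment samples have their regulatory-T fraction reduced
    by ``treg_shift`` (other fractions rescaled to keep the sum at 1), so
    the noise-free pre−post regulatory-T difference in survivors is exactly
    ``treg_shift``.  Mixture betas are the fraction-weighted reference
    profiles plus truncated Gaussian noise.
    """
    from .deconvolution import ImmuneReference

    rng = np.random.default_rng(np.random.SeedSequence([int(cfg.seed), 224737]))
    k = len(CELL_TYPES)
    n_sig = cfg.n_signature_cpgs
    if n_sig < 50:
        raise ValueError("need at least 50 signature CpGs")
    sig_ids = pd.Index([f"sig_cg{i:05d}" for i in range(1, n_sig + 1)])
    S = rng.uniform(0.05, 0.95, size=(n_sig, k))
    ref = ImmuneReference(pd.DataFrame(S, index=sig_ids, columns=list(CELL_TYPES)))

    treg_col = CELL_TYPES.index("regulatory_T")
    base: dict[str, np.ndarray] = {}
    for pid in dict.fromkeys(sheet.data["patient_id"]):
        f = rng.dirichlet(_IMMUNE_ALPHA)
        while f[treg_col] < cfg.treg_shift + 0.01:
            f = rng.dirichlet(_IMMUNE_ALPHA)
        base[pid] = f

    frac_rows = []
    for _, row in sheet.data.iterrows():
        f = base[row["patient_id"]].copy()
        if row["survival_group"] == "survivor" and row["timepoint"] == "post":
            new_treg = f[treg_col] - cfg.treg_shift
            scale = (1.0 - new_treg) / (1.0 - f[treg_col])
            f = f * scale
            f[treg_col] = new_treg
        assert abs(f.sum() - 1.0) < 1e-9, "fractions must sum to 1"
        frac_rows.append(f)
    fractions = pd.DataFrame(
        frac_rows, index=sheet.data["sample_id"], columns=list(CELL_TYPES)
    )

    mix = S @ fractions.to_numpy().T
    if cfg.immune_noise_sd > 0:
        mix = mix + rng.normal(0.0, cfg.immune_noise_sd, size=mix.shape)
    mix = np.clip(mix, 0.0, 1.0)
    mixtures = BetaMatrix(
        pd.DataFrame(mix, index=sig_ids, columns=fractions.index)
    )
    return ref, mixtures, fractions
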