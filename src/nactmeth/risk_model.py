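"""Δβ risk score by leave-one-out LASSO stability selection.

For every patient with both a pre- and a post-treatment sample, the
predictor is the per-CpG change in beta (Δβ = post − pre) over a candidate
set (by default the significant sites from the survivor comparison); the
outcome is death within five years.  One L1-penalized logistic model is fit
per left-out patient, with the penalty chosen by inner 5-fold
cross-validated log-loss under the one-standard-error rule (the sparser
conventional choice on a LASSO path).  CpGs whose coefficient is nonzero in
more than
80% of the leave-one-out fits enter the final score with the mean of their
nonzero coefficients; the score for a patient is the coefficient-weighted
sum of Δβ.  Discovery-cohort risk groups come from the held-out class
prediction (probability ≥ 0.5 → high risk); external cohorts are split at
the median score.

Columns are standardized inside each training fold (glmnet convention) and
coefficients mapped back to the raw Δβ scale, so a frozen model applies
directly to Δβ values of a new cohort.
"""

from __future__ import annotations

import json
import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from sklearn.linear_model import LogisticRegression
from sklearn.metrics import log_loss
from sklearn.model_selection import StratifiedKFold

from .io_model import BetaMatrix, SampleSheet, ValidationError

__all__ = [
    "RiskScoreModel",
    "build_delta_beta",
    "build_outcome",
    "loo_lasso_select",
    "apply_risk_score",
    "assign_groups_loo",
    "assign_groups_median",
]

logger = logging.getLogger(__name__)

_CS = np.logspace(-2.5, 1.5, 17)  # inverse-penalty grid for the inner CV


def _fit_l1(z, y, c, seed):
    clf = LogisticRegression(
        l1_ratio=1.0, C=c, solver="liblinear", max_iter=200, random_state=seed
    )
    return clf.fit(z, y)


def _choose_c_one_se(z, y, n_splits, seed):
    """Inner-CV penalty choice by deviance with the one-standard-error rule.

    Returns the strongest penalty (smallest C) whose mean cross-validated
    log-loss is within one standard error of the minimum — the sparser
    choice conventional for LASSO paths.
    """
    cv = StratifiedKFold(n_splits=n_splits, shuffle=True, random_state=seed)
    losses = np.zeros((len(_CS), n_splits))
    for f, (tr, te) in enumerate(cv.split(z, y)):
        for ci, c in enumerate(_CS):
            clf = _fit_l1(z[tr], y[tr], c, seed)
            p = clf.predict_proba(z[te])[:, 1]
            losses[ci, f] = log_loss(y[te], p, labels=[0, 1])
    mean = losses.mean(axis=1)
    se = losses.std(axis=1, ddof=1) / np.sqrt(n_splits)
    best = int(np.argmin(mean))
    threshold = mean[best] + se[best]
    return float(_CS[np.flatnonzero(mean <= threshold)[0]])


@dataclass
class RiskScoreModel:
    """Frozen Δβ risk score.

    ``coefficients`` maps selected cpg_id → mean nonzero LOO coefficient
    (raw Δβ scale); ``selection_frequency`` covers every candidate CpG.
    ``orientation`` records the Δβ sign convention so serialized models are
    portable.  An empty model (no CpG passed the stability threshold)
    scores every patient 0 and is flagged.
    """

    coefficients: pd.Series
    selection_frequency: pd.Series
    stability_threshold: float = 0.8
    orientation: str = "post_minus_pre"
    outcome: str = "death_within_5_years"
    n_loo_fits: int = 0
    n_skipped_fits: int = 0
    notes: list = field(default_factory=list)

    @property
    def is_empty(self) -> bool:
        return len(self.coefficients) == 0

    def to_json(self, path) -> None:
        out = {
            "coefficients": self.coefficients.to_dict(),
            "selection_frequency": self.selection_frequency.to_dict(),
            "stability_threshold": self.stability_threshold,
            "orientation": self.orientation,
            "outcome": self.outcome,
            "n_loo_fits": self.n_loo_fits,
            "n_skipped_fits": self.n_skipped_fits,
        }
        with open(path, "w") as fh:
            json.dump(out, fh, indent=1)

    @classmethod
    def from_json(cls, path) -> "RiskScoreModel":
        with open(path) as fh:
            d = json.load(fh)
        return cls(
            coefficients=pd.Series(d["coefficients"], dtype=float),
            selection_frequency=pd.Series(d["selection_frequency"], dtype=float),
            stability_threshold=d["stability_threshold"],
            orientation=d["orientation"],
            outcome=d["outcome"],
            n_loo_fits=d["n_loo_fits"],
            n_skipped_fits=d["n_skipped_fits"],
        )


def build_delta_beta(
    beta: BetaMatrix, sheet: SampleSheet, candidate_cpgs
) -> pd.DataFrame:
    """Patients × candidate-CpGs matrix of Δβ = β_post − β_pre.

    Only fully paired patients contribute rows; unpaired patients are
    excluded (and counted in the log).
    """
    candidates = pd.Index(candidate_cpgs)
    missing = candidates.difference(beta.cpg_ids)
    if len(missing):
        raise ValidationError(f"candidate CpGs absent from matrix: {missing[:5].tolist()}")
    paired = sheet.paired_patients()
    if not paired:
        raise ValidationError("no paired patients: cannot build delta-beta matrix")
    n_unpaired = len(sheet.unpaired_patients())
    if n_unpaired:
        logger.info("delta-beta: excluded %d unpaired patients", n_unpaired)
    rows = {}
    bv = beta.values
    for pid in paired:
        pre_id = sheet.pairing[pid]["pre"]
        post_id = sheet.pairing[pid]["post"]
        rows[pid] = (bv[post_id] - bv[pre_id]).loc[candidates]
    return pd.DataFrame(rows).T.rename_axis("patient_id")


def build_outcome(sheet: SampleSheet, patients) -> pd.Series:
    """Binary outcome: 1 = death within five years (non-survivor)."""
    per_patient = sheet.data.drop_duplicates("patient_id").set_index("patient_id")
    y = (per_patient.loc[list(patients), "survival_group"] == "non_survivor").astype(int)
    return y


def loo_lasso_select(
    x: pd.DataFrame,
    y: pd.Series,
    seed: int = 0,
    stability_threshold: float = 0.8,
    inner_folds: int = 5,
) -> tuple[RiskScoreModel, pd.Series]:
    """Leave-one-out LASSO logistic regression with stability selection.

    Returns the frozen model and the held-out predicted death probability
    per patient.  LOO training folds containing a single outcome class are
    skipped and counted.  Deterministic given ``seed`` (which shuffles the
    inner CV folds).
    """
    if len(x) < 10:
        raise ValidationError("need at least 10 paired patients")
    x = x[sorted(x.columns)]  # canonical column order → order-invariant fits
    y = y.loc[x.index].astype(int)
    if y.nunique() < 2:
        raise ValidationError("both outcome classes required")

    n, p = x.shape
    xa = x.to_numpy(float)
    ya = y.to_numpy()
    rng = np.random.default_rng(seed)
    nonzero_counts = np.zeros(p)
    coef_sums = np.zeros(p)
    coef_nonzero_fits = np.zeros(p)
    loo_pred = pd.Series(np.nan, index=x.index, dtype=float)
    n_fits = n_skipped = 0

    for i in range(n):
        train = np.ones(n, dtype=bool)
        train[i] = False
        y_tr = ya[train]
        if len(np.unique(y_tr)) < 2:
            n_skipped += 1
            logger.info("LOO fold %d skipped: single outcome class", i)
            continue
        x_tr = xa[train]
        mu = x_tr.mean(axis=0)
        sd = x_tr.std(axis=0, ddof=0)
        sd[sd == 0] = 1.0
        z_tr = (x_tr - mu) / sd

        n_splits = min(inner_folds, np.bincount(y_tr).min())
        if n_splits < 2:
            n_skipped += 1
            logger.info("LOO fold %d skipped: too few samples per class", i)
            continue
        fold_seed = int(rng.integers(0, 2**31 - 1))
        c_star = _choose_c_one_se(z_tr, y_tr, n_splits, fold_seed)
        clf = _fit_l1(z_tr, y_tr, c_star, fold_seed)
        w_std = clf.coef_.ravel()
        w_raw = w_std / sd
        nz = w_raw != 0
        nonzero_counts += nz
        coef_sums += np.where(nz, w_raw, 0.0)
        coef_nonzero_fits += nz
        z_test = (xa[i] - mu) / sd
        loo_pred.iloc[i] = float(clf.predict_proba(z_test[None, :])[0, 1])
        n_fits += 1

    if n_fits == 0:
        raise ValidationError("every LOO fold was skipped")
    freq = pd.Series(nonzero_counts / n_fits, index=x.columns)
    with np.errstate(invalid="ignore"):
        mean_nonzero = np.divide(
            coef_sums,
            coef_nonzero_fits,
            out=np.zeros(p),
            where=coef_nonzero_fits > 0,
        )
    selected = (freq > stability_threshold) & (mean_nonzero != 0)
    coefs = pd.Series(mean_nonzero, index=x.columns)[selected]
    model = RiskScoreModel(
        coefficients=coefs,
        selection_frequency=freq,
        stability_threshold=stability_threshold,
        n_loo_fits=n_fits,
        n_skipped_fits=n_skipped,
    )
    if model.is_empty:
        model.notes.append("no CpG passed the stability threshold; score is 0")
        logger.warning("empty risk model: no CpG passed stability threshold")
    return model, loo_pred


def apply_risk_score(model: RiskScoreModel, x: pd.DataFrame) -> pd.Series:
    """Risk score R_i = Σ_j w_j Δβ_ij for each patient row of ``x``."""
    if model.is_empty:
        return pd.Series(0.0, index=x.index, name="risk_score")
    missing = model.coefficients.index.difference(x.columns)
    if len(missing):
        raise ValidationError(f"cohort lacks model CpGs: {missing.tolist()}")
    scores = x[model.coefficients.index].to_numpy(float) @ model.coefficients.to_numpy()
    return pd.Series(scores, index=x.index, name="risk_score")


def assign_groups_loo(loo_pred: pd.Series) -> pd.DataFrame:
    """High risk iff held-out predicted death probability ≥ 0.5."""
    if loo_pred.isna().any():
        missing = loo_pred.index[loo_pred.isna()].tolist()
        raise ValidationError(f"missing LOO predictions for patients: {missing[:5]}")
    return pd.DataFrame(
        {
            "patient_id": loo_pred.index,
            "risk_score": loo_pred.to_numpy(),
            "group": np.where(loo_pred.to_numpy() >= 0.5, "high", "low"),
            "provenance": "loo_predicted",
        }
    ).set_index("patient_id")


def assign_groups_median(scores: pd.Series) -> pd.DataFrame:
    """Median-cutoff split for external cohorts: high iff score > median
    (ties at the median go low)."""
    if len(scores) < 2:
        raise ValidationError("need at least 2 patients for a median split")
    if scores.nunique() == 1:
        raise ValidationError("cutoff degenerate: all risk scores identical")
    med = float(scores.median())
    return pd.DataFrame(
        {
            "patient_id": scores.index,
            "risk_score": scores.to_numpy(),
            "group": np.where(scores.to_numpy() > med, "high", "low"),
            "provenance": "median_cutoff",
        }
    ).set_index("patient_id")
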