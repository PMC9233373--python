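"""Paired / partially-paired differential methylation on M-values.

The design mirrors the two-timepoint NACT study: every sample is pre- or
post-treatment, some patients contribute both timepoints.  Rather than a
full per-CpG mixed-model fit, the patient random intercept is handled the
way large methylation studies do it in practice:

1. a single *consensus* intra-patient correlation is estimated by
   restricted maximum likelihood per CpG and pooled by a trimmed mean on
   the atanh scale;
2. each CpG is fit by generalized least squares with a block-equicorrelated
   covariance (the consensus correlation within a patient, zero across
   patients; unpaired samples are singleton blocks);
3. per-CpG residual variances are shrunk toward a common prior estimated
   by empirical Bayes (method of moments on log variances), yielding
   moderated t-statistics with augmented degrees of freedom;
4. p-values are Benjamini–Hochberg adjusted; sites with adjusted p below
   ``alpha`` (default 0.01) are called differentially methylated.

The effect sign convention is Δ = post − pre throughout, so methylation
*loss* after treatment is a negative effect.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy.special import digamma, polygamma
from scipy.stats import t as t_dist
from scipy.stats import trim_mean

from .io_model import BetaMatrix, MValueMatrix, SampleSheet

__all__ = [
    "ConsensusCorrelation",
    "ModerationParams",
    "estimate_consensus_correlation",
    "fit_gls_per_cpg",
    "empirical_bayes_moderate",
    "bh_adjust",
    "run_comparison",
    "run_group_comparisons",
]

logger = logging.getLogger(__name__)

_RHO_GRID = np.round(np.arange(-0.90, 0.951, 0.01), 10)
_TRIM = 0.15  # trimmed-mean fraction for the consensus


@dataclass(frozen=True)
class ConsensusCorrelation:
    """Pooled intra-patient correlation."""

    consensus: float
    per_cpg: pd.Series
    n_cpgs_used: int


@dataclass(frozen=True)
class ModerationParams:
    """Empirical-Bayes variance-shrinkage parameters."""

    d0: float  # prior degrees of freedom (may be inf)
    s0_sq: float  # prior variance
    d_g: pd.Series  # residual df per CpG
    s_g_sq: pd.Series  # residual variance per CpG
    posterior_sq: pd.Series  # shrunken variance per CpG


# ---------------------------------------------------------------------------
# design helpers
# ---------------------------------------------------------------------------


def _design(sheet: SampleSheet, sample_ids) -> tuple[np.ndarray, np.ndarray]:
    """Design matrix (intercept + post indicator) and within-patient partner
    index for the given sample ordering."""
    df = sheet.data.set_index("sample_id").loc[list(sample_ids)]
    x = np.column_stack(
        [np.ones(len(df)), (df["timepoint"] == "post").to_numpy(float)]
    )
    pos = {sid: i for i, sid in enumerate(df.index)}
    partner = np.arange(len(df))
    for pid, tps in sheet.pairing.items():
        if set(tps) == {"pre", "post"}:
            a, b = tps["pre"], tps["post"]
            if a in pos and b in pos:
                partner[pos[a]] = pos[b]
                partner[pos[b]] = pos[a]
    return x, partner


def _gls_stats(y: np.ndarray, x: np.ndarray, partner: np.ndarray, rho: float):
    """Vectorized GLS for all CpG rows of ``y`` under block-equicorrelation.

    Returns (effect, rss, se_unit, logdet_R, logdet_XtWX, n - p).
    Blocks have size 1 or 2 (at most one pre and one post per patient), so
    the whitening weights are closed-form.
    """
    n, p = x.shape
    is_pair = partner != np.arange(n)
    a = np.where(is_pair, 1.0 / (1.0 - rho**2), 1.0)
    b = np.where(is_pair, -rho / (1.0 - rho**2), 0.0)

    def apply_w(mat):  # mat: (..., n)
        return a * mat + b * mat[..., partner]

    wx = apply_w(x.T).T  # n × p
    xtwx = x.T @ wx
    logdet_xtwx = float(np.log(np.linalg.det(xtwx)))
    logdet_r = float(np.log1p(-(rho**2)) * (is_pair.sum() // 2))
    xtwx_inv = np.linalg.inv(xtwx)

    xtwy = y @ wx  # G × p
    beta = xtwy @ xtwx_inv.T  # G × p
    ywy = np.einsum("gn,gn->g", y, apply_w(y))
    rss = ywy - np.einsum("gp,gp->g", beta, xtwy)
    rss = np.maximum(rss, 0.0)
    se_unit = float(np.sqrt(xtwx_inv[1, 1]))
    return beta[:, 1], rss, se_unit, logdet_r, logdet_xtwx, n - p


def estimate_consensus_correlation(
    m: MValueMatrix, sheet: SampleSheet
) -> ConsensusCorrelation:
    """Per-CpG REML estimate of the intra-patient correlation, pooled by a
    15%-trimmed mean on the atanh scale.

    The REML profile likelihood over the correlation is evaluated on a grid
    (step 0.01) simultaneously for all CpGs; CpGs that are constant or have
    missing values are excluded (and counted via ``n_cpgs_used``).
    """
    if not sheet.paired_patients():
        raise ValueError("pairing required: no patient has both timepoints")
    vals = m.values.loc[:, sheet.sample_ids.tolist()]
    complete = vals.notna().all(axis=1)
    varying = vals.var(axis=1, ddof=0) > 1e-12
    use = complete & varying
    n_excluded = int((~use).sum())
    if n_excluded:
        logger.info("consensus correlation: excluded %d CpGs", n_excluded)
    y = vals.loc[use].to_numpy()
    if y.shape[0] < 2:
        raise ValueError("too few usable CpGs for consensus estimation")
    x, partner = _design(sheet, vals.columns)

    best_ll = np.full(y.shape[0], -np.inf)
    best_rho = np.zeros(y.shape[0])
    for rho in _RHO_GRID:
        _, rss, _, ldr, ldx, dof = _gls_stats(y, x, partner, rho)
        with np.errstate(divide="ignore"):
            ll = -0.5 * (dof * np.log(rss / dof) + ldr + ldx)
        better = ll > best_ll
        best_ll[better] = ll[better]
        best_rho[better] = rho

    per_cpg = pd.Series(best_rho, index=vals.index[use])
    z = np.arctanh(np.clip(best_rho, -0.99, 0.99))
    consensus = float(np.tanh(trim_mean(z, _TRIM)))
    return ConsensusCorrelation(consensus, per_cpg, int(use.sum()))


def fit_gls_per_cpg(
    m: MValueMatrix,
    sheet: SampleSheet,
    consensus: ConsensusCorrelation | float,
) -> pd.DataFrame:
    """Per-CpG GLS fit of the pre→post effect under the consensus correlation.

    Returns a DataFrame indexed by cpg_id with columns ``effect`` (post −
    pre, M scale), ``s2`` (residual variance), ``df`` (residual degrees of
    freedom) and ``se_unit`` (unscaled standard error of the effect).  CpGs
    with fewer than two non-missing samples in either timepoint are skipped
    with a logged reason.
    """
    rho = consensus.consensus if isinstance(consensus, ConsensusCorrelation) else float(consensus)
    vals = m.values.loc[:, sheet.sample_ids.tolist()]
    is_post = (
        sheet.data.set_index("sample_id").loc[vals.columns, "timepoint"] == "post"
    ).to_numpy()

    results = {}
    obs = vals.notna().to_numpy()
    patterns = {}
    for i in range(len(vals)):
        patterns.setdefault(obs[i].tobytes(), []).append(i)

    for key, rows in patterns.items():
        mask = np.frombuffer(key, dtype=bool)
        if (is_post[mask].sum() < 2) or ((~is_post)[mask].sum() < 2):
            logger.info(
                "skipping %d CpGs: <2 samples in a timepoint after missingness",
                len(rows),
            )
            continue
        cols = vals.columns[mask]
        sub_sheet = sheet.subset(cols)
        x, partner = _design(sub_sheet, cols)
        y = vals.iloc[rows].loc[:, cols].to_numpy()
        eff, rss, se_unit, _, _, dof = _gls_stats(y, x, partner, rho)
        if dof < 1:
            logger.info("skipping %d CpGs: no residual degrees of freedom", len(rows))
            continue
        for k, i in enumerate(rows):
            results[vals.index[i]] = (eff[k], rss[k] / dof, dof, se_unit)

    out = pd.DataFrame.from_dict(
        results, orient="index", columns=["effect", "s2", "df", "se_unit"]
    )
    out.index.name = "cpg_id"
    return out.loc[[c for c in vals.index if c in results]]


# ---------------------------------------------------------------------------
# empirical Bayes moderation
# ---------------------------------------------------------------------------


def _trigamma_inverse(y: float) -> float:
    """Solve trigamma(x) = y for x > 0 (Newton iteration)."""
    if y > 1e7:
        return 1.0 / np.sqrt(y)
    if y < 1e-6:
        return 1.0 / y
    x = 0.5 + 1.0 / y
    for _ in range(50):
        tri = polygamma(1, x)
        dif = tri * (1.0 - tri / y) / polygamma(2, x)
        x = x + dif
        if abs(dif) / x < 1e-8:
            break
    return float(x)


def empirical_bayes_moderate(fits: pd.DataFrame) -> tuple[ModerationParams, pd.DataFrame]:
    """Shrink per-CpG variances toward an empirical prior; moderated t and p.

    The prior (d0, s0²) is estimated by matching the mean and variance of
    log s_g² against the scaled-F model (digamma/trigamma moments).  When
    the observed variances show no excess spread the prior degrees of
    freedom are infinite and every posterior variance equals s0².
    """
    if len(fits) < 10:
        raise ValueError("need at least 10 CpGs with positive residual df")
    pos = fits["s2"] > 0
    n_zero = int((~pos).sum())
    if n_zero:
        logger.info("moderation: excluding %d zero-variance CpGs", n_zero)
    f = fits.loc[pos]
    s2 = f["s2"].to_numpy()
    d = f["df"].to_numpy(float)

    e = np.log(s2) - digamma(d / 2.0) + np.log(d / 2.0)
    mean_e = float(e.mean())
    target = float(e.var(ddof=1)) - float(polygamma(1, d / 2.0).mean())
    if target <= 0:
        # no excess spread beyond chi-square sampling noise: infinite prior
        # df, prior = pooled (df-weighted) variance so equal variances are a
        # fixed point
        d0, s0_sq = np.inf, float((d * s2).sum() / d.sum())
    else:
        d0 = 2.0 * _trigamma_inverse(target)
        s0_sq = float(np.exp(mean_e + digamma(d0 / 2.0) - np.log(d0 / 2.0)))

    if np.isinf(d0):
        post = np.full_like(s2, s0_sq)
    else:
        post = (d0 * s0_sq + d * s2) / (d0 + d)

    t_stat = f["effect"].to_numpy() / (np.sqrt(post) * f["se_unit"].to_numpy())
    df_total = d + d0
    p = 2.0 * t_dist.sf(np.abs(t_stat), df_total)

    params = ModerationParams(
        d0=float(d0),
        s0_sq=s0_sq,
        d_g=pd.Series(d, index=f.index),
        s_g_sq=pd.Series(s2, index=f.index),
        posterior_sq=pd.Series(post, index=f.index),
    )
    table = pd.DataFrame({"t": t_stat, "p": p}, index=f.index)
    return params, table


def bh_adjust(p) -> np.ndarray:
    """Benjamini–Hochberg step-up adjusted p-values (input order preserved)."""
    p = np.asarray(p, float)
    if p.ndim != 1:
        raise ValueError("p must be a 1-D vector")
    if np.isnan(p).any() or (p < 0).any() or (p > 1).any():
        raise ValueError("p-values must lie in [0, 1]")
    n = len(p)
    order = np.argsort(p, kind="mergesort")
    ranked = p[order] * n / np.arange(1, n + 1)
    adj = np.minimum.accumulate(ranked[::-1])[::-1]
    out = np.empty(n)
    out[order] = np.minimum(adj, 1.0)
    return out


# ---------------------------------------------------------------------------
# full comparisons
# ---------------------------------------------------------------------------


def run_comparison(
    m: MValueMatrix,
    sheet: SampleSheet,
    alpha: float = 0.01,
    beta: BetaMatrix | None = None,
    consensus: ConsensusCorrelation | float | None = None,
) -> pd.DataFrame:
    """Full pre-vs-post comparison on one sample set.

    Returns the differential table (one row per tested CpG) sorted by
    adjusted p: effect (M scale, post − pre), group mean betas when a beta
    matrix is supplied, moderated t, p, BH-adjusted p, the significance call
    at ``alpha`` and the gain/loss direction.
    """
    if consensus is None:
        consensus = estimate_consensus_correlation(m, sheet)
    fits = fit_gls_per_cpg(m, sheet, consensus)
    _, mod = empirical_bayes_moderate(fits)
    table = fits.join(mod, how="inner")
    table["p_adj"] = bh_adjust(table["p"].to_numpy())
    table["significant"] = table["p_adj"] < alpha
    table["direction"] = np.where(table["effect"] > 0, "gain", "loss")

    if beta is not None:
        bv = beta.values.loc[table.index, sheet.sample_ids.tolist()]
        tp = sheet.data.set_index("sample_id").loc[bv.columns, "timepoint"]
        table["mean_beta_pre"] = bv.loc[:, (tp == "pre").to_numpy()].mean(axis=1)
        table["mean_beta_post"] = bv.loc[:, (tp == "post").to_numpy()].mean(axis=1)

    table = table.rename(columns={"effect": "effect_m"})
    table = table.sort_values(["p_adj", "p", "cpg_id"], kind="mergesort")
    cols = ["effect_m", "t", "p", "p_adj", "significant", "direction"]
    cols += [c for c in ("mean_beta_pre", "mean_beta_post") if c in table.columns]
    return table[cols]


DEFAULT_GROUPS = {
    "survivor": ("survival_group", "survivor"),
    "non_survivor": ("survival_group", "non_survivor"),
    "partial_response": ("response", "partial_response"),
    "stable_disease": ("response", "stable_disease"),
}


def run_group_comparisons(
    m: MValueMatrix,
    sheet: SampleSheet,
    groups: dict | str | None = None,
    alpha: float = 0.01,
    beta: BetaMatrix | None = None,
) -> dict[str, pd.DataFrame]:
    """Run the pre-vs-post pipeline within each requested subgroup.

    ``groups`` is a mapping name → (sheet column, level), a sheet column
    name (one comparison per level), or None for the default survivor /
    non-survivor / responder / non-responder grouping.  Subgroups with no
    paired patients are skipped with a logged reason.
    """
    if groups is None:
        groups = {k: v for k, v in DEFAULT_GROUPS.items() if v[0] in sheet.data.columns}
    elif isinstance(groups, str):
        col = groups
        groups = {
            str(level): (col, level)
            for level in sheet.data[col].dropna().unique()
        }

    results: dict[str, pd.DataFrame] = {}
    for name, (col, level) in groups.items():
        sub_ids = sheet.data.loc[sheet.data[col] == level, "sample_id"]
        if sub_ids.empty:
            logger.warning("subgroup %r is empty; skipped", name)
            continue
        sub_sheet = sheet.subset(sub_ids)
        if not sub_sheet.paired_patients():
            logger.warning("subgroup %r has no paired patients; skipped", name)
            continue
        sub_m = MValueMatrix(m.values.loc[:, sub_ids.tolist()])
        results[name] = run_comparison(sub_m, sub_sheet, alpha=alpha, beta=beta)
    return results
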