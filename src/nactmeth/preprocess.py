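"""Array preprocessing: detection filtering, type-II peak correction,
quantile normalization, and the beta ↔ M transforms.

The Illumina 450k array mixes two probe chemistries.  Type-II probes give
compressed beta distributions, so their M-value modes sit closer to zero
than type-I modes.  Peak correction rescales type-II M-values so the two
chemistries' unmethylated and methylated modes line up; quantile
normalization then forces every sample onto a common (mean-quantile)
distribution.

Scale conventions: the detection filter operates on betas, peak correction
on M-values, quantile normalization on betas.  The modelling scale is M:
``M = log2(beta / (1 - beta))``, with betas clipped to ``[eps, 1 - eps]``
first so the transform stays finite.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy.stats import gaussian_kde

from .io_model import (
    BetaMatrix,
    CpGAnnotation,
    DetectionPMatrix,
    MValueMatrix,
    ValidationError,
)

__all__ = [
    "PreprocessReport",
    "beta_to_m",
    "m_to_beta",
    "detection_filter",
    "peak_correct_type2",
    "quantile_normalize",
]

DEFAULT_EPSILON = 1e-3
_KDE_GRID = np.linspace(-8.0, 8.0, 512)


@dataclass
class PreprocessReport:
    """Bookkeeping emitted by the preprocessing steps."""

    n_sites_in: int = 0
    n_sites_removed_detection: int = 0
    peak_positions: dict = field(default_factory=dict)
    reference_quantiles: np.ndarray | None = None
    notes: list = field(default_factory=list)

    def to_dict(self) -> dict:
        out = {
            "n_sites_in": self.n_sites_in,
            "n_sites_removed_detection": self.n_sites_removed_detection,
            "peak_positions": self.peak_positions,
            "notes": list(self.notes),
        }
        if self.reference_quantiles is not None:
            out["reference_quantiles"] = np.asarray(self.reference_quantiles).tolist()
        return out


def beta_to_m(beta: BetaMatrix, epsilon: float = DEFAULT_EPSILON) -> MValueMatrix:
    """M = log2(beta / (1 - beta)) with betas clipped to [eps, 1 - eps].

    Missing values stay missing.  ``epsilon`` must lie in (0, 0.5).
    """
    if not 0 < epsilon < 0.5:
        raise ValueError(f"epsilon must be in (0, 0.5), got {epsilon}")
    b = beta.values.to_numpy(copy=True)
    mask = np.isnan(b)
    b = np.clip(b, epsilon, 1 - epsilon)
    m = np.log2(b / (1 - b))
    m[mask] = np.nan
    return MValueMatrix(
        pd.DataFrame(m, index=beta.cpg_ids, columns=beta.sample_ids)
    )


def m_to_beta(m: MValueMatrix) -> BetaMatrix:
    """Inverse transform: beta = 2**M / (1 + 2**M)."""
    arr = m.values.to_numpy()
    # expit on the natural-log scale avoids overflow for large |M|
    from scipy.special import expit

    b = expit(arr * np.log(2.0))
    return BetaMatrix(pd.DataFrame(b, index=m.cpg_ids, columns=m.sample_ids))


def detection_filter(
    beta: BetaMatrix,
    detp: DetectionPMatrix,
    p_threshold: float = 0.05,
    fail_fraction: float = 0.75,
) -> tuple[BetaMatrix, PreprocessReport]:
    """Remove sites whose measurements mostly fail detection.

    A measurement fails when its detection p ≥ ``p_threshold``.  A site is
    removed iff *strictly more than* ``fail_fraction`` of its measurements
    fail; 75% failing exactly is kept.
    """
    if beta.values.shape != detp.values.shape or not beta.cpg_ids.equals(
        detp.cpg_ids
    ) or not beta.sample_ids.equals(detp.sample_ids):
        raise ValidationError("beta and detection-p matrices are not aligned")
    fails = (detp.values.to_numpy() >= p_threshold).mean(axis=1)
    keep = fails <= fail_fraction
    report = PreprocessReport(
        n_sites_in=beta.shape[0],
        n_sites_removed_detection=int((~keep).sum()),
    )
    return BetaMatrix(beta.values.loc[keep]), report


def _modes(values: np.ndarray, sample: str, probe_type: str) -> tuple[float, float]:
    """(unmethylated mode over M<0, methylated mode over M>0) via KDE."""
    values = values[np.isfinite(values)]
    if len(values) < 2:
        raise ValidationError(f"sample {sample!r} has too few type-{probe_type} probes")
    dens = gaussian_kde(values)(_KDE_GRID)  # Silverman bandwidth default
    neg = _KDE_GRID < 0
    pos = _KDE_GRID > 0
    if not dens[neg].any() or not dens[pos].any():
        raise ValidationError(
            f"sample {sample!r}: no type-{probe_type} density mass on one side of M=0"
        )
    unmeth = float(_KDE_GRID[neg][np.argmax(dens[neg])])
    meth = float(_KDE_GRID[pos][np.argmax(dens[pos])])
    if unmeth >= 0 or meth <= 0:
        raise ValidationError(
            f"sample {sample!r}: could not locate both type-{probe_type} modes"
        )
    return unmeth, meth


def peak_correct_type2(
    m: MValueMatrix, annot: CpGAnnotation
) -> tuple[MValueMatrix, PreprocessReport]:
    """Rescale type-II probe M-values so their modes match type-I modes.

    Per sample, the unmethylated (M<0) and methylated (M>0) density modes are
    estimated separately for type-I and type-II probes by Gaussian KDE
    (Silverman bandwidth, 512-point grid on [-8, 8]).  Type-II values are then
    multiplied by ``peakI/peakII`` on each side of zero; type-I values are
    untouched and M=0 is a fixed point.
    """
    ann = annot.data.loc[m.cpg_ids]
    is_type2 = (ann["probe_type"] == "II").to_numpy()
    if not is_type2.any() or is_type2.all():
        raise ValidationError("peak correction requires both probe types")
    out = m.values.to_numpy(copy=True)
    report = PreprocessReport(n_sites_in=m.shape[0])
    for j, sample in enumerate(m.sample_ids):
        col = out[:, j]
        u1, m1 = _modes(col[~is_type2], sample, "I")
        u2, m2 = _modes(col[is_type2], sample, "II")
        t2 = col[is_type2]
        scaled = np.where(t2 < 0, t2 * (u1 / u2), t2 * (m1 / m2))
        out[is_type2, j] = scaled
        u2c, m2c = _modes(out[is_type2, j], sample, "II")
        report.peak_positions[str(sample)] = {
            "typeI": {"unmeth": u1, "meth": m1},
            "typeII_before": {"unmeth": u2, "meth": m2},
            "typeII_after": {"unmeth": u2c, "meth": m2c},
        }
    return (
        MValueMatrix(pd.DataFrame(out, index=m.cpg_ids, columns=m.sample_ids)),
        report,
    )


def quantile_normalize(beta: BetaMatrix) -> BetaMatrix:
    """Force every sample onto the across-sample mean quantile distribution.

    After normalization every column's sorted non-missing values equal the
    mean quantile vector; ties within a column receive the mean of the tied
    reference values.  Missing values are ignored when ranking and stay
    missing.  A single-sample matrix is returned unchanged with a warning.
    """
    arr = beta.values.to_numpy(copy=True)
    n_rows, n_cols = arr.shape
    if n_cols < 2:
        import warnings

        warnings.warn("quantile_normalize: single sample, returning input unchanged")
        return BetaMatrix(beta.values.copy())

    grid = np.linspace(0.0, 1.0, n_rows)
    # reference = mean across columns of each column's empirical quantile
    # function evaluated on a common grid (exact mean-of-sorted when no NaN)
    qfuncs = np.empty((n_cols, n_rows))
    for j in range(n_cols):
        col = np.sort(arr[:, j][~np.isnan(arr[:, j])])
        if len(col) == 0:
            raise ValidationError(f"column {beta.sample_ids[j]!r} entirely missing")
        if len(col) == n_rows:
            qfuncs[j] = col
        else:
            p = np.linspace(0.0, 1.0, len(col))
            qfuncs[j] = np.interp(grid, p, col)
    reference = qfuncs.mean(axis=0)

    out = np.full_like(arr, np.nan)
    for j in range(n_cols):
        col = arr[:, j]
        obs = ~np.isnan(col)
        vals = col[obs]
        n = len(vals)
        order = np.argsort(vals, kind="mergesort")
        ranks = np.empty(n)
        ranks[order] = np.arange(n)
        if n == n_rows:
            ref = reference
        else:
            p = np.linspace(0.0, 1.0, n)
            ref = np.interp(p, grid, reference)
        new = ref[ranks.astype(int)]
        # ties: average the reference values mapped to tied observations
        uniq, inv, counts = np.unique(vals, return_inverse=True, return_counts=True)
        if (counts > 1).any():
            sums = np.bincount(inv, weights=new)
            new = (sums / counts)[inv]
        out[:, j][obs] = new
    return BetaMatrix(pd.DataFrame(out, index=beta.cpg_ids, columns=beta.sample_ids))
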