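"""Genomic-region classification, gain/loss proportions, and the
toward-normal direction statistic.

Probes are cross-classified by genomic context (promoter / gene body /
intergenic) and CpG-island status into six regions.  Per region, the
proportion of significant gain (or loss) sites is the significant count
divided by the number of array sites in that region.  The toward-normal
statistic asks, for each significant site, whether the post-treatment group
mean beta is closer than the pre-treatment mean to a normal-tissue
reference mean; ties count as not-toward.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .io_model import BetaMatrix, CpGAnnotation, SampleSheet, ValidationError

__all__ = [
    "REGIONS",
    "TowardNormalResult",
    "classify_region",
    "region_proportions",
    "toward_normal_fraction",
]

REGIONS = (
    "promoter_CGI",
    "promoter_nonCGI",
    "body_CGI",
    "body_nonCGI",
    "intergenic_CGI",
    "intergenic_nonCGI",
)

_CONTEXT_SHORT = {"promoter": "promoter", "gene_body": "body", "intergenic": "intergenic"}


@dataclass(frozen=True)
class TowardNormalResult:
    n_evaluated: int
    n_toward: int
    n_excluded: int

    @property
    def fraction_toward(self) -> float:
        return self.n_toward / self.n_evaluated if self.n_evaluated else float("nan")


def classify_region(annot: CpGAnnotation) -> pd.Series:
    """Map each cpg_id to one of the six regions (context × island)."""
    df = annot.data
    ctx = df["genomic_context"].map(_CONTEXT_SHORT)
    return (ctx + "_" + df["island"]).rename("region")


def region_proportions(results: pd.DataFrame, annot: CpGAnnotation) -> pd.DataFrame:
    """Per-region gain/loss counts and proportions of significant sites.

    ``results`` is a differential table indexed by cpg_id with
    ``significant`` and ``direction`` columns; the denominator for each
    region is the number of *array* sites (all annotated probes) in it.
    """
    missing = results.index.difference(annot.cpg_ids)
    if len(missing):
        raise ValidationError(
            f"results contain CpGs absent from annotation: {missing[:5].tolist()}"
        )
    region = classify_region(annot)
    n_sites = region.value_counts()
    sig = results[results["significant"]]
    sig_region = region.loc[sig.index]

    rows = []
    for reg in REGIONS:
        total = int(n_sites.get(reg, 0))
        in_reg = sig[(sig_region == reg).reindex(sig.index, fill_value=False)]
        n_gain = int((in_reg["direction"] == "gain").sum())
        n_loss = int((in_reg["direction"] == "loss").sum())
        rows.append(
            {
                "region": reg,
                "n_array_sites": total,
                "n_significant_gain": n_gain,
                "n_significant_loss": n_loss,
                "proportion_gain": n_gain / total if total else 0.0,
                "proportion_loss": n_loss / total if total else 0.0,
                "empty_region": total == 0,
            }
        )
    return pd.DataFrame(rows)


def toward_normal_fraction(
    beta: BetaMatrix,
    sheet: SampleSheet,
    significant_cpgs,
    normal: pd.Series,
) -> TowardNormalResult:
    """Fraction of significant sites whose group-mean change moved toward
    the normal-tissue mean.

    Group means are taken over the pre and post samples of ``sheet`` (pass
    the subgroup the significant set came from, e.g. survivors).  A site
    counts toward normal iff |mean_post − μ| < |mean_pre − μ|; ties are
    not-toward.  Sites missing from the reference are excluded and counted.
    """
    sig = pd.Index(significant_cpgs)
    covered = sig.intersection(normal.index)
    n_excluded = len(sig) - len(covered)

    tp = sheet.data.set_index("sample_id")["timepoint"]
    bv = beta.values.loc[covered, sheet.sample_ids.tolist()]
    pre = bv.loc[:, (tp.loc[bv.columns] == "pre").to_numpy()].mean(axis=1)
    post = bv.loc[:, (tp.loc[bv.columns] == "post").to_numpy()].mean(axis=1)
    mu = normal.loc[covered]

    toward = (post - mu).abs() < (pre - mu).abs()
    return TowardNormalResult(
        n_evaluated=len(covered),
        n_toward=int(toward.sum()),
        n_excluded=n_excluded,
    )
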