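"""Agreement between histology- and collagenase-based mean adipocyte diameters.

Histology measures cell cross-sections, which need not pass through the
widest part of the cell, so histology-derived diameters run systematically
smaller than diameters of collagenase-liberated (spherical) adipocytes.
The comparison is done on subject-level mean diameters: Pearson concordance
plus a Bland–Altman analysis (bias and 1.96·SD limits of agreement), with
the difference fixed as histology − collagenase so the expected bias is
negative.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats

from .geometry import ValidationError

__all__ = ["BlandAltmanResult", "pair_subjects", "bland_altman", "method_concordance"]

#: Limits-of-agreement multiplier (95% under normal differences).
LOA_MULTIPLIER = 1.96


@dataclass(frozen=True)
class BlandAltmanResult:
    """Bland–Altman agreement between paired method means (µm)."""

    n_pairs: int
    bias: float
    sd_diff: float
    loa_low: float
    loa_high: float
    pairs: pd.DataFrame = field(repr=False, default=None)


def pair_subjects(
    means_histology: pd.DataFrame,
    means_collagenase: pd.DataFrame,
    pool_depots: bool = True,
) -> pd.DataFrame:
    """Inner-join subject mean diameters measured by both methods.

    Inputs are tables with columns ``subject_id``, ``depot`` and a mean-size
    column (the first column that is neither key).  With ``pool_depots``
    each subject×depot combination counts as one observation, so a subject
    contributing both depots appears twice.

    Returns a table with columns ``subject_id, depot, histology, collagenase``.
    """
    out = []
    for df, name in ((means_histology, "histology"), (means_collagenase, "collagenase")):
        value_cols = [c for c in df.columns if c not in ("subject_id", "depot")]
        if not value_cols:
            raise ValidationError(f"{name} table has no value column")
        out.append(
            df[["subject_id", "depot", value_cols[0]]].rename(
                columns={value_cols[0]: name}
            )
        )
    paired = out[0].merge(out[1], on=["subject_id", "depot"], how="inner")
    if paired.empty:
        raise ValidationError("no subject has both histology and collagenase means")
    if not pool_depots:
        # one observation per subject: average a subject's depots first
        paired = (
            paired.groupby("subject_id", as_index=False)[["histology", "collagenase"]]
            .mean()
            .assign(depot="pooled")
        )[["subject_id", "depot", "histology", "collagenase"]]
    return paired.sort_values(["subject_id", "depot"]).reset_index(drop=True)


def bland_altman(paired: pd.DataFrame) -> BlandAltmanResult:
    """Bland–Altman bias and limits of agreement on paired method means.

    bias = mean(histology − collagenase); LoA = bias ± 1.96·SD(differences).
    The bias equals the difference of the two sample means exactly, and
    swapping the method columns negates bias and mirrors the LoA.
    """
    if len(paired) < 3:
        raise ValidationError(f"Bland-Altman needs >= 3 pairs, got {len(paired)}")
    diff = paired["histology"].to_numpy(float) - paired["collagenase"].to_numpy(float)
    mean_pair = (paired["histology"].to_numpy(float) + paired["collagenase"].to_numpy(float)) / 2.0
    bias = float(diff.mean())
    sd = float(diff.std(ddof=1))
    table = paired[["subject_id", "depot"]].copy()
    table["pair_mean"] = mean_pair
    table["difference"] = diff
    return BlandAltmanResult(
        n_pairs=len(paired),
        bias=bias,
        sd_diff=sd,
        loa_low=bias - LOA_MULTIPLIER * sd,
        loa_high=bias + LOA_MULTIPLIER * sd,
        pairs=table,
    )


def method_concordance(paired: pd.DataFrame) -> tuple[float, float]:
    """Pearson correlation (r, two-sided p) between the paired method means.

    p comes from t = r·sqrt((n−2)/(1−r²)).  Zero variance in either method
    leaves r undefined and returns (nan, nan).
    """
    if len(paired) < 3:
        raise ValidationError(f"concordance needs >= 3 pairs, got {len(paired)}")
    x = paired["histology"].to_numpy(float)
    y = paired["collagenase"].to_numpy(float)
    if x.std(ddof=0) == 0 or y.std(ddof=0) == 0:
        return float("nan"), float("nan")
    r, p = stats.pearsonr(x, y)
    return float(r), float(p)
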