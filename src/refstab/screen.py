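"""Candidate reference-gene screening from an RNA-seq expression matrix.

A good reference gene is abundantly and uniformly expressed, so candidates
are screened on four per-gene statistics computed across samples:

* MV  — mean FPKM (abundance; must exceed ``mv_min``, default 50),
* SD  — standard deviation of FPKM (ranking key, ascending),
* MFC — maximum fold change, max(FPKM)/min(FPKM) (must be below
  ``mfc_max``, default 1.5),
* CV  — coefficient of variation, SD/MV (must be below ``cv_max``,
  default 0.1).

All threshold comparisons are strict.  A gene whose minimum FPKM is zero
has an undefined MFC and never passes.  Every column is treated as one
sample; if biological replicates should be averaged first, collapse them
before building the matrix.
"""
from __future__ import annotations

import numpy as np
import pandas as pd

from .datamodel import AnalysisConfig, ExpressionMatrix, ValidationError

SCREEN_COLUMNS = ("mv", "sd", "mfc", "cv", "passes")


def screen_stats(matrix: ExpressionMatrix,
                 config: AnalysisConfig | None = None) -> pd.DataFrame:
    """Per-gene screening statistics and pass/fail decision.

    Returns a DataFrame indexed by gene with columns mv, sd, mfc, cv and
    passes.  MFC is NaN (undefined) when the minimum FPKM is 0; CV is NaN
    when the mean is 0.  ``passes`` is True only when all three thresholds
    hold strictly and MFC is defined.
    """
    config = config or AnalysisConfig()
    v = matrix.values
    if v.shape[1] < 2:
        raise ValidationError("screening needs at least 2 samples (SD undefined)")
    arr = v.to_numpy(dtype=float)
    mv = arr.mean(axis=1)
    sd = arr.std(axis=1, ddof=config.ddof)
    mn = arr.min(axis=1)
    mx = arr.max(axis=1)
    with np.errstate(divide="ignore", invalid="ignore"):
        mfc = np.where(mn > 0, mx / np.where(mn > 0, mn, 1.0), np.nan)
        cv = np.where(mv > 0, sd / np.where(mv > 0, mv, 1.0), np.nan)
    passes = (
        (mv > config.mv_min)
        & ~np.isnan(mfc) & (mfc < config.mfc_max)
        & ~np.isnan(cv) & (cv < config.cv_max)
    )
    return pd.DataFrame(
        {"mv": mv, "sd": sd, "mfc": mfc, "cv": cv, "passes": passes},
        index=v.index.rename("gene"),
    )


def select_candidates(stats: pd.DataFrame,
                      config: AnalysisConfig | None = None,
                      top_n: int | None = None) -> list[str]:
    """Passing genes ordered by ascending SD (ties broken by gene id).

    ``top_n`` truncates the ranked list; it stands in for the manual,
    annotation-based curation that trims the SD-ranked pass list to a
    primer-design shortlist.  An empty result is allowed.
    """
    if stats.empty:
        raise ValidationError("screening statistics are empty")
    if top_n is not None and top_n < 1:
        raise ValidationError("top_n must be a positive integer")
    passing = stats.loc[stats["passes"].astype(bool)]
    # stable sort on sd after an index sort gives the lexicographic tie-break
    ordered = passing.sort_index().sort_values("sd", kind="mergesort")
    genes = list(ordered.index)
    return genes[:top_n] if top_n is not None else genes
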