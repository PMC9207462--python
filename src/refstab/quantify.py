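"""Standard-curve efficiency and ddCq relative quantification.

Amplification efficiency is estimated from a dilution series by ordinary
least squares of Cq on log10 template amount:

    E = (10^(-1/slope) - 1) * 100%          (slope ~ -3.32 at E = 100%)

Relative expression of a target gene against one or two reference genes
follows the 2^-ddCq method: per sample,

    dCq  = Cq_target - Cq_reference
    ddCq = dCq - mean(dCq over control samples)
    RQ   = 2^-ddCq

With two references, ddCq is the arithmetic mean of the two
single-reference ddCq values — algebraically, RQ is then the geometric
mean of the two single-reference RQ series.  The quantification base is 2
regardless of the measured primer efficiency (an efficiency-corrected base
1+E is available via ``base``).
"""
from __future__ import annotations

import logging
import warnings
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd
from scipy import stats

from .datamodel import (
    CqTable,
    DilutionSeries,
    QuantificationResult,
    ValidationError,
)

logger = logging.getLogger("refstab")


def fit_standard_curve(points: Iterable[tuple[float, float]]) -> DilutionSeries:
    """Fit Cq = intercept + slope * log10(concentration) by OLS.

    Needs at least 3 points with strictly positive, non-identical
    concentrations.  ``efficiency_percent`` is None with a warning when the
    slope is non-negative (no amplification gain with template — a primer
    failure signal).
    """
    pts = pd.DataFrame(list(points), columns=["concentration", "cq"]).astype(float)
    if len(pts) < 3:
        raise ValidationError("standard curve needs at least 3 dilution points")
    if (pts["concentration"] <= 0).any():
        raise ValidationError("concentrations must be strictly positive")
    x = np.log10(pts["concentration"].to_numpy())
    if np.ptp(x) == 0:
        raise ValidationError("concentrations must not all be equal")
    fit = stats.linregress(x, pts["cq"].to_numpy())
    if fit.slope >= 0:
        warnings.warn(
            f"standard-curve slope {fit.slope:.4g} >= 0: efficiency undefined",
            stacklevel=2,
        )
        eff = None
    else:
        eff = (10.0 ** (-1.0 / fit.slope) - 1.0) * 100.0
    return DilutionSeries(
        points=pts,
        slope=float(fit.slope),
        intercept=float(fit.intercept),
        r_squared=float(fit.rvalue ** 2),
        efficiency_percent=eff,
    )


def _delta_cq(cq: CqTable, target: str, reference: str) -> pd.Series:
    for gene in (target, reference):
        if gene not in cq.cq.index:
            raise ValidationError(f"gene {gene!r} not in Cq table")
    return cq.cq.loc[target] - cq.cq.loc[reference]


def _quantify(cq: CqTable, target: str, references: Sequence[str],
              control: str, base: float) -> QuantificationResult:
    if base <= 1:
        raise ValidationError("quantification base must exceed 1")
    meta = cq.metadata.loc[cq.sample_ids]
    is_control = meta["condition"] == control
    if not is_control.any():
        raise ValidationError(f"no sample has control condition {control!r}")

    ddcq_parts = []
    for ref in references:
        dcq = _delta_cq(cq, target, ref)
        ctrl = dcq[is_control.to_numpy()].dropna()
        if ctrl.empty:
            raise ValidationError(
                f"no usable control sample for target {target!r} "
                f"with reference {ref!r}"
            )
        ddcq_parts.append(dcq - ctrl.mean())
    ddcq = sum(ddcq_parts) / len(ddcq_parts)

    samples = pd.DataFrame(
        {
            "group": meta["group"],
            "condition": meta["condition"],
            "dcq": sum(_delta_cq(cq, target, r) for r in references) / len(references),
            "ddcq": ddcq,
            "rq": np.power(base, -ddcq),
        },
        index=pd.Index(cq.sample_ids, name="sample_id"),
    ).dropna(subset=["ddcq"])
    # error bars over biological replicates are SDs, labelled as such
    summary = samples.groupby("group", sort=False).agg(
        n=("rq", "size"),
        mean_ddcq=("ddcq", "mean"), sd_ddcq=("ddcq", lambda s: s.std(ddof=1)),
        mean_rq=("rq", "mean"), sd_rq=("rq", lambda s: s.std(ddof=1)),
    )
    return QuantificationResult(
        target=target, references=tuple(references), control=control,
        samples=samples, summary=summary,
    )


def relative_expression_single(cq: CqTable, target: str, reference: str,
                               control: str, base: float = 2.0) -> QuantificationResult:
    """2^-ddCq expression of ``target`` normalized by one reference gene.

    ``control`` names the level of the metadata ``condition`` column whose
    mean dCq is the calibrator; RQ averages to 1 over control samples by
    construction (on the ddCq scale).
    """
    return _quantify(cq, target, [reference], control, base)


def relative_expression_double(cq: CqTable, target: str, ref1: str, ref2: str,
                               control: str, base: float = 2.0) -> QuantificationResult:
    """2^-ddCq expression of ``target`` normalized by two reference genes.

    ddCq is the arithmetic mean of the two single-reference ddCq values, so
    RQ equals the geometric mean of the two single-reference RQ series.
    """
    if ref1 == ref2:
        raise ValidationError("the two reference genes must differ")
    return _quantify(cq, target, [ref1, ref2], control, base)


def normalization_concordance(series: Mapping[str, Sequence[float]] | pd.DataFrame,
                              ) -> pd.DataFrame:
    """Pairwise Pearson correlation matrix between aligned numeric vectors.

    The caller chooses the scale (raw Cq vectors for stability validation,
    log2 RQ for normalization validation).  Vectors must share length
    (>= 3); missing entries are dropped pairwise.  A zero-variance vector
    yields missing correlations for its pairs, with a warning.
    """
    df = pd.DataFrame(series).astype(float)
    if df.shape[1] < 2:
        raise ValidationError("concordance needs at least 2 vectors")
    if df.shape[0] < 3:
        raise ValidationError("concordance vectors need length >= 3")
    flat = df.std(ddof=0) == 0
    if flat.any():
        warnings.warn(
            "zero-variance vectors, correlations undefined: "
            + ", ".join(map(str, df.columns[flat])),
            stacklevel=2,
        )
    corr = df.corr(method="pearson", min_periods=3)
    np.fill_diagonal(corr.to_numpy(), 1.0)
    corr.loc[flat, :] = np.nan
    corr.loc[:, flat] = np.nan
    return corr
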