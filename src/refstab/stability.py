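"""Four RT-qPCR reference-gene stability algorithms.

Each algorithm consumes quantification-cycle (Cq) data for a panel of
candidate genes across samples and produces a per-gene stability value
(lower = more stable) plus a fractional ranking:

* comparative delta-Ct — mean, over all partner genes, of the standard
  deviation across samples of the pairwise Cq difference;
* BestKeeper — descriptive Cq statistics (SD, CV%, correlation with the
  BestKeeper index, the per-sample geometric mean of all candidate Cq);
* geNorm — M-value (mean SD of pairwise log2 expression ratios) with
  stepwise exclusion of the least stable gene, plus the pairwise variation
  V(n/n+1) between normalization factors;
* NormFinder — variance decomposition of log2 relative quantities into
  intragroup variance and (with >= 2 groups) a shrunken intergroup
  deviation.

Missing Cq values are excluded pairwise; any computation that falls below
its minimum sample count raises instead of silently degrading.
"""
from __future__ import annotations

import logging
import warnings
from typing import Mapping

import numpy as np
import pandas as pd

from .consensus import assign_ranks
from .datamodel import (
    AnalysisConfig,
    CqTable,
    RelativeQuantityMatrix,
    StabilityResult,
    ValidationError,
)

logger = logging.getLogger("refstab")


def cq_to_relative_quantity(
    cq: CqTable,
    efficiency: float | Mapping[str, float] | pd.Series | None = None,
    config: AnalysisConfig | None = None,
) -> RelativeQuantityMatrix:
    """Convert Cq to per-gene relative quantities q = E^(Cq_min - Cq).

    The per-gene minimum Cq (most abundant sample) maps to q = 1 and each
    additional cycle divides q by the amplification base E (default 2.0,
    perfect doubling).  Missing Cq propagate as missing.
    """
    config = config or AnalysisConfig()
    genes = cq.gene_ids
    if efficiency is None:
        eff = pd.Series(config.efficiency_default, index=genes, dtype=float)
    elif np.isscalar(efficiency):
        eff = pd.Series(float(efficiency), index=genes, dtype=float)
    else:
        eff = pd.Series(efficiency, dtype=float).reindex(genes)
        if eff.isna().any():
            missing = eff.index[eff.isna()].tolist()
            raise ValidationError(
                "no efficiency given for genes: " + ", ".join(missing)
            )
    if (eff <= 1).any():
        raise ValidationError("amplification efficiency base must exceed 1")
    arr = cq.cq.to_numpy(dtype=float)
    n_present = (~np.isnan(arr)).sum(axis=1)
    if (n_present < 2).any():
        bad = cq.cq.index[n_present < 2].tolist()
        raise ValidationError(
            "genes with fewer than 2 present Cq values: " + ", ".join(bad)
        )
    with warnings.catch_warnings():
        warnings.simplefilter("ignore", RuntimeWarning)
        cq_min = np.nanmin(arr, axis=1)
    log2q = (cq_min[:, None] - arr) * np.log2(eff.to_numpy())[:, None]
    q = np.exp2(log2q)
    return RelativeQuantityMatrix(
        pd.DataFrame(q, index=cq.cq.index, columns=cq.cq.columns), eff,
        pd.DataFrame(log2q, index=cq.cq.index, columns=cq.cq.columns),
    )


def _pair_sd(x: np.ndarray, y: np.ndarray, ddof: int, min_n: int = 3) -> float:
    """SD of x - y over samples where both are present; NaN below min_n."""
    mask = ~np.isnan(x) & ~np.isnan(y)
    if mask.sum() < min_n:
        return np.nan
    return float(np.std(x[mask] - y[mask], ddof=ddof))


def delta_ct_stability(cq: CqTable,
                       config: AnalysisConfig | None = None) -> StabilityResult:
    """Comparative delta-Ct stability.

    For every ordered gene pair (i, j) the SD across samples of
    Cq_i - Cq_j is computed on their common samples (at least 3, else the
    pair is skipped with a warning); the stability of gene i is the mean of
    these SDs over all partners j != i.  Units are PCR cycles.
    """
    config = config or AnalysisConfig()
    genes = cq.gene_ids
    if len(genes) < 2:
        raise ValidationError("delta-Ct needs at least 2 genes")
    arr = cq.cq.to_numpy(dtype=float)
    n = len(genes)
    sd = np.full((n, n), np.nan)
    skipped = []
    for i in range(n):
        for j in range(i + 1, n):
            s = _pair_sd(arr[i], arr[j], config.ddof)
            if np.isnan(s):
                skipped.append((genes[i], genes[j]))
            sd[i, j] = sd[j, i] = s
    if skipped:
        warnings.warn(
            f"delta-Ct skipped {len(skipped)} gene pair(s) with fewer than "
            f"3 common samples: {skipped[:5]}...", stacklevel=2,
        )
    off_diag = sd.copy()
    np.fill_diagonal(off_diag, np.nan)
    if np.isnan(off_diag).all(axis=1).any():
        bad = [genes[i] for i in range(n) if np.isnan(off_diag[i]).all()]
        raise ValidationError(
            "delta-Ct: no usable partner pair for genes: " + ", ".join(bad)
        )
    with warnings.catch_warnings():
        warnings.simplefilter("ignore", RuntimeWarning)
        stability = np.nanmean(off_diag, axis=1)
    table = pd.DataFrame({"value": stability}, index=pd.Index(genes, name="gene"))
    table["rank"] = assign_ranks(table["value"])
    extras = {"pairwise_sd": pd.DataFrame(sd, index=genes, columns=genes)}
    return StabilityResult("delta_ct", table, extras)


def bestkeeper(cq: CqTable, config: AnalysisConfig | None = None,
               use_mad: bool = False) -> StabilityResult:
    """BestKeeper descriptive stability.

    Uses complete-case samples (all genes present; at least 3 required).
    The BestKeeper index is the per-sample geometric mean of Cq over all
    input genes (the gene under study included).  The stability value is
    the per-gene SD of Cq (ascending ranking); the original mean-absolute-
    deviation variant is available with ``use_mad=True``.  Extras report
    arithmetic/geometric means, extrema, SD, CV% = 100*SD/mean and the
    Pearson correlation of each gene with the index.
    """
    config = config or AnalysisConfig()
    genes = cq.gene_ids
    if len(genes) < 2:
        raise ValidationError("BestKeeper needs at least 2 genes")
    complete = cq.cq.dropna(axis=1)
    if complete.shape[1] < 3:
        raise ValidationError(
            f"BestKeeper needs >= 3 complete-case samples, found {complete.shape[1]}"
        )
    logger.info("BestKeeper: %d complete-case samples of %d",
                complete.shape[1], cq.cq.shape[1])
    arr = complete.to_numpy(dtype=float)
    mean = arr.mean(axis=1)
    geo_mean = np.exp(np.log(arr).mean(axis=1))
    sd = arr.std(axis=1, ddof=config.ddof)
    mad = np.abs(arr - mean[:, None]).mean(axis=1)
    cv_pct = 100.0 * sd / mean
    index = np.exp(np.log(arr).mean(axis=0))  # per-sample geometric mean
    with np.errstate(invalid="ignore", divide="ignore"):
        r = np.array([
            np.corrcoef(arr[i], index)[0, 1]
            if arr[i].std() > 0 and index.std() > 0 else np.nan
            for i in range(len(genes))
        ])
    stability = mad if use_mad else sd
    table = pd.DataFrame({"value": stability}, index=pd.Index(genes, name="gene"))
    table["rank"] = assign_ranks(table["value"])
    descr = pd.DataFrame(
        {
            "mean": mean, "geo_mean": geo_mean,
            "min": arr.min(axis=1), "max": arr.max(axis=1),
            "sd": sd, "mad": mad, "cv_pct": cv_pct, "r_index": r,
        },
        index=pd.Index(genes, name="gene"),
    )
    extras = {
        "descriptives": descr,
        "index": pd.DataFrame({"index": index}, index=complete.columns),
    }
    logger.debug("BestKeeper stability basis: %s", "MAD" if use_mad else "SD")
    return StabilityResult("bestkeeper", table, extras)


def _pairwise_v_matrix(logq: np.ndarray, genes: list[str], ddof: int) -> np.ndarray:
    """V[j, k] = SD across common samples of log2(q_j) - log2(q_k).

    Each log-ratio vector is anchored at its first common sample before the
    SD (mathematically a no-op), so per-gene scale constants cancel exactly
    and the M-values are bit-invariant to rescaling any gene's q.
    """
    n = len(genes)
    v = np.zeros((n, n))
    for j in range(n):
        for k in range(j + 1, n):
            mask = ~np.isnan(logq[j]) & ~np.isnan(logq[k])
            if mask.sum() < 3:
                raise ValidationError(
                    f"geNorm: genes {genes[j]!r} and {genes[k]!r} share fewer "
                    "than 3 samples"
                )
            d = logq[j][mask] - logq[k][mask]
            d = d - d[0]
            v[j, k] = v[k, j] = float(np.std(d, ddof=ddof))
    return v


def genorm(q: RelativeQuantityMatrix,
           config: AnalysisConfig | None = None,
           pairwise_variation: bool = True) -> StabilityResult:
    """geNorm M-value stability with stepwise exclusion.

    For genes j, k let V_jk be the SD across samples of
    log2(q_j / q_k); the M-value of j is the mean of V_jk over the other
    genes still in play.  The gene with the highest M is removed and M is
    recomputed until two genes remain; those two cannot be ordered and tie
    at rank 1.5.  The reported stability value is the gene's M at the step
    it was removed (survivors: their final M).  Ties on the removal
    decision are broken by removing the lexicographically last gene id.

    Extras carry the initial M-values, the removal order, and (by default)
    the pairwise variation V(n/n+1) = SD of log2(NF_n / NF_{n+1}), where
    NF_n is the per-sample geometric mean of q over the n most stable
    genes.  The conventional V < 0.15 guideline for "enough references" is
    left to the caller.
    """
    config = config or AnalysisConfig()
    genes = q.gene_ids
    if len(genes) < 3:
        raise ValidationError("geNorm needs at least 3 genes")
    logq = (q.log2q.to_numpy(dtype=float) if q.log2q is not None
            else np.log2(q.q.to_numpy(dtype=float)))
    v = _pairwise_v_matrix(logq, genes, config.ddof)

    remaining = list(range(len(genes)))
    removal: list[tuple[str, float]] = []
    m_initial: np.ndarray | None = None
    final_m: dict[int, float] = {}
    while True:
        sub = v[np.ix_(remaining, remaining)]
        m = (sub.sum(axis=1)) / (len(remaining) - 1)
        if m_initial is None:
            m_initial = np.full(len(genes), np.nan)
            m_initial[remaining] = m
        if len(remaining) == 2:
            for idx, mi in zip(remaining, m):
                final_m[idx] = float(mi)
            break
        worst_m = m.max()
        tied = [remaining[i] for i in range(len(remaining))
                if m[i] == worst_m]
        drop = max(tied, key=lambda idx: genes[idx])
        removal.append((genes[drop], float(worst_m)))
        remaining.remove(drop)

    n = len(genes)
    value = pd.Series(np.nan, index=pd.Index(genes, name="gene"))
    rank = pd.Series(np.nan, index=value.index)
    for step, (gene, m_at) in enumerate(removal):
        value[gene] = m_at
        rank[gene] = n - step
    for idx, mi in final_m.items():
        value[genes[idx]] = mi
        rank[genes[idx]] = 1.5
    table = pd.DataFrame({"value": value, "rank": rank})

    extras: dict[str, pd.DataFrame] = {
        "initial_m": pd.DataFrame({"m": m_initial}, index=pd.Index(genes, name="gene")),
        "removal_order": pd.DataFrame(
            [{"step": i + 1, "gene": g, "m_at_removal": m}
             for i, (g, m) in enumerate(removal)]
        ),
    }
    if pairwise_variation and n >= 3:
        order = _stability_order(table)
        extras["pairwise_variation"] = _genorm_pairwise_variation(
            q.q, order, config.ddof
        )
    return StabilityResult("genorm", table, extras)


def _stability_order(table: pd.DataFrame) -> list[str]:
    """Genes from most to least stable; rank ties broken by gene id."""
    return list(table.sort_index().sort_values("rank", kind="mergesort").index)


def _genorm_pairwise_variation(qdf: pd.DataFrame, order: list[str],
                               ddof: int) -> pd.DataFrame:
    rows = []
    for n in range(2, len(order)):
        top = order[:n + 1]
        sub = qdf.loc[top].dropna(axis=1)
        if sub.shape[1] < 3:
            rows.append({"n": n, "v": np.nan})
            continue
        logq = np.log2(sub.to_numpy(dtype=float))
        nf_n = logq[:n].mean(axis=0)       # log2 geometric mean of top n
        nf_n1 = logq[:n + 1].mean(axis=0)
        rows.append({"n": n, "v": float(np.std(nf_n - nf_n1, ddof=ddof))})
    return pd.DataFrame(rows)


def _normfinder_group_variances(y: np.ndarray, ddof: int) -> tuple[np.ndarray, np.ndarray]:
    """Intragroup variance estimates for one group's complete-case matrix.

    ``y`` is genes x samples.  Removing per-sample means (over G genes)
    absorbs part of each gene's own noise, so the raw residual mean squares
    u_g = sum_s z_gs^2 / (n - 1), with
    z = y - rowmean - colmean + grandmean, estimate
    u_g = sigma_g^2 (1 - 2/G) + sigma_bar^2 / G.  Inverting that linear map
    (requires G >= 3) recovers unbiased per-gene variances, clipped at 0.
    Returns (sigma2_g, u_g).
    """
    g_count, n = y.shape
    z = y - y.mean(axis=1, keepdims=True) - y.mean(axis=0, keepdims=True) + y.mean()
    denom = max(n - ddof, 1)
    u = (z ** 2).sum(axis=1) / denom
    sigma_bar2 = u.mean() / (1.0 - 1.0 / g_count)
    sigma2 = (u - sigma_bar2 / g_count) / (1.0 - 2.0 / g_count)
    return np.clip(sigma2, 0.0, None), u


def normfinder(q: RelativeQuantityMatrix,
               groups: pd.Series | Mapping[str, str] | None = None,
               config: AnalysisConfig | None = None) -> StabilityResult:
    """NormFinder model-based stability on y = log2 q.

    Expression is decomposed into gene, sample and gene-by-group effects.
    With two or more groups the stability of gene g is

        rho_g = mean over groups i of ( |d~_gi| + sqrt(sigma2_gi / n_i) ),

    where d_gi = (ybar_gi - ybar_g.) - (ybar_.i - ybar_..) is the
    intergroup deviation, sigma2_gi the intragroup variance, and d~ the
    variance-shrunken deviation d * gamma2 / (gamma2 + sigma2/n) with
    gamma2 = max(0, var_g(d_gi) - mean_g(sigma2_gi / n_i)) estimated per
    group (gamma2 = 0 collapses d~ to 0).  With a single group (or none
    given) the stability is sqrt of the intragroup variance after removing
    per-sample means.

    Complete cases are used within each group; every group needs at least
    2 samples and the panel at least 3 genes.
    """
    config = config or AnalysisConfig()
    genes = q.gene_ids
    if len(genes) < 3:
        raise ValidationError("NormFinder needs at least 3 genes")
    samples = list(q.q.columns)
    if groups is None:
        grp = pd.Series("all", index=samples)
    else:
        grp = pd.Series(groups).reindex(samples)
        if grp.isna().any():
            missing = grp.index[grp.isna()].tolist()
            raise ValidationError(
                "no group label for samples: " + ", ".join(map(str, missing))
            )
    level_order = list(dict.fromkeys(grp))

    # complete cases within each group
    group_mats: dict[str, np.ndarray] = {}
    logq_df = (q.log2q if q.log2q is not None
               else np.log2(q.q.astype(float)))
    for level in level_order:
        cols = [s for s in samples if grp[s] == level]
        sub = logq_df.loc[:, cols].dropna(axis=1)
        if sub.shape[1] < 2:
            raise ValidationError(
                f"NormFinder: group {level!r} has fewer than 2 complete samples"
            )
        group_mats[level] = sub.to_numpy(dtype=float)

    gene_index = pd.Index(genes, name="gene")
    if len(level_order) == 1:
        y = group_mats[level_order[0]]
        sigma2, _ = _normfinder_group_variances(y, config.ddof)
        stability = np.sqrt(sigma2)
        table = pd.DataFrame({"value": stability}, index=gene_index)
        table["rank"] = assign_ranks(table["value"])
        extras = {"sigma2": pd.DataFrame({level_order[0]: sigma2}, index=gene_index)}
        return StabilityResult("normfinder", table, extras)

    all_y = np.concatenate([group_mats[lv] for lv in level_order], axis=1)
    ybar_g = all_y.mean(axis=1)       # per-gene mean over all retained samples
    ybar_all = all_y.mean()
    d = {}
    sigma2 = {}
    n_i = {}
    for level in level_order:
        y = group_mats[level]
        n_i[level] = y.shape[1]
        ybar_gi = y.mean(axis=1)
        ybar_i = y.mean()
        d[level] = (ybar_gi - ybar_g) - (ybar_i - ybar_all)
        sigma2[level], _ = _normfinder_group_variances(y, config.ddof)

    rho = np.zeros(len(genes))
    d_shrunk = {}
    for level in level_order:
        var_term = sigma2[level] / n_i[level]
        gamma2 = max(0.0, float(np.var(d[level], ddof=1)) - float(var_term.mean()))
        with np.errstate(invalid="ignore", divide="ignore"):
            shrink = np.where(gamma2 + var_term > 0,
                              gamma2 / np.where(gamma2 + var_term > 0,
                                                gamma2 + var_term, 1.0),
                              0.0)
        d_shrunk[level] = d[level] * shrink
        rho += np.abs(d_shrunk[level]) + np.sqrt(var_term)
    rho /= len(level_order)

    table = pd.DataFrame({"value": rho}, index=gene_index)
    table["rank"] = assign_ranks(table["value"])
    extras = {
        "intergroup_d": pd.DataFrame(d, index=gene_index),
        "intergroup_d_shrunk": pd.DataFrame(d_shrunk, index=gene_index),
        "sigma2": pd.DataFrame(sigma2, index=gene_index),
    }
    return StabilityResult("normfinder", table, extras)


def run_all_methods(cq: CqTable,
                    config: AnalysisConfig | None = None,
                    efficiency: float | Mapping[str, float] | None = None,
                    group_by: str | None = "group") -> dict[str, StabilityResult]:
    """Run the four stability algorithms on one Cq table.

    delta-Ct and BestKeeper work on raw Cq; geNorm and NormFinder on
    relative quantities.  ``group_by`` names the metadata column used as
    the NormFinder grouping (None = single group).
    """
    config = config or AnalysisConfig()
    q = cq_to_relative_quantity(cq, efficiency, config)
    groups = None
    if group_by is not None:
        if group_by not in cq.metadata.columns:
            raise ValidationError(f"metadata has no column {group_by!r}")
        groups = cq.metadata.loc[cq.sample_ids, group_by]
    return {
        "delta_ct": delta_ct_stability(cq, config),
        "bestkeeper": bestkeeper(cq, config),
        "genorm": genorm(q, config),
        "normfinder": normfinder(q, groups, config),
    }
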