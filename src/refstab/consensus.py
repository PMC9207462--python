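"""Comprehensive (RefFinder-style) consensus ranking.

Each stability algorithm contributes a fractional per-gene rank
(1 = most stable); the consensus weight of a gene is the geometric mean of
its ranks over the supplied methods, and the final order is ascending in
that geometric mean.  Ranks — not the method-specific stability values —
are aggregated, so methods with different units contribute equally.
"""
from __future__ import annotations

from typing import Iterable, Sequence

import numpy as np
import pandas as pd
from scipy.stats import rankdata

from .datamodel import ConsensusRanking, StabilityResult, ValidationError


def assign_ranks(values: pd.Series | Sequence[float]) -> pd.Series:
    """Fractional (mean-of-span) ranks, ascending: 1 = smallest value."""
    s = pd.Series(values, dtype=float)
    if s.empty:
        raise ValidationError("cannot rank an empty value set")
    if not np.isfinite(s.to_numpy()).all():
        bad = s.index[~np.isfinite(s)].tolist()
        raise ValidationError(f"non-finite stability values for: {bad}")
    return pd.Series(rankdata(s.to_numpy(), method="average"), index=s.index)


def reffinder_consensus(results: Iterable[StabilityResult]) -> ConsensusRanking:
    """Aggregate 2-4 method rankings by per-gene geometric mean rank.

    All results must cover the same gene set (a hard error lists the
    symmetric difference otherwise).  Fractional input ranks (such as
    geNorm's tied final pair) enter the geometric mean as-is.  The final
    rank is fractional over the geomeans; row order breaks remaining ties
    by gene id.
    """
    results = list(results)
    if not 2 <= len(results) <= 4:
        raise ValidationError("consensus needs between 2 and 4 method results")
    methods = [r.method for r in results]
    if len(set(methods)) != len(methods):
        raise ValidationError("duplicate methods supplied to consensus")
    base = set(results[0].table.index)
    for r in results[1:]:
        other = set(r.table.index)
        if other != base:
            diff = sorted(base.symmetric_difference(other))
            raise ValidationError(
                f"gene sets differ between {results[0].method} and {r.method}: "
                + ", ".join(diff)
            )

    genes = sorted(base)
    # canonical column order makes the result invariant to supply order
    rank_cols = {
        f"rank_{r.method}": r.table["rank"].reindex(genes)
        for r in sorted(results, key=lambda r: r.method)
    }
    table = pd.DataFrame(rank_cols, index=pd.Index(genes, name="gene"))
    log_ranks = np.log(table.to_numpy(dtype=float))
    table["geomean"] = np.exp(log_ranks.mean(axis=1))
    table["final_rank"] = assign_ranks(table["geomean"])
    table = table.sort_index().sort_values("geomean", kind="mergesort")
    return ConsensusRanking(table, tuple(sorted(methods)))
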