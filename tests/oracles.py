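"""Independent brute-force references used to cross-check the pipeline.

These deliberately share no code with the package: geNorm is recomputed
from the raw definitions at every exclusion step, and the geometric-mean
rank is evaluated with plain arithmetic.
"""
import math

import numpy as np
import pandas as pd


def _pair_v(qdf: pd.DataFrame, g: str, h: str, ddof: int) -> float:
    x = np.log2(qdf.loc[g].to_numpy(dtype=float))
    y = np.log2(qdf.loc[h].to_numpy(dtype=float))
    mask = ~np.isnan(x) & ~np.isnan(y)
    return float(np.std(x[mask] - y[mask], ddof=ddof))


def genorm_bruteforce(qdf: pd.DataFrame, ddof: int = 1):
    """Stepwise geNorm, recomputing every pairwise V from scratch per step.

    Returns (value, rank) dicts keyed by gene: value is the M at the step
    the gene was removed (survivors: final M), rank is the reverse removal
    order with the final two tied at 1.5.  Removal ties drop the
    lexicographically last gene id.
    """
    genes = list(qdf.index)
    remaining = list(genes)
    value: dict[str, float] = {}
    rank: dict[str, float] = {}
    n_removed = 0
    while len(remaining) > 2:
        m = {
            g: np.mean([_pair_v(qdf, g, h, ddof) for h in remaining if h != g])
            for g in remaining
        }
        worst = max(m.values())
        drop = max(g for g in remaining if m[g] == worst)
        value[drop] = worst
        rank[drop] = len(genes) - n_removed
        n_removed += 1
        remaining.remove(drop)
    g, h = remaining
    v = _pair_v(qdf, g, h, ddof)
    value[g] = value[h] = v
    rank[g] = rank[h] = 1.5
    return value, rank


def geomean_rank(ranks) -> float:
    """Plain-arithmetic geometric mean of a rank tuple."""
    prod = 1.0
    for r in ranks:
        prod *= r
    return prod ** (1.0 / len(ranks))


def delta_ct_bruteforce(cq: pd.DataFrame, ddof: int = 1) -> dict[str, float]:
    """Mean pairwise SD of Cq differences, straight from the definition."""
    out = {}
    for g in cq.index:
        sds = []
        for h in cq.index:
            if h == g:
                continue
            d = cq.loc[g].to_numpy(dtype=float) - cq.loc[h].to_numpy(dtype=float)
            d = d[~np.isnan(d)]
            sds.append(np.sqrt(sum((x - np.mean(d)) ** 2 for x in d) / (len(d) - ddof)))
        out[g] = math.fsum(sds) / len(sds)
    return out
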