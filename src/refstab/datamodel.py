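"""Shared domain types for the reference-gene pipeline.

Matrices are stored as pandas DataFrames with gene identifiers as the row
index and sample identifiers as the column index.  Missing quantification
cycles ("no amplification") are encoded as NaN and are *never* imputed;
each downstream computation applies pairwise deletion and fails loudly when
it drops below its minimum sample count.
"""
from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

logger = logging.getLogger("refstab")

REQUIRED_METADATA_COLUMNS = ("group", "condition")
OPTIONAL_METADATA_COLUMNS = ("tissue", "cultivar", "replicate")

STABILITY_METHODS = ("delta_ct", "bestkeeper", "genorm", "normfinder")


class ValidationError(ValueError):
    """An input violated a structural invariant of the pipeline."""


def _duplicates(index: pd.Index) -> list[str]:
    return sorted(index[index.duplicated()].unique().tolist())


def _check_unique(index: pd.Index, what: str) -> None:
    dups = _duplicates(index)
    if dups:
        raise ValidationError(f"duplicate {what} identifiers: {', '.join(map(str, dups))}")


@dataclass(frozen=True)
class AnalysisConfig:
    """Pipeline-wide thresholds and numeric conventions.

    Parameters
    ----------
    mv_min : float
        Minimum mean FPKM for a screening candidate (strict ``>``).
    mfc_max : float
        Maximum fold change (max/min FPKM) allowed, strict ``<``.
    cv_max : float
        Maximum coefficient of variation (SD/mean) allowed, strict ``<``.
    efficiency_default : float
        Default amplification base E used to convert Cq into relative
        quantities; 2.0 corresponds to perfect doubling per cycle.
    log_base : float
        Base of the fold-change exponentiation in ddCq quantification.
    sd_mode : {"sample", "population"}
        Denominator convention for every standard deviation in the
        pipeline; "sample" uses n-1.
    tie_method : {"fractional"}
        Tie handling in rankings (mean of the spanned ranks).
    rng_seed : int
        Seed for any stochastic helper that does not take its own.
    """

    mv_min: float = 50.0
    mfc_max: float = 1.5
    cv_max: float = 0.1
    efficiency_default: float = 2.0
    log_base: float = 2.0
    sd_mode: str = "sample"
    tie_method: str = "fractional"
    rng_seed: int = 0

    def __post_init__(self) -> None:
        for name in ("mv_min", "mfc_max", "cv_max"):
            if not getattr(self, name) > 0:
                raise ValidationError(f"{name} must be strictly positive")
        if not 1.0 < self.efficiency_default <= 3.0:
            raise ValidationError("efficiency_default must lie in (1, 3]")
        if self.sd_mode not in ("sample", "population"):
            raise ValidationError("sd_mode must be 'sample' or 'population'")
        if self.tie_method != "fractional":
            raise ValidationError("only fractional tie handling is supported")

    @property
    def ddof(self) -> int:
        return 1 if self.sd_mode == "sample" else 0


@dataclass
class ExpressionMatrix:
    """Non-negative FPKM abundances, genes x samples."""

    values: pd.DataFrame

    def __post_init__(self) -> None:
        v = self.values
        _check_unique(v.index, "gene")
        _check_unique(v.columns, "sample")
        if v.shape[1] < 2:
            raise ValidationError("expression matrix needs at least 2 samples")
        arr = v.to_numpy(dtype=float)
        if not np.isfinite(arr).all():
            raise ValidationError("expression matrix contains non-finite values")
        if (arr < 0).any():
            g, s = np.argwhere(arr < 0)[0]
            raise ValidationError(
                f"negative FPKM at gene {v.index[g]!r}, sample {v.columns[s]!r}"
            )

    @property
    def gene_ids(self) -> list[str]:
        return list(self.values.index)

    @property
    def sample_ids(self) -> list[str]:
        return list(self.values.columns)

    @property
    def n_samples(self) -> int:
        return self.values.shape[1]


def validate_metadata(metadata: pd.DataFrame) -> pd.DataFrame:
    """Validate a sample-metadata table indexed by sample_id."""
    _check_unique(metadata.index, "sample")
    for col in REQUIRED_METADATA_COLUMNS:
        if col not in metadata.columns:
            raise ValidationError(f"metadata is missing required column {col!r}")
    if metadata["group"].nunique() < 1:
        raise ValidationError("metadata group column has no levels")
    if "replicate" in metadata.columns:
        rep = pd.to_numeric(metadata["replicate"], errors="coerce")
        if rep.notna().any() and (rep.dropna() < 1).any():
            raise ValidationError("replicate numbers must be positive integers")
    return metadata


@dataclass
class CqTable:
    """Quantification-cycle values (genes x samples) plus sample metadata.

    Missing Cq entries are NaN.  Genes with fewer than three present values
    are retained but flagged; computations that need them fail loudly.
    """

    cq: pd.DataFrame
    metadata: pd.DataFrame
    flagged_genes: tuple[str, ...] = field(default=())

    def __post_init__(self) -> None:
        _check_unique(self.cq.index, "gene")
        _check_unique(self.cq.columns, "sample")
        validate_metadata(self.metadata)
        missing_meta = [s for s in self.cq.columns if s not in self.metadata.index]
        if missing_meta:
            raise ValidationError(
                "samples absent from metadata: " + ", ".join(map(str, missing_meta))
            )
        arr = self.cq.to_numpy(dtype=float)
        present = ~np.isnan(arr)
        if not np.isfinite(arr[present]).all() or (arr[present] <= 0).any():
            raise ValidationError("present Cq values must be finite and > 0")
        low = self.cq.index[present.sum(axis=1) < 3].tolist()
        if low:
            warnings.warn(
                f"genes with fewer than 3 present Cq values: {', '.join(low)}",
                stacklevel=2,
            )
        object.__setattr__(self, "flagged_genes", tuple(low))

    @property
    def gene_ids(self) -> list[str]:
        return list(self.cq.index)

    @property
    def sample_ids(self) -> list[str]:
        return list(self.cq.columns)

    @property
    def groups(self) -> pd.Series:
        """Group label per Cq sample, in Cq column order."""
        return self.metadata.loc[self.cq.columns, "group"]

    def subset_genes(self, genes: list[str]) -> "CqTable":
        missing = [g for g in genes if g not in self.cq.index]
        if missing:
            raise ValidationError("unknown genes: " + ", ".join(missing))
        return CqTable(self.cq.loc[genes], self.metadata)

    def subset_samples(self, samples: list[str]) -> "CqTable":
        return CqTable(self.cq.loc[:, samples], self.metadata.loc[samples])


@dataclass
class RelativeQuantityMatrix:
    """Per-gene relative quantities q = E^(Cq_min - Cq), in (0, 1].

    The per-gene maximum over present samples is 1 by construction; missing
    Cq entries stay missing.
    """

    q: pd.DataFrame
    efficiency: pd.Series
    # log2 quantities computed straight from Cq (no exp2/log2 round trip),
    # so log-ratio methods stay exact when the Cq arithmetic is exact
    log2q: pd.DataFrame | None = None

    def __post_init__(self) -> None:
        _check_unique(self.q.index, "gene")
        _check_unique(self.q.columns, "sample")
        arr = self.q.to_numpy(dtype=float)
        present = ~np.isnan(arr)
        if (arr[present] <= 0).any() or (arr[present] > 1 + 1e-9).any():
            raise ValidationError("relative quantities must lie in (0, 1]")
        if (self.efficiency <= 1).any():
            raise ValidationError("amplification efficiency base must exceed 1")

    @property
    def gene_ids(self) -> list[str]:
        return list(self.q.index)


@dataclass
class StabilityResult:
    """Output of one stability algorithm: per-gene value and fractional rank.

    ``table`` is indexed by gene with columns ``value`` (method-specific
    units; lower = more stable) and ``rank`` (fractional, 1 = most stable).
    """

    method: str
    table: pd.DataFrame
    extras: dict[str, pd.DataFrame] = field(default_factory=dict)

    def __post_init__(self) -> None:
        if self.method not in STABILITY_METHODS:
            raise ValidationError(f"unknown stability method {self.method!r}")
        for col in ("value", "rank"):
            if col not in self.table.columns:
                raise ValidationError(f"stability table lacks column {col!r}")

    @property
    def values(self) -> pd.Series:
        return self.table["value"]

    @property
    def ranks(self) -> pd.Series:
        return self.table["rank"]


@dataclass
class ConsensusRanking:
    """Geometric-mean aggregation of per-method ranks.

    ``table`` is indexed by gene with one ``rank_<method>`` column per input
    method plus ``geomean`` and ``final_rank``; rows are sorted by
    (geomean, gene id).
    """

    table: pd.DataFrame
    methods: tuple[str, ...]

    @property
    def order(self) -> list[str]:
        return list(self.table.index)


@dataclass
class DilutionSeries:
    """A fitted standard curve from a dilution series.

    ``efficiency_percent`` is None when the fitted slope is non-negative
    (a primer-failure signal), in which case a warning was emitted.
    """

    points: pd.DataFrame  # columns: concentration, cq
    slope: float
    intercept: float
    r_squared: float
    efficiency_percent: float | None


@dataclass
class QuantificationResult:
    """Relative expression of one target gene by the ddCq method."""

    target: str
    references: tuple[str, ...]
    control: str
    samples: pd.DataFrame  # per sample: group, condition, dcq, ddcq, rq
    summary: pd.DataFrame  # per group: n, mean_ddcq, sd_ddcq, mean_rq, sd_rq

    def __post_init__(self) -> None:
        if (self.samples["rq"] <= 0).any():
            raise ValidationError("relative quantities must be positive")
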