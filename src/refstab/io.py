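"""Readers, writers, configuration and logging.

File dialects: wide TSV/CSV with genes as rows and samples as columns for
expression and Cq matrices; a sample-metadata table with columns
``sample_id, group, condition[, tissue, cultivar, replicate]``; a flat YAML
file for configuration.  The delimiter is inferred from the file suffix
(.csv -> comma, otherwise tab) unless given explicitly.

Floats are serialized with 6 significant digits; re-reading a written
report reproduces values to that precision.
"""
from __future__ import annotations

import logging
import sys
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from .datamodel import (
    AnalysisConfig,
    ConsensusRanking,
    CqTable,
    DilutionSeries,
    ExpressionMatrix,
    QuantificationResult,
    StabilityResult,
    ValidationError,
    validate_metadata,
)

logger = logging.getLogger("refstab")

FLOAT_FORMAT = "%.6g"


def setup_logging(verbosity: int = 0) -> None:
    """Timestamped log lines to stderr; -v = INFO, -vv = DEBUG."""
    level = logging.WARNING - 10 * min(verbosity, 2)
    handler = logging.StreamHandler(sys.stderr)
    handler.setFormatter(
        logging.Formatter("%(asctime)s %(levelname)s %(name)s: %(message)s")
    )
    logger.handlers[:] = [handler]
    logger.setLevel(level)


def _infer_sep(path: Path, sep: str | None) -> str:
    if sep is not None:
        return sep
    return "," if path.suffix.lower() == ".csv" else "\t"


def _read_wide_numeric(path: Path, sep: str | None, what: str) -> pd.DataFrame:
    """Read a genes-x-samples table; empty cells -> NaN, bad cells -> error
    with row/column coordinates."""
    if not path.exists():
        raise FileNotFoundError(path)
    raw = pd.read_csv(
        path, sep=_infer_sep(path, sep), index_col=0, dtype=str,
        keep_default_na=False,
    )
    raw.index = raw.index.astype(str).str.strip()
    raw.columns = raw.columns.astype(str).str.strip()
    cells = raw.apply(lambda col: col.str.strip())
    numeric = cells.apply(lambda col: pd.to_numeric(col.replace("", np.nan),
                                                    errors="coerce"))
    bad = numeric.isna() & (cells != "") & ~cells.isin(("NA", "NaN", "nan"))
    if bad.to_numpy().any():
        g, s = np.argwhere(bad.to_numpy())[0]
        raise ValidationError(
            f"non-numeric {what} cell {cells.iat[g, s]!r} at "
            f"gene {raw.index[g]!r}, sample {raw.columns[s]!r}"
        )
    return numeric.astype(float)


def read_expression_matrix(path: str | Path, sep: str | None = None) -> ExpressionMatrix:
    """Read a wide FPKM matrix (first column gene ids, header sample ids).

    Row and column order are preserved as in the file.
    """
    path = Path(path)
    values = _read_wide_numeric(path, sep, "FPKM")
    if values.isna().to_numpy().any():
        g, s = np.argwhere(values.isna().to_numpy())[0]
        raise ValidationError(
            f"missing FPKM at gene {values.index[g]!r}, sample {values.columns[s]!r}"
        )
    logger.info("read expression matrix %s: %d genes x %d samples",
                path, *values.shape)
    return ExpressionMatrix(values)


def read_sample_metadata(path: str | Path, sep: str | None = None) -> pd.DataFrame:
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(path)
    meta = pd.read_csv(path, sep=_infer_sep(path, sep), dtype=str,
                       keep_default_na=False)
    meta.columns = meta.columns.str.strip()
    if "sample_id" not in meta.columns:
        raise ValidationError("metadata must have a sample_id column")
    for col in meta.columns:
        meta[col] = meta[col].str.strip()
    meta = meta.set_index("sample_id")
    if "replicate" in meta.columns:
        meta["replicate"] = pd.to_numeric(meta["replicate"].replace("", np.nan))
    return validate_metadata(meta)


def read_cq_table(cq_path: str | Path, metadata_path: str | Path,
                  sep: str | None = None) -> CqTable:
    """Read a wide Cq matrix and join it with sample metadata.

    Empty cells become missing values (never zero).  A sample present in the
    Cq header but absent from the metadata is a hard error; genes with fewer
    than three present values are flagged with a warning.
    """
    cq = _read_wide_numeric(Path(cq_path), sep, "Cq")
    meta = read_sample_metadata(metadata_path, sep)
    logger.info("read Cq table %s: %d genes x %d samples", cq_path, *cq.shape)
    return CqTable(cq, meta)


def collapse_technical_replicates(cq: pd.DataFrame, wells_to_sample: dict[str, str],
                                  how: str = "mean") -> pd.DataFrame:
    """Collapse technical replicate wells into one Cq column per sample.

    Optional pre-step for plates exported one column per well; ``how`` is
    "mean" or "median" over present wells.  The pipeline readers otherwise
    expect already-collapsed values.
    """
    if how not in ("mean", "median"):
        raise ValidationError("how must be 'mean' or 'median'")
    grouped = cq.T.groupby(cq.columns.map(wells_to_sample.get))
    out = (grouped.mean() if how == "mean" else grouped.median()).T
    return out


def _result_frame(result) -> pd.DataFrame:
    """Canonical tabular form of any pipeline result, for serialization."""
    if isinstance(result, StabilityResult):
        df = result.table.reset_index(names="gene")
        return df[["gene", "value", "rank"]]
    if isinstance(result, ConsensusRanking):
        return result.table.reset_index(names="gene")
    if isinstance(result, QuantificationResult):
        return result.samples.reset_index(names="sample_id")
    if isinstance(result, DilutionSeries):
        return pd.DataFrame(
            [{
                "slope": result.slope,
                "intercept": result.intercept,
                "r_squared": result.r_squared,
                "efficiency_percent": (np.nan if result.efficiency_percent is None
                                       else result.efficiency_percent),
            }]
        )
    if isinstance(result, ExpressionMatrix):
        return result.values.reset_index(names="gene")
    if isinstance(result, pd.DataFrame):
        return result.reset_index() if result.index.name else result
    raise TypeError(f"cannot serialize result of type {type(result).__name__}")


def write_report(result, path: str | Path, sep: str | None = None) -> None:
    """Write a pipeline result as a delimited text report.

    Column order is deterministic; floats carry 6 significant digits so a
    round-trip read reproduces values to that precision.  An empty result
    yields a header-only file.
    """
    path = Path(path)
    df = _result_frame(result)
    try:
        df.to_csv(path, sep=_infer_sep(path, sep), index=False,
                  float_format=FLOAT_FORMAT)
    except OSError as exc:
        raise OSError(f"cannot write report to {path}: {exc}") from exc
    logger.info("wrote %d rows to %s", len(df), path)


def read_stability_report(path: str | Path, method: str,
                          sep: str | None = None) -> StabilityResult:
    df = pd.read_csv(Path(path), sep=_infer_sep(Path(path), sep))
    df["gene"] = df["gene"].astype(str).str.strip()
    table = df.set_index("gene")[["value", "rank"]].astype(float)
    return StabilityResult(method, table)


def read_consensus_report(path: str | Path, sep: str | None = None) -> ConsensusRanking:
    df = pd.read_csv(Path(path), sep=_infer_sep(Path(path), sep))
    df["gene"] = df["gene"].astype(str).str.strip()
    df = df.set_index("gene")
    methods = tuple(c[len("rank_"):] for c in df.columns if c.startswith("rank_"))
    return ConsensusRanking(df, methods)


def load_config(path: str | Path | None) -> AnalysisConfig:
    """Load an AnalysisConfig from a flat YAML key/value file.

    Every field is optional and falls back to its default.
    """
    if path is None:
        return AnalysisConfig()
    raw = yaml.safe_load(Path(path).read_text()) or {}
    if not isinstance(raw, dict):
        raise ValidationError("config file must be a flat key/value mapping")
    known = set(AnalysisConfig.__dataclass_fields__)
    unknown = set(raw) - known
    if unknown:
        raise ValidationError("unknown config keys: " + ", ".join(sorted(unknown)))
    return AnalysisConfig(**raw)
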