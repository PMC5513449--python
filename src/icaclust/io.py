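"""Reading, validation and preprocessing of count and expression tables.

The pipeline's in-memory containers are plain :class:`pandas.DataFrame`
objects:

* a **count matrix** — genes in rows (unique index of gene ids), sequencing
  libraries in columns (unique sample ids), non-negative integer read counts;
* a **sample sheet** — one row per library with columns ``sample``, ``time``,
  ``replicate`` and optionally ``condition``;
* a **series matrix** — genes in rows, ordered time points in columns,
  real-valued mean expression (or log2 fold-change) per time point.  This is
  the ``Y`` matrix the decomposition operates on.
"""

from __future__ import annotations

import logging
from pathlib import Path

import numpy as np
import pandas as pd

logger = logging.getLogger(__name__)

__all__ = [
    "read_count_matrix",
    "read_sample_sheet",
    "validate_count_matrix",
    "validate_series_matrix",
    "filter_min_total",
    "average_replicates",
    "log2_fold_change",
    "write_series_matrix",
]


def _sep_for(path: Path, fmt: str | None) -> str:
    if fmt is None:
        fmt = "csv" if path.suffix.lower() == ".csv" else "tsv"
    if fmt not in ("tsv", "csv"):
        raise ValueError(f"unknown table format {fmt!r}; expected 'tsv' or 'csv'")
    return "," if fmt == "csv" else "\t"


def validate_count_matrix(counts: pd.DataFrame) -> pd.DataFrame:
    """Check the count-matrix invariants and return the frame unchanged.

    Entries must be finite, integral and non-negative; gene ids (index) and
    sample ids (columns) must be unique.
    """
    if counts.index.duplicated().any():
        dups = counts.index[counts.index.duplicated()].unique().tolist()
        raise ValueError(f"duplicate gene ids: {dups}")
    if counts.columns.duplicated().any():
        dups = counts.columns[counts.columns.duplicated()].unique().tolist()
        raise ValueError(f"duplicate sample ids: {dups}")
    values = counts.to_numpy()
    if values.size and not np.isfinite(values.astype(float)).all():
        raise ValueError("count matrix contains missing or non-finite entries")
    if (values.astype(float) < 0).any():
        bad = counts.index[(values.astype(float) < 0).any(axis=1)][0]
        raise ValueError(f"negative count found (gene {bad!r}); counts must be >= 0")
    if not np.array_equal(values.astype(float), np.round(values.astype(float))):
        raise ValueError("count matrix contains non-integral entries")
    return counts


def read_count_matrix(path: str | Path, format: str | None = None) -> pd.DataFrame:
    """Read a genes x samples count table (first column gene ids, header row
    sample ids) from TSV or CSV and validate it.
    """
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(f"count matrix file not found: {path}")
    sep = _sep_for(path, format)
    raw = pd.read_csv(path, sep=sep, index_col=0)
    try:
        values = raw.apply(pd.to_numeric)
    except (ValueError, TypeError) as exc:
        # locate the first offending cell for the error message
        for col in raw.columns:
            coerced = pd.to_numeric(raw[col], errors="coerce")
            bad = coerced.isna() & raw[col].notna()
            if bad.any():
                row = raw.index[bad.to_numpy().nonzero()[0][0]]
                raise ValueError(
                    f"non-numeric count at gene {row!r}, sample {col!r}"
                ) from exc
        raise
    counts = validate_count_matrix(values)
    return counts.astype(np.int64)


def read_sample_sheet(path: str | Path) -> pd.DataFrame:
    """Read a sample sheet CSV with columns sample, time, replicate[, condition]."""
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(f"sample sheet not found: {path}")
    sheet = pd.read_csv(path, dtype=str)
    required = {"sample", "time", "replicate"}
    missing = required - set(sheet.columns)
    if missing:
        raise ValueError(f"sample sheet missing columns: {sorted(missing)}")
    if sheet["sample"].duplicated().any():
        dups = sheet.loc[sheet["sample"].duplicated(), "sample"].tolist()
        raise ValueError(f"duplicate sample ids in sheet: {dups}")
    return sheet


def validate_series_matrix(series: pd.DataFrame) -> pd.DataFrame:
    """Check series-matrix invariants: finite entries, >= 2 time points and at
    least as many genes as time points."""
    values = series.to_numpy(dtype=float)
    if not np.isfinite(values).all():
        raise ValueError("series matrix contains missing or non-finite entries")
    if series.shape[1] < 2:
        raise ValueError("series matrix needs at least 2 time points")
    if series.shape[0] < series.shape[1]:
        raise ValueError(
            f"series matrix needs at least as many genes ({series.shape[0]}) "
            f"as time points ({series.shape[1]})"
        )
    if series.index.duplicated().any():
        raise ValueError("duplicate gene ids in series matrix")
    return series


def filter_min_total(counts: pd.DataFrame, min_total: int = 10) -> pd.DataFrame:
    """Keep genes whose read-count total over all libraries is at least
    ``min_total`` (inclusive boundary), preserving gene order.

    The default of 10 reflects the common low-abundance pre-filter for RNA-seq
    libraries: transcripts supported by fewer than ten mapped reads across all
    libraries carry too little signal to profile over time.
    """
    if min_total < 0:
        raise ValueError("min_total must be >= 0")
    keep = counts.sum(axis=1) >= min_total
    removed = int((~keep).sum())
    if removed:
        logger.info("filter_min_total: removed %d of %d genes", removed, len(counts))
    return counts.loc[keep]


def average_replicates(
    counts: pd.DataFrame,
    sheet: pd.DataFrame,
    condition: str | None = None,
    time_order: list[str] | None = None,
) -> pd.DataFrame:
    """Average replicate libraries per time point into a genes x time series
    matrix.

    Parameters
    ----------
    counts : genes x samples count matrix.
    sheet : sample sheet with columns sample, time, replicate[, condition].
    condition : restrict to libraries of this condition (e.g. one breed).
    time_order : explicit ordering of the time columns; defaults to the order
        in which the time labels first appear in the sheet.
    """
    sheet = sheet.copy()
    if condition is not None:
        if "condition" not in sheet.columns:
            raise ValueError("sample sheet has no 'condition' column")
        if condition not in set(sheet["condition"]):
            raise ValueError(f"condition {condition!r} absent from sample sheet")
        sheet = sheet[sheet["condition"] == condition]
    missing = set(sheet["sample"]) - set(counts.columns)
    if missing:
        raise ValueError(f"samples in sheet but not in count matrix: {sorted(missing)}")
    if time_order is None:
        time_order = list(dict.fromkeys(sheet["time"]))
    by_time = {}
    for t in time_order:
        samples = sheet.loc[sheet["time"] == t, "sample"].tolist()
        if not samples:
            raise ValueError(f"time point {t!r} has no samples after restriction")
        by_time[t] = counts[samples].mean(axis=1)
    series = pd.DataFrame(by_time, index=counts.index)[time_order]
    return validate_series_matrix(series)


def log2_fold_change(
    a: pd.DataFrame, b: pd.DataFrame, pseudocount: float = 1.0
) -> pd.DataFrame:
    """Per-gene, per-time log2((a + pseudocount) / (b + pseudocount)).

    Both series matrices must share gene ids and time labels.  A pseudocount
    of 1 keeps zero-expression time points finite; with pseudocount 0 all
    entries must be positive.
    """
    if not a.index.equals(b.index):
        diff = sorted(set(a.index).symmetric_difference(set(b.index)))
        raise ValueError(f"gene sets differ between the two matrices: {diff}")
    if list(a.columns) != list(b.columns):
        raise ValueError(
            f"time labels differ: {list(a.columns)} vs {list(b.columns)}"
        )
    if pseudocount < 0:
        raise ValueError("pseudocount must be >= 0")
    av = a.to_numpy(dtype=float) + pseudocount
    bv = b.to_numpy(dtype=float) + pseudocount
    if (av <= 0).any() or (bv <= 0).any():
        raise ValueError("non-positive values; use a positive pseudocount")
    fc = pd.DataFrame(np.log2(av / bv), index=a.index, columns=a.columns)
    return validate_series_matrix(fc)


def write_series_matrix(series: pd.DataFrame, path: str | Path) -> None:
    series.to_csv(path, sep="\t", index_label="gene_id")
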