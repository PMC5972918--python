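"""Expression-matrix container and file I/O.

The canonical in-memory layout is rows = samples, columns = genes
(conditional attributes), with one categorical class label per sample.
Expression files in the wild are frequently genes x samples, so the loader
takes an explicit ``orientation`` flag; no silent guessing.
"""

from __future__ import annotations

import json
import logging
from dataclasses import dataclass, field, replace
from pathlib import Path
from typing import Sequence

import numpy as np
import pandas as pd

logger = logging.getLogger(__name__)

__all__ = [
    "ExpressionDataset",
    "load_dataset",
    "drop_constant_columns",
    "minmax_normalize",
    "zscore_normalize",
    "write_result",
    "read_result",
]


class DatasetError(ValueError):
    """Raised when an expression dataset violates its structural contract."""


@dataclass(frozen=True)
class ExpressionDataset:
    """A sample x attribute real matrix with per-sample class labels.

    Parameters
    ----------
    matrix : ndarray, shape (n_samples, n_attributes)
        Real-valued expression intensities (unitless).
    labels : ndarray, shape (n_samples,)
        Categorical class label per sample; at least one sample per class.
    attribute_ids : tuple of str
        One identifier per column. Loaders keep 1-based column positions
        available through :meth:`positions` even when header names exist,
        because published gene subsets are routinely reported as 1-based
        column indices.
    sample_ids : tuple of str
        One identifier per row.
    """

    matrix: np.ndarray
    labels: np.ndarray
    attribute_ids: tuple = ()
    sample_ids: tuple = ()

    def __post_init__(self):
        m = np.asarray(self.matrix, dtype=float)
        if m.ndim != 2:
            raise DatasetError(f"matrix must be 2-D, got ndim={m.ndim}")
        labels = np.asarray(self.labels)
        if labels.shape[0] != m.shape[0]:
            raise DatasetError(
                f"sample axis mismatch: matrix has {m.shape[0]} rows "
                f"but {labels.shape[0]} labels were given"
            )
        attr = tuple(self.attribute_ids) or tuple(
            str(j + 1) for j in range(m.shape[1])
        )
        if len(attr) != m.shape[1]:
            raise DatasetError(
                f"attribute axis mismatch: matrix has {m.shape[1]} columns "
                f"but {len(attr)} attribute_ids were given"
            )
        samp = tuple(self.sample_ids) or tuple(
            str(i + 1) for i in range(m.shape[0])
        )
        if len(samp) != m.shape[0]:
            raise DatasetError(
                f"sample axis mismatch: matrix has {m.shape[0]} rows "
                f"but {len(samp)} sample_ids were given"
            )
        if np.isnan(m).any():
            i, j = np.argwhere(np.isnan(m))[0]
            raise DatasetError(f"missing value at row {i + 1}, column {j + 1}")
        if len(set(map(str, labels.tolist()))) < 1 or labels.shape[0] == 0:
            raise DatasetError("dataset has no samples")
        object.__setattr__(self, "matrix", m)
        object.__setattr__(self, "labels", labels)
        object.__setattr__(self, "attribute_ids", attr)
        object.__setattr__(self, "sample_ids", samp)

    @property
    def n_samples(self) -> int:
        return self.matrix.shape[0]

    @property
    def n_attributes(self) -> int:
        return self.matrix.shape[1]

    @property
    def classes(self) -> np.ndarray:
        return np.unique(self.labels)

    @property
    def n_classes(self) -> int:
        return self.classes.size

    def positions(self, ids: Sequence) -> np.ndarray:
        """Map attribute identifiers to 0-based column positions."""
        index = {a: j for j, a in enumerate(self.attribute_ids)}
        out = []
        for a in ids:
            key = a if a in index else str(a)
            if key not in index:
                raise KeyError(f"unknown attribute id {a!r}")
            out.append(index[key])
        return np.asarray(out, dtype=int)

    def subset(self, ids: Sequence) -> "ExpressionDataset":
        """Restrict to the given attribute ids, preserving their order."""
        cols = self.positions(ids)
        return ExpressionDataset(
            self.matrix[:, cols],
            self.labels,
            tuple(self.attribute_ids[c] for c in cols),
            self.sample_ids,
        )

    def to_frame(self) -> pd.DataFrame:
        df = pd.DataFrame(
            self.matrix, index=list(self.sample_ids), columns=list(self.attribute_ids)
        )
        df.insert(0, "label", self.labels)
        return df


def _read_table(path, delimiter=None, header=True):
    path = Path(path)
    if delimiter is None:
        delimiter = "\t" if path.suffix.lower() in {".tsv", ".txt"} else ","
    try:
        df = pd.read_csv(path, sep=delimiter, header=0 if header else None,
                         index_col=None)
    except FileNotFoundError:
        raise
    return df


def load_dataset(
    matrix_path,
    labels_spec,
    orientation: str = "samples",
    delimiter: str | None = None,
    header: bool = True,
    impute: bool = False,
) -> ExpressionDataset:
    """Load an expression matrix and its class labels from delimited text.

    Parameters
    ----------
    matrix_path : path
        CSV/TSV file (delimiter inferred from extension, overridable).
    labels_spec : path or str
        Either the name of a label column inside the matrix file, or the
        path of a separate one-label-per-line file.
    orientation : {"samples", "genes"}
        Whether file rows are samples or genes. Required, never inferred.
    impute : bool
        If True, per-column mean imputation of missing cells; default is to
        reject missing values.
    """
    if orientation not in {"samples", "genes"}:
        raise DatasetError(f"orientation must be 'samples' or 'genes', got {orientation!r}")
    df = _read_table(matrix_path, delimiter, header)

    labels = None
    if isinstance(labels_spec, (str, Path)) and not Path(str(labels_spec)).exists():
        # treat as a column name of the matrix file
        if str(labels_spec) not in df.columns:
            raise DatasetError(
                f"label column {labels_spec!r} not found in {matrix_path} "
                f"and no such file exists"
            )
        labels = df[str(labels_spec)].to_numpy()
        df = df.drop(columns=[str(labels_spec)])
    else:
        lab_df = _read_table(labels_spec, delimiter=None, header=False)
        labels = lab_df.iloc[:, 0].to_numpy()

    row_ids = None
    first = df.columns[0]
    if df.shape[1] > 1 and df[first].dtype == object:
        # leading non-numeric column holds row identifiers
        row_ids = tuple(str(v) for v in df[first])
        df = df.drop(columns=[first])

    matrix = _coerce_numeric(df)

    if orientation == "genes":
        attribute_ids = row_ids or tuple(str(j + 1) for j in range(matrix.shape[0]))
        sample_ids = tuple(str(c) for c in df.columns) if header else ()
        matrix = matrix.T
    else:
        attribute_ids = tuple(str(c) for c in df.columns) if header else ()
        sample_ids = row_ids or ()

    if np.isnan(matrix).any():
        if impute:
            col_mean = np.nanmean(matrix, axis=0)
            idx = np.where(np.isnan(matrix))
            matrix[idx] = np.take(col_mean, idx[1])
            logger.info("imputed %d missing cells with column means", len(idx[0]))
        # else ExpressionDataset rejects with coordinates

    if matrix.shape[0] != len(labels):
        raise DatasetError(
            f"sample axis mismatch: matrix has {matrix.shape[0]} samples "
            f"(orientation={orientation}) but {len(labels)} labels"
        )
    return ExpressionDataset(matrix, np.asarray(labels), attribute_ids, sample_ids)


def _coerce_numeric(df: pd.DataFrame) -> np.ndarray:
    try:
        return df.to_numpy(dtype=float)
    except (TypeError, ValueError):
        for j, col in enumerate(df.columns):
            coerced = pd.to_numeric(df[col], errors="coerce")
            bad = coerced.isna() & df[col].notna()
            if bad.any():
                i = int(np.flatnonzero(bad.to_numpy())[0])
                raise DatasetError(
                    f"non-numeric cell at row {i + 1}, column {j + 1} "
                    f"({df.iloc[i, j]!r})"
                ) from None
        raise


def drop_constant_columns(ds: ExpressionDataset):
    """Remove zero-variance attributes (all-zero or any constant column).

    Returns the filtered dataset and the list of removed attribute ids.
    Public microarray matrices often carry columns that are identically
    zero; those carry no class information and break normalization.
    """
    variances = ds.matrix.var(axis=0)
    keep = variances > 0.0
    removed = [ds.attribute_ids[j] for j in np.flatnonzero(~keep)]
    if not keep.any():
        raise DatasetError("all columns are constant; nothing left to analyse")
    if removed:
        logger.info("dropped %d constant columns: %s", len(removed), removed)
    out = ExpressionDataset(
        ds.matrix[:, keep],
        ds.labels,
        tuple(a for a, k in zip(ds.attribute_ids, keep) if k),
        ds.sample_ids,
    )
    return out, removed


def minmax_normalize(ds: ExpressionDataset) -> ExpressionDataset:
    """Affinely map every column onto [0, 1].

    A single neighborhood radius across attributes is only meaningful when
    the attributes share a scale; this is the default scaling of the
    pipeline. Constant columns must be removed first.
    """
    lo = ds.matrix.min(axis=0)
    hi = ds.matrix.max(axis=0)
    span = hi - lo
    if np.any(span == 0):
        j = int(np.flatnonzero(span == 0)[0])
        raise DatasetError(
            f"column {ds.attribute_ids[j]!r} is constant; "
            "call drop_constant_columns before minmax_normalize"
        )
    return replace(ds, matrix=(ds.matrix - lo) / span)


def zscore_normalize(ds: ExpressionDataset) -> ExpressionDataset:
    """Standardize every column to zero mean, unit (population) variance."""
    sd = ds.matrix.std(axis=0)
    if np.any(sd == 0):
        j = int(np.flatnonzero(sd == 0)[0])
        raise DatasetError(
            f"column {ds.attribute_ids[j]!r} is constant; "
            "call drop_constant_columns before zscore_normalize"
        )
    return replace(ds, matrix=(ds.matrix - ds.matrix.mean(axis=0)) / sd)


def write_result(res, path) -> None:
    """Serialize a reduction/evaluation result to a JSON report.

    ``res`` may be any object with a ``to_dict()`` method or a plain dict.
    A sibling ``<path stem>.genes.txt`` file with one selected attribute id
    per line is written when the result carries a selection.
    """
    payload = res.to_dict() if hasattr(res, "to_dict") else dict(res)
    path = Path(path)
    path.parent.mkdir(parents=True, exist_ok=True)
    with open(path, "w") as fh:
        json.dump(payload, fh, indent=2, default=_json_default)
        fh.write("\n")
    selected = payload.get("red") or payload.get("subset")
    if selected is not None:
        gene_path = path.with_suffix(".genes.txt")
        gene_path.write_text("".join(f"{a}\n" for a in selected))


def read_result(path) -> dict:
    with open(path) as fh:
        return json.load(fh)


def _json_default(o):
    if isinstance(o, (np.integer,)):
        return int(o)
    if isinstance(o, (np.floating,)):
        return float(o)
    if isinstance(o, np.ndarray):
        return o.tolist()
    if isinstance(o, (set, frozenset, tuple)):
        return sorted(o) if isinstance(o, (set, frozenset)) else list(o)
    raise TypeError(f"not JSON serializable: {type(o)}")
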