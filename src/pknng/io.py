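"""Delimited-text I/O, row normalization and config handling.

Conventions: rows are samples, columns are features; CSV with a header row
and the sample id in the first column; comma delimiter, period decimal,
no quoting of numerics.  Labels travel as two-column TSV (sample_id, cluster)
and benchmark reports as JSON.
"""
from __future__ import annotations

import json
from pathlib import Path
from typing import Optional

import numpy as np
import pandas as pd
import yaml

from .base_metrics import DataMatrix, PairwiseDistances
from .clustering_eval import BenchmarkReport, ClusteringResult

__all__ = ["read_matrix", "write_matrix", "normalize_rows", "write_distances",
           "read_distances", "write_labels", "read_labels", "write_report",
           "read_config", "write_config"]


def read_matrix(path, delimiter: str = ",",
                label_column: Optional[str] = None) -> DataMatrix:
    """Read a delimited numeric matrix (header row, ids in the first column).

    ``label_column`` names a column of integer class labels to split out.
    Ragged rows, duplicate ids, missing or non-numeric cells are rejected
    with the offending coordinates in the message.
    """
    path = Path(path)
    try:
        df = pd.read_csv(path, sep=delimiter, index_col=0)
    except pd.errors.ParserError as exc:
        raise ValueError(f"{path}: malformed delimited file ({exc})") from exc
    if df.index.has_duplicates:
        dup = df.index[df.index.duplicated()][0]
        raise ValueError(f"{path}: duplicate sample id {dup!r}")
    labels = None
    if label_column is not None:
        if label_column not in df.columns:
            raise ValueError(f"{path}: no column named {label_column!r}")
        labels = df.pop(label_column).to_numpy()
    if df.isna().any().any():
        row, col = next(zip(*np.nonzero(df.isna().to_numpy())))
        raise ValueError(f"{path}: missing value at row {df.index[row]!r}, "
                         f"column {df.columns[col]!r}")
    values = df.to_numpy()
    if not np.issubdtype(values.dtype, np.number):
        for col in df.columns:
            if not np.issubdtype(df[col].dtype, np.number):
                bad = df[col][pd.to_numeric(df[col], errors="coerce").isna()]
                raise ValueError(f"{path}: non-numeric cell at row "
                                 f"{bad.index[0]!r}, column {col!r}")
    return DataMatrix(values.astype(float), sample_ids=[str(i) for i in df.index],
                      labels=labels)


def write_matrix(X: DataMatrix, path, delimiter: str = ",") -> None:
    df = pd.DataFrame(X.values, index=X.sample_ids,
                      columns=[f"f{i}" for i in range(X.p)])
    df.index.name = "id"
    df.to_csv(path, sep=delimiter)


def normalize_rows(X: DataMatrix) -> DataMatrix:
    """Normalize every row (sample) to mean 0 and SD 1 (population SD).

    The standard preprocessing for expression matrices before distance
    computation; constant rows are rejected by name since their SD is zero.
    """
    sd = X.values.std(axis=1)
    if (sd == 0).any():
        bad = X.sample_ids[int(np.nonzero(sd == 0)[0][0])]
        raise ValueError(f"sample {bad!r} is constant; cannot normalize")
    v = (X.values - X.values.mean(axis=1, keepdims=True)) / sd[:, None]
    return DataMatrix(v, sample_ids=X.sample_ids, labels=X.labels)


def write_distances(D: PairwiseDistances, path) -> None:
    """Dense square CSV with an id header; symmetry and zero diagonal are
    re-asserted on write."""
    d = D.values
    if not np.allclose(d, d.T) or np.any(np.diag(d) != 0):
        raise ValueError("refusing to write an invalid distance matrix")
    ids = D.sample_ids or [f"s{i}" for i in range(D.n)]
    df = pd.DataFrame(d, index=ids, columns=ids)
    df.index.name = "id"
    df.to_csv(path)


def read_distances(path, metric: str = "precomputed") -> PairwiseDistances:
    df = pd.read_csv(path, index_col=0)
    return PairwiseDistances(df.to_numpy(dtype=float), metric=metric,
                             sample_ids=[str(i) for i in df.index])


def write_labels(result, path, sample_ids=None) -> None:
    """Two-column TSV: sample_id <TAB> cluster."""
    labels = result.labels if isinstance(result, ClusteringResult) else np.asarray(result)
    ids = sample_ids or [f"s{i}" for i in range(len(labels))]
    pd.DataFrame({"id": ids, "cluster": labels}).to_csv(path, sep="\t", index=False)


def read_labels(path) -> np.ndarray:
    return pd.read_csv(path, sep="\t")["cluster"].to_numpy()


def write_report(report: BenchmarkReport, path) -> None:
    with open(path, "w") as fh:
        json.dump(report.to_dict(), fh, indent=2, default=_json_default)


def _json_default(obj):
    if isinstance(obj, np.ndarray):
        return obj.tolist()
    if isinstance(obj, (np.integer, np.floating)):
        return obj.item()
    raise TypeError(f"not JSON serializable: {type(obj)}")


def read_config(path) -> dict:
    """YAML or JSON config file -> dict."""
    path = Path(path)
    text = path.read_text()
    if path.suffix == ".json":
        return json.loads(text)
    return yaml.safe_load(text)


def write_config(cfg: dict, path) -> None:
    path = Path(path)
    with open(path, "w") as fh:
        if path.suffix == ".json":
            json.dump(cfg, fh, indent=2, default=_json_default)
        else:
            yaml.safe_dump(cfg, fh, sort_keys=False)
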