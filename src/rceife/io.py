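"""Labeled matrices and delimited-text I/O.

The central container is :class:`LabeledMatrix`: a samples x features real
matrix with unique sample and feature identifiers and a binary pos/neg label
per sample — the shape of the gene-expression, miRNA, methylation and
metagenomic-abundance tables this tool targets.

Input files are plain CSV/TSV with a header row: one sample-id column
(first by default), one label column, and the remaining columns numeric
features. Feature-per-row exports (common for public expression matrices)
are handled by the ``features_in_rows`` orientation, in which the label
"column" is the row whose identifier matches ``label_column``.
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path
from typing import TYPE_CHECKING, Iterable

import numpy as np
import pandas as pd

from .exceptions import FormatError, IdError, LabelError, ParseError

if TYPE_CHECKING:  # pragma: no cover
    from .aggregate import AggregateResult

__all__ = [
    "LabeledMatrix",
    "POS",
    "NEG",
    "load_labeled_matrix",
    "write_results",
]

POS = "pos"
NEG = "neg"


@dataclass(frozen=True)
class LabeledMatrix:
    """A two-class labeled numeric matrix (rows = samples, columns = features)."""

    sample_ids: tuple[str, ...]
    feature_ids: tuple[str, ...]
    values: np.ndarray  # shape (p, q), float64
    labels: tuple[str, ...]  # each POS or NEG

    def __post_init__(self) -> None:
        values = np.asarray(self.values, dtype=np.float64)
        object.__setattr__(self, "values", values)
        object.__setattr__(self, "sample_ids", tuple(str(s) for s in self.sample_ids))
        object.__setattr__(self, "feature_ids", tuple(str(f) for f in self.feature_ids))
        object.__setattr__(self, "labels", tuple(self.labels))
        p, q = values.shape if values.ndim == 2 else (len(values), -1)
        if values.ndim != 2:
            raise FormatError("values must be a 2-D matrix")
        if len(self.sample_ids) != p or len(self.labels) != p:
            raise FormatError(
                f"sample_ids ({len(self.sample_ids)}) / labels ({len(self.labels)}) "
                f"must match the number of rows ({p})"
            )
        if len(self.feature_ids) != q:
            raise FormatError(
                f"feature_ids ({len(self.feature_ids)}) must match the number of columns ({q})"
            )
        if len(set(self.sample_ids)) != p:
            raise IdError("duplicate sample ids")
        if len(set(self.feature_ids)) != q:
            raise IdError("duplicate feature ids")
        bad = set(self.labels) - {POS, NEG}
        if bad:
            raise LabelError(f"labels must be '{POS}' or '{NEG}', got {sorted(bad)}")
        if np.isnan(values).any():
            rows, cols = np.nonzero(np.isnan(values))
            cells = [
                f"({self.sample_ids[r]}, {self.feature_ids[c]})"
                for r, c in zip(rows[:5], cols[:5])
            ]
            raise ParseError(f"missing values at cells {', '.join(cells)}"
                             + (" ..." if len(rows) > 5 else ""))

    # -- convenience views -------------------------------------------------
    @property
    def n_samples(self) -> int:
        return len(self.sample_ids)

    @property
    def n_features(self) -> int:
        return len(self.feature_ids)

    @property
    def y(self) -> np.ndarray:
        """Boolean label vector (True = positive class)."""
        return np.fromiter((lab == POS for lab in self.labels), dtype=bool,
                           count=self.n_samples)

    @property
    def n_pos(self) -> int:
        return int(self.y.sum())

    @property
    def n_neg(self) -> int:
        return self.n_samples - self.n_pos

    def feature_index(self, feature_ids: Iterable[str]) -> np.ndarray:
        pos = {f: i for i, f in enumerate(self.feature_ids)}
        try:
            return np.fromiter((pos[f] for f in feature_ids), dtype=np.intp)
        except KeyError as exc:  # pragma: no cover - message detail
            raise IdError(f"unknown feature id {exc.args[0]!r}") from None

    def subset_samples(self, row_indices: np.ndarray) -> "LabeledMatrix":
        idx = np.asarray(row_indices, dtype=np.intp)
        return LabeledMatrix(
            sample_ids=tuple(self.sample_ids[i] for i in idx),
            feature_ids=self.feature_ids,
            values=self.values[idx],
            labels=tuple(self.labels[i] for i in idx),
        )

    def subset_features(self, feature_ids: Iterable[str]) -> "LabeledMatrix":
        feature_ids = tuple(feature_ids)
        idx = self.feature_index(feature_ids)
        return LabeledMatrix(
            sample_ids=self.sample_ids,
            feature_ids=feature_ids,
            values=self.values[:, idx],
            labels=self.labels,
        )

    def require_two_classes(self) -> None:
        if self.n_pos == 0 or self.n_neg == 0:
            raise LabelError("both classes must be present")


def _sniff_delimiter(header_line: str) -> str:
    """Choose comma vs tab from the header line (tab wins if present)."""
    return "\t" if "\t" in header_line else ","


def load_labeled_matrix(
    path: str | Path,
    label_column: str,
    positive_label: str,
    orientation: str = "samples_in_rows",
    delimiter: str | None = None,
) -> LabeledMatrix:
    """Read a labeled matrix from a delimited text file.

    Parameters
    ----------
    path:
        CSV or TSV file with a header row. The first column holds
        identifiers (sample ids, or feature ids for ``features_in_rows``).
    label_column:
        Name of the label column (or, in ``features_in_rows`` orientation,
        of the row carrying the labels).
    positive_label:
        The label value mapped to the positive class; the single remaining
        value becomes the negative class.
    orientation:
        ``samples_in_rows`` (default) or ``features_in_rows``; the latter is
        transposed on load.
    delimiter:
        Explicit delimiter; auto-detected between comma and tab if omitted.
    """
    path = Path(path)
    if orientation not in ("samples_in_rows", "features_in_rows"):
        raise FormatError(f"unknown orientation {orientation!r}")
    with open(path, "r", encoding="utf-8") as fh:
        header = fh.readline()
    if not header.strip():
        raise FormatError(f"{path}: empty file")
    sep = delimiter if delimiter is not None else _sniff_delimiter(header)

    frame = pd.read_csv(path, sep=sep, header=0, index_col=0, dtype=str)
    frame.index = frame.index.map(str)
    if orientation == "features_in_rows":
        frame = frame.T

    if label_column not in frame.columns:
        raise FormatError(
            f"{path}: label column {label_column!r} not found "
            f"(columns: {list(frame.columns)[:8]}...)"
        )
    raw_labels = frame[label_column].astype(str)
    data = frame.drop(columns=[label_column])

    distinct = sorted(set(raw_labels))
    if positive_label not in distinct:
        raise LabelError(
            f"positive label {positive_label!r} absent from label column "
            f"(values: {distinct})"
        )
    if len(distinct) != 2:
        raise LabelError(
            f"label column must contain exactly two distinct values, got {distinct}"
        )

    sample_ids = tuple(data.index)
    feature_ids = tuple(str(c) for c in data.columns)
    if len(set(sample_ids)) != len(sample_ids):
        raise IdError(f"{path}: duplicate sample ids")
    if len(set(feature_ids)) != len(feature_ids):
        raise IdError(f"{path}: duplicate feature ids")
    if data.shape[0] < 2 or data.shape[1] < 1:
        raise FormatError(f"{path}: need at least 2 samples and 1 feature")

    values = np.empty(data.shape, dtype=np.float64)
    for j, col in enumerate(data.columns):
        converted = pd.to_numeric(data[col], errors="coerce")
        bad = converted.isna() & data[col].notna()
        if bad.any():
            row = data.index[bad.to_numpy().nonzero()[0][0]]
            raise ParseError(
                f"{path}: non-numeric value {data.loc[row, col]!r} at "
                f"row {row!r}, column {col!r}"
            )
        if converted.isna().any():
            row = data.index[converted.isna().to_numpy().nonzero()[0][0]]
            raise ParseError(f"{path}: missing value at row {row!r}, column {col!r}")
        # Python float() is correctly rounded; pd.to_numeric is not
        values[:, j] = [float(x) for x in data[col]]

    labels = tuple(POS if lab == positive_label else NEG for lab in raw_labels)
    return LabeledMatrix(sample_ids, feature_ids, values, labels)


def write_labeled_matrix(matrix: LabeledMatrix, path: str | Path,
                         label_column: str = "label") -> None:
    """Write a matrix in the canonical samples-in-rows CSV layout."""
    frame = pd.DataFrame(matrix.values, index=list(matrix.sample_ids),
                         columns=list(matrix.feature_ids))
    frame.insert(0, label_column, list(matrix.labels))
    frame.index.name = "id"
    # repr round-trips float64 exactly
    frame.to_csv(path, float_format=None)


def write_results(aggregate: "AggregateResult", out_dir: str | Path) -> dict[str, Path]:
    """Write the per-level metric table, the ranked feature list and a manifest.

    Returns a mapping of artifact name to path: ``metrics`` (CSV: level,
    metric, mean, std, n_defined), ``ranking`` (CSV: rank, feature_id,
    survival_score) and ``manifest`` (key: value lines echoing the
    configuration and seeds).
    """
    out_dir = Path(out_dir)
    try:
        out_dir.mkdir(parents=True, exist_ok=True)
        probe = out_dir / ".write_probe"
        probe.touch()
        probe.unlink()
    except OSError as exc:
        raise OSError(f"output directory {out_dir} is not writable: {exc}") from exc

    metrics_path = out_dir / "metrics.csv"
    rows = []
    for level in sorted(aggregate.per_level_stats, reverse=True):
        for metric, (mean, std, n_defined) in aggregate.per_level_stats[level].items():
            rows.append({"level": level, "metric": metric, "mean": mean,
                         "std": std, "n_defined": n_defined})
    pd.DataFrame(rows, columns=["level", "metric", "mean", "std", "n_defined"]) \
        .to_csv(metrics_path, index=False)

    ranking_path = out_dir / "ranking.csv"
    rank_rows = [
        {"rank": i + 1, "feature_id": fid, "survival_score": score}
        for i, (fid, score) in enumerate(aggregate.ranking)
    ]
    pd.DataFrame(rank_rows, columns=["rank", "feature_id", "survival_score"]) \
        .to_csv(ranking_path, index=False)

    manifest_path = out_dir / "manifest.txt"
    with open(manifest_path, "w", encoding="utf-8") as fh:
        fh.write(f"n_repeats: {aggregate.n_repeats}\n")
        for key, value in sorted(aggregate.manifest.items()):
            fh.write(f"{key}: {value}\n")

    return {"metrics": metrics_path, "ranking": ranking_path,
            "manifest": manifest_path}
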