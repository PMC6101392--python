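"""Expression-matrix data model, file readers/writers, and dataset summaries.

The central container is :class:`LabeledMatrix`: a dense samples x genes
matrix of expression values with exactly two class labels, internally coded
as -1 (minority class) and +1 (majority class).  Microarray datasets in this
problem domain ship as delimited text (CSV/TSV with a label column), dense
ARFF, or MATLAB ``.mat`` files; all three are supported.

Summary statistics follow the field's conventions for such data:

* **SDR** (sample-to-dimension ratio): total sample count / gene count,
  usually reported as a percentage well below 100% for microarray data.
* **IR** (imbalance ratio): majority class size / minority class size,
  1.0 meaning perfectly balanced.
"""

from __future__ import annotations

import csv
import io
import json
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
from scipy.io import arff as scipy_arff
from scipy.io import loadmat


class DatasetError(ValueError):
    """Raised for malformed input files or invalid matrix structure."""


@dataclass
class LabeledMatrix:
    """A two-class expression matrix: samples on rows, genes on columns.

    Parameters
    ----------
    values
        Real matrix of shape (n_samples, n_genes).
    gene_ids
        Unique gene identifier per column.
    sample_ids
        Sample identifier per row.
    labels
        Array of -1/+1 class codes, one per sample.  By convention the
        minority class is -1 and the majority +1 (ties broken so the
        lexicographically smaller original code maps to -1).
    label_codes
        Mapping from internal code (-1, +1) to the original class code
        found in the source file, preserved for round-tripping.
    """

    values: np.ndarray
    gene_ids: list[str]
    sample_ids: list[str]
    labels: np.ndarray
    label_codes: dict[int, str] = field(default_factory=dict)

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=float)
        self.labels = np.asarray(self.labels)
        if self.values.ndim != 2:
            raise DatasetError("values must be a 2-D matrix")
        n, d = self.values.shape
        if len(self.labels) != n or len(self.sample_ids) != n:
            raise DatasetError(
                f"row count {n} does not match labels ({len(self.labels)}) "
                f"or sample_ids ({len(self.sample_ids)})"
            )
        if len(self.gene_ids) != d:
            raise DatasetError(
                f"column count {d} does not match gene_ids ({len(self.gene_ids)})"
            )
        if len(set(self.gene_ids)) != d:
            seen: set[str] = set()
            dup = next(g for g in self.gene_ids if g in seen or seen.add(g))
            raise DatasetError(f"duplicate gene identifier: {dup!r}")
        if not np.all(np.isfinite(self.values)):
            i, j = np.argwhere(~np.isfinite(self.values))[0]
            raise DatasetError(
                f"non-finite value at sample {self.sample_ids[i]!r}, "
                f"gene {self.gene_ids[j]!r}"
            )

    @property
    def n_samples(self) -> int:
        return self.values.shape[0]

    @property
    def n_genes(self) -> int:
        return self.values.shape[1]

    def class_counts(self) -> tuple[int, int]:
        """(minority, majority) counts, i.e. (#labels==-1, #labels==+1)."""
        return int(np.sum(self.labels == -1)), int(np.sum(self.labels == +1))

    def require_two_classes(self) -> None:
        present = set(np.unique(self.labels).tolist())
        if present != {-1, 1}:
            raise DatasetError(
                f"operation requires both classes present; found codes {sorted(present)}"
            )

    def subset_samples(self, index: np.ndarray) -> "LabeledMatrix":
        index = np.asarray(index)
        return LabeledMatrix(
            values=self.values[index],
            gene_ids=list(self.gene_ids),
            sample_ids=[self.sample_ids[i] for i in index],
            labels=self.labels[index],
            label_codes=dict(self.label_codes),
        )

    def subset_genes(self, columns: np.ndarray) -> "LabeledMatrix":
        columns = np.asarray(columns)
        return LabeledMatrix(
            values=self.values[:, columns],
            gene_ids=[self.gene_ids[j] for j in columns],
            sample_ids=list(self.sample_ids),
            labels=self.labels.copy(),
            label_codes=dict(self.label_codes),
        )


@dataclass(frozen=True)
class DatasetSummary:
    """Class counts and the SDR / IR ratios of a two-class dataset."""

    n_class1: int  # minority
    n_class2: int  # majority
    n_features: int
    sdr: float  # fraction, not percent
    ir: float

    def sdr_percent(self, decimals: int = 2) -> float:
        """SDR as a percentage, rounded half away from zero."""
        return _round_half_away(100.0 * self.sdr, decimals)

    def to_json(self, decimals: int = 2) -> str:
        return json.dumps(
            {
                "n_class1": self.n_class1,
                "n_class2": self.n_class2,
                "n_features": self.n_features,
                "sdr_percent": self.sdr_percent(decimals),
                "ir": _round_half_away(self.ir, decimals),
            }
        )


def _round_half_away(x: float, decimals: int) -> float:
    """Round half away from zero (13.5 -> 14, -13.5 -> -14) at `decimals`."""
    factor = 10.0**decimals
    return float(np.sign(x) * np.floor(abs(x) * factor + 0.5) / factor)


def _map_labels(raw: list[str]) -> tuple[np.ndarray, dict[int, str]]:
    """Map two raw class codes to -1 (minority) / +1 (majority).

    Ties in class size are broken by lexicographic order of the original
    codes: the smaller code becomes -1.
    """
    codes = sorted(set(raw))
    if len(codes) != 2:
        raise DatasetError(
            f"expected exactly two classes, found {len(codes)}: {codes[:5]}"
        )
    counts = {c: raw.count(c) for c in codes}
    # sort by (count, code): first entry is the minority (or lexicographic
    # smaller on a tie)
    minority = min(codes, key=lambda c: (counts[c], c))
    majority = codes[0] if codes[1] == minority else codes[1]
    labels = np.array([-1 if r == minority else +1 for r in raw], dtype=int)
    return labels, {-1: minority, +1: majority}


def load_matrix(
    path: str | Path,
    format: str = "delimited",
    label_column: str | int = "label",
) -> LabeledMatrix:
    """Load a labeled expression matrix from disk.

    Parameters
    ----------
    path
        File to read.
    format
        ``"delimited"`` (CSV or TSV, dialect auto-detected from the header
        line), ``"arff"`` (dense ARFF), or ``"mat"`` (MATLAB file with
        variables ``X`` and ``Y``).
    label_column
        Name (or integer position) of the class-label column.  Ignored for
        ``"mat"``.

    Raises
    ------
    DatasetError
        On missing files, non-numeric expression cells, class counts other
        than two, or duplicate gene identifiers; the message names the
        offending row/column.
    """
    path = Path(path)
    if not path.exists():
        raise DatasetError(f"no such file: {path}")
    if format == "delimited":
        return _load_delimited(path, label_column)
    if format == "arff":
        return _load_arff(path, label_column)
    if format == "mat":
        return _load_mat(path)
    raise DatasetError(f"unknown format {format!r}; expected delimited|arff|mat")


def _load_delimited(path: Path, label_column: str | int) -> LabeledMatrix:
    header = path.open().readline()
    sep = "\t" if header.count("\t") >= header.count(",") and "\t" in header else ","
    df = pd.read_csv(path, sep=sep, header=0, dtype=str,
                     float_precision="round_trip")
    if isinstance(label_column, int):
        label_name = df.columns[label_column]
    else:
        if label_column not in df.columns:
            raise DatasetError(
                f"label column {label_column!r} not found in {path.name} "
                f"(columns: {list(df.columns)[:5]}...)"
            )
        label_name = label_column
    raw_labels = df[label_name].astype(str).tolist()
    expr = df.drop(columns=[label_name])
    gene_ids = [str(c) for c in expr.columns]
    values = np.empty(expr.shape, dtype=float)
    for j, col in enumerate(expr.columns):
        try:
            # float() is correctly rounded, so writes round-trip exactly
            values[:, j] = [float(s) for s in expr[col]]
        except (ValueError, TypeError):
            bad = expr[col][pd.to_numeric(expr[col], errors="coerce").isna()]
            row = bad.index[0]
            raise DatasetError(
                f"non-numeric expression value {bad.iloc[0]!r} at row {row}, "
                f"column {col!r} of {path.name}"
            ) from None
    if np.isnan(values).any():
        i, j = np.argwhere(np.isnan(values))[0]
        raise DatasetError(
            f"missing value at row {i}, column {gene_ids[j]!r} of {path.name}"
        )
    labels, label_codes = _map_labels(raw_labels)
    sample_ids = [f"s{i}" for i in range(len(labels))]
    return LabeledMatrix(values, gene_ids, sample_ids, labels, label_codes)


def _load_arff(path: Path, label_column: str | int) -> LabeledMatrix:
    try:
        data, meta = scipy_arff.loadarff(str(path))
    except NotImplementedError as exc:
        raise DatasetError(
            f"{path.name}: sparse ARFF is not supported; convert to dense"
        ) from exc
    names = list(meta.names())
    if isinstance(label_column, int):
        label_name = names[label_column]
    elif label_column in names:
        label_name = label_column
    else:
        # fall back to the single nominal attribute (the class column)
        nominal = [n for n in names if meta[n][0] == "nominal"]
        if len(nominal) != 1:
            raise DatasetError(
                f"label column {label_column!r} not found in {path.name} and "
                f"no unique nominal attribute to fall back on"
            )
        label_name = nominal[0]
    raw_labels = [
        v.decode() if isinstance(v, bytes) else str(v) for v in data[label_name]
    ]
    gene_ids = [n for n in names if n != label_name]
    values = np.column_stack([np.asarray(data[n], dtype=float) for n in gene_ids])
    if np.isnan(values).any():
        i, j = np.argwhere(np.isnan(values))[0]
        raise DatasetError(
            f"missing value at row {i}, attribute {gene_ids[j]!r} of {path.name}"
        )
    labels, label_codes = _map_labels(raw_labels)
    sample_ids = [f"s{i}" for i in range(len(labels))]
    return LabeledMatrix(values, gene_ids, sample_ids, labels, label_codes)


def _load_mat(path: Path) -> LabeledMatrix:
    mat = loadmat(str(path))
    if "X" not in mat or "Y" not in mat:
        raise DatasetError(
            f"{path.name}: expected variables 'X' (samples x genes) and 'Y' (labels)"
        )
    values = np.asarray(mat["X"], dtype=float)
    raw = [str(v) for v in np.asarray(mat["Y"]).ravel()]
    labels, label_codes = _map_labels(raw)
    gene_ids = [f"g{j}" for j in range(values.shape[1])]
    sample_ids = [f"s{i}" for i in range(values.shape[0])]
    return LabeledMatrix(values, gene_ids, sample_ids, labels, label_codes)


def write_matrix(m: LabeledMatrix, path: str | Path, sep: str = ",") -> None:
    """Write a LabeledMatrix as delimited text (genes as columns + ``label``).

    Uses full ``repr`` float precision so ``load_matrix(write_matrix(m)) == m``.
    """
    path = Path(path)
    codes = m.label_codes or {-1: "-1", +1: "1"}
    with path.open("w", newline="") as fh:
        w = csv.writer(fh, delimiter=sep)
        w.writerow([*m.gene_ids, "label"])
        for i in range(m.n_samples):
            w.writerow(
                [repr(float(v)) for v in m.values[i]] + [codes[int(m.labels[i])]]
            )


def summarize(m: LabeledMatrix) -> DatasetSummary:
    """Class counts, sample-to-dimension ratio, and imbalance ratio."""
    n_minority, n_majority = m.class_counts()
    if min(n_minority, n_majority) == 0:
        raise DatasetError("summarize requires two classes present")
    n_features = m.n_genes
    sdr = (n_minority + n_majority) / n_features
    ir = max(n_minority, n_majority) / min(n_minority, n_majority)
    return DatasetSummary(
        n_class1=n_minority,
        n_class2=n_majority,
        n_features=n_features,
        sdr=sdr,
        ir=ir,
    )


def write_selection(
    gene_ids: list[str],
    ranks: list[int],
    path: str | Path,
    elimination_iteration: list[int] | None = None,
) -> None:
    """Write a gene ranking as TSV with columns gene_id, rank,
    elimination_iteration (rank 1 = most important), sorted by rank."""
    if len(set(ranks)) != len(ranks):
        raise DatasetError("duplicate ranks in selection")
    if elimination_iteration is None:
        elimination_iteration = [-1] * len(gene_ids)
    rows = sorted(
        zip(gene_ids, ranks, elimination_iteration), key=lambda r: r[1]
    )
    with Path(path).open("w", newline="") as fh:
        w = csv.writer(fh, delimiter="\t")
        w.writerow(["gene_id", "rank", "elimination_iteration"])
        for gid, rank, it in rows:
            w.writerow([gid, rank, it])


def read_selection(path: str | Path) -> pd.DataFrame:
    """Read a ranking TSV written by :func:`write_selection`."""
    df = pd.read_csv(path, sep="\t", dtype={"gene_id": str})
    if list(df.columns) != ["gene_id", "rank", "elimination_iteration"]:
        raise DatasetError(f"unexpected ranking file columns: {list(df.columns)}")
    return df
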