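"""Core data containers and plain-text I/O.

Expression profiles are held as a dense samples x variables matrix with string
sample ids, string variable names and a binary group label per sample. Labels
are canonicalized internally to {0, 1}: the lexicographically smaller original
label becomes class 0. Original label names are preserved for output.

On-disk format is a rectangular TSV/CSV. In the default ``variables_as_rows``
orientation (the common layout of expression matrices, e.g. a GEO series-matrix
body) rows are variables, columns are samples, the first column holds variable
names and a designated row named ``group`` (or ``label``) holds the per-sample
class labels. Alternatively labels may come from a separate two-column
``sample_id<TAB>label`` file. Numeric text is written with shortest
round-tripping precision so that write -> read reproduces values bit-exactly.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np

LABEL_ROW_NAMES = ("group", "label")


class DataFormatError(ValueError):
    """Malformed expression table: ragged rows, non-numeric or missing cells."""


class LabelError(ValueError):
    """Label row/file problems: missing, not exactly two classes, id mismatch."""


@dataclass
class ExpressionMatrix:
    """Expression profile in canonical samples x variables orientation.

    Attributes
    ----------
    values : ndarray, shape (n_samples, n_variables)
        Expression levels (unitless). No missing entries allowed.
    sample_ids, variable_names : list of str
    labels : ndarray of int, shape (n_samples,)
        Canonical class codes in {0, 1}.
    class_names : tuple of two str
        Original label names; ``class_names[0]`` is the lexicographically
        smaller original label and maps to class 0.
    """

    values: np.ndarray
    sample_ids: list[str]
    variable_names: list[str]
    labels: np.ndarray
    class_names: tuple[str, str]

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=np.float64)
        self.labels = np.asarray(self.labels, dtype=np.int64)
        if self.values.ndim != 2:
            raise DataFormatError("values must be a 2-D matrix")
        n, p = self.values.shape
        if len(self.sample_ids) != n:
            raise DataFormatError(f"{len(self.sample_ids)} sample ids for {n} samples")
        if len(self.variable_names) != p:
            raise DataFormatError(f"{len(self.variable_names)} variable names for {p} variables")
        if self.labels.shape != (n,):
            raise LabelError(f"{self.labels.shape[0]} labels for {n} samples")
        if not np.isfinite(self.values).all():
            bad = np.argwhere(~np.isfinite(self.values))[0]
            raise DataFormatError(
                f"missing/non-finite value for sample {self.sample_ids[bad[0]]!r}, "
                f"variable {self.variable_names[bad[1]]!r}"
            )
        present = np.unique(self.labels)
        if not np.array_equal(present, [0, 1]):
            raise LabelError("exactly two label classes (both present) are required")
        if len(self.class_names) != 2 or self.class_names[0] >= self.class_names[1]:
            raise LabelError("class_names must be two distinct names in ascending order")

    @property
    def n_samples(self) -> int:
        return self.values.shape[0]

    @property
    def n_variables(self) -> int:
        return self.values.shape[1]

    @classmethod
    def from_raw_labels(
        cls,
        values: np.ndarray,
        sample_ids: list[str],
        variable_names: list[str],
        raw_labels: list[str],
    ) -> "ExpressionMatrix":
        """Build a matrix canonicalizing arbitrary binary label names to {0, 1}."""
        names = sorted(set(str(x) for x in raw_labels))
        if len(names) != 2:
            raise LabelError(f"expected exactly 2 label classes, found {len(names)}: {names}")
        mapping = {names[0]: 0, names[1]: 1}
        labels = np.array([mapping[str(x)] for x in raw_labels], dtype=np.int64)
        return cls(values, list(sample_ids), list(variable_names), labels, (names[0], names[1]))

    def label_strings(self) -> list[str]:
        """Original label names in sample order."""
        return [self.class_names[c] for c in self.labels]


@dataclass
class DataSplit:
    """Disjoint train/test partition of sample indices (stratified by class)."""

    train_indices: np.ndarray
    test_indices: np.ndarray

    def __post_init__(self) -> None:
        self.train_indices = np.asarray(self.train_indices, dtype=np.int64)
        self.test_indices = np.asarray(self.test_indices, dtype=np.int64)
        if np.intersect1d(self.train_indices, self.test_indices).size:
            raise ValueError("train and test indices overlap")

    def check_covers(self, n_samples: int) -> None:
        union = np.union1d(self.train_indices, self.test_indices)
        if not np.array_equal(union, np.arange(n_samples)):
            raise ValueError("split does not partition the sample set")


def _delimiter_for(path: Path, delimiter: str | None) -> str:
    if delimiter is not None:
        if delimiter not in ("\t", ","):
            raise ValueError("delimiter must be tab or comma")
        return delimiter
    return "," if path.suffix.lower() == ".csv" else "\t"


def _parse_body(rows: list[list[str]], row_names: list[str], col_names: list[str]) -> np.ndarray:
    arr = np.empty((len(rows), len(rows[0])), dtype=np.float64)
    for i, row in enumerate(rows):
        for j, cell in enumerate(row):
            text = cell.strip()
            if text == "" or text.upper() in ("NA", "NAN"):
                raise DataFormatError(
                    f"missing value at row {row_names[i]!r}, column {col_names[j]!r}"
                )
            try:
                arr[i, j] = float(text)
            except ValueError:
                raise DataFormatError(
                    f"non-numeric cell {text!r} at row {row_names[i]!r}, "
                    f"column {col_names[j]!r}"
                ) from None
    if not np.isfinite(arr).all():
        i, j = np.argwhere(~np.isfinite(arr))[0]
        raise DataFormatError(f"non-finite value at row {row_names[i]!r}, column {col_names[j]!r}")
    return arr


def _read_label_file(path: Path, delimiter: str | None) -> dict[str, str]:
    path = Path(path)
    sep = _delimiter_for(path, delimiter)
    mapping: dict[str, str] = {}
    with open(path) as fh:
        for lineno, line in enumerate(fh, start=1):
            line = line.rstrip("\n")
            if not line.strip():
                continue
            parts = line.split(sep)
            if len(parts) != 2:
                raise LabelError(f"label file line {lineno}: expected 2 columns, got {len(parts)}")
            sid, lab = parts[0].strip(), parts[1].strip()
            if lineno == 1 and lab.lower() in LABEL_ROW_NAMES:
                continue  # optional header line
            if sid in mapping:
                raise LabelError(f"duplicate sample id {sid!r} in label file")
            mapping[sid] = lab
    return mapping


def read_expression_table(
    path: str | Path,
    *,
    orientation: str = "variables_as_rows",
    delimiter: str | None = None,
    label_file: str | Path | None = None,
) -> ExpressionMatrix:
    """Read a rectangular expression table into canonical orientation.

    Parameters
    ----------
    path : path to a TSV/CSV table with a header line and a first name column.
    orientation : ``"variables_as_rows"`` (default) or ``"samples_as_rows"``.
        Auto-detection is deliberately refused; the caller states the layout.
    delimiter : ``"\\t"`` or ``","``; inferred from the ``.csv`` suffix if None.
    label_file : optional two-column sample_id -> label file. If omitted, a row
        (or column, depending on orientation) named ``group``/``label`` must be
        present in the table.
    """
    if orientation not in ("variables_as_rows", "samples_as_rows"):
        raise ValueError(f"unknown orientation {orientation!r}")
    path = Path(path)
    sep = _delimiter_for(path, delimiter)

    with open(path) as fh:
        lines = [ln.rstrip("\n") for ln in fh if ln.strip() != ""]
    if len(lines) < 2:
        raise DataFormatError("table needs a header line and at least one data row")
    table = [ln.split(sep) for ln in lines]
    width = len(table[0])
    for lineno, row in enumerate(table, start=1):
        if len(row) != width:
            raise DataFormatError(
                f"ragged table: line {lineno} has {len(row)} fields, expected {width}"
            )

    col_names = [c.strip() for c in table[0][1:]]
    row_names = [r[0].strip() for r in table[1:]]
    body_rows = [r[1:] for r in table[1:]]

    raw_labels_from_row: list[str] | None = None
    if label_file is None:
        if orientation == "variables_as_rows":
            hits = [i for i, name in enumerate(row_names) if name.lower() in LABEL_ROW_NAMES]
            if not hits:
                raise LabelError("no 'group'/'label' row found and no label file given")
            raw_labels_from_row = [c.strip() for c in body_rows[hits[0]]]
            body_rows = [r for i, r in enumerate(body_rows) if i != hits[0]]
            row_names = [n for i, n in enumerate(row_names) if i != hits[0]]
        else:
            hits = [j for j, name in enumerate(col_names) if name.lower() in LABEL_ROW_NAMES]
            if not hits:
                raise LabelError("no 'group'/'label' column found and no label file given")
            j = hits[0]
            raw_labels_from_row = [r[j].strip() for r in body_rows]
            body_rows = [[c for jj, c in enumerate(r) if jj != j] for r in body_rows]
            col_names = [n for jj, n in enumerate(col_names) if jj != j]

    values = _parse_body(body_rows, row_names, col_names)
    if orientation == "variables_as_rows":
        values = values.T
        sample_ids, variable_names = col_names, row_names
    else:
        sample_ids, variable_names = row_names, col_names

    if label_file is not None:
        mapping = _read_label_file(Path(label_file), delimiter)
        missing = [s for s in sample_ids if s not in mapping]
        extra = [s for s in mapping if s not in sample_ids]
        if missing or extra:
            raise LabelError(
                f"label file/sample id mismatch: missing={missing[:5]} extra={extra[:5]}"
            )
        raw_labels = [mapping[s] for s in sample_ids]
    else:
        assert raw_labels_from_row is not None
        raw_labels = raw_labels_from_row

    return ExpressionMatrix.from_raw_labels(values, sample_ids, variable_names, raw_labels)


def write_expression_table(
    matrix: ExpressionMatrix,
    path: str | Path,
    *,
    orientation: str = "variables_as_rows",
    delimiter: str | None = None,
) -> None:
    """Write a matrix (with its group row/column) so that a re-read is bit-identical."""
    if orientation not in ("variables_as_rows", "samples_as_rows"):
        raise ValueError(f"unknown orientation {orientation!r}")
    path = Path(path)
    sep = _delimiter_for(path, delimiter)
    labels = matrix.label_strings()
    with open(path, "w") as fh:
        if orientation == "variables_as_rows":
            fh.write(sep.join(["id", *matrix.sample_ids]) + "\n")
            fh.write(sep.join(["group", *labels]) + "\n")
            for j, name in enumerate(matrix.variable_names):
                cells = (repr(v) for v in matrix.values[:, j].tolist())
                fh.write(sep.join([name, *cells]) + "\n")
        else:
            fh.write(sep.join(["id", *matrix.variable_names, "group"]) + "\n")
            for i, sid in enumerate(matrix.sample_ids):
                cells = (repr(v) for v in matrix.values[i, :].tolist())
                fh.write(sep.join([sid, *cells, labels[i]]) + "\n")


def write_importance_table(result, path: str | Path, *, header_comment: str | None = None) -> None:
    """Write the ranked importance table (TSV).

    Columns: rank, variable_index, variable_name, importance; rows sorted by
    descending importance with ties broken by ascending variable index.
    """
    from .importance import rank_variables  # local import to avoid a cycle

    ranked = rank_variables(result)
    if not ranked:
        raise ValueError("empty importance result")
    names = result.variable_names
    with open(path, "w") as fh:
        if header_comment:
            for line in header_comment.splitlines():
                fh.write(f"# {line}\n")
        fh.write("rank\tvariable_index\tvariable_name\timportance\n")
        for rank, (idx, imp) in enumerate(ranked, start=1):
            name = names[idx] if names is not None else f"var{idx}"
            fh.write(f"{rank}\t{idx}\t{name}\t{imp!r}\n")


def save_split(split: DataSplit, path: str | Path, *, meta: dict | None = None) -> None:
    """Persist a train/test split as JSON with optional provenance metadata."""
    payload = {
        "train_indices": split.train_indices.tolist(),
        "test_indices": split.test_indices.tolist(),
    }
    if meta:
        payload["meta"] = meta
    with open(path, "w") as fh:
        json.dump(payload, fh, indent=1)


def load_split(path: str | Path) -> DataSplit:
    with open(path) as fh:
        payload = json.load(fh)
    return DataSplit(
        np.asarray(payload["train_indices"], dtype=np.int64),
        np.asarray(payload["test_indices"], dtype=np.int64),
    )
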