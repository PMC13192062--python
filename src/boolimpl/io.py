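"""Reading and writing the pipeline's text formats.

The universal currency is a genes x samples :class:`pandas.DataFrame` of
log-scale expression values (index = gene ids, columns = sample ids).
Sample labels are a :class:`pandas.Series` mapping sample id to a class
label; signatures are a DataFrame with columns ``gene_id`` and ``weight``
(weights restricted to +1/-1).

All formats are TSV with a header row, UTF-8, '.' decimal separator.
Missing values are rejected, not imputed.
"""

from __future__ import annotations

import numpy as np
import pandas as pd

__all__ = [
    "read_matrix",
    "write_matrix",
    "read_labels",
    "write_labels",
    "read_signature",
    "write_signature",
    "log2_tpm_transform",
    "validate_matrix",
    "validate_labels",
    "read_states",
    "write_states",
]

GENE_COLUMN = "gene_id"


class FormatError(ValueError):
    """Malformed input table (duplicate ids, ragged rows, bad cells)."""


def validate_matrix(matrix: pd.DataFrame) -> pd.DataFrame:
    """Check expression-matrix invariants: unique ids, finite float values."""
    if matrix.index.has_duplicates:
        dups = matrix.index[matrix.index.duplicated()].unique().tolist()
        raise FormatError(f"duplicate gene id(s): {dups}")
    if matrix.columns.has_duplicates:
        dups = matrix.columns[matrix.columns.duplicated()].unique().tolist()
        raise FormatError(f"duplicate sample id(s): {dups}")
    values = matrix.to_numpy()
    if not np.issubdtype(values.dtype, np.number):
        raise FormatError("expression matrix contains non-numeric values")
    bad = ~np.isfinite(values)
    if bad.any():
        g, s = np.argwhere(bad)[0]
        raise FormatError(
            f"non-finite value at gene {matrix.index[g]!r}, sample {matrix.columns[s]!r}"
        )
    return matrix


def read_matrix(path, delimiter: str = "\t") -> pd.DataFrame:
    """Read a genes x samples expression matrix from delimited text.

    First header cell is the gene-id column name; remaining header cells
    are sample ids. Every cell must parse as a finite float; ``NA`` or
    empty cells are errors with their coordinates reported.
    """
    with open(path, encoding="utf-8") as fh:
        header = fh.readline().rstrip("\n").split(delimiter)[1:]
    if len(set(header)) != len(header):
        dups = sorted({h for h in header if header.count(h) > 1})
        raise FormatError(f"duplicate sample id(s) in header: {dups}")
    raw = pd.read_csv(
        path, sep=delimiter, index_col=0, dtype=str, keep_default_na=False
    )
    if raw.index.has_duplicates:
        dups = raw.index[raw.index.duplicated()].unique().tolist()
        raise FormatError(f"duplicate gene id(s): {dups}")
    try:
        matrix = raw.astype(float)
    except ValueError:
        for gene, row in raw.iterrows():
            for sample, cell in row.items():
                try:
                    float(cell)
                except ValueError:
                    raise FormatError(
                        f"cannot parse cell {cell!r} at gene {gene!r}, "
                        f"sample {sample!r}"
                    ) from None
        raise  # pragma: no cover - astype failed but every cell parsed
    matrix.index = matrix.index.astype(str)
    matrix.index.name = GENE_COLUMN
    matrix.columns = matrix.columns.astype(str)
    return validate_matrix(matrix)


def write_matrix(matrix: pd.DataFrame, path, delimiter: str = "\t") -> None:
    validate_matrix(matrix)
    out = matrix.copy()
    out.index.name = GENE_COLUMN
    out.to_csv(path, sep=delimiter)


def log2_tpm_transform(matrix: pd.DataFrame) -> pd.DataFrame:
    """Apply the log2(TPM + 1) convention to a raw-TPM matrix."""
    values = matrix.to_numpy(dtype=float)
    if (values < 0).any():
        g, s = np.argwhere(values < 0)[0]
        raise ValueError(
            f"negative TPM at gene {matrix.index[g]!r}, sample {matrix.columns[s]!r}"
        )
    return pd.DataFrame(
        np.log2(values + 1.0), index=matrix.index, columns=matrix.columns
    )


def read_labels(path, delimiter: str = "\t") -> pd.Series:
    """Read a two-column sample_id -> label table as a Series."""
    table = pd.read_csv(path, sep=delimiter, dtype=str, keep_default_na=False)
    if table.shape[1] != 2:
        raise FormatError(f"labels file must have 2 columns, got {table.shape[1]}")
    if table.iloc[:, 0].duplicated().any():
        dups = table.iloc[:, 0][table.iloc[:, 0].duplicated()].unique().tolist()
        raise FormatError(f"duplicate sample id(s) in labels: {dups}")
    labels = pd.Series(
        table.iloc[:, 1].to_numpy(), index=table.iloc[:, 0].to_numpy(), name="label"
    )
    labels.index.name = "sample_id"
    return labels


def write_labels(labels: pd.Series, path, delimiter: str = "\t") -> None:
    out = labels.rename("label")
    out.index.name = "sample_id"
    out.to_csv(path, sep=delimiter)


def validate_labels(
    labels: pd.Series, matrix: pd.DataFrame, require_binary: bool = True
) -> pd.Series:
    """Align labels with a matrix's samples; optionally require two classes."""
    missing = labels.index.difference(matrix.columns)
    if len(missing) > 0:
        raise ValueError(f"labeled sample(s) absent from matrix: {list(missing)}")
    aligned = labels.loc[[s for s in matrix.columns if s in labels.index]]
    classes = pd.unique(aligned)
    if require_binary and len(classes) != 2:
        raise ValueError(
            f"expected exactly 2 classes for training/evaluation, got {len(classes)}: "
            f"{sorted(map(str, classes))}"
        )
    return aligned


def read_signature(path, delimiter: str = "\t") -> pd.DataFrame:
    """Read a gene_id/weight signature; weights must be +1 or -1."""
    table = pd.read_csv(path, sep=delimiter, dtype={0: str}, keep_default_na=False)
    if table.shape[1] != 2:
        raise FormatError(f"signature file must have 2 columns, got {table.shape[1]}")
    table.columns = ["gene_id", "weight"]
    if table.empty:
        return pd.DataFrame({"gene_id": pd.Series(dtype=str),
                             "weight": pd.Series(dtype=int)})
    table["weight"] = table["weight"].astype(int)
    if table["gene_id"].duplicated().any():
        dups = table["gene_id"][table["gene_id"].duplicated()].unique().tolist()
        raise FormatError(f"duplicate gene id(s) in signature: {dups}")
    bad = ~table["weight"].isin([1, -1])
    if bad.any():
        raise FormatError(
            f"signature weights must be +1/-1, got {table['weight'][bad].tolist()}"
        )
    return table


def write_signature(signature: pd.DataFrame, path, delimiter: str = "\t") -> None:
    signature.to_csv(path, sep=delimiter, index=False)


# ternary states travel as "0" (low), "x" (intermediate), "1" (high)
_STATE_TO_CHAR = {-1: "0", 0: "x", 1: "1"}
_CHAR_TO_STATE = {"0": -1, "x": 0, "1": 1}


def write_states(states: pd.DataFrame, path, delimiter: str = "\t") -> None:
    arr = states.to_numpy()
    encoded = np.full(arr.shape, "x", dtype=object)
    encoded[arr == -1] = "0"
    encoded[arr == 1] = "1"
    out = pd.DataFrame(encoded, index=states.index, columns=states.columns)
    out.index.name = GENE_COLUMN
    out.to_csv(path, sep=delimiter)


def read_states(path, delimiter: str = "\t") -> pd.DataFrame:
    raw = pd.read_csv(path, sep=delimiter, index_col=0, dtype=str,
                      keep_default_na=False)
    bad = ~raw.isin(list(_CHAR_TO_STATE)).to_numpy()
    if bad.any():
        g, s = np.argwhere(bad)[0]
        raise FormatError(
            f"invalid state {raw.iloc[g, s]!r} at gene {raw.index[g]!r}, "
            f"sample {raw.columns[s]!r} (expected one of 0, x, 1)"
        )
    decoded = raw.apply(lambda col: col.map(_CHAR_TO_STATE)).astype(np.int8)
    decoded.index = decoded.index.astype(str)
    decoded.columns = decoded.columns.astype(str)
    return decoded
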