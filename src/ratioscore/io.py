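"""Reading, linearizing and reference-normalizing qPCR C_T tables.

Input is a delimited text table (comma or tab, auto-detected): header row of
gene names, first column the subject id. A second two-column file maps every
subject id to a cohort name. Cells reading "Undetermined" (the instrument's
no-amplification marker), "NA", "NaN" or empty are treated according to
``missing_policy``: under ``as_40`` they become C_T 40, the assay's
detection floor (linear level 1); under ``error`` they raise.
"""

from __future__ import annotations

import csv
from pathlib import Path

import numpy as np
import pandas as pd

from .containers import CT_MAX, CT_MIN, CtMatrix, ExpressionMatrix

MISSING_TOKENS = {"undetermined", "na", "nan", "n/a", ""}
_HEADER_TOKENS = {"subject", "subject_id", "id", "sample", "cohort", "label", "group"}


def _sniff_delimiter(path: Path) -> str:
    with open(path, newline="") as fh:
        first = fh.readline()
    try:
        return csv.Sniffer().sniff(first, delimiters=",\t;").delimiter
    except csv.Error:
        return "\t" if "\t" in first else ","


def ct_to_linear(ct_value):
    """Linear expression level 2**(40 - C_T); strictly decreasing in C_T.

    Accepts scalars or arrays; values must lie in [0, 40].
    """
    arr = np.asarray(ct_value, dtype=float)
    if (arr < CT_MIN).any() or (arr > CT_MAX).any():
        raise ValueError(f"C_T outside [{CT_MIN}, {CT_MAX}]")
    out = np.exp2(CT_MAX - arr)
    return float(out) if np.isscalar(ct_value) or arr.ndim == 0 else out


def read_labels(labels_path: str | Path, delimiter: str | None = None) -> pd.Series:
    """Read a two-column subject-id -> cohort file; header row optional."""
    labels_path = Path(labels_path)
    delim = delimiter or _sniff_delimiter(labels_path)
    df = pd.read_csv(labels_path, sep=delim, header=None, dtype=str)
    if df.shape[1] < 2:
        raise ValueError(f"{labels_path}: expected two columns (subject, cohort)")
    first = [str(v).strip().lower() for v in df.iloc[0]]
    if any(v in _HEADER_TOKENS for v in first):
        df = df.iloc[1:]
    ser = pd.Series(
        df.iloc[:, 1].str.strip().to_numpy(),
        index=pd.Index(df.iloc[:, 0].str.strip(), name="subject"),
        name="cohort",
    )
    if ser.index.has_duplicates:
        dups = ser.index[ser.index.duplicated()].unique().tolist()
        raise ValueError(f"duplicate subject ids in labels file: {dups}")
    return ser


def read_ct_table(
    table_path: str | Path,
    labels_path: str | Path,
    missing_policy: str = "as_40",
) -> CtMatrix:
    """Read a C_T table and its cohort-label file into a validated CtMatrix."""
    if missing_policy not in ("as_40", "error"):
        raise ValueError(f"unknown missing_policy {missing_policy!r}")
    table_path = Path(table_path)
    delim = _sniff_delimiter(table_path)
    raw = pd.read_csv(table_path, sep=delim, index_col=0, dtype=str)
    raw.index = raw.index.astype(str).str.strip()
    raw.columns = raw.columns.astype(str).str.strip()

    def parse_cell(value, subject, gene):
        text = "" if value is None or (isinstance(value, float) and np.isnan(value)) else str(value).strip()
        if text.lower() in MISSING_TOKENS:
            if missing_policy == "as_40":
                return CT_MAX
            raise ValueError(f"missing C_T for subject {subject!r}, gene {gene!r}")
        try:
            return float(text)
        except ValueError:
            raise ValueError(
                f"non-numeric C_T {text!r} for subject {subject!r}, gene {gene!r}"
            ) from None

    ct = pd.DataFrame(
        [[parse_cell(raw.at[s, g], s, g) for g in raw.columns] for s in raw.index],
        index=raw.index,
        columns=raw.columns,
        dtype=float,
    )
    labels = read_labels(labels_path)
    unlabeled = [s for s in ct.index if s not in labels.index]
    if unlabeled:
        raise ValueError(f"subjects missing from labels file: {unlabeled}")
    return CtMatrix(ct, labels.loc[ct.index])


def write_ct_table(
    matrix: CtMatrix,
    table_path: str | Path,
    labels_path: str | Path,
    delimiter: str = ",",
) -> None:
    """Write a CtMatrix as a delimited table plus a two-column label file."""
    matrix.ct.to_csv(table_path, sep=delimiter, index_label="subject")
    matrix.cohorts.rename("cohort").to_csv(
        labels_path, sep=delimiter, index_label="subject"
    )


def normalize_to_reference(ct: CtMatrix, reference_gene: str = "GAPDH") -> ExpressionMatrix:
    """Linearize C_T values and normalize each subject to the reference gene.

    level[s, g] = 2**(40 - ct[s, g]) / 2**(40 - ct[s, ref]) = 2**(ct[s, ref] - ct[s, g]).
    The reference column is dropped: its normalized value is identically 1 and
    would create degenerate gene/gene ratios downstream.
    """
    if reference_gene not in ct.ct.columns:
        raise KeyError(f"reference gene {reference_gene!r} not in table")
    linear = ct_to_linear(ct.ct.to_numpy())
    ref = linear[:, ct.ct.columns.get_loc(reference_gene)]
    levels = pd.DataFrame(
        linear / ref[:, None], index=ct.ct.index, columns=ct.ct.columns
    ).drop(columns=[reference_gene])
    return ExpressionMatrix(levels, ct.cohorts)
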