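"""In-memory containers for qPCR threshold-cycle and expression data.

Both containers wrap a pandas DataFrame (rows = subjects, columns = genes)
plus a per-subject cohort label Series aligned on the subject index.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

CT_MIN = 0.0
CT_MAX = 40.0


def _check_labels(values: pd.DataFrame, cohorts: pd.Series) -> pd.Series:
    cohorts = cohorts.reindex(values.index)
    missing = cohorts[cohorts.isna()].index.tolist()
    if missing:
        raise ValueError(f"subjects without a cohort label: {missing}")
    return cohorts


@dataclass
class CtMatrix:
    """Raw threshold-cycle values per subject x gene, with cohort labels.

    Parameters
    ----------
    ct
        DataFrame of C_T values in [0, 40]; index = subject ids,
        columns = gene ids, both unique.
    cohorts
        Series mapping every subject id to a cohort name.
    """

    ct: pd.DataFrame
    cohorts: pd.Series = field(repr=False)

    def __post_init__(self) -> None:
        if self.ct.index.has_duplicates:
            raise ValueError("duplicate subject identifiers")
        if self.ct.columns.has_duplicates:
            raise ValueError("duplicate gene identifiers")
        values = self.ct.to_numpy(dtype=float)
        if not np.isfinite(values).all():
            raise ValueError("non-finite C_T values")
        if (values < CT_MIN).any() or (values > CT_MAX).any():
            raise ValueError(f"C_T values outside [{CT_MIN}, {CT_MAX}]")
        self.ct = self.ct.astype(float)
        self.cohorts = _check_labels(self.ct, self.cohorts)

    @property
    def subject_ids(self) -> list[str]:
        return list(self.ct.index)

    @property
    def gene_ids(self) -> list[str]:
        return list(self.ct.columns)

    def subset(self, cohort: str | list[str]) -> "CtMatrix":
        names = [cohort] if isinstance(cohort, str) else list(cohort)
        unknown = set(names) - set(self.cohorts.unique())
        if unknown:
            raise KeyError(f"unknown cohort(s): {sorted(unknown)}")
        mask = self.cohorts.isin(names)
        return CtMatrix(self.ct.loc[mask], self.cohorts.loc[mask])


@dataclass
class ExpressionMatrix:
    """Reference-normalized linear expression levels (dimensionless).

    Levels are strictly positive; the reference gene, if retained, would be
    identically 1 and is normally dropped at normalization time.
    """

    levels: pd.DataFrame
    cohorts: pd.Series | None = field(default=None, repr=False)

    def __post_init__(self) -> None:
        if self.levels.index.has_duplicates:
            raise ValueError("duplicate subject identifiers")
        if self.levels.columns.has_duplicates:
            raise ValueError("duplicate gene identifiers")
        values = self.levels.to_numpy(dtype=float)
        if not np.isfinite(values).all() or (values <= 0).any():
            raise ValueError("expression levels must be finite and strictly positive")
        self.levels = self.levels.astype(float)
        if self.cohorts is not None:
            self.cohorts = _check_labels(self.levels, self.cohorts)

    @property
    def subject_ids(self) -> list[str]:
        return list(self.levels.index)

    @property
    def gene_ids(self) -> list[str]:
        return list(self.levels.columns)

    def subset(self, cohort: str | list[str]) -> "ExpressionMatrix":
        if self.cohorts is None:
            raise ValueError("matrix carries no cohort labels")
        names = [cohort] if isinstance(cohort, str) else list(cohort)
        unknown = set(names) - set(self.cohorts.unique())
        if unknown:
            raise KeyError(f"unknown cohort(s): {sorted(unknown)}")
        mask = self.cohorts.isin(names)
        return ExpressionMatrix(self.levels.loc[mask], self.cohorts.loc[mask])
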