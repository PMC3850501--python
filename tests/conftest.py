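import numpy as np
import pandas as pd
import pytest

from ratioscore import CtMatrix, ExpressionMatrix


def make_expression(values, cohorts=None, genes=None, prefix="S"):
    """ExpressionMatrix from a plain 2-D array of positive levels."""
    values = np.asarray(values, dtype=float)
    n, g = values.shape
    genes = genes or [chr(ord("A") + k) for k in range(g)]
    idx = pd.Index([f"{prefix}{k + 1}" for k in range(n)], name="subject")
    labels = None
    if cohorts is not None:
        labels = pd.Series(list(cohorts), index=idx)
    return ExpressionMatrix(pd.DataFrame(values, index=idx, columns=genes), labels)


def make_ct(values, cohorts, genes=None, prefix="S"):
    values = np.asarray(values, dtype=float)
    n, g = values.shape
    genes = genes or [f"G{k + 1}" for k in range(g)]
    idx = pd.Index([f"{prefix}{k + 1}" for k in range(n)], name="subject")
    return CtMatrix(
        pd.DataFrame(values, index=idx, columns=genes),
        pd.Series(list(cohorts), index=idx),
    )


@pytest.fixture
def rng():
    return np.random.default_rng(20260925)


@pytest.fixture
def random_expression_pair(rng):
    """Small random case/control expression matrices sharing a gene set."""

    def build(n_case=8, n_ctrl=8, n_genes=5, seed=7):
        local = np.random.default_rng(seed)
        genes = [f"G{k + 1}" for k in range(n_genes)]
        case = make_expression(
            np.exp2(local.normal(0, 1, size=(n_case, n_genes))), genes=genes, prefix="CASE"
        )
        ctrl = make_expression(
            np.exp2(local.normal(0, 1, size=(n_ctrl, n_genes))), genes=genes, prefix="CTRL"
        )
        return case, ctrl

    return build
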