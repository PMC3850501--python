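"""Cohort-level differential-expression summaries.

For each gene the case:control contrast is summarized by the log2 ratio of
cohort mean expression levels and a per-gene two-sample t-test on log2
levels, Bonferroni-corrected across genes.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy import stats as sps

from .containers import ExpressionMatrix


@dataclass(frozen=True)
class GeneCohortStat:
    gene: str
    log2_ratio: float
    p_value: float            # raw t-test p
    p_adjusted: float         # Bonferroni: min(1, p * n_genes)
    log10_p: float
    bonferroni_significant: bool
    direction: str            # 'over' | 'under' | 'ns'
    degenerate: bool = False  # zero variance in both cohorts; p reported as 1


def cohort_log2_ratio(
    case_expr: ExpressionMatrix,
    ctrl_expr: ExpressionMatrix,
    gene: str,
    geometric: bool = False,
) -> float:
    """log2 of (case cohort mean level / control cohort mean level).

    Arithmetic means of linear levels by default; ``geometric=True`` switches
    to geometric means (i.e. difference of mean log2 levels).
    """
    for m in (case_expr, ctrl_expr):
        if gene not in m.gene_ids:
            raise KeyError(f"gene {gene!r} not present")
        if not m.subject_ids:
            raise ValueError("empty cohort")
    a = case_expr.levels[gene].to_numpy()
    b = ctrl_expr.levels[gene].to_numpy()
    if geometric:
        return float(np.log2(a).mean() - np.log2(b).mean())
    return float(np.log2(a.mean() / b.mean()))


def differential_significance(
    case_expr: ExpressionMatrix,
    ctrl_expr: ExpressionMatrix,
    alpha: float = 0.05,
    equal_var: bool = False,
    geometric_ratio: bool = False,
) -> list[GeneCohortStat]:
    """Per-gene t-tests on log2 levels with Bonferroni correction.

    Welch's variant by default (``equal_var=False``); the classic
    pooled-variance Student's test is available via ``equal_var=True``.
    """
    if list(case_expr.gene_ids) != list(ctrl_expr.gene_ids):
        raise ValueError("case and control matrices must share the same gene set")
    if len(case_expr.subject_ids) < 2 or len(ctrl_expr.subject_ids) < 2:
        raise ValueError("need >= 2 subjects per cohort")
    genes = case_expr.gene_ids
    n_genes = len(genes)
    la = np.log2(case_expr.levels.to_numpy())
    lb = np.log2(ctrl_expr.levels.to_numpy())
    out = []
    for k, gene in enumerate(genes):
        a, b = la[:, k], lb[:, k]
        degenerate = a.std() == 0 and b.std() == 0
        if degenerate:
            p = 1.0
        else:
            p = float(sps.ttest_ind(a, b, equal_var=equal_var).pvalue)
            if np.isnan(p):
                p, degenerate = 1.0, True
        p_adj = min(1.0, p * n_genes)
        sig = p_adj < alpha
        lr = cohort_log2_ratio(case_expr, ctrl_expr, gene, geometric=geometric_ratio)
        direction = "ns" if not sig else ("over" if lr > 0 else "under")
        out.append(
            GeneCohortStat(
                gene=gene,
                log2_ratio=lr,
                p_value=p,
                p_adjusted=p_adj,
                log10_p=float(np.log10(p)) if p > 0 else -np.inf,
                bonferroni_significant=sig,
                direction=direction,
                degenerate=degenerate,
            )
        )
    return out


def over_under_summary(stats: list[GeneCohortStat]) -> tuple[float, float, float]:
    """Percentages of significantly over-, under-expressed and ns genes."""
    if not stats:
        raise ValueError("empty stats list")
    n = len(stats)
    over = 100 * sum(s.direction == "over" for s in stats) / n
    under = 100 * sum(s.direction == "under" for s in stats) / n
    return over, under, 100.0 - over - under
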