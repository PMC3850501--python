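"""Tiered case/control training workflow and evaluation.

The study design trains one ratio panel against healthy controls (tier 1)
and a second against disease controls (tier 2), rather than pooling all
controls into one comparison — pooled control-max thresholds can only rise,
eroding case coverage. New subjects are scored against both panels; the
combined call is positive only when every tier is positive (configurable in
principle, AND by default; per-tier calls are always reported alongside,
since the study reports per-comparison assignments and the combination rule
is this package's extension).
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .containers import ExpressionMatrix
from .metrics import EvalMetrics, compute_metrics
from .ratios import (
    RatioPanel,
    classify_scores,
    permutation_ratio_subsets,
    score_subjects,
    select_minimal_panel,
)


@dataclass
class PipelineConfig:
    n_perm: int = 200
    ctrl_frac: float = 0.8
    retention_frac: float = 1.0
    seed: int = 0


@dataclass
class TierReport:
    panels: dict[str, RatioPanel]
    case_calls: pd.DataFrame = field(repr=False)     # cases x (tiers..., combined)
    control_calls: dict[str, pd.Series] = field(repr=False)  # tier -> its controls
    new_calls: pd.DataFrame | None = field(repr=False, default=None)
    training_metrics: dict[str, EvalMetrics] = field(default_factory=dict)
    new_subject_positive_rate: dict[str, float] = field(default_factory=dict)
    pooled: bool = False


def train_comparison(
    case_expr: ExpressionMatrix,
    ctrl_expr: ExpressionMatrix,
    config: PipelineConfig,
    comparison: tuple[str, str] = ("case", "control"),
) -> RatioPanel:
    """Permutation subsets + minimal-panel selection for one comparison."""
    subsets = permutation_ratio_subsets(
        case_expr, ctrl_expr,
        n_perm=config.n_perm, ctrl_frac=config.ctrl_frac, seed=config.seed,
    )
    return select_minimal_panel(
        case_expr, ctrl_expr, subsets,
        retention_frac=config.retention_frac,
        comparison=comparison,
        provenance={
            "n_perm": config.n_perm,
            "ctrl_frac": config.ctrl_frac,
            "seed": config.seed,
            "retention_frac": config.retention_frac,
        },
    )


def _calls(panel: RatioPanel, expr: ExpressionMatrix) -> pd.Series:
    return pd.Series(
        classify_scores(score_subjects(panel, expr)), index=expr.levels.index
    )


def run_two_tier(
    case_expr: ExpressionMatrix,
    ctrl_expr: ExpressionMatrix,
    ond_expr: ExpressionMatrix,
    new_expr: ExpressionMatrix | None,
    config: PipelineConfig,
    pooled: bool = False,
) -> TierReport:
    """Train the tiered (or pooled) ratioscore workflow and score everyone.

    Tiered mode trains tier 1 = case vs ctrl and tier 2 = case vs ond, with
    combined call = AND over tiers. Pooled mode trains a single comparison of
    case vs the concatenated ctrl+ond cohort. Sub-group comparisons (e.g.
    case vs an inflammatory subset of the disease controls) are run by
    passing that subset as ``ond_expr``.
    """
    for other in (ctrl_expr, ond_expr) + ((new_expr,) if new_expr is not None else ()):
        if list(other.gene_ids) != list(case_expr.gene_ids):
            raise ValueError("all cohorts must share the same gene set")
    overlap = set(case_expr.subject_ids) & (set(ctrl_expr.subject_ids) | set(ond_expr.subject_ids))
    if overlap:
        raise ValueError(f"case subjects also present in a control cohort: {sorted(overlap)}")

    if pooled:
        pooled_levels = pd.concat([ctrl_expr.levels, ond_expr.levels])
        pooled_expr = ExpressionMatrix(pooled_levels)
        tiers = {"pooled": (pooled_expr, ("case", "ctrl+ond"))}
    else:
        tiers = {
            "tier1_vs_ctrl": (ctrl_expr, ("case", "ctrl")),
            "tier2_vs_ond": (ond_expr, ("case", "ond")),
        }

    panels, control_calls, training_metrics = {}, {}, {}
    case_calls = pd.DataFrame(index=case_expr.levels.index)
    new_calls = pd.DataFrame(index=new_expr.levels.index) if new_expr is not None else None
    positive_rate: dict[str, float] = {}
    for name, (controls, comparison) in tiers.items():
        panel = train_comparison(case_expr, controls, config, comparison)
        panels[name] = panel
        case_calls[name] = _calls(panel, case_expr)
        control_calls[name] = _calls(panel, controls)
        truth = np.concatenate([
            np.ones(len(case_expr.subject_ids), dtype=bool),
            np.zeros(len(controls.subject_ids), dtype=bool),
        ])
        calls = np.concatenate([case_calls[name].to_numpy(), control_calls[name].to_numpy()])
        training_metrics[name] = compute_metrics(calls, truth)
        if new_calls is not None:
            new_calls[name] = _calls(panel, new_expr)
            positive_rate[name] = float(new_calls[name].mean())

    tier_names = list(tiers)
    case_calls["combined"] = case_calls[tier_names].all(axis=1)
    if new_calls is not None:
        new_calls["combined"] = new_calls[tier_names].all(axis=1)
        positive_rate["combined"] = float(new_calls["combined"].mean())

    return TierReport(
        panels=panels,
        case_calls=case_calls,
        control_calls=control_calls,
        new_calls=new_calls,
        training_metrics=training_metrics,
        new_subject_positive_rate=positive_rate,
        pooled=pooled,
    )
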