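"""The ratioscore algorithm: gene-pair ratio features with control-derived
thresholds, permutation-based panel selection, and subject scoring.

For an ordered gene pair (i, j) the feature value of a subject is the ratio
of its expression levels level_i / level_j. The pair's threshold is the
maximum ratio observed anywhere in the control cohort, so by construction no
training control exceeds it. A subject's ratioscore against a panel of such
pairs is the number of thresholds it strictly exceeds; one or more positive
ratios (score >= 1) makes the subject a case call.

Panel selection follows the published procedure: enumerate all ordered pairs
with at least one case above the control maximum; repeat the enumeration on
200 random 80% subsets of the controls; retain pairs robust across subsets;
then choose the smallest set of retained pairs that covers the most case
subjects (greedy set cover with deterministic tie-breaking, followed by
redundancy pruning), with thresholds recomputed on the full control cohort.
"""

from __future__ import annotations

import warnings
from collections import Counter
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .containers import ExpressionMatrix

Pair = tuple[str, str]


@dataclass(frozen=True)
class RatioFeature:
    """An ordered gene pair with its control-max threshold."""

    numerator_gene: str
    denominator_gene: str
    threshold: float
    case_count: int

    def __post_init__(self) -> None:
        if self.numerator_gene == self.denominator_gene:
            raise ValueError("numerator and denominator genes must differ")
        if self.threshold <= 0:
            raise ValueError("threshold must be positive")
        if self.case_count < 0:
            raise ValueError("case_count must be non-negative")

    @property
    def pair(self) -> Pair:
        return (self.numerator_gene, self.denominator_gene)


@dataclass
class RatioPanel:
    """The minimal discriminating ratio set for one case:control comparison."""

    comparison: tuple[str, str]
    ratios: list[RatioFeature]
    covered_case_ids: frozenset[str]
    provenance: dict = field(default_factory=dict)

    def __len__(self) -> int:
        return len(self.ratios)

    @property
    def pairs(self) -> list[Pair]:
        return [r.pair for r in self.ratios]

    def to_frame(self) -> pd.DataFrame:
        rows = [
            {
                "numerator": r.numerator_gene,
                "denominator": r.denominator_gene,
                "threshold": r.threshold,
                "case_count": r.case_count,
                **{k: v for k, v in self.provenance.items()},
                "case_cohort": self.comparison[0],
                "control_cohort": self.comparison[1],
            }
            for r in self.ratios
        ]
        cols = ["numerator", "denominator", "threshold", "case_count",
                "case_cohort", "control_cohort", *self.provenance.keys()]
        return pd.DataFrame(rows, columns=cols)


@dataclass
class RatioScoreResult:
    """Per-subject ratioscore: indicator vector over panel ratios, integer
    score (its sum) and binary case call (score >= 1)."""

    subject_id: str
    score: int
    call: bool
    indicator: np.ndarray

    def __post_init__(self) -> None:
        assert self.score == int(self.indicator.sum())
        assert self.call == (self.score >= 1)


def _ratio_cube(levels: np.ndarray) -> np.ndarray:
    """All pairwise level ratios: cube[s, i, j] = levels[s, i] / levels[s, j]."""
    return levels[:, :, None] / levels[:, None, :]


def _check_cohorts(case_expr: ExpressionMatrix, ctrl_expr: ExpressionMatrix) -> None:
    if list(case_expr.gene_ids) != list(ctrl_expr.gene_ids):
        raise ValueError("case and control matrices must share the same gene set")
    if len(case_expr.subject_ids) == 0 or len(ctrl_expr.subject_ids) == 0:
        raise ValueError("empty cohort")


def enumerate_candidate_ratios(
    case_expr: ExpressionMatrix, ctrl_expr: ExpressionMatrix
) -> list[RatioFeature]:
    """All ordered gene pairs with >= 1 case strictly above the control max.

    The threshold of pair (i, j) is max over controls of level_i / level_j;
    case_count is the number of case subjects strictly exceeding it. Results
    are sorted by descending case_count, ties broken lexicographically by
    (numerator, denominator).
    """
    _check_cohorts(case_expr, ctrl_expr)
    genes = case_expr.gene_ids
    thresholds = _ratio_cube(ctrl_expr.levels.to_numpy()).max(axis=0)
    counts = (_ratio_cube(case_expr.levels.to_numpy()) > thresholds).sum(axis=0)
    out = []
    for i, gi in enumerate(genes):
        for j, gj in enumerate(genes):
            if i != j and counts[i, j] >= 1:
                out.append(RatioFeature(gi, gj, float(thresholds[i, j]), int(counts[i, j])))
    out.sort(key=lambda r: (-r.case_count, r.numerator_gene, r.denominator_gene))
    return out


def permutation_ratio_subsets(
    case_expr: ExpressionMatrix,
    ctrl_expr: ExpressionMatrix,
    n_perm: int = 200,
    ctrl_frac: float = 0.8,
    seed: int = 0,
) -> list[frozenset[Pair]]:
    """Candidate-pair sets from ``n_perm`` random control subsamples.

    Each subset is the set of (numerator, denominator) pairs saved by
    :func:`enumerate_candidate_ratios` when the control cohort is replaced by
    a without-replacement sample of ``ctrl_frac`` of its subjects (floored).
    """
    _check_cohorts(case_expr, ctrl_expr)
    if n_perm < 1:
        raise ValueError("n_perm must be >= 1")
    if not 0 < ctrl_frac <= 1:
        raise ValueError("ctrl_frac must be in (0, 1]")
    n_ctrl = len(ctrl_expr.subject_ids)
    n_take = int(np.floor(ctrl_frac * n_ctrl))
    if n_take < 1:
        raise ValueError("control subsample would be empty")

    genes = case_expr.gene_ids
    ctrl_cube = _ratio_cube(ctrl_expr.levels.to_numpy())
    case_cube = _ratio_cube(case_expr.levels.to_numpy())
    offdiag = ~np.eye(len(genes), dtype=bool)
    rng = np.random.default_rng(seed)
    subsets: list[frozenset[Pair]] = []
    for _ in range(n_perm):
        idx = rng.choice(n_ctrl, size=n_take, replace=False)
        thr = ctrl_cube[idx].max(axis=0)
        saved = ((case_cube > thr).sum(axis=0) >= 1) & offdiag
        ii, jj = np.nonzero(saved)
        subsets.append(frozenset((genes[i], genes[j]) for i, j in zip(ii, jj)))
    return subsets


def _recompute_features(
    pairs: list[Pair], case_expr: ExpressionMatrix, ctrl_expr: ExpressionMatrix
) -> tuple[list[RatioFeature], dict[Pair, np.ndarray]]:
    """Thresholds on the full control cohort and per-case coverage masks."""
    genes = list(case_expr.gene_ids)
    gidx = {g: k for k, g in enumerate(genes)}
    ctrl = ctrl_expr.levels.to_numpy()
    case = case_expr.levels.to_numpy()
    feats, masks = [], {}
    for num, den in pairs:
        i, j = gidx[num], gidx[den]
        thr = float((ctrl[:, i] / ctrl[:, j]).max())
        above = (case[:, i] / case[:, j]) > thr
        if above.any():
            feats.append(RatioFeature(num, den, thr, int(above.sum())))
            masks[(num, den)] = above
    return feats, masks


def select_minimal_panel(
    case_expr: ExpressionMatrix,
    ctrl_expr: ExpressionMatrix,
    subsets: list[frozenset[Pair]],
    retention_frac: float = 1.0,
    comparison: tuple[str, str] = ("case", "control"),
    provenance: dict | None = None,
) -> RatioPanel:
    """Smallest ratio set with maximal case coverage from permutation subsets.

    Pairs present in at least ``retention_frac`` of the subsets are retained;
    their thresholds are recomputed on the full control cohort (so every
    training control scores 0 by construction); a greedy set cover over case
    subjects then picks ratios (ties: larger minimum log-margin above
    threshold among newly covered cases, then lexicographic pair order), and
    ratios whose removal leaves coverage unchanged are pruned.
    """
    if not subsets:
        raise ValueError("empty subsets list")
    if not 0 < retention_frac <= 1:
        raise ValueError("retention_frac must be in (0, 1]")
    n_perm = len(subsets)
    tally = Counter(pair for s in subsets for pair in s)
    need = retention_frac * n_perm - 1e-9
    retained = sorted(pair for pair, c in tally.items() if c >= need)

    feats, masks = _recompute_features(retained, case_expr, ctrl_expr)
    case_ids = np.asarray(case_expr.subject_ids)
    case = case_expr.levels.to_numpy()
    gidx = {g: k for k, g in enumerate(case_expr.gene_ids)}

    def min_margin(feat: RatioFeature, new_mask: np.ndarray) -> float:
        i, j = gidx[feat.numerator_gene], gidx[feat.denominator_gene]
        vals = (case[:, i] / case[:, j])[new_mask]
        return float(np.log2(vals / feat.threshold).min())

    chosen: list[RatioFeature] = []
    covered = np.zeros(len(case_ids), dtype=bool)
    remaining = list(feats)
    while remaining:
        best, best_key = None, None
        for feat in remaining:
            new = masks[feat.pair] & ~covered
            gain = int(new.sum())
            if gain == 0:
                continue
            key = (-gain, -min_margin(feat, new), feat.numerator_gene, feat.denominator_gene)
            if best_key is None or key < best_key:
                best, best_key = feat, key
        if best is None:
            break
        chosen.append(best)
        covered |= masks[best.pair]
        remaining.remove(best)

    # prune ratios made redundant by later greedy picks
    pruned = list(chosen)
    for feat in list(chosen):
        others = [f for f in pruned if f is not feat]
        cover_without = np.zeros(len(case_ids), dtype=bool)
        for f in others:
            cover_without |= masks[f.pair]
        if covered.any() and (cover_without == covered).all():
            pruned = others
    if not pruned:
        warnings.warn(
            f"no retained ratio covers any case subject for comparison {comparison}; "
            "panel is empty",
            stacklevel=2,
        )
    prov = {
        "n_perm": n_perm,
        "ctrl_frac": None,
        "seed": None,
        "retention_frac": retention_frac,
        "retention_rule": "pair present in >= retention_frac of permutation subsets",
    }
    prov.update(provenance or {})
    return RatioPanel(
        comparison=comparison,
        ratios=pruned,
        covered_case_ids=frozenset(case_ids[covered]),
        provenance=prov,
    )


def score_subjects(panel: RatioPanel, expr: ExpressionMatrix) -> list[RatioScoreResult]:
    """Score every subject of ``expr`` against the panel.

    indicator[s, r] = 1 iff the subject's ratio strictly exceeds ratio r's
    threshold; score is the row sum; call is score >= 1. Subject order is
    preserved.
    """
    missing = {g for r in panel.ratios for g in r.pair} - set(expr.gene_ids)
    if missing:
        raise KeyError(f"panel genes absent from expression matrix: {sorted(missing)}")
    levels = expr.levels
    indicators = np.zeros((len(expr.subject_ids), len(panel.ratios)), dtype=int)
    for k, r in enumerate(panel.ratios):
        vals = levels[r.numerator_gene].to_numpy() / levels[r.denominator_gene].to_numpy()
        indicators[:, k] = vals > r.threshold
    return [
        RatioScoreResult(
            subject_id=s,
            score=int(indicators[n].sum()),
            call=bool(indicators[n].sum() >= 1),
            indicator=indicators[n],
        )
        for n, s in enumerate(expr.subject_ids)
    ]


def classify_scores(results: list[RatioScoreResult]) -> np.ndarray:
    """Binary call vector: positive iff score >= 1."""
    return np.array([r.score >= 1 for r in results], dtype=bool)


def indicator_frame(panel: RatioPanel, expr: ExpressionMatrix) -> pd.DataFrame:
    """Subjects x ratios 0/1 matrix — one heatmap row per subject."""
    results = score_subjects(panel, expr)
    cols = [f"{r.numerator_gene}/{r.denominator_gene}" for r in panel.ratios]
    return pd.DataFrame(
        [r.indicator for r in results],
        index=pd.Index([r.subject_id for r in results], name="subject"),
        columns=cols,
        dtype=int,
    )


def write_panel(panel: RatioPanel, path) -> None:
    """Serialize a panel as tab-delimited text."""
    panel.to_frame().to_csv(path, sep="\t", index=False)


def read_panel(path) -> RatioPanel:
    """Load a panel written by :func:`write_panel`."""
    # round_trip parsing: a threshold off by one ulp could turn a training
    # control positive under the strict > rule
    df = pd.read_csv(path, sep="\t", float_precision="round_trip")
    ratios = [
        RatioFeature(
            str(row["numerator"]), str(row["denominator"]),
            float(row["threshold"]), int(row["case_count"]),
        )
        for _, row in df.iterrows()
    ]
    if len(df):
        comparison = (str(df["case_cohort"].iloc[0]), str(df["control_cohort"].iloc[0]))
        prov_cols = [c for c in df.columns if c not in
                     ("numerator", "denominator", "threshold", "case_count",
                      "case_cohort", "control_cohort")]
        provenance = {c: df[c].iloc[0] for c in prov_cols}
    else:
        comparison, provenance = ("case", "control"), {}
    return RatioPanel(comparison, ratios, frozenset(), provenance)
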