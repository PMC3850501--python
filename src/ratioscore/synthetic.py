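"""Synthetic qPCR cohort generator with planted discriminative gene pairs.

The generator emulates TaqMan low-density-array style C_T matrices for a
multi-cohort blood-expression study. Noise is Gaussian in C_T space (hence
log2-linear in expression), which matches qPCR convention and makes planted
log2 effects exact: subject s of cohort c gets, for target gene g,

    C_T[s, g] ~ Normal(baseline_ct[g] - shift[c, g], ct_noise_sd),

clamped to the instrument range [0, 40]; the reference gene is drawn with
shift 0 in every cohort. Discriminative gene pairs are planted by lowering
the numerator gene's C_T (raising its expression) by a stated log2 effect in
a random fraction of case subjects, with the affected subjects recorded as
ground truth for recovery testing.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .containers import CT_MAX, CT_MIN, CtMatrix

#: (numerator gene, denominator gene, log2 effect, fraction of case subjects)
PlantSpec = tuple[str, str, float, float]

DEFAULT_N_GENES = 29  # targets, excluding the reference gene


def default_gene_names(n_genes: int) -> list[str]:
    return [f"G{k + 1:02d}" for k in range(n_genes)]


def default_baseline_ct(n_genes: int) -> np.ndarray:
    """Per-gene baseline C_T spread over a realistic blood qPCR range."""
    return np.linspace(22.0, 32.0, n_genes)


def preset_shifts(preset: str, n_genes: int) -> np.ndarray:
    """Deterministic per-gene log2 shift vectors for the study cohorts.

    ``cis_ms``: most genes over-expressed vs CTRL; ``ms_established``: most
    under-expressed; ``ms_naive``: mixed. Magnitudes +1.5 / -1.0 log2.
    """
    idx = np.arange(n_genes)
    up, down = 1.5, -1.0
    if preset == "cis_ms":
        return np.where(idx % 10 < 8, up, np.where(idx % 10 == 8, down, 0.0))
    if preset == "ms_established":
        return np.where(idx % 10 < 8, down, np.where(idx % 10 == 8, up, 0.0))
    if preset == "ms_naive":
        return np.where(idx % 2 == 0, up / 1.5, np.where(idx % 4 == 1, down, 0.0))
    if preset == "null":
        return np.zeros(n_genes)
    raise KeyError(f"unknown preset {preset!r}")


@dataclass
class SyntheticConfig:
    """Parameters of one synthetic cohort dataset."""

    n_per_cohort: dict[str, int]
    n_genes: int = DEFAULT_N_GENES
    reference_gene_name: str = "GAPDH"
    baseline_ct_mean: float | list[float] | np.ndarray | None = None
    reference_baseline_ct: float = 20.0
    ct_noise_sd: float = 1.0
    cohort_log2_shifts: dict[str, np.ndarray] = field(default_factory=dict)
    planted_pairs: list[PlantSpec] = field(default_factory=list)
    case_cohort: str | None = None
    seed: int = 0

    def __post_init__(self) -> None:
        if not self.n_per_cohort:
            raise ValueError("n_per_cohort must name at least one cohort")
        for name, n in self.n_per_cohort.items():
            if n < 1:
                raise ValueError(f"non-positive cohort size for {name!r}")
        if self.n_genes < 1:
            raise ValueError("n_genes must be positive")
        if self.baseline_ct_mean is None:
            self.baseline_ct_mean = default_baseline_ct(self.n_genes)
        baseline = np.broadcast_to(
            np.asarray(self.baseline_ct_mean, dtype=float), (self.n_genes,)
        ).copy()
        if (baseline <= 15).any() or (baseline >= 38).any():
            raise ValueError("baseline C_T means must lie in (15, 38)")
        self.baseline_ct_mean = baseline
        if self.ct_noise_sd <= 0:
            raise ValueError("ct_noise_sd must be positive")
        shifts = {}
        for cohort, vec in self.cohort_log2_shifts.items():
            if cohort not in self.n_per_cohort:
                raise ValueError(f"shift vector for unknown cohort {cohort!r}")
            arr = np.asarray(vec, dtype=float)
            if arr.shape != (self.n_genes,):
                raise ValueError(
                    f"shift vector for {cohort!r} has length {arr.shape}, "
                    f"expected ({self.n_genes},)"
                )
            shifts[cohort] = arr
        self.cohort_log2_shifts = shifts
        for num, den, effect, frac in self.planted_pairs:
            if num == den:
                raise ValueError("planted pair genes must differ")
            if effect <= 0:
                raise ValueError("planted effect must be positive")
            if not 0 <= frac <= 1:
                raise ValueError("fraction_of_cases must be in [0, 1]")

    @property
    def gene_names(self) -> list[str]:
        return default_gene_names(self.n_genes)


@dataclass
class PlantedTruth:
    """Ground truth of planted pairs: which case subjects carry each effect."""

    pairs: list[tuple[str, str]]
    affected_case_ids: dict[tuple[str, str], frozenset[str]]


def generate_cohort_dataset(config: SyntheticConfig) -> CtMatrix:
    """Draw a labeled C_T matrix under the Gaussian-in-C_T model.

    A positive log2 shift means higher expression, i.e. a *lower* C_T.
    Identical (config, seed) reproduces the matrix bit-for-bit.
    """
    rng = np.random.default_rng(config.seed)
    genes = config.gene_names
    rows, subjects, labels = [], [], []
    for cohort in config.n_per_cohort:  # insertion order: deterministic
        n = config.n_per_cohort[cohort]
        shift = config.cohort_log2_shifts.get(cohort, np.zeros(config.n_genes))
        mean_ct = config.baseline_ct_mean - shift
        block = rng.normal(mean_ct, config.ct_noise_sd, size=(n, config.n_genes))
        ref = rng.normal(config.reference_baseline_ct, config.ct_noise_sd, size=(n, 1))
        rows.append(np.hstack([block, ref]))
        subjects.extend(f"{cohort}_{k + 1:03d}" for k in range(n))
        labels.extend([cohort] * n)
    ct = np.clip(np.vstack(rows), CT_MIN, CT_MAX)
    frame = pd.DataFrame(
        ct,
        index=pd.Index(subjects, name="subject"),
        columns=genes + [config.reference_gene_name],
    )
    return CtMatrix(frame, pd.Series(labels, index=frame.index, name="cohort"))


def plant_discriminative_pairs(
    dataset: CtMatrix,
    truth_spec: list[PlantSpec],
    case_cohort: str,
    seed: int = 0,
) -> tuple[CtMatrix, PlantedTruth]:
    """Plant separable gene-pair signals into the case cohort.

    For each (numerator, denominator, effect, fraction) a random
    ``fraction`` of case subjects has the numerator/denominator expression
    ratio raised by ``effect`` log2 units, applied symmetrically: numerator
    C_T lowered by effect/2 and denominator C_T raised by effect/2 (one
    cycle = one log2 unit of expression). Control rows are untouched.
    Splitting the effect across both genes makes the planted *pair* — not
    just its numerator — the maximal-margin discriminator, so panel
    selection can identify it; a one-sided shift would leave every
    denominator statistically exchangeable. Returns the modified copy and
    the ground truth of affected subjects.
    """
    if case_cohort not in set(dataset.cohorts):
        raise KeyError(f"unknown case cohort {case_cohort!r}")
    rng = np.random.default_rng(seed)
    ct = dataset.ct.copy()
    case_ids = [s for s in dataset.subject_ids if dataset.cohorts[s] == case_cohort]
    pairs, affected = [], {}
    for num, den, effect, frac in truth_spec:
        if num == den:
            raise ValueError("planted pair genes must differ")
        if effect <= 0:
            raise ValueError("planted effect must be positive")
        for g in (num, den):
            if g not in ct.columns:
                raise KeyError(f"planted gene {g!r} not in dataset")
        n_hit = int(round(frac * len(case_ids)))
        hit = sorted(rng.choice(case_ids, size=n_hit, replace=False)) if n_hit else []
        ct.loc[hit, num] = np.clip(ct.loc[hit, num] - effect / 2, CT_MIN, CT_MAX)
        ct.loc[hit, den] = np.clip(ct.loc[hit, den] + effect / 2, CT_MIN, CT_MAX)
        pairs.append((num, den))
        affected[(num, den)] = frozenset(hit)
    return CtMatrix(ct, dataset.cohorts), PlantedTruth(pairs, affected)


def simulate_dataset(config: SyntheticConfig) -> tuple[CtMatrix, PlantedTruth]:
    """Generate a dataset and plant config.planted_pairs into config.case_cohort."""
    data = generate_cohort_dataset(config)
    if not config.planted_pairs:
        return data, PlantedTruth([], {})
    if config.case_cohort is None:
        raise ValueError("planted_pairs given but case_cohort is not set")
    # derived planting seed, distinct from the drawing seed
    return plant_discriminative_pairs(
        data, config.planted_pairs, config.case_cohort, seed=config.seed + 1_000_003
    )
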