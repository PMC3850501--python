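# Methods

## The classification problem

The package classifies subjects as case or control from a panel of blood
gene-expression measurements made by quantitative RT-PCR (e.g. TaqMan
low-density arrays). The motivating application is neuro-immunology: deciding
whether a subject presenting with a first demyelinating episode (clinically
isolated syndrome, CIS) carries the blood transcript signature of multiple
sclerosis (MS), against both healthy controls (CTRL) and disease controls
with other neurologic disorders (OND, split into inflammatory OND-I and
non-inflammatory OND-NI). Nothing in the implementation is specific to that
disease setting: any wide C_T table with cohort labels works.

## From threshold cycles to expression ratios

A qPCR instrument reports a threshold cycle C_T per (subject, gene); each
cycle is a doubling, so linear expression is taken as

    level = 2^(40 − C_T),

with 40 cycles the conventional detection limit (an undetected well maps to
C_T 40, i.e. level 1, the assay floor; whether undetected wells should
instead be excluded is configurable via `missing_policy`). Each subject's
levels are divided by their housekeeping-gene level (GAPDH by default),
giving dimensionless levels; the reference column is dropped afterwards
because its normalized value is identically 1 and would create degenerate
gene/gene ratios. Note that within-subject gene/gene ratios are
algebraically unchanged by reference normalization — the tests assert this —
so normalization matters only for the cohort-level statistics, not for the
classifier itself.

## The ratioscore classifier

For an ordered gene pair (i, j) define the subject feature r = level_i /
level_j and the pair's threshold

    t_ij = max over control cohort of r.

A subject is *positive on the pair* iff r > t_ij (strict, so by construction
no training control is ever positive). Panel construction:

1. **Enumeration** — every ordered pair with at least one case subject above
   its control-max threshold is a candidate. We save all such pairs rather
   than applying a count cutoff; ranking happens later.
2. **Permutation subsetting** — enumeration is repeated on `n_perm = 200`
   random 80% subsets of the controls (`ctrl_frac = 0.8`, sampled without
   replacement, seeded). Pairs present in at least `retention_frac` of the
   subsets are retained; the default `retention_frac = 1.0` is the strictest
   reading of robustness, and is exposed because any majority rule is
   defensible.
3. **Thresholds on the full control cohort** — retained pairs get their final
   threshold from *all* controls, which forces training specificity 1.0.
4. **Greedy minimal cover** — exact minimum set cover is NP-hard, so the
   panel is built greedily: repeatedly add the retained pair covering the
   most not-yet-covered cases; break ties by the larger minimum log2 margin
   above threshold among the newly covered cases (a robustness preference),
   then lexicographically by (numerator, denominator) so builds are
   deterministic. Pairs whose removal leaves coverage unchanged are pruned.
   On instances small enough for exhaustive subset search the greedy cover
   attains the optimal coverage (asserted in the tests).

A subject's **ratioscore** against a panel is the number of panel thresholds
it strictly exceeds; score ≥ 1 is a case call. Everything is a ratio of two
within-subject measurements, so all outputs are invariant to per-subject
rescaling of expression (e.g. input-amount or efficiency differences that
multiply every gene alike).

## Tiered versus pooled comparisons

Pooling heterogeneous controls (CTRL + OND) into one comparison can only
raise control-max thresholds, so case coverage can only fall. The pipeline
therefore trains two tiers — case vs CTRL, then case vs OND — and classifies
a new subject as combined-positive only if positive in both. The source
studies report per-comparison assignments without stating a combination
rule; the AND rule is this package's choice, per-tier calls are always
reported alongside, and the rule is labelled as an extension in the run
output. A pooled single-tier mode and sub-group modes (case vs OND-I or
OND-NI alone) are available for comparison.

## SVM counterpart

The SVM consumes the same panel ratios, encoded as log2(r / t) so that 0 is
the ratioscore decision boundary and features stay scale-free. (The source
method description ties the SVM to "each set of ratioscores" without giving
the encoding; this symmetric, threshold-centred encoding is our choice.)
Training mirrors the study design: a stratified 60/40 train/validation
split; hyperparameters (soft-margin C, and RBF width γ for the default RBF
kernel) chosen by L-fold cross-validated accuracy within the 60%; final
refit on the full 60%; accuracies, sensitivity and specificity reported for
training, validation and total sets. L is not fixed by the study design;
the default is 10 (configurable). We use a standard soft-margin SVM
(scikit-learn's SVC) rather than a least-squares SVM: the comparison is
methodological and LS-specific numerics are out of scope. The fitted model
serializes to JSON (support vectors, dual coefficients, intercept, kernel
parameters) so predictions can be reproduced without binary artifacts.

## Cohort-level statistics

Per gene, the case:control contrast is summarized by log2(mean case level /
mean control level) — arithmetic means of linear levels, matching how such
fold-changes are conventionally displayed; a geometric-mean variant is a
flag away — and a two-sample t-test on log2 levels with Bonferroni
correction (adjusted p = min(1, p × n_genes)). Welch's unequal-variance
variant is the default since cohort variances are not credibly equal; the
pooled-variance test is available via `equal_var=True`. The test scale
(log2) is our choice: t-tests on heavily right-skewed linear levels would be
dominated by a few subjects. Genes with zero variance in both cohorts are
reported as p = 1 with a `degenerate` flag rather than raising.

## Synthetic cohorts

No patient-level dataset accompanies the method, so the package ships a
generator that emulates the assay's statistical structure and provides
ground truth for recovery testing:

- **Noise model**: C_T[s, g] ~ Normal(baseline_g − shift_{cohort,g}, σ),
  clamped to [0, 40]. Gaussian noise in C_T space is log2-linear in
  expression, the qPCR convention, and makes planted log2 effects exact.
- **Defaults**: baselines spread over 22–32 cycles across target genes
  (a realistic blood qPCR range), reference gene at 20 cycles (abundant
  housekeeping transcript), σ = 1.0 cycle for combined technical plus
  biological variation. 29 target genes plus one reference by default; the
  roster is a parameter because the assayed gene list varies by study.
- **Cohort presets** mimic the observed regime structure: a CIS→MS-like
  preset with ~80% of genes over-expressed, an established-disease preset
  with ~80% under-expressed, and a mixed naïve preset; magnitudes (+1.5 /
  −1.0 log2) are free parameters chosen once as typical blood fold-changes.
- **Planted pairs**: a chosen fraction of case subjects has the pair's
  expression ratio raised by a stated log2 effect, applied symmetrically
  (numerator C_T − effect/2, denominator C_T + effect/2). The symmetric
  split is deliberate: if only the numerator moved, every pair sharing that
  numerator would be statistically exchangeable and the planted *pair*
  would be unidentifiable in principle; splitting the effect makes it the
  unique maximal-margin discriminator, so recovery is a meaningful test.

What the generator does **not** emulate: plate/batch effects, technical
replicates, amplification-efficiency drift, heavy-tailed or censored C_T
distributions, correlated gene modules, or demographic structure. Passing
tests therefore certify the algorithmic machinery (thresholding, selection,
scoring, invariances) under a clean generative model — not clinical
performance on real cohorts.

## Recovery behaviour and its limits

With every case affected (fraction 1.0), a planted pair at effect 6 log2 and
σ = 0.25 dominates every competitor's margin and is recovered in every seed.
With fraction < 1 recovery is probabilistic *in principle*: an unaffected
case exceeds all n controls on some competitor pair with probability
1/(n+1) per (case, pair) by exchangeability, and such a pair then covers
strictly more cases than the planted one, which the greedy gain rule must
prefer. The recovery simulations therefore assert a high recovery frequency
across seeds at fraction 0.9, not per-seed certainty, with cohort sizes
(114 controls, 10 cases, 6 genes) at which the analytic failure rate is a
few percent.

## Numerical choices and degenerate inputs

- Strict `>` at thresholds everywhere, so a training control equal to the
  max is negative; serialized panels are parsed with round-trip float
  precision because a threshold off by one ulp could flip that.
- Candidate ordering and greedy tie-breaks are fully deterministic;
  identical (data, config, seed) reproduce every output bit-for-bit.
- An empty retained set yields an empty panel with an explicit warning (all
  subjects then score 0 and are called negative).
- Undefined rates (zero denominators in sensitivity/specificity) are
  reported as `None`, never coerced to 0.
- All randomness flows through `numpy.random.default_rng(seed)`; the
  permutation, planting, splitting and CV seeds are independent inputs.

## Problem sizes used in the shipped analyses

The test-suite simulations and the reproduction script use cohorts of tens
to ~120 subjects, 6–30 target genes, 30–200 permutation subsets, and 20–25
seeds per property — sizes at which the permutation machinery and exhaustive
test oracles are comfortably exact while still exhibiting the cohort-scale
behaviour of interest (training-specificity construction, pooled-control
degradation, recovery, train/validation accuracy gaps).
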