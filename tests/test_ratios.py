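import numpy as np
import pandas as pd
import pytest

from ratioscore import (
    ExpressionMatrix,
    RatioFeature,
    RatioPanel,
    classify_scores,
    enumerate_candidate_ratios,
    indicator_frame,
    permutation_ratio_subsets,
    read_panel,
    score_subjects,
    select_minimal_panel,
    write_panel,
)

from conftest import make_expression
from oracles import brute_force_candidates, exhaustive_best_coverage


class TestEnumerate:
    def test_hand_worked_two_gene_example(self):
        # controls have A/B = 1.0 and 2.0; cases 2.5 and 3.0 -> (A,B) saved at
        # threshold 2.0 with both cases above; (B,A) max control ratio is 1.0
        # (=1/1.0) and no case exceeds it
        ctrl = make_expression([[1.0, 1.0], [2.0, 1.0]], prefix="C")
        case = make_expression([[2.5, 1.0], [3.0, 1.0]], prefix="M")
        saved = enumerate_candidate_ratios(case, ctrl)
        assert [(r.pair, r.threshold, r.case_count) for r in saved] == [
            (("A", "B"), 2.0, 2)
        ]

    def test_identical_cohorts_save_nothing(self):
        levels = [[1.0, 2.0, 3.0], [2.0, 1.0, 0.5]]
        case = make_expression(levels, prefix="M")
        ctrl = make_expression(levels, prefix="C")
        assert enumerate_candidate_ratios(case, ctrl) == []

    def test_matches_brute_force_triple_loop(self, random_expression_pair):
        case, ctrl = random_expression_pair(n_case=8, n_ctrl=8, n_genes=5, seed=7)
        expected = brute_force_candidates(
            case.levels.to_numpy().tolist(),
            ctrl.levels.to_numpy().tolist(),
            case.gene_ids,
        )
        got = {r.pair: (r.threshold, r.case_count) for r in enumerate_candidate_ratios(case, ctrl)}
        assert set(got) == set(expected)
        for pair in expected:
            assert got[pair][0] == pytest.approx(expected[pair][0], rel=1e-12)
            assert got[pair][1] == expected[pair][1]

    def test_sorted_by_descending_case_count_then_pair(self, random_expression_pair):
        case, ctrl = random_expression_pair(seed=3)
        saved = enumerate_candidate_ratios(case, ctrl)
        keys = [(-r.case_count, r.numerator_gene, r.denominator_gene) for r in saved]
        assert keys == sorted(keys)

    def test_gene_set_mismatch_rejected(self):
        case = make_expression([[1.0, 2.0]], genes=["A", "B"])
        ctrl = make_expression([[1.0, 2.0]], genes=["A", "C"])
        with pytest.raises(ValueError):
            enumerate_candidate_ratios(case, ctrl)

    def test_antisymmetry_at_most_one_full_cover(self, random_expression_pair):
        """(i,j) and (j,i) cannot both cover the entire case cohort: a case
        above the control max on i/j is below the control min on j/i."""
        for seed in range(10):
            case, ctrl = random_expression_pair(n_case=6, n_ctrl=6, seed=seed)
            n_case = len(case.subject_ids)
            full = {r.pair for r in enumerate_candidate_ratios(case, ctrl) if r.case_count == n_case}
            assert not any((j, i) in full for (i, j) in full)

    def test_monotone_coverage_in_cohort_growth(self, random_expression_pair):
        """Adding a case never lowers, adding a control never raises, any
        pair's case_count."""
        case, ctrl = random_expression_pair(n_case=6, n_ctrl=6, seed=12)
        base = {r.pair: r.case_count for r in enumerate_candidate_ratios(case, ctrl)}

        extra_case = ExpressionMatrix(
            pd.concat([case.levels, case.levels.iloc[[0]].rename(index={"CASE1": "CASEX"}) * 1.7])
        )
        grown = {r.pair: r.case_count for r in enumerate_candidate_ratios(extra_case, ctrl)}
        assert all(grown.get(p, 0) >= c for p, c in base.items())

        extra_ctrl = ExpressionMatrix(
            pd.concat([ctrl.levels, ctrl.levels.iloc[[0]].rename(index={"CTRL1": "CTRLX"}) * 1.7])
        )
        shrunk = {r.pair: r.case_count for r in enumerate_candidate_ratios(case, extra_ctrl)}
        assert all(shrunk.get(p, 0) <= c for p, c in base.items())


class TestPermutationSubsets:
    def test_returns_exactly_n_perm_sets(self, random_expression_pair):
        case, ctrl = random_expression_pair(seed=1)
        subsets = permutation_ratio_subsets(case, ctrl, n_perm=200, seed=0)
        assert len(subsets) == 200

    def test_full_fraction_equals_full_cohort_candidates(self, random_expression_pair):
        case, ctrl = random_expression_pair(seed=2)
        full = {r.pair for r in enumerate_candidate_ratios(case, ctrl)}
        subsets = permutation_ratio_subsets(case, ctrl, n_perm=5, ctrl_frac=1.0, seed=0)
        assert all(s == full for s in subsets)

    def test_seeded_determinism(self, random_expression_pair):
        case, ctrl = random_expression_pair(seed=4)
        a = permutation_ratio_subsets(case, ctrl, n_perm=20, seed=9)
        b = permutation_ratio_subsets(case, ctrl, n_perm=20, seed=9)
        assert a == b

    @pytest.mark.parametrize("kwargs", [{"n_perm": 0}, {"ctrl_frac": 0.0}, {"ctrl_frac": 1.5}])
    def test_invalid_parameters_rejected(self, random_expression_pair, kwargs):
        case, ctrl = random_expression_pair(seed=5)
        with pytest.raises(ValueError):
            permutation_ratio_subsets(case, ctrl, seed=0, **kwargs)


def _panel_toy():
    """4 cases, marker genes R1..R3 plus a flat denominator gene D.

    Gene Rk is elevated (2.0 vs 0.5) in a chosen case subset; R3's subset
    {1, 2} lies inside R1's {0, 1} union R2's {2, 3}, so every ratio built
    from R3 is redundant for coverage.
    """
    genes = ["R1", "R2", "R3", "D"]
    cover = {"R1": {0, 1}, "R2": {2, 3}, "R3": {1, 2}}
    ctrl = make_expression(
        [[1.0] * 4, [1.1, 1.1, 1.1, 1.0]], genes=genes, prefix="C"
    )
    rows = [
        [2.0 if s in cover[g] else 0.5 for g in genes[:3]] + [1.0]
        for s in range(4)
    ]
    case = make_expression(rows, genes=genes, prefix="M")
    return case, ctrl, cover


class TestSelectMinimalPanel:
    def test_single_covering_ratio_is_forced(self):
        ctrl = make_expression([[1.0, 1.0]], prefix="C")
        case = make_expression([[3.0, 1.0], [4.0, 1.0]], prefix="M")
        subsets = permutation_ratio_subsets(case, ctrl, n_perm=10, ctrl_frac=1.0, seed=0)
        panel = select_minimal_panel(case, ctrl, subsets)
        assert panel.pairs == [("A", "B")]
        assert panel.covered_case_ids == frozenset({"M1", "M2"})

    def test_redundant_ratio_excluded_and_coverage_optimal(self):
        case, ctrl, _ = _panel_toy()
        subsets = permutation_ratio_subsets(case, ctrl, n_perm=20, ctrl_frac=1.0, seed=0)
        panel = select_minimal_panel(case, ctrl, subsets)
        assert "R3" not in {r.numerator_gene for r in panel.ratios}
        # oracle: exhaustive search over all subsets of every candidate's
        # case-cover set (the full 2^n_candidates space)
        cover_sets = []
        for r in enumerate_candidate_ratios(case, ctrl):
            vals = case.levels[r.numerator_gene] / case.levels[r.denominator_gene]
            cover_sets.append(frozenset(vals.index[vals > r.threshold]))
        best_cover, min_size = exhaustive_best_coverage(cover_sets)
        assert len(panel.covered_case_ids) == best_cover == 4
        assert len(panel.ratios) == min_size

    def test_greedy_coverage_matches_exhaustive_on_random_instances(
        self, random_expression_pair
    ):
        for seed in range(8):
            case, ctrl = random_expression_pair(n_case=7, n_ctrl=7, n_genes=4, seed=seed)
            subsets = permutation_ratio_subsets(case, ctrl, n_perm=30, ctrl_frac=0.8, seed=seed)
            panel = select_minimal_panel(case, ctrl, subsets)
            feats = enumerate_candidate_ratios(case, ctrl)
            retained_pairs = set.intersection(*[set(s) for s in subsets]) if subsets else set()
            levels = case.levels
            cover_sets = []
            for r in feats:
                if r.pair not in retained_pairs:
                    continue
                vals = levels[r.numerator_gene] / levels[r.denominator_gene]
                cover_sets.append(frozenset(vals.index[vals > r.threshold]))
            if len(cover_sets) > 12:
                continue  # keep the exhaustive oracle tractable
            best_cover, _ = exhaustive_best_coverage(cover_sets)
            assert len(panel.covered_case_ids) == best_cover

    def test_irredundancy_invariant(self, random_expression_pair):
        for seed in range(6):
            case, ctrl = random_expression_pair(n_case=10, n_ctrl=6, n_genes=5, seed=seed)
            subsets = permutation_ratio_subsets(case, ctrl, n_perm=50, seed=seed)
            panel = select_minimal_panel(case, ctrl, subsets)
            masks = []
            for r in panel.ratios:
                vals = case.levels[r.numerator_gene] / case.levels[r.denominator_gene]
                masks.append(frozenset(vals.index[vals > r.threshold]))
            union = frozenset().union(*masks) if masks else frozenset()
            for k in range(len(masks)):
                without = frozenset().union(*(m for i, m in enumerate(masks) if i != k)) if len(masks) > 1 else frozenset()
                assert without != union, "panel contains a redundant ratio"

    def test_no_retained_ratios_warns_and_returns_empty(self):
        levels = [[1.0, 2.0], [2.0, 1.0]]
        case = make_expression(levels, prefix="M")
        ctrl = make_expression(levels, prefix="C")
        subsets = permutation_ratio_subsets(case, ctrl, n_perm=10, ctrl_frac=1.0, seed=0)
        with pytest.warns(UserWarning, match="empty"):
            panel = select_minimal_panel(case, ctrl, subsets)
        assert panel.ratios == [] and panel.covered_case_ids == frozenset()

    def test_empty_subsets_rejected(self, random_expression_pair):
        case, ctrl = random_expression_pair(seed=6)
        with pytest.raises(ValueError):
            select_minimal_panel(case, ctrl, [])


class TestScoring:
    def _panel(self):
        return RatioPanel(
            comparison=("MS", "CTRL"),
            ratios=[
                RatioFeature("A", "B", 2.0, 1),
                RatioFeature("B", "C", 1.5, 1),
                RatioFeature("A", "C", 4.0, 1),
            ],
            covered_case_ids=frozenset(),
        )

    def test_subject_below_all_thresholds_negative(self):
        expr = make_expression([[1.0, 1.0, 1.0]], genes=["A", "B", "C"])
        (res,) = score_subjects(self._panel(), expr)
        assert res.score == 0 and res.call is False

    @pytest.mark.parametrize(
        "levels,score",
        [
            ([3.0, 1.0, 0.9], 1),   # only A/B = 3.0 exceeds its threshold
            ([4.2, 2.0, 1.2], 2),   # A/B = 2.1 and B/C = 1.67 exceed; A/C = 3.5 does not
            ([6.0, 2.0, 1.0], 3),   # all three ratios exceed
        ],
    )
    def test_partial_threshold_exceedance(self, levels, score):
        expr = make_expression([levels], genes=["A", "B", "C"])
        (res,) = score_subjects(self._panel(), expr)
        assert res.score == score and res.call is (score >= 1)

    def test_score_equals_indicator_sum_and_call_rule(self, random_expression_pair):
        case, ctrl = random_expression_pair(seed=8)
        subsets = permutation_ratio_subsets(case, ctrl, n_perm=20, seed=1)
        panel = select_minimal_panel(case, ctrl, subsets)
        for res in score_subjects(panel, case):
            assert res.score == res.indicator.sum()
            assert res.call == (res.score >= 1)

    def test_training_controls_always_score_zero(self, random_expression_pair):
        for seed in range(5):
            case, ctrl = random_expression_pair(n_case=10, n_ctrl=12, seed=seed)
            subsets = permutation_ratio_subsets(case, ctrl, n_perm=50, seed=seed)
            panel = select_minimal_panel(case, ctrl, subsets)
            assert all(r.score == 0 for r in score_subjects(panel, ctrl))

    def test_missing_gene_rejected(self):
        expr = make_expression([[1.0, 1.0]], genes=["A", "B"])
        with pytest.raises(KeyError):
            score_subjects(self._panel(), expr)

    def test_classify_scores(self):
        panel = RatioPanel(("a", "b"), [RatioFeature("A", "B", 1.0, 1)], frozenset())
        expr = make_expression([[0.5, 1.0], [2.0, 1.0], [9.0, 1.0]], genes=["A", "B"])
        calls = classify_scores(score_subjects(panel, expr))
        assert calls.tolist() == [False, True, True]
        assert classify_scores([]).tolist() == []


class TestSerialization:
    def test_panel_round_trip_preserves_thresholds_exactly(self, tmp_path, random_expression_pair):
        case, ctrl = random_expression_pair(seed=10)
        subsets = permutation_ratio_subsets(case, ctrl, n_perm=20, seed=2)
        panel = select_minimal_panel(
            case, ctrl, subsets, comparison=("MS", "CTRL"),
            provenance={"n_perm": 20, "ctrl_frac": 0.8, "seed": 2, "retention_frac": 1.0},
        )
        write_panel(panel, tmp_path / "panel.tsv")
        back = read_panel(tmp_path / "panel.tsv")
        assert back.pairs == panel.pairs
        for a, b in zip(back.ratios, panel.ratios):
            assert a.threshold == b.threshold  # bit-exact: controls stay at score 0
        assert all(r.score == 0 for r in score_subjects(back, ctrl))

    def test_indicator_frame_shape_and_values(self, random_expression_pair):
        case, ctrl = random_expression_pair(seed=11)
        subsets = permutation_ratio_subsets(case, ctrl, n_perm=20, seed=3)
        panel = select_minimal_panel(case, ctrl, subsets)
        frame = indicator_frame(panel, case)
        assert frame.shape == (len(case.subject_ids), len(panel.ratios))
        assert set(np.unique(frame.to_numpy())) <= {0, 1}


class TestScaleInvariance:
    def test_per_subject_scaling_changes_nothing(self, random_expression_pair):
        case, ctrl = random_expression_pair(n_case=8, n_ctrl=8, seed=13)
        rng = np.random.default_rng(0)
        scaled_case = ExpressionMatrix(
            case.levels * rng.uniform(0.1, 10, size=(8, 1))
        )
        scaled_ctrl = ExpressionMatrix(
            ctrl.levels * rng.uniform(0.1, 10, size=(8, 1))
        )
        a = enumerate_candidate_ratios(case, ctrl)
        b = enumerate_candidate_ratios(scaled_case, scaled_ctrl)
        assert [(r.pair, r.case_count) for r in a] == [(r.pair, r.case_count) for r in b]
        for ra, rb in zip(a, b):
            assert ra.threshold == pytest.approx(rb.threshold, rel=1e-9)
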