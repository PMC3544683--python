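"""Wrapper selection: AUC, cross-validated scoring, traces and best subsets."""

import numpy as np
import pandas as pd
import pytest

from _oracles import auc_by_pair_counting
from conftest import make_matrix
from fieldmarker import (
    CRITERIA,
    BestSubset,
    ClassifierSpec,
    CohortDesign,
    CVSpec,
    ScoreMatrix,
    SelectionTrace,
    TissueGroup,
    auc_from_scores,
    best_subset,
    cv_auc,
    default_design,
    effect_from_auc,
    incremental_selection,
    null_effect,
    simulate_cohort,
    single_gene_aucs,
)

FAST_CV = CVSpec(n_folds=5, n_repeats=2, seed=0)


def small_cohort(targets: dict, n_pos=40, n_neg=30, seed=0) -> ScoreMatrix:
    d = CohortDesign(
        (TissueGroup("a", "malignant", n_pos), TissueGroup("b", "benign", n_neg))
    )
    effects = [
        effect_from_auc(g, a, 0.005) if a > 0.5 else null_effect(g)
        for g, a in targets.items()
    ]
    return simulate_cohort(d, effects, seed=seed)


class TestAUC:
    @pytest.mark.parametrize(
        "pos, neg, expected",
        [
            ([0.9, 0.8], [0.1, 0.2], 1.0),
            ([1], [1], 0.5),
            ([3, 1], [2, 0], 0.75),
            ([0, 0], [1, 1], 0.0),
        ],
    )
    def test_worked_examples(self, pos, neg, expected):
        assert auc_from_scores(pos, neg) == pytest.approx(expected, abs=1e-12)

    def test_matches_pair_counting_on_small_instances(self):
        # exhaustive lists of length <= 3 over a 3-value alphabet
        from itertools import product

        lists = [list(t) for k in (1, 2, 3) for t in product((0, 1, 2), repeat=k)]
        for pos in lists[::3]:
            for neg in lists[::3]:
                assert auc_from_scores(pos, neg) == pytest.approx(
                    auc_by_pair_counting(pos, neg), abs=1e-12
                )

    def test_complement_symmetry(self):
        rng = np.random.default_rng(2)
        pos = rng.normal(size=9)
        neg = rng.normal(size=5)
        assert auc_from_scores(pos, neg) + auc_from_scores(neg, pos) == pytest.approx(1.0)

    def test_empty_rejected(self):
        with pytest.raises(ValueError):
            auc_from_scores([], [1.0])


class TestCVAUC:
    def test_separable_gene_scores_near_one(self):
        m = make_matrix(
            {"g": [6] * 25 + [0] * 25}, ["NTAC"] * 25 + ["NTAB"] * 25
        )
        mean, sd = cv_auc(m, ["g"], ClassifierSpec(), FAST_CV)
        assert mean >= 0.99

    def test_permuted_labels_near_half(self, spiked_cohort):
        rng = np.random.default_rng(0)
        perm = rng.permutation(spiked_cohort.n_samples)
        shuffled = ScoreMatrix(
            scores=spiked_cohort.scores,
            tissue=spiked_cohort.tissue,
            class_label=pd.Series(
                spiked_cohort.class_label.to_numpy()[perm],
                index=spiked_cohort.scores.index,
                name="class",
            ),
        )
        mean, _ = cv_auc(shuffled, None, ClassifierSpec(), CVSpec(n_repeats=3, seed=1))
        assert 0.40 <= mean <= 0.60

    def test_seed_determinism(self, spiked_cohort):
        a = cv_auc(spiked_cohort, ["TP53"], ClassifierSpec(), CVSpec(n_repeats=2, seed=5))
        b = cv_auc(spiked_cohort, ["TP53"], ClassifierSpec(), CVSpec(n_repeats=2, seed=5))
        assert a == b

    def test_row_permutation_invariance(self, spiked_cohort):
        rng = np.random.default_rng(1)
        perm = rng.permutation(spiked_cohort.n_samples)
        permuted = ScoreMatrix(
            scores=spiked_cohort.scores.iloc[perm],
            tissue=spiked_cohort.tissue.iloc[perm],
            class_label=spiked_cohort.class_label.iloc[perm],
        )
        cv = CVSpec(n_repeats=2, seed=7)
        assert cv_auc(spiked_cohort, ["TP53"], cv=cv) == pytest.approx(
            cv_auc(permuted, ["TP53"], cv=cv), abs=1e-12
        )

    def test_pooled_aggregation_close_to_fold_mean(self, spiked_cohort):
        m1, _ = cv_auc(spiked_cohort, ["TP53"], cv=CVSpec(n_repeats=2, seed=3))
        m2, _ = cv_auc(spiked_cohort, ["TP53"], cv=CVSpec(n_repeats=2, seed=3, pooled=True))
        assert abs(m1 - m2) < 0.03

    def test_class_smaller_than_folds_rejected(self):
        m = make_matrix({"g": [1, 2, 3, 4, 5, 0]}, ["NTAC"] * 3 + ["NTAB"] * 3)
        with pytest.raises(ValueError, match="n_folds"):
            cv_auc(m, ["g"], ClassifierSpec(), CVSpec(n_folds=10))

    def test_spec_validation(self):
        with pytest.raises(ValueError):
            CVSpec(n_folds=1)
        with pytest.raises(ValueError):
            ClassifierSpec(kernel="rbf")
        with pytest.raises(ValueError):
            ClassifierSpec(regularization_strength=0.0)


class TestSingleGeneAUC:
    def test_recovery_and_null(self):
        m = small_cohort({"strong": 0.87, "n1": 0.5, "n2": 0.5}, 120, 80, seed=4)
        tab = single_gene_aucs(m, ClassifierSpec(), CVSpec(n_folds=5, n_repeats=3, seed=2))
        assert abs(tab.loc["strong", "mean_auc"] - 0.87) < 0.07
        assert abs(tab.loc["n1", "mean_auc"] - 0.5) < 0.10
        assert list(tab.index) == ["strong", "n1", "n2"]

    def test_effect_ordering_recovered(self):
        # genes at analytic AUC 0.6 < 0.75 < 0.9 keep that order, most seeds
        correct = 0
        for i in range(10):
            m = small_cohort({"a": 0.6, "b": 0.75, "c": 0.9}, 120, 80, seed=100 + i)
            tab = single_gene_aucs(m, ClassifierSpec(), CVSpec(n_folds=5, n_repeats=3, seed=i))
            correct += list(tab["mean_auc"].sort_values().index) == ["a", "b", "c"]
        assert correct >= 9


class TestIncrementalSelection:
    def test_trace_structure(self):
        m = small_cohort({"s": 0.85, "n1": 0.5, "n2": 0.5, "n3": 0.5}, 50, 40, seed=8)
        tr = incremental_selection(m, "wilcoxon", ClassifierSpec(), FAST_CV)
        assert len(tr.subsets) == 4
        for k in range(1, 4):
            assert tr.subsets[k][:-1] == tr.subsets[k - 1]  # nested, +1 gene
        assert tr.subsets[0] == ("s",)
        assert set(tr.subsets[-1]) == set(m.genes)

    def test_first_step_matches_single_gene_auc(self):
        m = small_cohort({"s": 0.85, "n1": 0.5, "n2": 0.5}, 60, 50, seed=9)
        cv = CVSpec(n_folds=5, n_repeats=3, seed=11)
        tr = incremental_selection(m, "ttest", ClassifierSpec(), cv)
        solo, _ = cv_auc(m, [tr.subsets[0][0]], ClassifierSpec(), cv)
        assert tr.mean_auc[0] == pytest.approx(solo, abs=1e-12)

    def test_best_subset_contains_strong_gene_each_criterion(self):
        hits = {c: 0 for c in CRITERIA}
        n_rep = 5
        for i in range(n_rep):
            m = small_cohort(
                {"s": 0.87, "n1": 0.5, "n2": 0.5, "n3": 0.5, "n4": 0.5},
                120, 80, seed=300 + i,
            )
            for c in CRITERIA:
                tr = incremental_selection(m, c, ClassifierSpec(), FAST_CV)
                hits[c] += "s" in best_subset(tr).genes
        for c in CRITERIA:
            assert hits[c] == n_rep, c


class TestBestSubset:
    def _trace(self, aucs):
        genes = tuple(f"g{i}" for i in range(len(aucs)))
        subsets = tuple(genes[: k + 1] for k in range(len(aucs)))
        return SelectionTrace("ttest", subsets, tuple(aucs), tuple(0.0 for _ in aucs))

    def test_peak_at_one(self):
        bs = best_subset(self._trace([0.9, 0.8, 0.7]))
        assert bs.genes == ("g0",) and bs.mean_auc == 0.9

    def test_tie_prefers_smaller_subset(self):
        bs = best_subset(self._trace([0.7, 0.9, 0.9]))
        assert len(bs.genes) == 2

    def test_increasing_trace_returns_full_panel(self):
        bs = best_subset(self._trace([0.6, 0.7, 0.8, 0.85]))
        assert len(bs.genes) == 4

    def test_empty_trace_rejected(self):
        with pytest.raises(ValueError):
            best_subset(SelectionTrace("ttest", (), (), ()))
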