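import math

import numpy as np
import pytest

from comorbnet.evaluation import (
    CohortTable,
    PairCounts,
    assign_tiers,
    categorize_comorbidity,
    ehr_labels,
    evaluate_index_disease,
    phi_correlation,
    relative_risk,
    roc_auc,
    spearman_rank,
    youden_threshold,
)


class TestPhiCorrelation:
    def test_perfect_co_occurrence(self):
        assert phi_correlation(PairCounts(2, 2, 2, 4)) == pytest.approx(1.0)

    def test_independence_gives_zero(self):
        assert phi_correlation(PairCounts(2, 20, 10, 100)) == pytest.approx(0.0)

    def test_worked_example(self):
        assert phi_correlation(PairCounts(5, 20, 10, 100)) == pytest.approx(0.25)

    def test_zero_prevalence_undefined(self):
        assert math.isnan(phi_correlation(PairCounts(0, 0, 10, 100)))

    def test_full_prevalence_undefined(self):
        assert math.isnan(phi_correlation(PairCounts(10, 100, 10, 100)))


class TestRelativeRisk:
    def test_independence_gives_one(self):
        assert relative_risk(PairCounts(2, 20, 10, 100)).rr == pytest.approx(1.0)

    def test_worked_example(self):
        assert relative_risk(PairCounts(5, 20, 10, 100)).rr == pytest.approx(2.5)

    def test_zero_co_occurrence(self):
        rr = relative_risk(PairCounts(0, 20, 10, 100))
        assert rr.rr == 0.0
        assert math.isnan(rr.ci_low)

    def test_ci_brackets_point_estimate(self):
        # counts chosen so the clamped SE^2 = 1/C - N/(Pi Pj) stays positive
        rr = relative_risk(PairCounts(5, 20, 40, 100))
        assert rr.ci_low < rr.rr < rr.ci_high

    def test_ci_narrows_with_scale(self):
        small = relative_risk(PairCounts(5, 20, 40, 100))
        big = relative_risk(PairCounts(500, 2000, 4000, 10000))
        assert big.rr == pytest.approx(small.rr)
        assert (big.ci_high - big.ci_low) < (small.ci_high - small.ci_low)

    def test_zero_prevalence_undefined(self):
        assert math.isnan(relative_risk(PairCounts(0, 0, 10, 100)).rr)


class TestSignAgreementIdentity:
    def test_phi_and_rr_agree_in_sign_small_n(self):
        """sign(phi) == sign(RR - 1): both share the numerator C*N - Pi*Pj."""
        for n in range(2, 16):
            for p_i in range(1, n):
                for p_j in range(1, n):
                    lo, hi = max(0, p_i + p_j - n), min(p_i, p_j)
                    for c in range(lo, hi + 1):
                        pc = PairCounts(c, p_i, p_j, n)
                        phi = phi_correlation(pc)
                        rr = relative_risk(pc).rr
                        assert np.sign(phi) == np.sign(rr - 1)


class TestEhrLabels:
    def cohort(self, cols):
        X = np.array(cols).T
        return CohortTable([f"D{i}" for i in range(X.shape[1])], X)

    def test_perfect_co_occurrence_positive_label(self):
        c = self.cohort([[1, 1, 0, 0], [1, 1, 0, 0], [0, 0, 1, 0]])
        labels = ehr_labels(c, "D0")
        assert labels.loc["D1", "label"] == 1

    def test_never_co_occurring_negative_label(self):
        c = self.cohort([[1, 1, 0, 0], [0, 0, 1, 1]])
        labels = ehr_labels(c, "D0")
        assert labels.loc["D1", "label"] == -1

    def test_undefined_measures_flagged_not_crashed(self):
        c = self.cohort([[1, 1, 0, 0], [0, 0, 0, 0]])
        labels = ehr_labels(c, "D0")
        assert not labels.loc["D1", "evaluable"]

    def test_non_binary_cohort_fatal(self):
        with pytest.raises(ValueError, match="binary"):
            CohortTable(["a"], np.array([[2]]))

    def test_round_trip_io(self, tmp_path, rng):
        X = (rng.random((50, 4)) < 0.3).astype(int)
        c = CohortTable(list("abcd"), X)
        c.write(tmp_path / "cohort.tsv")
        c2 = CohortTable.read(tmp_path / "cohort.tsv")
        assert c2.phenotypes == c.phenotypes
        np.testing.assert_array_equal(c2.matrix, c.matrix)


class TestRocAuc:
    def test_worked_example(self):
        scores = np.array([0.9, 0.7, 0.8, 0.1])
        labels = np.array([1, 1, -1, -1])
        assert roc_auc(scores, labels) == pytest.approx(0.75)

    def test_perfect_separation(self):
        assert roc_auc(np.array([3, 2, 1, 0]), np.array([1, 1, -1, -1])) == 1.0

    def test_one_class_undefined(self):
        assert math.isnan(roc_auc(np.array([1, 2]), np.array([1, 1])))

    def test_monotone_transform_invariance(self, rng):
        scores = rng.normal(size=40)
        labels = np.where(rng.random(40) < 0.5, 1, -1)
        a = roc_auc(scores, labels)
        b = roc_auc(np.exp(3 * scores), labels)
        assert a == pytest.approx(b)


class TestYoudenThreshold:
    def test_tie_broken_toward_smallest_threshold(self):
        scores = np.array([0.9, 0.7, 0.8, 0.1])
        labels = np.array([1, 1, -1, -1])
        assert youden_threshold(scores, labels) == pytest.approx(0.7)

    def test_perfect_separation_returns_smallest_positive_score(self):
        scores = np.array([0.9, 0.7, 0.3, 0.1])
        labels = np.array([1, 1, -1, -1])
        assert youden_threshold(scores, labels) == pytest.approx(0.7)

    def test_single_positive_with_top_score(self):
        scores = np.array([0.9, 0.5, 0.2])
        labels = np.array([1, -1, -1])
        assert youden_threshold(scores, labels) == pytest.approx(0.9)

    def test_consistent_with_categorization_confusion_counts(self, rng):
        scores = rng.normal(size=30)
        labels = np.where(rng.random(30) < 0.4, 1, -1)
        j = youden_threshold(scores, labels)
        named = {str(i): s for i, s in enumerate(scores)}
        direct, inverse = categorize_comorbidity(named, j)
        tp = sum(labels[int(i)] == 1 for i in direct)
        fp = len(direct) - tp
        assert tp == np.sum((scores >= j) & (labels == 1))
        assert fp == np.sum((scores >= j) & (labels == -1))


class TestCategorize:
    def test_partition_with_boundary_in_direct_set(self):
        direct, inverse = categorize_comorbidity({"a": 1.0, "b": 0.2, "c": -0.4}, 0.2)
        assert direct == {"a", "b"}
        assert inverse == {"c"}

    def test_all_above_threshold(self):
        direct, inverse = categorize_comorbidity({"a": 1.0, "b": 0.5}, 0.0)
        assert inverse == set()


class TestAssignTiers:
    def test_even_split(self):
        scores = {f"D{i:02d}": -i for i in range(20)}
        tiers = assign_tiers(scores)
        assert tiers["D00"] == 1
        assert tiers["D19"] == 10
        sizes = [list(tiers.values()).count(t) for t in range(1, 11)]
        assert sizes == [2] * 10

    def test_remainder_goes_to_top_tiers(self):
        scores = {f"D{i:02d}": -i for i in range(23)}
        tiers = assign_tiers(scores)
        sizes = [list(tiers.values()).count(t) for t in range(1, 11)]
        assert sizes == [3, 3, 3, 2, 2, 2, 2, 2, 2, 2]

    def test_ties_stable_by_phenotype_id(self):
        scores = {"b": 1.0, "a": 1.0}
        scores.update({f"x{i}": -i for i in range(8)})
        tiers = assign_tiers(scores)
        assert tiers["a"] == 1 and tiers["b"] == 2

    def test_too_few_diseases_fatal(self):
        with pytest.raises(ValueError, match="n_tiers"):
            assign_tiers({"a": 1.0})


class TestSpearman:
    def test_identical_rankings(self):
        rho, _ = spearman_rank([1, 2, 3, 4], [10, 20, 30, 40])
        assert rho == pytest.approx(1.0)

    def test_reversed_rankings(self):
        rho, _ = spearman_rank([1, 2, 3, 4], [4, 3, 2, 1])
        assert rho == pytest.approx(-1.0)

    def test_worked_example(self):
        rho, _ = spearman_rank([1, 2, 3, 4], [1, 3, 2, 4])
        assert rho == pytest.approx(0.8)

    def test_constant_input_undefined(self):
        rho, p = spearman_rank([1, 1, 1], [1, 2, 3])
        assert math.isnan(rho)

    def test_exact_permutation_p(self):
        rho, p = spearman_rank([1, 2, 3, 4, 5], [1, 2, 3, 5, 4],
                               p_method="permutation")
        # 10 of 120 permutations reach |rho| >= 0.9
        assert p == pytest.approx(10 / 120)

    def test_too_few_observations_fatal(self):
        with pytest.raises(ValueError):
            spearman_rank([1, 2], [1, 2])


class TestEvaluateIndexDisease:
    def test_end_to_end_on_planted_cohort(self, rng):
        # D0 index; D1..D5 co-occur, D6..D10 avoid
        n = 2000
        base = rng.random(n) < 0.3
        cols = [base.astype(int)]
        for _ in range(5):
            cols.append((base & (rng.random(n) < 0.8)).astype(int)
                        | (~base & (rng.random(n) < 0.05)).astype(int))
        for _ in range(5):
            cols.append((~base & (rng.random(n) < 0.4)).astype(int)
                        | (base & (rng.random(n) < 0.02)).astype(int))
        cohort = CohortTable([f"D{i}" for i in range(11)], np.array(cols).T)
        scores = {f"D{i}": 1.0 - 0.1 * i for i in range(1, 6)}
        scores.update({f"D{i}": -0.5 - 0.05 * i for i in range(6, 11)})
        res = evaluate_index_disease(scores, cohort, "D0")
        assert res.auc == 1.0
        assert res.direct_set == {f"D{i}" for i in range(1, 6)}
        assert res.tiers["D1"] == 1
        assert res.spearman_rho > 0.5
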