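"""ROC conventions, the 2/N baseline, overlap statistics, characterisation."""

from itertools import combinations

import numpy as np
import pytest
from scipy import stats

from molaudit.privacy_eval import (
    baseline_tpr,
    characterize_identified,
    expected_overlap,
    identified_members,
    overlap_fraction,
    overlap_significance,
    overlap_stats,
    roc_points,
    significance_vs_baseline,
    similarity_profile,
    tpr_at_fpr,
)
from molaudit.synthetic_fixtures import expected_identified_random


class TestROC:
    def test_perfect_separation_passes_through_0_1(self):
        scores = np.array([5.0, 4.0, 1.0, 0.0])
        truth = np.array([True, True, False, False])
        fpr, tpr = roc_points(scores, truth)
        assert any(f == 0.0 and t == 1.0 for f, t in zip(fpr, tpr))

    def test_all_tied_scores_collapse_to_diagonal_endpoints(self):
        scores = np.ones(6)
        truth = np.array([True] * 4 + [False] * 2)
        fpr, tpr = roc_points(scores, truth)
        assert set(zip(fpr, tpr)) == {(0.0, 0.0), (1.0, 1.0)}

    def test_monotone_from_origin_to_one(self):
        rng = np.random.default_rng(0)
        scores = rng.normal(size=40)
        truth = rng.random(40) < 0.6
        fpr, tpr = roc_points(scores, truth)
        assert fpr[0] == tpr[0] == 0.0
        assert fpr[-1] == tpr[-1] == 1.0
        assert np.all(np.diff(fpr) >= 0) and np.all(np.diff(tpr) >= 0)

    def test_single_class_rejected(self):
        with pytest.raises(ValueError):
            roc_points(np.array([1.0, 2.0]), np.array([True, True]))


class TestTprAtFpr:
    def test_hand_example(self):
        scores = np.array([3.0, 2.0, 1.0])
        truth = np.array([True, True, False])
        assert tpr_at_fpr(scores, truth, 0.0) == 1.0

    def test_member_tied_with_max_nonmember_not_counted(self):
        scores = np.array([3.0, 2.0, 2.0])
        truth = np.array([True, True, False])
        assert tpr_at_fpr(scores, truth, 0.0) == pytest.approx(0.5)

    def test_monotone_in_alpha(self):
        rng = np.random.default_rng(1)
        scores = rng.normal(size=200)
        truth = rng.random(200) < 2 / 3
        t0 = tpr_at_fpr(scores, truth, 0.0)
        t3 = tpr_at_fpr(scores, truth, 1e-3)
        t2 = tpr_at_fpr(scores, truth, 1e-2)
        assert t0 <= t3 <= t2

    def test_uniform_scores_match_order_statistics_expectation(self):
        # Monte-Carlo oracle: expected TP count at FPR 0 is m/(n+1)
        m, n = 6, 3
        rng = np.random.default_rng(2)
        reps = 100_000
        member = rng.random((reps, m))
        non = rng.random((reps, n))
        counts = (member > non.max(axis=1, keepdims=True)).sum(axis=1)
        assert counts.mean() == pytest.approx(m / (n + 1), abs=0.02)
        # spot-check the thresholding implementation agrees on a few draws
        for i in range(50):
            scores = np.concatenate([member[i], non[i]])
            truth = np.array([True] * m + [False] * n)
            assert tpr_at_fpr(scores, truth, 0.0) * m == counts[i]

    def test_identified_members_returns_fpr0_set(self):
        scores = np.array([5.0, 3.0, 1.0, 2.0])
        truth = np.array([True, True, True, False])
        keys = ["a", "b", "c", "z"]
        assert identified_members(scores, truth, keys, 0.0) == {"a", "b"}


class TestBaseline:
    def test_two_over_n(self):
        assert baseline_tpr(859) == pytest.approx(2 / 859)
        assert baseline_tpr(859) * 859 == pytest.approx(2.0)

    def test_capped_at_one(self):
        assert baseline_tpr(2) == 1.0

    def test_order_statistics_brute_force(self):
        # enumerate every placement of m member ranks among m+n; the count of
        # members above all nonmembers has mean m/(n+1)
        for m, n in [(4, 2), (3, 3), (2, 5)]:
            total = 0
            cases = 0
            for member_ranks in combinations(range(m + n), m):
                top_nonmember = max(set(range(m + n)) - set(member_ranks))
                total += sum(1 for r in member_ranks if r > top_nonmember)
                cases += 1
            assert total / cases == pytest.approx(m / (n + 1))
            assert expected_identified_random(m, n) == pytest.approx(m / (n + 1))


class TestSignificance:
    def test_all_repetitions_above_baseline_significant(self):
        tprs = [0.02] * 20
        res = significance_vs_baseline(tprs, 0.002)
        assert res.p_value < 0.05 and res.stars != ""

    def test_all_equal_to_baseline_flagged(self):
        res = significance_vs_baseline([0.01] * 10, 0.01)
        assert res.p_value == 1.0 and res.all_ties

    def test_too_few_repetitions_rejected(self):
        with pytest.raises(ValueError, match="6"):
            significance_vs_baseline([0.1] * 5, 0.0)


class TestOverlap:
    def test_identical_sets(self):
        assert overlap_fraction({"a", "b"}, {"a", "b"}) == 1.0

    def test_disjoint_sets(self):
        assert overlap_fraction({"a"}, {"b"}) == 0.0

    def test_printed_formula_example(self):
        assert overlap_fraction({"a", "b", "c"}, {"b", "c", "d", "e"}) == pytest.approx(
            2 / 3
        )

    def test_symmetric(self):
        rng = np.random.default_rng(3)
        for _ in range(20):
            a = set(rng.integers(0, 30, size=rng.integers(1, 10)).tolist())
            b = set(rng.integers(0, 30, size=rng.integers(1, 10)).tolist())
            assert overlap_fraction(a, b) == overlap_fraction(b, a)

    def test_empty_set_undefined(self):
        assert np.isnan(overlap_fraction(set(), {"a"}))

    def test_expected_overlap_arithmetic(self):
        assert expected_overlap(10, 5, 2) == pytest.approx(1.0)
        assert expected_overlap(10, 0, 4) == 0.0

    def test_hypergeometric_simulation(self):
        # uniform random subset pairs match the nK/N mean
        N, ka, kb = 200, 40, 15
        rng = np.random.default_rng(4)
        draws = 4000
        inters = np.empty(draws)
        for i in range(draws):
            a = rng.choice(N, ka, replace=False)
            b = rng.choice(N, kb, replace=False)
            inters[i] = np.intersect1d(a, b).size
        se = inters.std(ddof=1) / np.sqrt(draws)
        assert abs(inters.mean() - expected_overlap(N, ka, kb)) < 3 * se

    def test_overlap_significance_relabelling_invariant(self):
        obs = [3, 4, 5, 2, 6, 4, 3, 5]
        exp = [2.0] * 8
        p1 = overlap_significance(obs, exp).p_value
        p2 = overlap_significance(obs, exp).p_value
        assert p1 == p2 and p1 < 0.05


class TestCharacterize:
    def test_identified_label_fractions(self, small_library):
        train = small_library.records[:40]
        # identify two molecules with labels 1 and 0
        pos = next(r for r in train if r.label == 1)
        neg = next(r for r in train if r.label == 0)
        out = characterize_identified({pos.smiles, neg.smiles}, train)
        assert out["identified_positive_fraction"] == pytest.approx(0.5)
        assert out["defined"]

    def test_minority_tpr_perfect_when_all_minority_identified(self, small_library):
        train = small_library.records[:40]
        labels = np.array([r.label for r in train])
        minority = 1 if labels.mean() < 0.5 else 0
        minority_keys = {r.smiles for r in train if r.label == minority}
        keys = [r.smiles for r in train] + ["non1", "non2"]
        truth = np.array([True] * len(train) + [False, False])
        # minority members score above everything else
        scores = np.array(
            [2.0 if r.label == minority else 0.5 for r in train] + [1.0, 0.9]
        )
        out = characterize_identified(
            minority_keys, train, scores=scores, truth=truth, keys=keys
        )
        assert out["minority_tpr"] == 1.0

    def test_uniform_random_identification_rarely_significant(self, small_library):
        train = small_library.records[:60]
        rng = np.random.default_rng(5)
        pvals = []
        for _ in range(40):
            picked = rng.choice(len(train), size=12, replace=False)
            identified = {train[i].smiles for i in picked}
            out = characterize_identified(identified, train)
            pvals.append(out["label_p_value"])
        # under the null, p-values should not concentrate below 0.05
        assert np.mean(np.array(pvals) < 0.05) < 0.3

    def test_empty_identified_flagged(self, small_library):
        out = characterize_identified(set(), small_library.records[:30])
        assert out["defined"] is False
        assert np.isnan(out["identified_positive_fraction"])

    def test_non_subset_rejected(self, small_library):
        with pytest.raises(ValueError, match="subset"):
            characterize_identified({"CCCCC#N"}, small_library.records[:5])


class TestSimilarityProfile:
    def test_duplicated_molecule_has_unit_nearest_neighbour(self, small_library):
        from molaudit.chem_data import MoleculeRecord

        base = small_library.records[:10]
        twin = [MoleculeRecord(base[0].smiles, base[0].label)]
        # a duplicate record of the first molecule drives its NN similarity to 1
        prof = similarity_profile(base + twin, identified=set())
        assert prof.nearest[0] == pytest.approx(1.0)
        assert prof.nearest[-1] == pytest.approx(1.0)

    def test_bin_edges_equal_width(self, small_library):
        prof = similarity_profile(small_library.records[:30], identified=set())
        assert np.allclose(prof.nearest_bin_edges, np.linspace(0, 1, 11))
        assert len(prof.mean_bin_edges) == 11

    def test_tanimoto_arithmetic(self):
        from molaudit.featurization import tanimoto

        a = np.zeros(8)
        b = np.zeros(8)
        a[[0, 1, 2]] = 1
        b[[2, 3]] = 1
        assert tanimoto(a, b) == pytest.approx(1 / 4)

    def test_identified_lower_similarity_detected(self, small_library):
        train = small_library.records[:60]
        prof0 = similarity_profile(train, identified=set())
        # identify the 8 molecules with the lowest nearest-neighbour similarity
        order = np.argsort(prof0.nearest)[:8]
        identified = {train[i].smiles for i in order}
        prof = similarity_profile(train, identified)
        assert prof.nearest_p_value < 0.05
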