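"""Query assembly, shadow ensembles, and the LiRA / RMIA scoring rules."""

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st
from scipy import stats

from molaudit.chem_data import split_dataset
from molaudit.mia_attacks import (
    AttackResult,
    RMIAConfig,
    assemble_query_set,
    decide,
    lira_log_ratio,
    lira_score_from_confidences,
    lira_scores,
    rescaled_confidence,
    rmia_score,
    rmia_scores,
    run_attacks,
    train_shadow_ensemble,
)
from molaudit.modeling import MLPHyperparams
from molaudit.synthetic_fixtures import generate_chemistry_free_library


@pytest.fixture(scope="module")
def cf_split():
    lib = generate_chemistry_free_library(240, dim=48, seed=3)
    return lib, split_dataset(lib.records, seed=1)


class TestQuerySet:
    def test_two_to_one_ratio(self, cf_split):
        lib, split = cf_split
        qs = assemble_query_set(split, seed=0)
        n = len(split.train)
        assert qs.n_members == n
        assert (~qs.truth).sum() == int(np.ceil(n / 2))
        assert qs.member_fraction == pytest.approx(2 / 3, abs=0.01)

    def test_members_disjoint_from_nonmembers(self, cf_split):
        _, split = cf_split
        qs = assemble_query_set(split, seed=0)
        members = {r.smiles for r, t in zip(qs.records, qs.truth) if t}
        nonmembers = {r.smiles for r, t in zip(qs.records, qs.truth) if not t}
        assert not members & nonmembers

    def test_z_disjoint_from_training(self, cf_split):
        _, split = cf_split
        qs = assemble_query_set(split, seed=0)
        train = {r.smiles for r in split.train}
        assert not train & {r.smiles for r in qs.z_records}

    def test_deterministic_under_seed(self, cf_split):
        _, split = cf_split
        a = assemble_query_set(split, seed=9)
        b = assemble_query_set(split, seed=9)
        assert [r.smiles for r in a.records] == [r.smiles for r in b.records]


@pytest.fixture(scope="module")
def small_ensemble(cf_split):
    lib, split = cf_split
    qs = assemble_query_set(split, seed=0)
    pool = list(split.train) + list(split.population)
    hp = MLPHyperparams(n_layers=1, hidden_dim=16, dropout=0.0)
    ens = train_shadow_ensemble(
        pool, lib.featurizer(pool), qs.records, hp, n_shadows=6, epochs=3, seed=4
    )
    return lib, split, qs, ens


class TestShadowEnsemble:
    def test_every_query_has_in_and_out_shadow(self, small_ensemble):
        _, _, qs, ens = small_ensemble
        mask = ens.membership_of(qs.records)
        assert mask.any(axis=0).all()
        assert (~mask).any(axis=0).all()

    def test_subset_fraction_is_half(self, small_ensemble):
        _, _, _, ens = small_ensemble
        per_shadow = ens.mask.sum(axis=1)
        assert np.all(np.abs(per_shadow - ens.mask.shape[1] * 0.5) <= 1)

    def test_in_counts_near_binomial_mean(self, small_ensemble):
        _, _, qs, ens = small_ensemble
        mask = ens.membership_of(qs.records)
        # each record IN ~ Binomial(6, 0.5); mean within 4 sigma of 3
        mean_in = mask.sum(axis=0).mean()
        sigma = np.sqrt(6 * 0.25 / mask.shape[1])
        assert abs(mean_in - 3.0) < 4 * sigma + 0.2

    def test_too_few_shadows_rejected(self, small_ensemble):
        lib, split, qs, _ = small_ensemble
        pool = list(split.train) + list(split.population)
        with pytest.raises(ValueError, match="at least two"):
            train_shadow_ensemble(
                pool, lib.featurizer(pool), qs.records, MLPHyperparams(), n_shadows=1
            )


class TestRescaledConfidence:
    def test_half_maps_to_zero(self):
        assert rescaled_confidence(0.5) == pytest.approx(0.0)

    def test_point_nine(self):
        assert rescaled_confidence(0.9) == pytest.approx(np.log(9), abs=1e-9)

    def test_clamped_at_one(self):
        eps = 1e-6
        assert rescaled_confidence(1.0) == pytest.approx(np.log((1 - eps) / eps))
        assert np.isfinite(rescaled_confidence(0.0))


class TestLiRA:
    def test_identical_distributions_score_zero(self):
        assert lira_log_ratio(1.7, 0.3, 1.0, 0.3, 1.0) == pytest.approx(0.0)

    def test_midpoint_symmetry(self):
        assert lira_log_ratio(0.0, 1.0, 1.0, -1.0, 1.0) == pytest.approx(0.0)

    def test_unit_shift_density_ratio(self):
        assert lira_log_ratio(1.0, 1.0, 1.0, -1.0, 1.0) == pytest.approx(2.0)

    def test_matches_scipy_normal_densities(self):
        rng = np.random.default_rng(0)
        for _ in range(20):
            c, mi, mo = rng.normal(size=3)
            si, so = rng.uniform(0.2, 2.0, size=2)
            expected = stats.norm.logpdf(c, mi, si) - stats.norm.logpdf(c, mo, so)
            assert lira_log_ratio(c, mi, si, mo, so) == pytest.approx(expected)

    def test_fit_from_samples(self):
        # samples engineered to have mean ±1 and unit population variance
        score0 = lira_score_from_confidences(0.0, [0.0, 2.0], [-2.0, 0.0])
        score1 = lira_score_from_confidences(1.0, [0.0, 2.0], [-2.0, 0.0])
        assert score0 == pytest.approx(0.0, abs=1e-9)
        assert score1 == pytest.approx(2.0, abs=1e-9)

    def test_missing_side_rejected(self):
        with pytest.raises(ValueError, match="IN and one OUT"):
            lira_score_from_confidences(0.0, [], [1.0])

    def test_variance_floor_applies(self):
        # all IN confidences identical: variance 0 floored at 1e-4
        s = lira_score_from_confidences(5.0, [5.0, 5.0], [0.0, 1.0])
        assert np.isfinite(s) and s > 0


class TestRMIA:
    def test_shadow_mean_is_pm(self):
        # P(m) = mean of shadow correct-class probabilities = 0.3;
        # target 0.6 -> ratio 2; single z with ratio 1 and gamma 2 -> score 1
        score = rmia_score(
            0.6,
            np.array([0.2, 0.4]),
            target_p_z=np.array([0.3]),
            shadow_p_z=np.array([[0.3], [0.3]]),
            cfg=RMIAConfig(gamma=2.0),
        )
        assert score == pytest.approx(1.0)

    def test_all_z_dominate_gives_zero(self):
        score = rmia_score(
            0.1,
            np.array([0.5, 0.5]),
            target_p_z=np.array([0.9, 0.8]),
            shadow_p_z=np.array([[0.5, 0.5], [0.5, 0.5]]),
        )
        assert score == 0.0

    def test_monotone_in_target_probability(self):
        rng = np.random.default_rng(1)
        shadow_p_m = rng.uniform(0.1, 0.9, size=(5, 1))
        z_t = rng.uniform(0.1, 0.9, 50)
        z_s = rng.uniform(0.1, 0.9, (5, 50))
        scores = [
            rmia_scores(np.array([p]), shadow_p_m, z_t, z_s)[0]
            for p in np.linspace(0.01, 0.99, 25)
        ]
        assert all(b >= a for a, b in zip(scores, scores[1:]))

    def test_empty_reference_rejected(self):
        with pytest.raises(ValueError, match="reference"):
            rmia_scores(
                np.array([0.5]), np.array([[0.5]]), np.array([]), np.zeros((1, 0))
            )


class TestDecide:
    def _result(self):
        return AttackResult(
            "LiRA",
            keys=["a", "b", "c"],
            scores=np.array([3.0, 2.0, 1.0]),
            truth=np.array([True, True, False]),
        )

    def test_infinite_thresholds(self):
        res = self._result()
        assert decide(res, np.inf) == set()
        assert decide(res, -np.inf) == {"a", "b", "c"}

    def test_max_nonmember_threshold_is_fpr0_set(self):
        res = self._result()
        t = res.scores[~res.truth].max()
        assert decide(res, t) == {"a", "b"}

    def test_csv_round_trip(self, tmp_path):
        res = self._result()
        path = tmp_path / "attack.csv"
        res.to_csv(path)
        back = AttackResult.from_csv(path)
        assert back.keys == res.keys
        assert np.allclose(back.scores, res.scores)
        assert np.array_equal(back.truth, res.truth)


class TestEnsembleReuse:
    def test_one_ensemble_serves_both_attacks_deterministically(self, small_ensemble):
        lib, split, qs, ens = small_ensemble
        import molaudit.modeling as mod

        target = mod.train_model(
            lib.featurizer(split.train),
            np.array([r.label for r in split.train]),
            None,
            None,
            MLPHyperparams(n_layers=1, hidden_dim=16, dropout=0.0),
            mod.TrainingConfig(max_epochs=3, seed=0, early_stopping=False),
        )
        r1 = run_attacks(target, ens, qs, lib.featurizer)
        r2 = run_attacks(target, ens, qs, lib.featurizer)
        for name in ("LiRA", "RMIA"):
            assert np.array_equal(r1[name].scores, r2[name].scores)
        assert r1["LiRA"].keys == r1["RMIA"].keys
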