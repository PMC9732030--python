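import numpy as np
import pytest
from helpers import pairwise_auc

import smmira
from smmira.data_io import AssociationData, RunConfig
from smmira.evaluation import (case_study, global_loocv, kfold_cv, kfold_partition,
                               local_loocv, make_oracle_scorer, random_control,
                               random_scorer, rank_auc)


@pytest.fixture
def cfg():
    return RunConfig(seed=0, cv_seed=0)


class TestRankAuc:
    def test_perfect_separation(self):
        assert rank_auc([0.9, 0.8], [0.1, 0.2]) == 1.0

    def test_perfect_inversion(self):
        assert rank_auc([0.1], [0.9]) == 0.0

    def test_pure_ties_give_half(self):
        assert rank_auc([0.5, 0.5], [0.5, 0.5, 0.5]) == 0.5

    def test_empty_lists_rejected(self):
        with pytest.raises(ValueError):
            rank_auc([], [0.1])

    @pytest.mark.parametrize("seed", range(4))
    def test_matches_pairwise_oracle(self, seed):
        rng = np.random.default_rng(seed)
        t = np.round(rng.random(30), 2)  # rounding forces some ties
        c = np.round(rng.random(300), 2)
        assert rank_auc(t, c) == pytest.approx(pairwise_auc(t, c), abs=1e-12)


@pytest.fixture
def small_data():
    rng = np.random.default_rng(12)
    A = (rng.random((6, 15)) < 0.25).astype(float)
    A[0, 0] = 1  # ensure at least 2 associations
    A[1, 1] = 1
    return AssociationData([f"s{i}" for i in range(6)],
                           [f"m{j}" for j in range(15)], A)


@pytest.fixture
def small_sims(small_data):
    SSM = smmira.SimilarityMatrix(np.eye(small_data.n_sm), small_data.sm_ids)
    SMR = smmira.SimilarityMatrix(np.eye(small_data.n_mirna), small_data.mirna_ids)
    return SSM, SMR


class TestGlobalLoocv:
    def test_oracle_scorer_achieves_perfect_auc(self, small_data, small_sims, cfg):
        res = global_loocv(small_data, *small_sims, cfg,
                           scorer=make_oracle_scorer(small_data))
        assert res.auc_mean == 1.0
        assert res.n_test_samples == small_data.n_associations

    def test_inverted_oracle_achieves_zero(self, small_data, small_sims, cfg):
        res = global_loocv(small_data, *small_sims, cfg,
                           scorer=make_oracle_scorer(small_data, invert=True))
        assert res.auc_mean == 0.0

    def test_one_retraining_per_known_pair(self, small_data, small_sims, cfg):
        calls = []

        def counting_scorer(train, SSM, SMR, cfg, rng=None):
            calls.append(train.A.sum())
            return np.random.default_rng(0).random(train.A.shape)

        global_loocv(small_data, *small_sims, cfg, scorer=counting_scorer)
        n = small_data.n_associations
        assert len(calls) == n
        assert all(c == n - 1 for c in calls)  # exactly one pair zeroed each time

    def test_random_scorer_near_half_over_replicates(self, small_data, small_sims, cfg):
        rng = np.random.default_rng(99)
        aucs = [global_loocv(small_data, *small_sims, cfg,
                             scorer=random_scorer, rng=rng).auc_mean
                for _ in range(40)]
        assert np.mean(aucs) == pytest.approx(0.5, abs=0.03)


class TestLocalLoocv:
    def test_candidate_sets_are_restricted(self):
        data = AssociationData(["s1", "s2"], ["m1", "m2"],
                               np.array([[1.0, 0.0], [0.0, 1.0]]))
        seen = []

        def recording_scorer(train, SSM, SMR, cfg, rng=None):
            seen.append(train.A.copy())
            return np.arange(4.0).reshape(2, 2)

        SSM = smmira.SimilarityMatrix(np.eye(2), ["s1", "s2"])
        SMR = smmira.SimilarityMatrix(np.eye(2), ["m1", "m2"])
        res = local_loocv(data, SSM, SMR, RunConfig(), "mirna_fixed",
                          scorer=recording_scorer)
        # for held-out (s1,m1) the only candidate sharing m1 is (s2,m1)
        assert res.n_test_samples == 2 and res.n_skipped == 0

    @pytest.mark.parametrize("mode", ["mirna_fixed", "sm_fixed"])
    def test_oracle_scorer_perfect_in_both_modes(self, small_data, small_sims, cfg, mode):
        res = local_loocv(small_data, *small_sims, cfg, mode,
                          scorer=make_oracle_scorer(small_data))
        assert res.auc_mean == 1.0

    @pytest.mark.parametrize("mode", ["mirna_fixed", "sm_fixed"])
    def test_random_scorer_near_half(self, small_sims, cfg, mode):
        rng = np.random.default_rng(5)
        data = AssociationData([f"s{i}" for i in range(6)],
                               [f"m{j}" for j in range(15)],
                               (np.random.default_rng(3).random((6, 15)) < 0.3).astype(float))
        SSM = smmira.SimilarityMatrix(np.eye(6), data.sm_ids)
        SMR = smmira.SimilarityMatrix(np.eye(15), data.mirna_ids)
        aucs = [local_loocv(data, SSM, SMR, cfg, mode,
                            scorer=random_scorer, rng=rng).auc_mean
                for _ in range(60)]
        assert np.mean(aucs) == pytest.approx(0.5, abs=0.04)

    def test_unknown_mode_rejected(self, small_data, small_sims, cfg):
        with pytest.raises(ValueError, match="mode"):
            local_loocv(small_data, *small_sims, cfg, "disease_fixed")


class TestKfold:
    def test_fold_sizes_differ_by_at_most_one(self):
        rng = np.random.default_rng(0)
        for n in (10, 11, 13):
            sizes = [len(f) for f in kfold_partition(n, 5, rng)]
            assert sum(sizes) == n and max(sizes) - min(sizes) <= 1

    def test_every_pair_tested_exactly_once_per_repeat(self):
        folds = kfold_partition(23, 5, np.random.default_rng(1))
        seen = np.concatenate(folds)
        assert sorted(seen) == list(range(23))

    def test_same_seed_gives_identical_partitions_and_aucs(self, small_data, small_sims, cfg):
        def det_scorer(train, SSM, SMR, cfg, rng=None):
            return np.random.default_rng(7).random(train.A.shape)

        r1 = kfold_cv(small_data, *small_sims, cfg, k=5, seed=3, scorer=det_scorer)
        r2 = kfold_cv(small_data, *small_sims, cfg, k=5, seed=3, scorer=det_scorer)
        assert r1.per_repeat_aucs == r2.per_repeat_aucs

    def test_oracle_scorer_perfect(self, small_data, small_sims, cfg):
        res = kfold_cv(small_data, *small_sims, cfg, k=5, seed=0,
                       scorer=make_oracle_scorer(small_data))
        assert res.auc_mean == 1.0 and len(res.per_repeat_aucs) == 5

    def test_repeats_multiply_fold_count(self, small_data, small_sims, cfg):
        res = kfold_cv(small_data, *small_sims, cfg, k=3, repeats=2, seed=0,
                       scorer=make_oracle_scorer(small_data))
        assert len(res.per_repeat_aucs) == 6

    def test_too_many_folds_rejected(self, small_sims, cfg):
        data = AssociationData(["s1", "s2"], ["m1", "m2"],
                               np.array([[1.0, 0.0], [0.0, 1.0]]))
        SSM = smmira.SimilarityMatrix(np.eye(2), data.sm_ids)
        SMR = smmira.SimilarityMatrix(np.eye(2), data.mirna_ids)
        with pytest.raises(ValueError):
            kfold_cv(data, SSM, SMR, cfg, k=5, seed=0,
                     scorer=make_oracle_scorer(data))


class TestCaseStudy:
    def _deg_scorer(self, train, SSM, SMR, cfg, rng=None):
        rng = np.random.default_rng(1)
        return rng.random(train.A.shape)

    def test_mode2_removes_all_known_associations_of_the_sm(self, small_data, small_sims, cfg):
        i = int(np.argmax(small_data.A.sum(axis=1)))
        sm_id = small_data.sm_ids[i]
        seen = {}

        def recording_scorer(train, SSM, SMR, cfg, rng=None):
            seen["ones"] = train.n_associations
            return self._deg_scorer(train, SSM, SMR, cfg)

        case_study(small_data, *small_sims, cfg, sm_id, mode=2,
                   scorer=recording_scorer)
        removed = int(small_data.A[i].sum())
        assert seen["ones"] == small_data.n_associations - removed

    def test_mode1_excludes_known_mirnas_from_candidates(self, small_data, small_sims, cfg):
        i = int(np.argmax(small_data.A.sum(axis=1)))
        sm_id = small_data.sm_ids[i]
        ranking = case_study(small_data, *small_sims, cfg, sm_id, mode=1,
                             top_n=small_data.n_mirna, scorer=self._deg_scorer)
        known = {small_data.mirna_ids[j] for j in np.nonzero(small_data.A[i])[0]}
        assert known.isdisjoint(set(ranking["mirna_id"]))
        assert len(ranking) == small_data.n_mirna - len(known)

    def test_top_n_truncation(self, small_data, small_sims, cfg):
        sm_id = small_data.sm_ids[0]
        ranking = case_study(small_data, *small_sims, cfg, sm_id, mode=1,
                             top_n=5, scorer=self._deg_scorer)
        assert len(ranking) == 5
        assert list(ranking["rank"]) == [1, 2, 3, 4, 5]

    def test_unknown_sm_rejected(self, small_data, small_sims, cfg):
        with pytest.raises(ValueError, match="sX"):
            case_study(small_data, *small_sims, cfg, "sX")


class TestRandomControl:
    def _scorer(self, train, SSM, SMR, cfg, rng=None):
        return np.random.default_rng(4).random(train.A.shape)

    def test_exhaustive_sample_returns_every_unknown_pair(self, small_data, small_sims, cfg):
        n_unknown = int((small_data.A == 0).sum())
        out = random_control(small_data, *small_sims, cfg, n_unknown, seed=1,
                             scorer=self._scorer)
        assert len(out) == n_unknown
        assert not out.duplicated(["sm_id", "mirna_id"]).any()

    def test_same_seed_same_sample(self, small_data, small_sims, cfg):
        a = random_control(small_data, *small_sims, cfg, 10, seed=2, scorer=self._scorer)
        b = random_control(small_data, *small_sims, cfg, 10, seed=2, scorer=self._scorer)
        assert a.equals(b)

    def test_oversized_request_rejected(self, small_data, small_sims, cfg):
        with pytest.raises(ValueError):
            random_control(small_data, *small_sims, cfg, 10_000, seed=0,
                           scorer=self._scorer)

    def test_mean_rank_near_median_under_random_scores(self, small_data, small_sims, cfg):
        n_unknown = int((small_data.A == 0).sum())
        ranks = []
        for s in range(200):
            def scorer(train, SSM, SMR, cfg, rng=None, s=s):
                return np.random.default_rng(1000 + s).random(train.A.shape)
            out = random_control(small_data, *small_sims, cfg, 5, seed=s, scorer=scorer)
            ranks.extend(out["global_rank"])
        assert np.mean(ranks) == pytest.approx((n_unknown + 1) / 2, rel=0.05)
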