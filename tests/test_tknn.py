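import numpy as np
import pytest

from channelpat import cv_predict, enumerate_configs, greedy_final, imv, run_tknn
from channelpat.tknn import KnnConfig, PredictionEnsemble, assign_folds


class TestEnumeration:
    def test_sixty_distinct_configs(self):
        configs = enumerate_configs()
        assert len(configs) == 60
        assert len(set(configs)) == 60

    def test_documented_order(self):
        configs = enumerate_configs()
        assert configs[0] == KnnConfig(k=1, distance="L1", weight="equal")
        assert configs[1] == KnnConfig(k=1, distance="L1", weight="inverse")
        assert configs[-1] == KnnConfig(k=10, distance="L2", weight="squared_inverse")

    def test_invalid_config_rejected(self):
        with pytest.raises(ValueError):
            KnnConfig(k=0, distance="L1", weight="equal")
        with pytest.raises(ValueError):
            KnnConfig(k=1, distance="L3", weight="equal")


def two_clusters(rng, n_per=20, spread=0.1):
    X = np.vstack(
        [rng.normal(0, spread, size=(n_per, 2)), rng.normal(5, spread, size=(n_per, 2))]
    )
    y = np.array(["A"] * n_per + ["B"] * n_per)
    return X, y


class TestCvPredict:
    def test_separable_data_is_perfect(self, rng):
        X, y = two_clusters(rng)
        folds = assign_folds(y, n_folds=5, seed=0)
        for cfg in enumerate_configs()[::7]:
            _, acc = cv_predict(X, y, cfg, folds)
            assert acc == 1.0

    def test_zero_distance_duplicate_dominates(self):
        # two exact copies of one point with label A among B-heavy data:
        # inverse weighting must give the duplicate's label at any k
        X = np.array([[0.0], [0.0], [1.0], [1.1], [1.2], [1.3]])
        y = np.array(["A", "A", "B", "B", "B", "B"])
        folds = np.array([0, 1, 0, 1, 0, 1])
        for weight in ("inverse", "squared_inverse"):
            cfg = KnnConfig(k=3, distance="L2", weight=weight)
            pred, _ = cv_predict(X, y, cfg, folds, standardize=False)
            assert pred[0] == "A" and pred[1] == "A"

    def test_matches_brute_force_neighbors(self, rng):
        """Small 2-feature sets, k=3, L1, equal weights: predictions equal
        the majority label of the 3 nearest training points, brute-forced.
        Continuous coordinates keep all pairwise distances distinct."""
        cfg = KnnConfig(k=3, distance="L1", weight="equal")
        y = np.array(["A", "A", "B", "B", "A", "B", "B", "A"])
        folds = np.array([0, 1] * 4)  # both classes present in each half
        for _ in range(20):
            X = rng.normal(size=(8, 2))
            pred, _ = cv_predict(X, y, cfg, folds, standardize=False)
            for i in range(8):
                train = folds != folds[i]
                d = np.abs(X[train] - X[i]).sum(axis=1)
                nearest = np.argsort(d)[:3]
                labs, cnt = np.unique(y[train][nearest], return_counts=True)
                assert pred[i] == labs[np.argmax(cnt)]

    def test_fold_missing_class_rejected(self, rng):
        X, y = two_clusters(rng, n_per=3)
        folds = np.where(y == "A", 0, 1)  # each training split loses a class
        with pytest.raises(ValueError, match="missing a class"):
            cv_predict(X, y, KnnConfig(k=1, distance="L2", weight="equal"), folds)


class TestImv:
    def test_hand_checked_mode(self):
        preds = np.array([[1, 1, 2], [1, 2, 2], [2, 1, 2]])
        voted, _, _ = imv(preds, np.array([0.9, 0.8, 0.7]))
        np.testing.assert_array_equal(voted[0], [1, 1, 2])

    def test_unanimity(self):
        preds = np.tile(np.array([0, 1, 1, 0]), (60, 1))
        voted, vacc, _ = imv(preds, np.linspace(0.9, 0.3, 60), y=np.array([0, 1, 1, 0]))
        assert voted.shape == (58, 4)
        assert (voted == preds[0]).all()
        assert (vacc == 1.0).all()

    def test_tie_breaks_toward_most_accurate(self):
        # q=4 with a 2-2 split: winner is the label of the top-accuracy row
        preds = np.array([[2], [1], [2], [1], [1]])
        accs = np.array([0.9, 0.8, 0.7, 0.6, 0.5])
        voted, _, _ = imv(preds, accs)
        assert voted[1][0] == 2  # q=4: {2,1,2,1} tie -> row of acc 0.9 says 2

    def test_needs_three_outcomes(self):
        with pytest.raises(ValueError):
            imv(np.array([[1], [2]]), np.array([0.5, 0.5]))

    def test_q60_vote_is_order_free(self, rng):
        n = 30
        preds = rng.integers(0, 2, size=(60, n))
        accs = rng.uniform(0.4, 0.9, size=60)
        voted_a, _, _ = imv(preds, accs)
        perm = rng.permutation(60)
        voted_b, _, _ = imv(preds[perm], accs[perm])
        counts = np.stack([(preds == v).sum(0) for v in (0, 1)])
        clear = counts.max(0) > 30  # strict majority of all 60
        np.testing.assert_array_equal(voted_a[-1][clear], voted_b[-1][clear])


class TestGreedy:
    def _ensemble(self, rng, y):
        n = len(y)
        preds = rng.integers(0, 2, size=(60, n))
        accs = (preds == y[None, :]).mean(axis=1)
        voted, vacc, order = imv(preds, accs, y)
        return PredictionEnsemble(
            configs=enumerate_configs(),
            classifier_preds=preds,
            classifier_accs=accs,
            voted_preds=voted,
            voted_accs=vacc,
            sort_order=order,
        )

    def test_pools_118_outcomes_and_takes_max(self, rng):
        y = rng.integers(0, 2, size=25)
        ens = self._ensemble(rng, y)
        assert ens.n_outcomes == 118
        res = greedy_final(ens)
        pooled = np.concatenate([ens.classifier_accs, ens.voted_accs])
        assert res.final_accuracy == pooled.max()

    def test_perfect_outcome_selected(self, rng):
        y = rng.integers(0, 2, size=25)
        ens = self._ensemble(rng, y)
        ens.classifier_preds[17] = y
        ens.classifier_accs[17] = 1.0
        res = greedy_final(ens)
        assert res.source == "classifier" and res.source_index == 17
        np.testing.assert_array_equal(res.final_labels, y)

    def test_tie_prefers_earlier_classifier(self, rng):
        y = rng.integers(0, 2, size=25)
        ens = self._ensemble(rng, y)
        ens.classifier_preds[:] = y  # every outcome perfect
        ens.classifier_accs[:] = 1.0
        ens.voted_accs[:] = 1.0
        res = greedy_final(ens)
        assert res.source == "classifier" and res.source_index == 0


class TestRunTknn:
    def test_final_dominates_every_classifier(self, rng):
        X, y = two_clusters(rng, n_per=15, spread=2.0)  # overlapping clusters
        ens, res = run_tknn(X, y, seed=0, n_folds=5)
        assert res.final_accuracy >= ens.classifier_accs.max()
        assert res.final_accuracy >= ens.voted_accs.max()
        assert ens.n_outcomes == 118
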