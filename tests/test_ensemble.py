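import itertools

import numpy as np
import pytest

from ewnn.data import Dataset
from ewnn.ensemble import (ClassifierPool, EmptyEnsembleError, EnsembleMask,
                           PruneConfig, active_count, enumerate_best_fitness,
                           ensemble_predictions, ensemble_vote, majority_vote,
                           prune, prune_fitness)
from ewnn.evolve import derive_seed
from ewnn.genome import init_genome

from conftest import build_genome, build_wavelon


def threshold_genome(weight, bias, n_features=1):
    """Linear one-feature classifier: predicts 1 iff weight*x + bias >= 0.5."""
    wv = build_wavelon([0], [1], active=0)
    shortcut = np.zeros(n_features)
    shortcut[0] = weight
    return build_genome([wv], n_features=n_features, shortcut=shortcut,
                        bias=bias)


class TestMajorityVote:
    def test_strict_majority_wins(self):
        assert majority_vote([1, 1, 0]) == 1

    def test_even_split_goes_to_zero(self):
        assert majority_vote([1, 0, 0, 1]) == 0

    def test_single_voter(self):
        assert majority_vote([1]) == 1
        assert majority_vote([0]) == 0

    def test_empty_votes_rejected(self):
        with pytest.raises(EmptyEnsembleError):
            majority_vote([])

    def test_exhaustive_against_brute_count(self):
        for k in range(1, 7):
            for votes in itertools.product([0, 1], repeat=k):
                brute = 1 if sum(votes) > k - sum(votes) else 0
                # ties (sum == k/2) must fall to 0 under the strict rule
                if 2 * sum(votes) == k:
                    brute = 0
                assert majority_vote(list(votes)) == brute


class TestEnsembleVote:
    def test_votes_only_active_members(self):
        # classifiers: predict 1 iff x >= 0.5 / always 1 / always 0
        pool = ClassifierPool([threshold_genome(1.0, 0.0),
                               threshold_genome(0.0, 1.0),
                               threshold_genome(0.0, 0.0)])
        x = np.array([0.7])
        assert ensemble_vote(pool, EnsembleMask([1, 1, 1]), x) == 1
        assert ensemble_vote(pool, EnsembleMask([0, 0, 1]), x) == 0
        assert ensemble_vote(pool, EnsembleMask([1, 0, 1]), x) == 0  # tie

    def test_empty_mask_is_error(self):
        pool = ClassifierPool([threshold_genome(1.0, 0.0)])
        with pytest.raises(EmptyEnsembleError, match="empty ensemble"):
            ensemble_vote(pool, EnsembleMask([0]), np.array([1.0]))


class TestPruneFitness:
    def test_hand_computed_value(self):
        # U: x = (0, 0.4, 0.6, 1), labels (0, 0, 1, 1)
        U = Dataset(np.array([[0.0], [0.4], [0.6], [1.0]]),
                    np.array([0, 0, 1, 1]))
        pool = ClassifierPool([
            threshold_genome(1.0, 0.0),   # predicts (0,0,1,1): acc 1.0
            threshold_genome(0.0, 1.0),   # predicts (1,1,1,1): acc 0.5
            threshold_genome(0.0, 0.0),   # predicts (0,0,0,0): acc 0.5
        ])
        # mask 110: Tr_acc = (1.0+0.5)/2 = 0.75; votes (even k) give
        # (0,0,1,1) -> Ens(U) = 1.0 ... wait: votes per record are
        # (1+0, 1+0, 1+1, 1+1)/2 -> strict majority -> (0,0,1,1), acc 1.0
        f = prune_fitness(EnsembleMask([1, 1, 0]), pool, U)
        assert f == pytest.approx(0.5 * (0.75 + 1.0))

    def test_arithmetic_of_the_average(self):
        U = Dataset(np.array([[0.0], [1.0]]), np.array([0, 1]))
        pool = ClassifierPool([threshold_genome(1.0, 0.0)])
        assert prune_fitness(EnsembleMask([1]), pool, U) == pytest.approx(1.0)

    def test_empty_mask_scores_zero(self):
        U = Dataset(np.array([[0.0]]), np.array([0]))
        pool = ClassifierPool([threshold_genome(1.0, 0.0)])
        assert prune_fitness(EnsembleMask([0]), pool, U) == 0.0

    def test_bounded_in_unit_interval(self, rng):
        U = Dataset(rng.normal(size=(20, 2)), rng.integers(0, 2, 20))
        pool = ClassifierPool([init_genome(2, 2, rng=rng) for _ in range(6)])
        for _ in range(30):
            bits = rng.integers(0, 2, 6)
            if bits.sum() == 0:
                continue
            f = prune_fitness(EnsembleMask(bits), pool, U)
            assert 0.0 <= f <= 1.0


class TestActiveCount:
    def test_examples(self):
        assert active_count(EnsembleMask([1, 1, 1, 0, 0, 0])) == 3
        assert active_count(EnsembleMask([0, 0])) == 0

    def test_against_popcount_oracle(self, rng):
        for _ in range(20):
            bits = rng.integers(0, 2, 12)
            oracle = sum(1 for b in bits if b == 1)  # bit-loop oracle
            assert active_count(EnsembleMask(bits)) == oracle


def random_pool_and_data(seed, pool_size=6, n_records=25):
    rng = np.random.default_rng(seed)
    U = Dataset(rng.normal(size=(n_records, 3)), rng.integers(0, 2, n_records))
    pool = ClassifierPool([init_genome(3, 2, rng=rng) for _ in range(pool_size)])
    return pool, U


class TestPrune:
    def test_ga_matches_enumeration_on_small_pool(self):
        pool, U = random_pool_and_data(17)
        oracle, _ = enumerate_best_fitness(pool, U)
        best = 0.0
        for r in range(2):
            cfg = PruneConfig(generations=300, seed=derive_seed(88, r))
            best = max(best, prune(pool, U, U, cfg).fitness)
        assert best == pytest.approx(oracle, abs=1e-12)

    def test_trajectory_nondecreasing_and_deterministic(self):
        pool, U = random_pool_and_data(23)
        cfg = PruneConfig(generations=100, seed=7)
        a = prune(pool, U, U, cfg)
        b = prune(pool, U, U, cfg)
        traj = a.fitness_trajectory
        assert all(y >= x for x, y in zip(traj, traj[1:]))
        np.testing.assert_array_equal(a.mask.bits, b.mask.bits)

    def test_equal_fitness_prefers_smaller_ensemble(self):
        # three identical perfect classifiers: every nonempty mask has
        # fitness 1.0, so the tie-break must pick a single classifier
        U = Dataset(np.array([[0.0], [1.0]]), np.array([0, 1]))
        pool = ClassifierPool([threshold_genome(1.0, 0.0)] * 3)
        oracle_f, oracle_mask = enumerate_best_fitness(pool, U)
        assert oracle_f == pytest.approx(1.0)
        assert active_count(oracle_mask) == 1
        res = prune(pool, U, U, PruneConfig(generations=150, seed=2))
        assert res.fitness == pytest.approx(1.0)
        assert active_count(res.mask) == 1

    def test_test_set_read_exactly_once(self):
        pool, U = random_pool_and_data(31)

        class AccessCounter:
            def __init__(self, data):
                self._data = data
                self.feature_reads = 0

            def __len__(self):
                return len(self._data)

            @property
            def features(self):
                self.feature_reads += 1
                return self._data.features

            @property
            def labels(self):
                return self._data.labels

        V = AccessCounter(U)
        prune(pool, U, V, PruneConfig(generations=60, seed=3))
        assert V.feature_reads == 1

    def test_swap_mutation_variant_runs(self):
        pool, U = random_pool_and_data(41)
        res = prune(pool, U, U, PruneConfig(generations=50, seed=5,
                                            mutation="swap"))
        assert 0.0 <= res.fitness <= 1.0
        assert len(res.mask) == len(pool)

    def test_reports_test_metrics_of_best_mask(self):
        U = Dataset(np.array([[0.0], [0.4], [0.6], [1.0]]),
                    np.array([0, 0, 1, 1]))
        pool = ClassifierPool([threshold_genome(1.0, 0.0)])
        res = prune(pool, U, U, PruneConfig(generations=10, seed=1))
        assert res.ete_acc == 1.0
        assert res.sensitivity == 1.0
        assert res.specificity == 1.0
        assert res.mcc == pytest.approx(1.0)


def test_ensemble_predictions_matches_per_sample_vote(rng):
    pool, U = random_pool_and_data(53, pool_size=5, n_records=10)
    bits = np.array([1, 0, 1, 1, 0])
    batch = ensemble_predictions(pool.predictions(U.features), bits)
    single = [ensemble_vote(pool, EnsembleMask(bits), x) for x in U.features]
    np.testing.assert_array_equal(batch, single)
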