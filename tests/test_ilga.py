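import numpy as np
import pytest
from scipy import stats
from sklearn.metrics import adjusted_rand_score, calinski_harabasz_score

from methylga.ilga import (ClusterPartition, IlgaConfig, PartitionScorer,
                           _mpx_child, ch_fitness, compute_alpha,
                           compute_gamma, init_partition, mpx_crossover,
                           roulette_select, run_ilga, split_merge_mutation)


def assert_valid_partition(p, n):
    assert np.array_equal(np.sort(p.arrangement), np.arange(n))
    sizes = p.cluster_sizes()
    assert (sizes > 0).all()
    assert sizes.sum() == n
    if p.boundaries.size:
        assert (np.diff(p.boundaries) > 0).all()


def random_partition(n, rng):
    return init_partition(n, rng)


def centroid_gamma_oracle(partition, X):
    """Within-cluster SSD via cluster centroids (independent of the
    pairwise-distance implementation)."""
    total = 0.0
    for members in partition.clusters():
        centroid = X[members].mean(axis=0)
        total += ((X[members] - centroid) ** 2).sum()
    return total


class TestClusterPartition:
    def test_permutation_enforced(self):
        with pytest.raises(ValueError, match="permutation"):
            ClusterPartition(np.array([0, 0, 1]), np.array([1]))

    def test_boundary_order_enforced(self):
        with pytest.raises(ValueError, match="increasing"):
            ClusterPartition(np.arange(4), np.array([2, 2]))

    def test_labels_inverse_of_clusters(self, rng):
        p = random_partition(12, rng)
        labels = p.labels()
        for h, members in enumerate(p.clusters()):
            assert (labels[members] == h).all()

    def test_serialization(self, tmp_path):
        p = ClusterPartition(np.array([2, 0, 1]), np.array([2]))
        path = tmp_path / "part.tsv"
        p.write(path, sample_ids=["a", "b", "c"])
        assert path.read_text() == "c\ta\nb\n"


class TestInitPartition:
    def test_two_samples_two_singletons(self, rng):
        p = init_partition(2, rng)
        assert p.n_clusters == 2 and all(c.size == 1 for c in p.clusters())

    def test_too_few_samples(self, rng):
        with pytest.raises(ValueError):
            init_partition(1, rng)

    def test_invariants_over_draws(self, rng):
        for _ in range(200):
            assert_valid_partition(init_partition(17, rng), 17)

    def test_cluster_count_range_covered(self, rng):
        # n=16 -> counts drawn uniformly from 2..4
        counts = {init_partition(16, rng).n_clusters for _ in range(10_000)}
        assert counts == {2, 3, 4}


class TestDispersionTerms:
    def test_single_cluster_alpha_zero(self, rng):
        X = rng.random((8, 3))
        p = ClusterPartition(np.arange(8), np.array([], dtype=int))
        assert compute_alpha(p, X) == pytest.approx(0.0, abs=1e-12)

    def test_two_singletons_1d(self):
        X = np.array([[0.0], [2.0]])
        p = ClusterPartition(np.array([0, 1]), np.array([1]))
        # centroid 1: each singleton contributes 1^2 * 1
        assert compute_alpha(p, X) == pytest.approx(2.0)
        assert compute_gamma(p, X) == pytest.approx(0.0)

    def test_pairwise_gamma_hand_value(self):
        X = np.array([[0.0], [2.0]])
        p = ClusterPartition(np.array([0, 1]), np.array([], dtype=int))
        # (1/(2*2)) * (0+4+4+0) = 2, equal to centroid form 1+1
        assert compute_gamma(p, X) == pytest.approx(2.0)

    def test_duplicating_samples_doubles_alpha(self, rng):
        X = rng.random((6, 4))
        p = random_partition(6, rng)
        doubled = np.vstack([X, X])
        # same grouping with every member duplicated
        members2 = [np.concatenate([c, c + 6]) for c in p.clusters()]
        arrangement = np.concatenate(members2)
        boundaries = np.cumsum([m.size for m in members2])[:-1]
        p2 = ClusterPartition(arrangement, boundaries)
        assert compute_alpha(p2, doubled) == pytest.approx(2 * compute_alpha(p, X))

    @pytest.mark.parametrize("trial", range(10))
    def test_gamma_equals_centroid_oracle(self, trial):
        rng = np.random.default_rng(100 + trial)
        n = int(rng.integers(4, 31))
        X = rng.random((n, int(rng.integers(2, 8))))
        p = random_partition(n, rng)
        assert compute_gamma(p, X) == pytest.approx(
            centroid_gamma_oracle(p, X), abs=1e-9)

    def test_total_variance_decomposition(self, rng):
        # alpha + gamma = total SSD about the global centroid
        X = rng.random((15, 6))
        total = ((X - X.mean(axis=0)) ** 2).sum()
        for _ in range(10):
            p = random_partition(15, rng)
            assert compute_alpha(p, X) + compute_gamma(p, X) == \
                pytest.approx(total, rel=1e-9)


class TestChFitness:
    def test_matches_reference_calinski_harabasz(self):
        for trial in range(10):
            rng = np.random.default_rng(trial)
            n = int(rng.integers(6, 25))
            X = rng.random((n, 4))
            p = random_partition(n, rng)
            rec = ch_fitness(p, X)
            if rec.degenerate:
                continue
            assert rec.f_ch == pytest.approx(
                calinski_harabasz_score(X, p.labels()), rel=1e-9)

    def test_normalization_factor(self, rng):
        X = rng.random((4, 3))
        p = ClusterPartition(np.arange(4), np.array([2]))
        rec = ch_fitness(p, X)
        # (n - k)/(k - 1) = (4-2)/(2-1) = 2
        assert rec.f_ch == pytest.approx(2.0 * rec.alpha_c / rec.gamma_c)

    def test_true_clusters_beat_random_split(self):
        rng = np.random.default_rng(0)
        X = np.vstack([rng.normal(0.0, 0.05, (10, 4)),
                       rng.normal(1.0, 0.05, (10, 4))])
        truth = ClusterPartition(np.arange(20), np.array([10]))
        shuffled = rng.permutation(20)
        rand = ClusterPartition(shuffled, np.array([10]))
        assert ch_fitness(truth, X).f_ch > ch_fitness(rand, X).f_ch

    def test_all_singletons_degenerate(self, rng):
        X = rng.random((5, 2))
        p = ClusterPartition(np.arange(5), np.arange(1, 5))
        rec = ch_fitness(p, X)
        assert rec.degenerate and rec.gamma_c == 0.0

    def test_scorer_equals_literal_fitness(self, rng):
        X = rng.random((20, 7))
        scorer = PartitionScorer(X)
        for _ in range(25):
            p = random_partition(20, rng)
            a, b = scorer.score(p), ch_fitness(p, X)
            assert a.f_ch == pytest.approx(b.f_ch, rel=1e-9)
            assert a.gamma_c == pytest.approx(b.gamma_c, abs=1e-9)

    def test_canonicalize_preserves_grouping_and_fitness(self, rng):
        X = rng.random((18, 5))
        scorer = PartitionScorer(X)
        for _ in range(20):
            p = random_partition(18, rng)
            c = scorer.canonicalize(p)
            assert_valid_partition(c, 18)
            group = lambda q: sorted(sorted(m.tolist()) for m in q.clusters())
            assert group(c) == group(p)
            assert scorer.score(c).f_ch == pytest.approx(scorer.score(p).f_ch,
                                                         rel=1e-12)


class TestMpxCrossover:
    def _fig3_parents(self):
        # items 1..10 mapped to indices 0..9; parent1 clusters
        # [1,10][9,4,2][3,5,7,8,6]; the middle cluster sits at the data
        # centroid, so it is the transplant target
        p1 = ClusterPartition(np.array([0, 9, 8, 3, 1, 2, 4, 6, 7, 5]),
                              np.array([2, 5]))
        p2 = ClusterPartition(np.array([8, 3, 1, 0, 9, 2, 4, 6, 7, 5]),
                              np.array([5]))
        X = np.zeros((10, 1))
        X[[8, 3, 1]] = 0.5
        X[[2, 4, 6, 7, 5]] = 1.0
        return p1, p2, X

    def test_worked_example_prefix(self):
        p1, p2, X = self._fig3_parents()
        scorer = PartitionScorer(X)
        assert scorer.nearest_cluster_to_centre(p1) == 1
        rng = np.random.default_rng(2)  # draws substring size 3, cut 0
        child = _mpx_child(p1, p2, scorer, rng)
        # remainder [1,10,3,5,7,8,6] then 9,4,2 in parent2's relative order
        assert child.arrangement.tolist() == [0, 9, 2, 4, 6, 7, 5, 8, 3, 1]
        assert (child.arrangement[:7] + 1).tolist() == [1, 10, 3, 5, 7, 8, 6]

    def test_identical_parents_yield_permutation(self, rng):
        X = rng.random((8, 2))
        p = random_partition(8, rng)
        child = mpx_crossover(p, p.copy(), X, rng)
        assert_valid_partition(child, 8)

    def test_offspring_invariants_over_many_pairs(self):
        rng = np.random.default_rng(1)
        X = rng.random((12, 3))
        scorer = PartitionScorer(X)
        for _ in range(500):
            a, b = random_partition(12, rng), random_partition(12, rng)
            child = mpx_crossover(a, b, scorer, rng)
            assert_valid_partition(child, 12)

    def test_mismatched_parents_error(self, rng):
        with pytest.raises(ValueError, match="same sample set"):
            mpx_crossover(random_partition(5, rng), random_partition(6, rng),
                          np.random.default_rng(0).random((5, 2)), rng)


class TestSplitMergeMutation:
    def test_single_cluster_can_only_split(self, rng):
        p = ClusterPartition(np.arange(6), np.array([], dtype=int))
        out = split_merge_mutation(p, 1.0, rng)
        assert out.n_clusters == 2

    def test_all_singletons_can_only_merge(self, rng):
        p = ClusterPartition(np.arange(6), np.arange(1, 6))
        out = split_merge_mutation(p, 1.0, rng)
        assert out.n_clusters == 5

    def test_probability_zero_identity(self, rng):
        p = random_partition(9, rng)
        out = split_merge_mutation(p, 0.0, rng)
        assert np.array_equal(out.arrangement, p.arrangement)
        assert np.array_equal(out.boundaries, p.boundaries)

    def test_sample_conservation_and_step_size(self, rng):
        for _ in range(300):
            p = random_partition(10, rng)
            out = split_merge_mutation(p, 1.0, rng)
            assert_valid_partition(out, 10)
            assert abs(out.n_clusters - p.n_clusters) == 1
            assert np.array_equal(out.arrangement, p.arrangement)


class TestRouletteSelect:
    def test_dominant_individual_always_selected(self, rng):
        # after min-shift, fitness [5,0,0] leaves all mass on the first
        for _ in range(50):
            assert roulette_select(["a", "b", "c"], [5.0, 0.0, 0.0], rng) == "a"

    def test_equal_fitness_is_uniform(self, rng):
        counts = {"a": 0, "b": 0, "c": 0}
        for _ in range(10_000):
            counts[roulette_select(list("abc"), [2.0, 2.0, 2.0], rng)] += 1
        chi2 = sum((c - 10_000 / 3) ** 2 / (10_000 / 3) for c in counts.values())
        assert chi2 < stats.chi2.ppf(0.99, df=2)

    def test_single_member(self, rng):
        assert roulette_select(["only"], [1.0], rng) == "only"

    def test_empty_population_error(self, rng):
        with pytest.raises(ValueError):
            roulette_select([], [], rng)

    def test_nonfinite_fitness_error(self, rng):
        with pytest.raises(ValueError):
            roulette_select(["a"], [np.inf], rng)


class TestRunIlga:
    def test_recovers_two_separated_clusters(self, two_class_cohort):
        matrix, truth = two_class_cohort
        X = matrix.values[:, :30]  # informative loci
        result = run_ilga(X, IlgaConfig(population_size=50, generations=300,
                                        seed=0))
        found = result.best_partition.labels()
        truth_labels = [0] * 10 + [1] * 10
        assert adjusted_rand_score(found, truth_labels) >= 0.9

    def test_elite_trajectory_monotone(self, two_class_cohort):
        matrix, _ = two_class_cohort
        result = run_ilga(matrix.values, IlgaConfig(population_size=15,
                                                    generations=40, seed=4))
        best = result.history["best"].to_numpy()
        assert (np.diff(best) >= -1e-9).all()

    def test_same_seed_same_history(self, two_class_cohort):
        matrix, _ = two_class_cohort
        cfg = IlgaConfig(population_size=10, generations=20, seed=9)
        r1 = run_ilga(matrix.values, cfg)
        r2 = run_ilga(matrix.values, cfg)
        assert r1.history.equals(r2.history)
        assert np.array_equal(r1.best_partition.arrangement,
                              r2.best_partition.arrangement)

    def test_degenerate_data_flagged(self):
        X = np.full((6, 4), 0.5)
        result = run_ilga(X, IlgaConfig(population_size=8, generations=5,
                                        seed=0))
        assert result.best_record.degenerate

    def test_missing_data_rejected(self):
        X = np.full((4, 3), 0.5)
        X[0, 0] = np.nan
        with pytest.raises(ValueError, match="observed"):
            run_ilga(X, IlgaConfig(population_size=8, generations=2, seed=0))
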