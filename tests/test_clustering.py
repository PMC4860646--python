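import numpy as np
import pytest
from scipy.spatial.distance import cdist

from netparticles.clustering import (
    SeedSet,
    adapt_seeds,
    assign_particles,
    cluster_particles,
    seed_error,
    update_seed_positions,
)
from netparticles.dynamics import ParticleState


def make_seedset(state, seed_pos):
    assignments = assign_particles(state, seed_pos)
    errors = np.array(
        [seed_error(state, assignments, seed_pos, k) for k in range(len(seed_pos))]
    )
    return SeedSet(seed_pos.copy(), assignments, errors)


def blobs(centers, n_per, sigma, seed=0):
    rng = np.random.default_rng(seed)
    pts = np.vstack(
        [c + sigma * rng.standard_normal((n_per, 3)) for c in np.asarray(centers, float)]
    )
    return ParticleState(pts)


class TestAssignment:
    def test_single_seed_takes_all(self):
        state = blobs([[0, 0, 0]], 10, 0.5)
        out = assign_particles(state, np.zeros((1, 3)))
        assert np.all(out == 0)

    def test_tie_goes_to_lowest_index(self):
        state = ParticleState(np.array([[0.0, 0, 0]]))
        seeds = np.array([[1.0, 0, 0], [-1.0, 0, 0]])
        assert assign_particles(state, seeds)[0] == 0

    def test_matches_brute_force_nearest_neighbor(self):
        state = blobs([[0, 0, 0], [4, 0, 0], [0, 4, 0]], 7, 1.0, seed=3)
        seeds = np.array([[0.0, 0, 0], [4.0, 0, 0], [0.0, 4, 0]])
        out = assign_particles(state, seeds)
        oracle = np.argmin(cdist(state.positions, seeds), axis=1)
        np.testing.assert_array_equal(out, oracle)


class TestSeedError:
    def test_two_symmetric_members(self):
        state = ParticleState(np.array([[1.0, 0, 0], [-1.0, 0, 0]]))
        seeds = np.zeros((1, 3))
        a = assign_particles(state, seeds)
        assert seed_error(state, a, seeds, 0) == pytest.approx(1.0)

    def test_empty_seed_error_zero(self):
        state = ParticleState(np.array([[0.0, 0, 0]]))
        seeds = np.array([[0.0, 0, 0], [99.0, 0, 0]])
        a = assign_particles(state, seeds)
        assert seed_error(state, a, seeds, 1) == 0.0

    def test_seed_on_single_member_zero(self):
        state = ParticleState(np.array([[2.0, 1, 0]]))
        seeds = np.array([[2.0, 1, 0]])
        a = assign_particles(state, seeds)
        assert seed_error(state, a, seeds, 0) == 0.0


class TestAdaptation:
    def test_tight_cluster_stable(self):
        state = blobs([[0, 0, 0]], 20, 0.05, seed=1)
        seeds = make_seedset(state, state.positions.mean(0, keepdims=True))
        out, changed = adapt_seeds(state, seeds, theta_s=0.5)
        assert not changed
        assert out.n_seeds == 1

    def test_overloaded_seed_splits_two_blobs(self):
        state = blobs([[0, 0, 0], [10, 0, 0]], 15, 0.1, seed=2)
        seeds = make_seedset(state, state.positions.mean(0, keepdims=True))
        assert seeds.errors[0] > 0.5
        out, changed = adapt_seeds(state, seeds, theta_s=0.5)
        assert changed
        assert out.n_seeds == 2
        # next assignment separates the blobs
        left = set(out.assignments[:15].tolist())
        right = set(out.assignments[15:].tolist())
        assert left.isdisjoint(right)

    def test_singleton_seed_removed(self):
        state = blobs([[0, 0, 0]], 10, 0.05, seed=3)
        lonely = np.array([[50.0, 0, 0]])
        state = ParticleState(np.vstack([state.positions, lonely]))
        seed_pos = np.array([[0.0, 0, 0], [50.0, 0, 0]])
        seeds = make_seedset(state, seed_pos)
        out, changed = adapt_seeds(state, seeds, theta_s=0.5)
        assert changed
        assert out.n_seeds == 1

    def test_all_singletons_reseeded_at_centroid(self):
        state = ParticleState(np.array([[0.0, 0, 0], [4.0, 0, 0]]))
        seed_pos = np.array([[0.0, 0, 0], [4.0, 0, 0]])
        seeds = make_seedset(state, seed_pos)
        out, changed = adapt_seeds(state, seeds, theta_s=0.5)
        assert out.n_seeds == 1
        np.testing.assert_allclose(out.positions[0], [2, 0, 0])

    def test_coincident_seeds_merged(self):
        state = blobs([[0, 0, 0]], 30, 0.05, seed=4)
        seed_pos = np.array([[0.02, 0, 0], [-0.02, 0, 0]])
        seeds = make_seedset(state, seed_pos)
        out, changed = adapt_seeds(state, seeds, theta_s=0.5)
        assert changed
        assert out.n_seeds == 1


class TestCentroidUpdate:
    def test_mean_of_members(self):
        state = ParticleState(np.array([[0.0, 0, 0], [2.0, 0, 0]]))
        seeds = np.array([[1.0, 1, 0]])
        a = assign_particles(state, seeds)
        out = update_seed_positions(state, a, seeds)
        np.testing.assert_allclose(out[0], [1, 0, 0])

    def test_single_member_lands_on_it(self):
        state = ParticleState(np.array([[3.0, -1, 2]]))
        out = update_seed_positions(state, np.array([0]), np.array([[0.0, 0, 0]]))
        np.testing.assert_allclose(out[0], [3, -1, 2])

    def test_matches_arithmetic_mean_oracle(self):
        state = blobs([[0, 0, 0], [5, 0, 0]], 8, 0.4, seed=5)
        seeds = np.array([[0.0, 0, 0], [5.0, 0, 0]])
        a = assign_particles(state, seeds)
        out = update_seed_positions(state, a, seeds)
        for k in range(2):
            np.testing.assert_allclose(
                out[k], state.positions[a == k].mean(axis=0), atol=1e-12
            )

    def test_centroid_never_increases_weighted_error(self):
        state = blobs([[0, 0, 0], [3, 0, 0]], 10, 0.8, seed=6)
        seeds = np.array([[0.5, 0.2, 0], [2.5, -0.1, 0]])
        a = assign_particles(state, seeds)
        before = sum(
            np.sum((state.positions[a == k] - seeds[k]) ** 2) for k in range(2)
        )
        updated = update_seed_positions(state, a, seeds)
        after = sum(
            np.sum((state.positions[a == k] - updated[k]) ** 2) for k in range(2)
        )
        assert after <= before + 1e-12


class TestClusterLoop:
    def test_single_point_cloud_one_community(self):
        state = ParticleState(np.full((12, 3), 0.7))
        labels, converged, _ = cluster_particles(state, rng_seed=0)
        assert converged
        assert len(set(labels.tolist())) == 1

    def test_two_separated_clouds(self):
        state = blobs([[0, 0, 0], [5, 0, 0]], 20, 0.1, seed=7)
        labels, converged, _ = cluster_particles(state, rng_seed=1)
        assert converged
        assert len(set(labels.tolist())) == 2
        assert len(set(labels[:20].tolist())) == 1
        assert len(set(labels[20:].tolist())) == 1

    def test_three_gaussian_blobs_match_kmeans_oracle(self):
        from sklearn.cluster import KMeans

        centers = np.array([[0, 0, 0], [5, 0, 0], [0, 5, 5]], dtype=float)
        state = blobs(centers, 15, 0.2, seed=8)
        labels, converged, _ = cluster_particles(state, rng_seed=2)
        oracle = KMeans(n_clusters=3, init=centers, n_init=1).fit_predict(
            state.positions
        )
        assert converged
        # same partition up to relabeling
        mapping = {}
        for ours, theirs in zip(labels.tolist(), oracle.tolist()):
            mapping.setdefault(ours, theirs)
            assert mapping[ours] == theirs

    def test_assignment_optimality_after_convergence(self):
        state = blobs([[0, 0, 0], [4, 4, 0]], 15, 0.3, seed=9)
        labels, _, seeds = cluster_particles(state, rng_seed=3)
        d = cdist(state.positions, seeds.positions)
        np.testing.assert_array_equal(np.argmin(d, axis=1), seeds.assignments)

    def test_deterministic_given_seed(self):
        state = blobs([[0, 0, 0], [6, 0, 0], [0, 6, 0]], 12, 0.3, seed=10)
        a, _, _ = cluster_particles(state, rng_seed=5)
        b, _, _ = cluster_particles(state, rng_seed=5)
        np.testing.assert_array_equal(a, b)

    def test_partition_invariant_under_index_permutation(self):
        state = blobs([[0, 0, 0], [6, 0, 0]], 10, 0.2, seed=11)
        labels, _, _ = cluster_particles(state, rng_seed=6)
        perm = np.random.default_rng(0).permutation(20)
        state_p = ParticleState(state.positions[perm])
        labels_p, _, _ = cluster_particles(state_p, rng_seed=6)
        # compare as partitions of the same underlying points
        def groups(lab, order):
            out = {}
            for idx, l in zip(order, lab.tolist()):
                out.setdefault(l, set()).add(int(idx))
            return {frozenset(s) for s in out.values()}

        assert groups(labels, range(20)) == groups(labels_p, perm)

    def test_round_count_grows_with_cluster_count(self):
        # growing from a minimal seed set adds at most one seed per
        # overloaded cluster per round, hence rounds scale with clusters
        rounds = []
        for n_clusters in (2, 4, 8):
            centers = 6 * np.arange(n_clusters)[:, None] * np.array([[1.0, 0, 0]])
            state = blobs(centers, 10, 0.1, seed=12)
            _, converged, seeds = cluster_particles(state, rng_seed=7, n_init=2)
            assert converged
            rounds.append(seeds.iteration)
        assert rounds[0] <= rounds[1] <= rounds[2]
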