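import numpy as np
import pytest
from _oracles import brute_force_upgma_partition, dice_formula, same_partition
from hypothesis import given, settings
from hypothesis import strategies as st

from tmdimer.clustering import (
    UNASSIGNED,
    cluster_frequencies,
    cluster_interfaces,
    contact_frequency_map,
    dice_dissimilarity,
)
from tmdimer.contacts import ContactMap


def random_maps(rng, n_maps, density=0.08, shape=(25, 25)):
    maps = []
    for _ in range(n_maps):
        matrix = rng.random(shape) < density
        maps.append(
            ContactMap(matrix, np.arange(72, 72 + shape[0]), np.arange(72, 72 + shape[1]), 0.6)
        )
    return maps


def maps_from_matrices(matrices):
    return [
        ContactMap(m, np.arange(1, m.shape[0] + 1), np.arange(1, m.shape[1] + 1), 0.6)
        for m in matrices
    ]


class TestDice:
    def test_identical_nonzero_vectors(self):
        u = np.array([1, 0, 1, 1], bool)
        assert dice_dissimilarity(u, u) == 0.0

    def test_disjoint_vectors(self):
        assert dice_dissimilarity([1, 1, 0, 0], [0, 0, 1, 1]) == 1.0

    def test_hand_example(self):
        assert dice_dissimilarity([1, 1, 0], [1, 0, 1]) == 0.5

    def test_both_empty_rejected(self):
        with pytest.raises(ValueError, match="all-false"):
            dice_dissimilarity([0, 0], [0, 0])

    def test_length_mismatch_rejected(self):
        with pytest.raises(ValueError, match="length"):
            dice_dissimilarity([1, 0], [1, 0, 1])

    @settings(max_examples=200, deadline=None, derandomize=True)
    @given(st.lists(st.tuples(st.booleans(), st.booleans()), min_size=1, max_size=40))
    def test_symmetric_bounded_and_matches_scipy(self, pairs):
        u = np.array([p[0] for p in pairs])
        v = np.array([p[1] for p in pairs])
        if not (u.any() or v.any()):
            return
        d = dice_dissimilarity(u, v)
        assert d == dice_dissimilarity(v, u)
        assert 0.0 <= d <= 1.0
        assert (d == 0.0) == bool(np.array_equal(u, v))
        from scipy.spatial.distance import dice as scipy_dice

        if u.any() and v.any():
            assert d == pytest.approx(scipy_dice(u, v), abs=1e-12)


class TestClusterInterfaces:
    def test_identical_maps_form_one_cluster(self, rng):
        matrix = rng.random((25, 25)) < 0.08
        clustering = cluster_interfaces(
            maps_from_matrices([matrix] * 6), min_contacts=1
        )
        assert clustering.n_clusters == 1
        assert set(clustering.labels) == {1}

    def test_two_disjoint_groups_form_two_clusters(self):
        a = np.zeros((25, 25), bool)
        a[:5, :5] = True
        b = np.zeros((25, 25), bool)
        b[-5:, -5:] = True
        clustering = cluster_interfaces(
            maps_from_matrices([a] * 4 + [b] * 2), min_contacts=1
        )
        assert clustering.n_clusters == 2
        # ids ordered by decreasing size
        assert list(clustering.labels) == [1, 1, 1, 1, 2, 2]

    def test_matches_brute_force_upgma_oracle(self, rng):
        maps = random_maps(rng, 12)
        clustering = cluster_interfaces(maps, min_contacts=1)
        oracle = brute_force_upgma_partition([m.flatten() for m in maps], 0.5)
        oracle_labels = np.empty(len(maps), dtype=int)
        for k, members in enumerate(oracle):
            for i in members:
                oracle_labels[i] = k
        assert same_partition(clustering.labels, oracle_labels)

    def test_partition_invariant_under_input_order(self, rng):
        maps = random_maps(rng, 10)
        clustering = cluster_interfaces(maps, min_contacts=1)
        perm = rng.permutation(len(maps))
        permuted = cluster_interfaces([maps[i] for i in perm], min_contacts=1)
        assert same_partition(clustering.labels[perm], permuted.labels)

    def test_minimum_contact_filter_marks_unassigned(self, rng):
        dense = np.zeros((25, 25), bool)
        dense[:5, :5] = True  # 25 contacts
        sparse = np.zeros((25, 25), bool)
        sparse[0, :5] = True  # 5 contacts, below the 19-contact rule
        clustering = cluster_interfaces(maps_from_matrices([dense, dense, sparse]))
        assert list(clustering.labels) == [1, 1, UNASSIGNED]

    def test_all_filtered_input_rejected(self):
        sparse = np.zeros((25, 25), bool)
        sparse[0, 0] = True
        with pytest.raises(ValueError, match="nothing to cluster"):
            cluster_interfaces(maps_from_matrices([sparse]))


class TestFrequencyTable:
    def test_single_condition_single_cluster(self):
        table = cluster_frequencies(np.array([1, 1, 1]), np.array(["x"] * 3),
                                    proportions=True)
        assert table.loc[1, "x"] == 1.0

    def test_counts_conserved_per_condition(self, rng):
        labels = rng.integers(1, 5, size=60)
        conditions = np.array(["a"] * 30 + ["b"] * 30)
        table = cluster_frequencies(labels, conditions)
        assert table["a"].sum() == 30
        assert table["b"].sum() == 30

    def test_small_clusters_lumped_into_others(self):
        labels = np.array([1] * 5 + [2] * 2)
        conditions = np.array(["x"] * 7)
        table = cluster_frequencies(labels, conditions, min_count=3)
        assert "others" in table.index
        assert table.loc["others", "x"] == 2
        assert 2 not in table.index

    def test_unassigned_maps_are_excluded(self):
        labels = np.array([1, 1, UNASSIGNED])
        table = cluster_frequencies(labels, np.array(["x"] * 3))
        assert table["x"].sum() == 2

    def test_length_mismatch_rejected(self):
        with pytest.raises(ValueError, match="equal length"):
            cluster_frequencies(np.array([1, 2]), np.array(["x"]))

    def test_planted_condition_frequencies_recovered(self):
        from tmdimer.synthetic import ConditionSpec, sample_condition_assemblies

        probs = {"s1": 0.5, "s2": 0.3, "s3": 0.2}
        labels = sample_condition_assemblies(ConditionSpec("c", probs), 100_000, seed=4)
        table = cluster_frequencies(
            np.array(labels, dtype=object), np.array(["c"] * len(labels)),
            proportions=True,
        )
        for state, p in probs.items():
            assert table.loc[state, "c"] == pytest.approx(p, abs=0.01)


class TestContactFrequencyMap:
    def test_single_member_cluster_is_its_own_map(self, rng):
        maps = random_maps(rng, 1)
        clustering = cluster_interfaces(maps, min_contacts=1)
        cfm = contact_frequency_map(clustering, 1, maps)
        assert np.array_equal(cfm.matrix, maps[0].matrix.astype(float))
        assert cfm.n_members == 1

    def test_half_frequency_for_single_differing_contact(self):
        a = np.zeros((25, 25), bool)
        a[:5, :4] = True
        b = a.copy()
        b[10, 10] = True
        clustering = cluster_interfaces(maps_from_matrices([a, b]), min_contacts=1)
        assert clustering.n_clusters == 1  # dice 1/41 << 0.5
        cfm = contact_frequency_map(clustering, 1, maps_from_matrices([a, b]))
        assert cfm.matrix[10, 10] == 0.5
        assert cfm.matrix[0, 0] == 1.0

    def test_unknown_cluster_rejected(self, rng):
        maps = random_maps(rng, 3)
        clustering = cluster_interfaces(maps, min_contacts=1)
        with pytest.raises(KeyError):
            contact_frequency_map(clustering, 99, maps)

    def test_planted_state_frequency_map_close_to_noiseless(self, default_model):
        from tmdimer.contacts import compute_contact_map
        from tmdimer.synthetic import render_assembly_frames

        frames = render_assembly_frames(default_model, ["parallel-sym"] * 30, seed=2)
        maps = [compute_contact_map(f) for f in frames]
        clustering = cluster_interfaces(maps, min_contacts=1)
        cfm = contact_frequency_map(clustering, 1, maps)
        from tmdimer.contacts import count_contacts

        noiseless = compute_contact_map(
            __import__("tmdimer.synthetic", fromlist=["place_dimer"]).place_dimer(
                default_model.helix_template(),
                default_model.helix_template(),
                default_model.states[0],
            )
        )
        # high-frequency entries coincide with the noiseless planted map
        assert np.array_equal(cfm.matrix > 0.8, noiseless.matrix & (cfm.matrix > 0.8))
        assert (cfm.matrix[noiseless.matrix] > 0.5).mean() > 0.9
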