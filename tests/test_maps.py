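import numpy as np
import pytest

from cpqsar.cpann import CPANNClassifier, TrainingConfig, initialize, train
from cpqsar.maps import (
    InfluentialZone,
    MapLayer,
    class_separation_within_alert,
    class_surface,
    count_contiguous_clusters,
    influential_zone,
    sa_group_map,
    top_map,
    weight_level_map,
    zone_overlap,
)


@pytest.fixture(scope="module")
def two_object_model():
    cfg = TrainingConfig(nx=2, ny=2, epochs=60, seed=1)
    model = initialize(cfg, 3, 1)
    X = np.array([[0.0, 0.0, 0.0], [1.0, 1.0, 1.0]])
    Y = np.array([[1.0], [2.0]])
    train(model, X, Y)
    model.column_names = ["a", "b", "c"]
    return model, X


class TestTopMap:
    def test_two_objects_two_neurons(self, two_object_model):
        model, X = two_object_model
        tm = top_map(model, X, ids=["lo", "hi"])
        assert tm.counts.sum() == 2
        assert sorted(v for v in tm.counts.flatten() if v) == [1, 1]
        occupants = sorted(sum(tm.assignments.values(), []))
        assert occupants == ["hi", "lo"]

    def test_identical_objects_share_neuron(self, two_object_model):
        model, _ = two_object_model
        X = np.tile([0.5, 0.5, 0.5], (7, 1))
        tm = top_map(model, X)
        assert (tm.counts > 0).sum() == 1
        assert tm.counts.max() == 7

    def test_occupancy_conserved(self, fitted_classifier, separable_data):
        matrix, _ = separable_data
        tm = top_map(fitted_classifier, matrix.values, matrix.row_ids)
        assert tm.counts.sum() == len(matrix.values)


class TestWeightLevelMap:
    def test_slice_by_name_and_restack(self, two_object_model):
        model, _ = two_object_model
        layers = [weight_level_map(model, name).values for name in model.column_names]
        np.testing.assert_array_equal(np.stack(layers, axis=-1), model.kohonen_weights)

    def test_unknown_level_errors(self, two_object_model):
        model, _ = two_object_model
        with pytest.raises(KeyError):
            weight_level_map(model, "nope")
        with pytest.raises(KeyError):
            weight_level_map(model, 17)

    def test_view_does_not_mutate_model(self, two_object_model):
        model, _ = two_object_model
        before = model.kohonen_weights.copy()
        layer = weight_level_map(model, 0)
        layer.values[:] = -1
        np.testing.assert_array_equal(model.kohonen_weights, before)


class TestClassSurface:
    def test_values_are_class_labels(self, two_object_model):
        model, _ = two_object_model
        surface = class_surface(model)
        assert set(np.unique(surface.values)) <= {1.0, 2.0}

    def test_all_class2_training(self):
        # objects spread to cover every neuron of the small grid
        cfg = TrainingConfig(nx=2, ny=2, epochs=40, seed=0)
        model = initialize(cfg, 2, 1)
        X = np.array([[0.1, 0.1], [0.1, 0.9], [0.9, 0.1], [0.9, 0.9]])
        train(model, X, np.full((4, 1), 2.0))
        assert np.all(class_surface(model).values == 2.0)

    def test_separable_fixture_partitions_in_two_regions(self, fitted_classifier):
        surface = class_surface(fitted_classifier)
        for cls in (1.0, 2.0):
            region = {
                (i + 1, j + 1)
                for i, j in zip(*np.where(surface.values == cls))
            }
            assert region, f"class {cls} absent from surface"
            assert count_contiguous_clusters(region) <= 2


class TestInfluentialZone:
    def test_single_maximum_high_quantile(self):
        layer = MapLayer(np.arange(9.0).reshape(3, 3), "t")
        zone = influential_zone(layer, 0.99)
        assert zone.positions == frozenset({(3, 3)})

    def test_median_quantile_takes_half(self):
        layer = MapLayer(np.arange(16.0).reshape(4, 4), "t")
        zone = influential_zone(layer, 0.5)
        assert abs(len(zone.positions) - 8) <= 1

    def test_zone_shrinks_with_quantile(self, rng):
        layer = MapLayer(rng.random((6, 6)), "t")
        sizes = [len(influential_zone(layer, q).positions) for q in (0.5, 0.7, 0.9)]
        assert sizes == sorted(sizes, reverse=True)

    def test_constant_layer_empty_zone(self):
        zone = influential_zone(MapLayer(np.ones((3, 3)), "t"), 0.9)
        assert zone.positions == frozenset()

    def test_invalid_quantile(self):
        with pytest.raises(ValueError):
            influential_zone(MapLayer(np.ones((2, 2)), "t"), 1.5)


class TestZoneOverlap:
    def z(self, positions):
        return InfluentialZone(frozenset(positions), "t", 0.0)

    def test_identical_is_one(self):
        a = self.z({(1, 1), (2, 2)})
        assert zone_overlap(a, a) == 1.0

    def test_disjoint_is_zero(self):
        assert zone_overlap(self.z({(1, 1)}), self.z({(2, 2)})) == 0.0

    def test_subset_ratio(self):
        small = self.z({(i, 1) for i in range(1, 6)})
        big = self.z({(i, 1) for i in range(1, 11)})
        assert zone_overlap(small, big) == 0.5

    def test_symmetry_and_bounds(self, rng):
        for _ in range(50):
            a = self.z({(int(i), int(j)) for i, j in rng.integers(1, 6, size=(rng.integers(0, 8), 2))})
            b = self.z({(int(i), int(j)) for i, j in rng.integers(1, 6, size=(rng.integers(0, 8), 2))})
            ab, ba = zone_overlap(a, b), zone_overlap(b, a)
            assert ab == ba
            assert 0.0 <= ab <= 1.0
            if a.positions or b.positions:
                assert (ab == 1.0) == (a.positions == b.positions)

    def test_both_empty_defined_zero(self):
        assert zone_overlap(self.z(set()), self.z(set())) == 0.0


@pytest.fixture(scope="module")
def sa_model():
    from cpqsar.synthetic import SAGroupSpec, generate_sa_group_dataset

    matrix, groups = generate_sa_group_dataset(SAGroupSpec(n_per_group=10, seed=4))
    clf = CPANNClassifier(
        nx=8, ny=8, epochs=60, output_encoding="one_hot", random_state=4
    )
    clf.fit(matrix.values, groups)
    return clf, matrix, groups


class TestSAGroupMap:
    def test_group_layer_peaks_where_group_maps(self, sa_model):
        clf, matrix, groups = sa_model
        layer = sa_group_map(clf, 5)
        winners = clf.winners(matrix.values[groups == 5])
        peak_value = np.mean([layer.values[i - 1, j - 1] for i, j in winners])
        assert peak_value > layer.values.mean()

    def test_levels_stay_in_unit_interval(self, sa_model):
        clf, _, _ = sa_model
        total = np.zeros((8, 8))
        for g in range(1, 11):
            layer = sa_group_map(clf, g).values
            assert layer.min() >= 0.0 and layer.max() <= 1.0
            total += layer
        assert total.max() <= 10.0

    def test_na_layer_complements_alert_groups(self, sa_model):
        clf, matrix, groups = sa_model
        na_layer = sa_group_map(clf, 10)
        na_winners = clf.winners(matrix.values[groups == 10])
        other_winners = clf.winners(matrix.values[groups != 10])
        na_at_na = np.mean([na_layer.values[i - 1, j - 1] for i, j in na_winners])
        na_at_other = np.mean([na_layer.values[i - 1, j - 1] for i, j in other_winners])
        assert na_at_na > na_at_other

    def test_unknown_group_errors(self, sa_model):
        clf, _, _ = sa_model
        with pytest.raises(KeyError):
            sa_group_map(clf, 11)

    def test_requires_one_hot(self, fitted_classifier):
        with pytest.raises(ValueError, match="one_hot"):
            sa_group_map(fitted_classifier, 1)


class TestClassSeparation:
    def test_disjoint_class_clusters_fully_separate(self):
        cfg = TrainingConfig(nx=4, ny=4, epochs=50, seed=3)
        model = initialize(cfg, 2, 1)
        X = np.vstack([np.full((5, 2), 0.1), np.full((5, 2), 0.9)])
        Y = np.array([[1.0]] * 5 + [[2.0]] * 5)
        train(model, X, Y)
        ids = [f"m{i}" for i in range(10)]
        annotations = {i: {"SA_21"} for i in ids}
        labels = {f"m{i}": (1 if i < 5 else 2) for i in range(10)}
        report = class_separation_within_alert(model, X, ids, annotations, labels, "SA_21")
        assert report.purity == 1.0
        assert report.jaccard == 0.0
        assert report.n_molecules == 10

    def test_single_class_trivially_pure(self, two_object_model):
        model, X = two_object_model
        ids = ["a", "b"]
        report = class_separation_within_alert(
            model, X, ids, {"a": {"SA_8"}, "b": {"SA_8"}}, {"a": 2, "b": 2}, "SA_8"
        )
        assert report.purity == 1.0

    def test_no_matching_molecule_empty_report(self, two_object_model):
        model, X = two_object_model
        report = class_separation_within_alert(model, X, ["a", "b"], {}, {}, "SA_21")
        assert report.n_molecules == 0 and report.occupancy == {}

    def test_purity_bounded(self, fitted_classifier, separable_data):
        matrix, labels = separable_data
        ids = matrix.row_ids
        annotations = {i: {"SA_8"} for i in ids}
        label_map = dict(zip(ids, labels))
        report = class_separation_within_alert(
            fitted_classifier, matrix.values, ids, annotations, label_map, "SA_8"
        )
        assert 0.0 <= report.purity <= 1.0
        assert 0.0 <= report.jaccard <= 1.0


class TestContiguity:
    def test_counts_components(self):
        assert count_contiguous_clusters({(1, 1), (1, 2), (2, 2)}) == 1
        assert count_contiguous_clusters({(1, 1), (3, 3)}) == 2
        assert count_contiguous_clusters({(1, 1), (2, 2)}) == 2  # diagonal not connected
        assert count_contiguous_clusters(set()) == 0
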