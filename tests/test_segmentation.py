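"""Correlation distance, bisecting k-means (vs an exhaustive-enumeration
oracle), dataset segmentation and compartment assignment."""

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st
from sklearn.base import clone

from msidissect.io import ValidationError
from msidissect.preprocess import MassWindow, tissue_mask
from msidissect.segmentation import (
    AssignmentError,
    BisectingKMeans,
    Compartment,
    CompartmentAssignment,
    DegenerateSplitError,
    DegenerateVectorWarning,
    SegmentMap,
    _cluster_cost,
    _standardize_rows,
    adjusted_rand_index,
    assign_compartments,
    correlation_distance,
    segment_dataset,
)


def exhaustive_two_partition_cost(X):
    """Oracle: minimum of the 2-cluster objective (sum of correlation
    distances to arithmetic-mean centroids) over all 2^(n-1)-1 bipartitions,
    by direct enumeration."""
    n = X.shape[0]
    Z, degen = _standardize_rows(X)
    idx = np.arange(n)
    best = np.inf
    for bits in range(1, 2 ** (n - 1)):
        sel = np.array([(bits >> i) & 1 for i in range(n)], dtype=bool)
        cost = _cluster_cost(X, Z, degen, idx[sel]) + _cluster_cost(
            X, Z, degen, idx[~sel]
        )
        best = min(best, cost)
    return best


class TestCorrelationDistance:
    def test_positive_affine_map_gives_zero(self):
        u = np.array([1.0, 5.0, 2.0, 8.0])
        assert correlation_distance(u, 3.0 * u + 7.0) == pytest.approx(0.0, abs=1e-12)

    def test_negation_gives_two(self):
        u = np.array([1.0, -1.0, 2.0])
        assert correlation_distance(u, -u) == pytest.approx(2.0, abs=1e-12)

    def test_mean_centered_orthogonal_gives_one(self):
        # hand computation: both mean-centered, dot product 1*1 + (-1)*1 + 0*(-2) = 0
        assert correlation_distance([1.0, -1.0, 0.0], [1.0, 1.0, -2.0]) == pytest.approx(
            1.0, abs=1e-12
        )

    def test_zero_variance_convention(self):
        with pytest.warns(DegenerateVectorWarning):
            d = correlation_distance([2.0, 2.0, 2.0], [1.0, 2.0, 3.0])
        assert d == 1.0

    def test_length_mismatch(self):
        with pytest.raises(ValidationError):
            correlation_distance([1.0, 2.0], [1.0, 2.0, 3.0])

    @settings(max_examples=25, derandomize=True)
    @given(st.integers(0, 10_000))
    def test_bounds_and_symmetry(self, seed):
        rng = np.random.default_rng(seed)
        u, v = rng.normal(size=(2, 6))
        d = correlation_distance(u, v)
        assert 0.0 <= d <= 2.0
        assert d == pytest.approx(correlation_distance(v, u), abs=1e-12)


class TestBisectingKMeans:
    def test_k_one_single_label(self):
        X = np.random.default_rng(0).normal(size=(5, 4))
        labels = BisectingKMeans(n_clusters=1).fit(X).labels_
        assert set(labels) == {0}

    def test_k_equals_n_all_singletons(self):
        X = np.random.default_rng(1).normal(size=(6, 4))
        labels = BisectingKMeans(n_clusters=6, random_state=0).fit(X).labels_
        assert len(set(labels)) == 6

    def test_two_groups_recovered_and_globally_optimal(self):
        """8 rows as two groups of duplicated, non-collinear profiles: the
        2-split must match the groups, which enumeration confirms is the
        global optimum."""
        rng = np.random.default_rng(7)
        a, b = rng.normal(size=(2, 10))
        X = np.vstack([np.tile(a, (4, 1)), np.tile(b, (4, 1))])
        model = BisectingKMeans(n_clusters=2, random_state=0).fit(X)
        assert len(set(model.labels_[:4])) == 1
        assert len(set(model.labels_[4:])) == 1
        assert model.labels_[0] != model.labels_[4]
        assert model.inertia_ <= exhaustive_two_partition_cost(X) + 1e-9

    def test_deterministic_under_seed(self):
        X = np.random.default_rng(3).normal(size=(30, 8))
        l1 = BisectingKMeans(n_clusters=3, random_state=5).fit(X).labels_
        l2 = BisectingKMeans(n_clusters=3, random_state=5).fit(X).labels_
        np.testing.assert_array_equal(l1, l2)

    def test_k_larger_than_n_rejected(self):
        with pytest.raises(ValidationError):
            BisectingKMeans(n_clusters=3).fit(np.ones((2, 4)))

    def test_identical_rows_degenerate_split(self):
        X = np.tile([1.0, 2.0, 3.0], (5, 1))
        with pytest.raises(DegenerateSplitError):
            BisectingKMeans(n_clusters=2, random_state=0).fit(X)

    def test_inertia_nonincreasing_in_k(self):
        rng = np.random.default_rng(11)
        X = rng.normal(size=(40, 6)) + np.repeat(
            rng.normal(size=(4, 6)) * 3, 10, axis=0
        )
        inertias = [
            BisectingKMeans(n_clusters=k, random_state=2).fit(X).inertia_
            for k in range(1, 6)
        ]
        assert all(b <= a + 1e-9 for a, b in zip(inertias, inertias[1:]))

    def test_sklearn_estimator_contract(self):
        model = BisectingKMeans(n_clusters=4, random_state=1)
        params = model.get_params()
        assert params["n_clusters"] == 4
        cloned = clone(model).set_params(n_clusters=2)
        X = np.random.default_rng(0).normal(size=(12, 5))
        labels = cloned.fit_predict(X)
        assert labels.shape == (12,)
        np.testing.assert_array_equal(cloned.predict(X), labels)


class TestSegmentDataset:
    def test_noiseless_phantom_recovered(self, noiseless_phantom):
        ds, truth = noiseless_phantom
        mask = tissue_mask(ds, quantile=0.6)
        segmap = segment_dataset(ds, mask, k=3, seed=0)
        assert adjusted_rand_index(segmap.labels, truth.labels) == pytest.approx(1.0)

    def test_deterministic(self, noisy_phantom):
        ds, _ = noisy_phantom
        mask = tissue_mask(ds, quantile=0.6)
        a = segment_dataset(ds, mask, k=3, seed=9)
        b = segment_dataset(ds, mask, k=3, seed=9)
        np.testing.assert_array_equal(a.labels, b.labels)

    def test_k2_separates_lumen_first(self, noiseless_phantom):
        """With k = 2 the two tissue compartments merge before the lumen
        splits off: one cluster equals the true lumen."""
        ds, truth = noiseless_phantom
        mask = tissue_mask(ds, quantile=0.6)
        segmap = segment_dataset(ds, mask, k=2, seed=0)
        lumen_truth = truth.labels == 1
        match = [
            np.array_equal(segmap.labels == lab, lumen_truth) for lab in (1, 2)
        ]
        assert any(match)

    def test_labels_off_mask_are_zero(self, noisy_phantom):
        ds, _ = noisy_phantom
        mask = tissue_mask(ds, quantile=0.6)
        segmap = segment_dataset(ds, mask, k=3, seed=0)
        assert (segmap.labels[~mask.mask] == 0).all()
        assert set(np.unique(segmap.labels[mask.mask])) == {1, 2, 3}


class TestAssignCompartments:
    def manual_map(self):
        return {1: "lumen", 2: "mucosa", 3: "outer_tissue"}

    def test_manual_verbatim(self, noiseless_phantom):
        ds, _ = noiseless_phantom
        mask = tissue_mask(ds, quantile=0.6)
        segmap = segment_dataset(ds, mask, k=3, seed=0)
        assignment = assign_compartments(segmap, manual=self.manual_map())
        assert assignment.provenance == "manual"
        assert assignment.mapping[2] == Compartment.MUCOSA

    def test_marker_based_identifies_mucosa(self, noiseless_phantom):
        ds, truth = noiseless_phantom
        mask = tissue_mask(ds, quantile=0.6)
        segmap = segment_dataset(ds, mask, k=3, seed=0)
        markers = [
            (MassWindow(760.58, 0.1), Compartment.LUMEN),
            (MassWindow(796.53, 0.1), Compartment.MUCOSA),
            (MassWindow(772.53, 0.1), Compartment.OUTER_TISSUE),
        ]
        assignment = assign_compartments(segmap, ds, marker_windows=markers)
        mucosa_clusters = assignment.clusters_of(Compartment.MUCOSA)
        assert len(mucosa_clusters) == 1
        assert np.array_equal(
            segmap.labels == mucosa_clusters[0], truth.labels == 2
        )

    def test_single_segment_rejected(self):
        segmap = SegmentMap(
            labels=np.array([[1, 1]]),
            k=1,
            metric="correlation",
            seed=0,
            cluster_centroids=np.ones((1, 3)),
        )
        with pytest.raises(AssignmentError):
            assign_compartments(segmap, manual={1: "lumen"})

    def test_assignment_needs_tissue_compartment(self):
        with pytest.raises(AssignmentError):
            CompartmentAssignment(
                mapping={1: "lumen", 2: "lumen"}, provenance="manual"
            )


class TestAdjustedRandIndex:
    def test_identical(self):
        grid = np.array([[1, 1], [2, 3]])
        assert adjusted_rand_index(grid, grid) == 1.0

    def test_label_permutation_invariance(self):
        a = np.array([[1, 1], [2, 3]])
        b = np.array([[3, 3], [1, 2]])
        assert adjusted_rand_index(a, b) == 1.0

    def test_hand_computed_value(self):
        """(1,1,2,2) vs (1,2,1,2): the pair-counting formula gives -0.5."""
        a = np.array([[1, 1, 2, 2]])
        b = np.array([[1, 2, 1, 2]])
        assert adjusted_rand_index(a, b) == pytest.approx(-0.5)

    def test_disjoint_support_rejected(self):
        a = np.array([[1, 0]])
        b = np.array([[0, 1]])
        with pytest.raises(ValidationError):
            adjusted_rand_index(a, b)
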