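"""Digital dissection: bisecting k-means segmentation of tissue sections
under correlation distance, and mapping of clusters to histological
compartments (lumen, mucosa, outer tissue).

Correlation distance, d(u, v) = 1 - Pearson r(u, v), compares the *shape* of
two pixel spectra irrespective of overall intensity, which makes it robust to
pixel-to-pixel TIC variation; it is the metric of choice for clustering MSI
feature matrices.  Bisecting k-means grows a flat k-partition divisively:
starting from one cluster, the most heterogeneous cluster (largest
within-cluster sum of distances to its centroid) is repeatedly split in two
by a seeded, restarted 2-means until k clusters exist.

No exact "centroid" exists under correlation distance; the arithmetic mean of
the member rows is used, with assignment by minimal correlation distance —
the common practical compromise, documented as an approximation.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass
from enum import Enum
from typing import Dict, List, Optional, Sequence, Tuple

import numpy as np
from sklearn.base import BaseEstimator, ClusterMixin
from sklearn.metrics import adjusted_rand_score
from sklearn.utils.validation import check_array

from .io import MSIDataset, ValidationError
from .preprocess import (
    FeatureMatrix,
    MassWindow,
    TissueMask,
    build_feature_matrix,
    extract_ion_image,
    tic_normalize,
)

__all__ = [
    "Compartment",
    "SegmentMap",
    "CompartmentAssignment",
    "BisectingKMeans",
    "correlation_distance",
    "bisecting_kmeans",
    "segment_dataset",
    "assign_compartments",
    "adjusted_rand_index",
    "DegenerateSplitError",
    "AssignmentError",
    "DegenerateVectorWarning",
]


class Compartment(str, Enum):
    """Histological compartments of an intestinal cross-section."""

    LUMEN = "lumen"
    MUCOSA = "mucosa"
    OUTER_TISSUE = "outer_tissue"


TISSUE_COMPARTMENTS = (Compartment.MUCOSA, Compartment.OUTER_TISSUE)


class DegenerateSplitError(ValueError):
    """All rows identical: no 2-partition can reduce the objective."""


class AssignmentError(ValueError):
    """Clusters could not be mapped to compartments."""


class DegenerateVectorWarning(UserWarning):
    """A zero-variance vector forced the d = 1 convention."""


def _standardize_rows(X: np.ndarray) -> Tuple[np.ndarray, np.ndarray]:
    """Center and L2-normalize each row, so that correlation(u, v) is the dot
    product of the standardized rows.  Returns (Z, zero_variance_mask)."""
    Xc = X - X.mean(axis=1, keepdims=True)
    norms = np.linalg.norm(Xc, axis=1)
    degenerate = norms == 0
    safe = np.where(degenerate, 1.0, norms)
    return Xc / safe[:, None], degenerate


def correlation_distance(u: Sequence[float], v: Sequence[float]) -> float:
    """1 - Pearson correlation of two feature rows; in [0, 2].

    Zero-variance input gives d = 1 by convention and raises
    :class:`DegenerateVectorWarning`.
    """
    u = np.asarray(u, dtype=float)
    v = np.asarray(v, dtype=float)
    if u.shape != v.shape:
        raise ValidationError("length mismatch")
    if u.ndim != 1 or u.size < 2:
        raise ValidationError("vectors must be 1-D with length >= 2")
    Z, degen = _standardize_rows(np.vstack([u, v]))
    if degen.any():
        warnings.warn(
            "zero-variance vector in correlation distance; d = 1 by convention",
            DegenerateVectorWarning,
        )
        return 1.0
    r = float(np.clip(Z[0] @ Z[1], -1.0, 1.0))
    return 1.0 - r


def _distances_to_centroid(Z: np.ndarray, degen: np.ndarray, centroid: np.ndarray) -> np.ndarray:
    """Correlation distances of standardized rows Z to one raw centroid."""
    zc, cdegen = _standardize_rows(centroid[None, :])
    if cdegen[0]:
        d = np.ones(Z.shape[0])
    else:
        d = 1.0 - np.clip(Z @ zc[0], -1.0, 1.0)
    d[degen] = 1.0
    return d


def _cluster_cost(X: np.ndarray, Z: np.ndarray, degen: np.ndarray, idx: np.ndarray) -> float:
    """Within-cluster sum of correlation distances to the arithmetic-mean
    centroid of the rows ``idx``."""
    centroid = X[idx].mean(axis=0)
    return float(_distances_to_centroid(Z[idx], degen[idx], centroid).sum())


def _two_means(
    X: np.ndarray,
    Z: np.ndarray,
    degen: np.ndarray,
    idx: np.ndarray,
    rng: np.random.Generator,
    n_restarts: int,
    max_iter: int,
) -> Tuple[np.ndarray, np.ndarray, float]:
    """Best-of-``n_restarts`` 2-means on rows ``idx`` under correlation
    distance.  Each restart seeds the two centroids with 2 distinct member
    rows drawn at random.  Returns (idx_a, idx_b, total_cost)."""
    best = None
    m = idx.size
    for _ in range(n_restarts):
        seeds = rng.choice(m, size=2, replace=False)
        centroids = X[idx[seeds]].astype(float)
        assign = None
        for _ in range(max_iter):
            d = np.stack(
                [_distances_to_centroid(Z[idx], degen[idx], c) for c in centroids]
            )
            new_assign = np.argmin(d, axis=0)
            # keep both clusters non-empty: move the row farthest from the
            # winning centroid into the empty cluster
            for g in (0, 1):
                if not np.any(new_assign == g):
                    far = int(np.argmax(d[1 - g]))
                    new_assign[far] = g
            if assign is not None and np.array_equal(new_assign, assign):
                break
            assign = new_assign
            for g in (0, 1):
                centroids[g] = X[idx[assign == g]].mean(axis=0)
        cost = sum(
            _cluster_cost(X, Z, degen, idx[assign == g]) for g in (0, 1)
        )
        if best is None or cost < best[2] - 1e-12:
            best = (idx[assign == 0], idx[assign == 1], cost)
    return best


class BisectingKMeans(BaseEstimator, ClusterMixin):
    """Bisecting k-means clustering under correlation distance.

    Parameters
    ----------
    n_clusters : int, default=3
        Number of clusters to produce (the three histological segments by
        default).
    n_restarts : int, default=10
        Seeded 2-means initializations per split; the best split (lowest
        summed within-cluster distance) is kept.
    max_iter : int, default=100
        Lloyd iterations per 2-means run.
    random_state : int or None
        Seed for the restart initializations.  Mandatory for reproducible
        segment maps; ``None`` draws fresh entropy.

    Attributes
    ----------
    labels_ : ndarray of shape (n_samples,)
        Cluster index in ``0..n_clusters-1`` per row.
    cluster_centers_ : ndarray of shape (n_clusters, n_features)
        Arithmetic-mean centroid of each cluster.
    inertia_ : float
        Total within-cluster sum of correlation distances to the centroids.

    Notes
    -----
    The cluster selected for splitting is the one with the largest
    within-cluster sum of distances (the most heterogeneous); singleton and
    zero-variance clusters are never split.
    """

    def __init__(
        self,
        n_clusters: int = 3,
        n_restarts: int = 10,
        max_iter: int = 100,
        random_state: Optional[int] = None,
    ):
        self.n_clusters = n_clusters
        self.n_restarts = n_restarts
        self.max_iter = max_iter
        self.random_state = random_state

    def fit(self, X, y=None):
        X = check_array(X, dtype=np.float64)
        n = X.shape[0]
        if self.n_clusters < 1:
            raise ValidationError("n_clusters must be >= 1")
        if self.n_clusters > n:
            raise ValidationError(
                f"n_clusters={self.n_clusters} exceeds n_samples={n}"
            )
        rng = np.random.default_rng(self.random_state)
        Z, degen = _standardize_rows(X)

        clusters: List[np.ndarray] = [np.arange(n)]
        costs: List[float] = [_cluster_cost(X, Z, degen, clusters[0])]
        while len(clusters) < self.n_clusters:
            splittable = [
                i
                for i, idx in enumerate(clusters)
                if idx.size >= 2 and not self._is_degenerate(X, idx)
            ]
            if not splittable:
                raise DegenerateSplitError(
                    "no cluster can be split further (all rows identical "
                    "within every remaining cluster)"
                )
            i = max(splittable, key=lambda j: costs[j])
            idx = clusters.pop(i)
            costs.pop(i)
            a, b, _ = _two_means(
                X, Z, degen, idx, rng, self.n_restarts, self.max_iter
            )
            clusters += [a, b]
            costs += [
                _cluster_cost(X, Z, degen, a),
                _cluster_cost(X, Z, degen, b),
            ]

        self.labels_ = np.empty(n, dtype=int)
        for lab, idx in enumerate(clusters):
            self.labels_[idx] = lab
        self.cluster_centers_ = np.vstack(
            [X[idx].mean(axis=0) for idx in clusters]
        )
        self.inertia_ = float(sum(costs))
        return self

    @staticmethod
    def _is_degenerate(X: np.ndarray, idx: np.ndarray) -> bool:
        """True when all member rows are identical (or the centroid has zero
        variance), so a split cannot improve the objective."""
        sub = X[idx]
        if np.all(sub == sub[0]):
            return True
        # all rows constant: every pairwise correlation distance is 1 by
        # convention, so no split can reduce the objective
        return bool(np.all(np.ptp(sub, axis=1) == 0))

    def predict(self, X):
        X = check_array(X, dtype=np.float64)
        Z, degen = _standardize_rows(X)
        d = np.stack(
            [_distances_to_centroid(Z, degen, c) for c in self.cluster_centers_]
        )
        return np.argmin(d, axis=0)


def bisecting_kmeans(
    features: FeatureMatrix,
    k: int,
    seed: Optional[int] = None,
    n_restarts: int = 10,
) -> np.ndarray:
    """Functional wrapper: cluster a feature matrix into ``k`` groups.

    Returns one label per row (0-based)."""
    model = BisectingKMeans(
        n_clusters=k, n_restarts=n_restarts, random_state=seed
    )
    return model.fit(features.matrix).labels_


@dataclass
class SegmentMap:
    """Per-pixel cluster labels on the dataset grid.

    0 marks off-tissue/background; clusters are numbered 1..k on the mask.
    """

    labels: np.ndarray
    k: int
    metric: str
    seed: Optional[int]
    cluster_centroids: np.ndarray

    def __post_init__(self) -> None:
        on = self.labels[self.labels > 0]
        present = set(np.unique(on).tolist())
        if present != set(range(1, self.k + 1)):
            raise ValidationError(
                f"labels on mask must be exactly 1..{self.k}, got {present}"
            )
        if self.cluster_centroids.shape[0] != self.k:
            raise ValidationError("centroid count must equal k")

    def pixels_of(self, label: int) -> np.ndarray:
        return self.labels == label

    @property
    def mask(self) -> np.ndarray:
        return self.labels > 0


@dataclass
class CompartmentAssignment:
    """Mapping of cluster labels (1..k) to histological compartments."""

    mapping: Dict[int, Compartment]
    provenance: str  # "manual" or "marker_based"

    def __post_init__(self) -> None:
        self.mapping = {
            int(k): Compartment(v) for k, v in self.mapping.items()
        }
        if not any(v in TISSUE_COMPARTMENTS for v in self.mapping.values()):
            raise AssignmentError(
                "assignment contains no tissue compartment (mucosa or "
                "outer_tissue)"
            )

    def clusters_of(self, compartment: Compartment) -> List[int]:
        return [c for c, comp in self.mapping.items() if comp == compartment]


def segment_dataset(
    dataset: MSIDataset,
    mask: TissueMask,
    k: int = 3,
    mz_lo: float = 750.0,
    mz_hi: float = 850.0,
    seed: Optional[int] = None,
    bin_width: float = 0.1,
    n_restarts: int = 10,
    normalize: bool = True,
) -> SegmentMap:
    """Segment the masked pixels of a section into ``k`` clusters.

    The feature matrix is built from TIC-normalized spectra over the lipid
    range (normalization is skipped if the dataset is already normalized; it
    does not change correlation distances, which are row-scale invariant, but
    keeps centroid spectra comparable).  Deterministic given ``seed``.
    """
    if k < 2:
        raise ValidationError("segmentation needs k >= 2")
    ds = dataset
    if normalize and not dataset.normalized:
        ds = tic_normalize(dataset)
    features = build_feature_matrix(ds, mask, mz_lo, mz_hi, bin_width)
    model = BisectingKMeans(n_clusters=k, n_restarts=n_restarts, random_state=seed)
    row_labels = model.fit(features.matrix).labels_
    labels = np.zeros(dataset.grid_shape, dtype=int)
    for (r, c), lab in zip(features.pixel_indices, row_labels):
        labels[r, c] = lab + 1
    return SegmentMap(
        labels=labels,
        k=k,
        metric="correlation",
        seed=seed,
        cluster_centroids=model.cluster_centers_,
    )


def assign_compartments(
    segmap: SegmentMap,
    dataset: Optional[MSIDataset] = None,
    marker_windows: Optional[List[Tuple[MassWindow, Compartment]]] = None,
    manual: Optional[Dict[int, str]] = None,
) -> CompartmentAssignment:
    """Map clusters to compartments, manually or by marker ions.

    Manual mode applies the user mapping verbatim.  Marker mode assigns each
    cluster to the compartment whose marker window has the highest mean
    abundance z-score (standardized across clusters) in that cluster; ties
    break toward the larger cluster's preferred compartment first.
    """
    if segmap.k < 2:
        raise AssignmentError(
            "a single segment cannot separate lumen from tissue"
        )
    if manual is not None:
        if set(manual) != set(range(1, segmap.k + 1)):
            raise AssignmentError(
                f"manual mapping must cover exactly clusters 1..{segmap.k}"
            )
        return CompartmentAssignment(
            mapping={c: Compartment(v) for c, v in manual.items()},
            provenance="manual",
        )
    if dataset is None or not marker_windows:
        raise AssignmentError(
            "marker-based assignment needs the dataset and marker windows"
        )

    clusters = list(range(1, segmap.k + 1))
    sizes = {c: int((segmap.labels == c).sum()) for c in clusters}
    # cluster-mean abundance per marker, z-scored across clusters
    zscores = np.zeros((len(marker_windows), len(clusters)))
    for i, (window, _comp) in enumerate(marker_windows):
        img = extract_ion_image(dataset, window)
        means = np.array(
            [np.nanmean(img.values[segmap.labels == c]) for c in clusters]
        )
        sd = means.std()
        zscores[i] = (means - means.mean()) / sd if sd > 0 else 0.0

    mapping: Dict[int, Compartment] = {}
    # larger clusters choose first, so a tie resolves toward cluster size
    for j in sorted(range(len(clusters)), key=lambda j: -sizes[clusters[j]]):
        best = int(np.argmax(zscores[:, j]))
        mapping[clusters[j]] = marker_windows[best][1]
    try:
        return CompartmentAssignment(mapping=mapping, provenance="marker_based")
    except AssignmentError as exc:
        raise AssignmentError(
            f"marker-based assignment failed ({exc}); supply a manual mapping"
        ) from exc


def adjusted_rand_index(labels_a: np.ndarray, labels_b: np.ndarray) -> float:
    """Adjusted Rand index between two label grids over their shared masked
    support (labels > 0).  1.0 means identical partitions up to renaming."""
    labels_a = np.asarray(labels_a)
    labels_b = np.asarray(labels_b)
    if labels_a.shape != labels_b.shape:
        raise ValidationError("label grids must share a shape")
    support = (labels_a > 0) & (labels_b > 0)
    if not support.any():
        raise ValidationError("label grids have disjoint masked supports")
    return float(adjusted_rand_score(labels_a[support], labels_b[support]))
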