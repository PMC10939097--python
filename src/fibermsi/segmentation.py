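"""Spatial segmentation of MSI data into metabolic classes.

Pixels are clustered on their (optionally denoised, per-feature
standardized) peak-intensity vectors with K-means; a Ward dendrogram over
the class centroids supports operator-guided merging of classes — the
"semi-supervised" step in which segmentation output is curated against
histology (e.g. dropping non-tissue artifact classes or merging classes
that map to the same fiber type).
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
from scipy.cluster.hierarchy import linkage
from sklearn.cluster import KMeans

from .core import PeakTable, ROILabelMap, ValidationError
from .preprocess import median_filter_image


@dataclass
class SegmentationResult:
    """K-means labels, class centroids and the centroid dendrogram.

    ``labels`` assigns classes 1..k to occupied pixels (0 = background);
    ``centroids`` is the class x feature matrix in the clustering (denoised,
    standardized) space rescaled back to intensity units; ``dendrogram`` is
    a scipy linkage matrix over the k class centroids.
    """

    labels: ROILabelMap
    centroids: np.ndarray
    dendrogram: np.ndarray
    k: int
    seed: int
    pixel_labels: np.ndarray = None  # per-pixel class, aligned with PeakTable coords

    def class_counts(self) -> dict:
        labs, counts = np.unique(self.pixel_labels, return_counts=True)
        return {int(l): int(c) for l, c in zip(labs, counts)}


def _pixel_matrix(pt: PeakTable, denoise: bool, kernel: int = 3) -> np.ndarray:
    """Pixel x feature matrix, optionally median-filtered per feature image."""
    if not denoise:
        return pt.matrix.T.copy()
    rows, cols = pt.coords[:, 1], pt.coords[:, 0]
    X = np.empty((pt.n_pixels, pt.n_features))
    for i in range(pt.n_features):
        img = median_filter_image(pt.feature_image(i), kernel)
        X[:, i] = img[rows, cols]
    return X


def _centroid_dendrogram(centroids: np.ndarray) -> np.ndarray:
    if len(centroids) < 2:
        return np.empty((0, 4))
    return linkage(centroids, method="ward")


def segment(pt: PeakTable, k: int = 9, seed: int = 0,
            denoise: bool = True, kernel: int = 3) -> SegmentationResult:
    """Cluster the pixels of a peak table into ``k`` metabolic classes.

    Features are z-scored before clustering so high-abundance lipids do not
    dominate the distance; K-means uses k-means++ initialization with 10
    restarts at a fixed seed, keeping the best inertia. Class indices are
    relabeled by decreasing pixel count so the largest class is 1.
    """
    if k < 2:
        raise ValidationError("k must be >= 2")
    if pt.n_pixels < k:
        raise ValidationError(f"k={k} exceeds the {pt.n_pixels} occupied pixels")
    X = _pixel_matrix(pt, denoise, kernel)
    mu, sd = X.mean(axis=0), X.std(axis=0)
    constant = sd == 0
    if constant.all():
        warnings.warn("all pixels identical: a single effective cluster",
                      stacklevel=2)
    sd[constant] = 1.0
    Z = (X - mu) / sd

    km = KMeans(n_clusters=k, init="k-means++", n_init=10, random_state=seed)
    raw = km.fit_predict(Z)

    # stable relabeling: 1 = most pixels
    order = np.argsort(-np.bincount(raw, minlength=k), kind="stable")
    remap = np.empty(k, dtype=int)
    remap[order] = np.arange(1, k + 1)
    pixel_labels = remap[raw]
    centroids_std = np.empty_like(km.cluster_centers_)
    centroids_std[remap - 1] = km.cluster_centers_
    centroids = centroids_std * sd + mu  # back to intensity units

    labels = np.zeros(pt.grid_shape, dtype=int)
    labels[pt.coords[:, 1], pt.coords[:, 0]] = pixel_labels
    return SegmentationResult(ROILabelMap(labels), centroids,
                              _centroid_dendrogram(centroids_std), k, seed,
                              pixel_labels=pixel_labels)


def merge_classes(seg: SegmentationResult, mapping: dict) -> SegmentationResult:
    """Merge segmentation classes according to ``{old_label: new_label}``.

    Labels absent from the mapping are kept; merged centroids are the
    pixel-count-weighted means of their members and the dendrogram is
    rebuilt over the surviving classes. Mapping to background (0) is
    forbidden — use histology-guided filtering on the label map instead.
    """
    existing = set(np.unique(seg.pixel_labels))
    bad = set(mapping) - existing
    if bad:
        raise ValidationError(f"mapping references absent labels: {sorted(bad)}")
    if 0 in mapping.values():
        raise ValidationError("cannot merge a class into background (0)")

    new_pixel = np.array([mapping.get(int(l), int(l)) for l in seg.pixel_labels])
    new_labels_sorted = np.unique(new_pixel)
    # compact to 1..k' preserving order
    compact = {int(old): i + 1 for i, old in enumerate(new_labels_sorted)}
    new_pixel = np.array([compact[int(l)] for l in new_pixel])
    k_new = len(new_labels_sorted)

    counts = np.bincount(seg.pixel_labels, minlength=seg.k + 1)[1:]
    centroids = np.zeros((k_new, seg.centroids.shape[1]))
    weights = np.zeros(k_new)
    for old in range(1, seg.k + 1):
        if counts[old - 1] == 0:
            continue
        tgt = compact[int(mapping.get(old, old))]
        centroids[tgt - 1] += counts[old - 1] * seg.centroids[old - 1]
        weights[tgt - 1] += counts[old - 1]
    centroids /= weights[:, None]

    labels = np.zeros_like(seg.labels.labels)
    rows, cols = np.nonzero(seg.labels.labels)
    flat_old = seg.labels.labels[rows, cols]
    labels[rows, cols] = [compact[int(mapping.get(int(l), int(l)))] for l in flat_old]
    return SegmentationResult(ROILabelMap(labels), centroids,
                              _centroid_dendrogram(centroids), k_new, seg.seed,
                              pixel_labels=new_pixel)


def class_mean_spectra(pt: PeakTable, labels: ROILabelMap) -> dict:
    """Mean intensity per feature for each nonzero class of a label map.

    This is the "region-specific mass spectrum" extraction used to compare
    fiber-type ROIs: returns ``{class_label: mean feature vector}``.
    """
    lab_at_pixel = labels.labels[pt.coords[:, 1], pt.coords[:, 0]]
    out = {}
    for cls in labels.classes:
        mask = lab_at_pixel == cls
        if not mask.any():
            raise ValidationError(f"class {cls} covers no occupied pixel")
        out[int(cls)] = pt.matrix[:, mask].mean(axis=1)
    return out
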