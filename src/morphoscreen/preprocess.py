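"""Patch-level preprocessing: tiling, artifact filtering, baseline segmentation.

Whole-slide images are partitioned into 224x224 tiles; background tiles are
dropped by a white-fraction rule and pen-marked tiles by a linear SVM over
concatenated per-channel RGB histograms (768 features).  A classical
watershed segmenter over hematoxylin optical density provides nucleus masks
when no trained segmentation model is available; any mask supplier can feed
the morphometry stage through the same interface.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy import ndimage as ndi
from skimage.filters import threshold_otsu
from skimage.measure import label as cc_label
from skimage.segmentation import relabel_sequential, watershed
from sklearn.model_selection import train_test_split
from sklearn.svm import LinearSVC

PATCH_SIZE = 224
HISTOGRAM_DIM = 768  # 3 channels x 256 bins

__all__ = [
    "Patch",
    "PenMarkClassifier",
    "partition_image",
    "rgb_histogram",
    "train_penmark_classifier",
    "filter_background",
    "segment_nuclei_baseline",
]


@dataclass
class Patch:
    """One RGB tile of a slide with its grid position and optional mask."""

    patient_id: str
    slide_id: str
    row: int
    col: int
    rgb: np.ndarray
    mask: np.ndarray | None = None

    def __post_init__(self) -> None:
        rgb = np.asarray(self.rgb)
        if rgb.ndim != 3 or rgb.shape[2] != 3:
            raise ValueError("patch rgb must be HxWx3")
        if self.mask is not None and self.mask.shape != rgb.shape[:2]:
            raise ValueError("mask shape must match rgb")


@dataclass
class PenMarkClassifier:
    """Linear max-margin pen-mark detector over 768-bin RGB histograms."""

    model: LinearSVC
    feature_dim: int
    training_accuracy: float
    test_accuracy: float

    def predict(self, features: np.ndarray) -> np.ndarray:
        X = np.atleast_2d(np.asarray(features, dtype=float))
        if X.shape[1] != self.feature_dim:
            raise ValueError(f"expected {self.feature_dim} features")
        return self.model.predict(_l1_normalize(X))


def partition_image(image: np.ndarray, patch_size: int = PATCH_SIZE) -> list[Patch]:
    """Tile an RGB image into non-overlapping patch_size squares, row-major.

    Trailing remainders smaller than ``patch_size`` are dropped, matching the
    fixed input size of patch-level models.
    """
    image = np.asarray(image)
    if image.ndim != 3 or image.shape[2] != 3:
        raise ValueError("image must be HxWx3 RGB")
    H, W = image.shape[:2]
    if H < patch_size or W < patch_size:
        raise ValueError(
            f"image {H}x{W} smaller than patch size {patch_size}"
        )
    patches = []
    for r in range(H // patch_size):
        for c in range(W // patch_size):
            tile = image[
                r * patch_size : (r + 1) * patch_size,
                c * patch_size : (c + 1) * patch_size,
            ]
            patches.append(Patch("", "", r, c, tile))
    return patches


def rgb_histogram(patch: np.ndarray | Patch) -> tuple[np.ndarray, np.ndarray]:
    """Concatenated 256-bin per-channel histogram (R then G then B).

    Returns the raw counts (summing to 3 * n_pixels) and an L1-normalized
    copy (summing to 3) used as the classifier feature vector.
    """
    rgb = patch.rgb if isinstance(patch, Patch) else np.asarray(patch)
    if rgb.ndim != 3 or rgb.shape[2] != 3:
        raise ValueError("expected HxWx3 RGB array")
    counts = np.concatenate(
        [np.bincount(rgb[..., ch].ravel(), minlength=256) for ch in range(3)]
    ).astype(float)
    return counts, counts / rgb[..., 0].size


def _l1_normalize(X: np.ndarray) -> np.ndarray:
    sums = X.sum(axis=1, keepdims=True)
    sums[sums == 0] = 1.0
    # scale so each channel histogram sums to one (total 3), matching
    # rgb_histogram's normalized output regardless of input scaling
    return 3.0 * X / sums


def train_penmark_classifier(
    features: np.ndarray,
    labels: np.ndarray,
    train_fraction: float = 0.9,
    seed: int = 0,
) -> PenMarkClassifier:
    """Fit the pen-mark detector on a train/test split of histogram features.

    Features may be raw counts or normalized histograms; they are
    L1-normalized internally so the classifier is scale-free.
    """
    X = np.asarray(features, dtype=float)
    y = np.asarray(labels).astype(int)
    if X.ndim != 2 or X.shape[1] != HISTOGRAM_DIM:
        raise ValueError(f"features must be n x {HISTOGRAM_DIM}")
    if X.shape[0] < 20:
        raise ValueError("need at least 20 labeled patches")
    if len(np.unique(y)) < 2:
        raise ValueError("both classes must be present")
    X = _l1_normalize(X)
    X_tr, X_te, y_tr, y_te = train_test_split(
        X, y, train_size=train_fraction, random_state=seed, stratify=y
    )
    model = LinearSVC(C=1.0, random_state=seed)
    model.fit(X_tr, y_tr)
    return PenMarkClassifier(
        model=model,
        feature_dim=HISTOGRAM_DIM,
        training_accuracy=float(model.score(X_tr, y_tr)),
        test_accuracy=float(model.score(X_te, y_te)),
    )


def filter_background(
    patch: np.ndarray | Patch,
    white_fraction_threshold: float = 0.8,
    white_level: int = 220,
) -> bool:
    """Keep a patch unless it is mostly unstained background.

    Returns False (drop) iff the fraction of pixels whose minimum channel
    intensity is at least ``white_level`` exceeds ``white_fraction_threshold``.
    """
    rgb = patch.rgb if isinstance(patch, Patch) else np.asarray(patch)
    white = rgb.min(axis=2) >= white_level
    return bool(white.mean() <= white_fraction_threshold)


def segment_nuclei_baseline(
    od_hematoxylin: np.ndarray,
    min_area: int = 15,
    seed: int = 0,
    min_peak_distance: int = 6,
) -> np.ndarray:
    """Classical watershed nucleus segmenter over a hematoxylin OD image.

    Otsu threshold on OD -> distance-transform peaks as markers -> watershed
    to split touching blobs -> components below ``min_area`` removed; output
    labels are consecutive starting at 1.  A blank image yields an empty mask.
    """
    od = np.asarray(od_hematoxylin, dtype=float)
    if np.any(od < 0):
        raise ValueError("OD image must be nonnegative")
    if od.max() <= 0 or np.ptp(od) == 0:
        return np.zeros(od.shape, dtype=np.int32)
    thresh = threshold_otsu(od)
    fg = od > thresh
    if not fg.any():
        return np.zeros(od.shape, dtype=np.int32)
    dist = ndi.distance_transform_edt(fg)
    # smooth before peak detection: discrete EDT ridges of elongated nuclei
    # carry multiple near-equal maxima that would over-split
    smooth = ndi.gaussian_filter(dist, sigma=1.0)
    footprint = np.ones((2 * min_peak_distance + 1,) * 2, dtype=bool)
    peaks = (smooth == ndi.maximum_filter(smooth, footprint=footprint)) & (dist > 1.0)
    markers = cc_label(peaks)
    if markers.max() == 0:
        markers = cc_label(fg)
    labels = watershed(-dist, markers=markers, mask=fg)
    # drop small fragments, relabel consecutively
    sizes = np.bincount(labels.ravel())
    small = np.flatnonzero(sizes < min_area)
    labels[np.isin(labels, small)] = 0
    labels, _, _ = relabel_sequential(labels)
    return labels.astype(np.int32)
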