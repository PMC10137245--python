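"""Per-nucleus morphometric indices and per-patch median profiles.

The indices quantify the diagnostic criteria a pathologist reads from a GBM
section: nuclear size (area), chromatin content (mean/total hematoxylin OD),
local cell density (cellularity from the Delaunay triangulation of nucleus
centroids), elongation (ellipse-equivalent eccentricity, a spindle-geometry
surrogate) and pleomorphism (solidity, area over convex-hull area).
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy.spatial import ConvexHull, Delaunay, QhullError
from skimage.measure import regionprops

__all__ = [
    "MIN_NUCLEI_PER_PATCH",
    "PatchProfile",
    "shape_indices",
    "cellularity",
    "patch_profile",
]

MIN_NUCLEI_PER_PATCH = 5
INDEX_COLUMNS = ["area", "eccentricity", "solidity", "mean_hod", "total_hod", "cellularity"]


@dataclass
class PatchProfile:
    """Per-index median over one patch's non-border nuclei."""

    patch_id: str
    medians: pd.Series
    n_nuclei: int


def shape_indices(label_mask: np.ndarray) -> pd.DataFrame:
    """Area, centroid, eccentricity and solidity for every labeled nucleus.

    Eccentricity comes from the central second moments (the ellipse with the
    same moments; e = sqrt(1 - (minor/major)^2)).  Solidity is pixel area
    over the area of the convex hull of the pixel centers (clipped at 1):
    treating pixels as point samples avoids the downward bias a pixelated
    hull imposes on small convex nuclei, so a convex nucleus scores ~1 and
    only genuine concavity (pleomorphism) lowers the index.  Nuclei touching
    the patch border are flagged ``border=True`` so truncated shapes can be
    excluded from summaries.
    """
    labels = np.asarray(label_mask)
    if labels.ndim != 2:
        raise ValueError("label mask must be 2-D")
    H, W = labels.shape
    rows = []
    for rp in regionprops(labels.astype(np.int64)):
        minr, minc, maxr, maxc = rp.bbox
        border = minr == 0 or minc == 0 or maxr == H or maxc == W
        cy, cx = rp.centroid
        rows.append(
            {
                "nucleus_id": int(rp.label),
                "x": float(cx),
                "y": float(cy),
                "area": int(rp.area),
                "eccentricity": float(rp.eccentricity),
                "solidity": _point_hull_solidity(rp.coords),
                "border": bool(border),
            }
        )
    return pd.DataFrame(
        rows, columns=["nucleus_id", "x", "y", "area", "eccentricity", "solidity", "border"]
    )


def _point_hull_solidity(coords: np.ndarray) -> float:
    """Pixel count over the area of the convex hull of pixel centers."""
    pts = np.asarray(coords, dtype=float)
    if len(pts) < 3:
        return 1.0
    try:
        hull_area = ConvexHull(pts).volume
    except QhullError:  # collinear pixel runs
        return 1.0
    if hull_area <= 0:
        return 1.0
    return float(min(1.0, len(pts) / hull_area))


def cellularity(
    centroids: np.ndarray, edge_cutoff: float = 100.0
) -> np.ndarray:
    """Per-nucleus cell density from the Delaunay triangulation of centroids.

    Each nucleus's cellularity is the reciprocal of the mean length of the
    Delaunay edges incident to its centroid, in 1/px: tighter packing means
    shorter edges and larger cellularity.  Edges longer than ``edge_cutoff``
    are dropped to suppress convex-hull boundary artifacts; a nucleus with no
    remaining edges, and every nucleus when fewer than three non-collinear
    centroids exist, gets NaN.
    """
    pts = np.asarray(centroids, dtype=float)
    n = len(pts)
    out = np.full(n, np.nan)
    if n < 3:
        return out
    try:
        tri = Delaunay(pts)
    except QhullError:
        return out  # collinear or otherwise degenerate
    edges: set[tuple[int, int]] = set()
    for simplex in tri.simplices:
        for i in range(3):
            a, b = sorted((simplex[i], simplex[(i + 1) % 3]))
            edges.add((a, b))
    incident: list[list[float]] = [[] for _ in range(n)]
    for a, b in edges:
        length = float(np.linalg.norm(pts[a] - pts[b]))
        if length <= edge_cutoff:
            incident[a].append(length)
            incident[b].append(length)
    for i, lengths in enumerate(incident):
        if lengths:
            out[i] = 1.0 / float(np.mean(lengths))
    return out


def patch_profile(
    records: pd.DataFrame,
    patch_id: str = "",
    min_nuclei: int = MIN_NUCLEI_PER_PATCH,
) -> PatchProfile | None:
    """Median of each index over a patch's non-border nuclei.

    Returns None when fewer than ``min_nuclei`` usable nuclei remain, so
    degenerate patches drop out of dictionary learning.  Indices that are
    entirely missing yield a missing median.
    """
    df = records
    if "border" in df.columns:
        df = df[~df["border"].astype(bool)]
    if len(df) < min_nuclei:
        return None
    cols = [c for c in INDEX_COLUMNS if c in df.columns]
    medians = df[cols].median(skipna=True)
    return PatchProfile(patch_id=patch_id, medians=medians, n_nuclei=len(df))
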