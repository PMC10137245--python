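"""Stain normalization by sparse NMF and hematoxylin optical density readout.

H&E staining varies across slides and labs, which artificially modulates the
apparent chromatin content of nuclei.  Each patch's 3xN optical-density
matrix is factorized as OD ~ W H with W a 3x2 unit-column stain matrix
(hematoxylin, eosin) and H >= 0 the per-pixel stain concentrations, under an
L1 penalty on H that encourages each pixel to be explained by few stains.
The nucleus mask initializes W (mean OD direction inside vs outside nuclei),
which speeds convergence and pins the channel ordering.  Mapping the
concentrations through one target stain matrix puts every patch on a common
color scale, after which the hematoxylin concentration (HOD) is a comparable
per-nucleus measurement across the cohort.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .synthetic import StainModel

__all__ = [
    "StainEstimate",
    "rgb_to_od",
    "od_to_rgb",
    "estimate_stain_matrix",
    "order_stain_channels",
    "normalize_to_target",
    "normalized_concentrations",
    "compute_hod",
]

INFORMATIVE_OD = 0.05  # pixels with OD magnitude above this carry stain signal
MIN_INFORMATIVE_PIXELS = 100


def rgb_to_od(rgb: np.ndarray, background_intensity: float = 255.0) -> np.ndarray:
    """Convert an 8-bit RGB patch to a 3 x n_pixels optical-density matrix.

    Beer-Lambert with base-10 logarithm: OD_c = -log10(max(I_c, 1) / I_0).
    Intensities are clipped to >= 1 so OD is bounded by log10(I_0).
    """
    rgb = np.asarray(rgb, dtype=float)
    if rgb.ndim != 3 or rgb.shape[2] != 3:
        raise ValueError("expected HxWx3 RGB array")
    I = np.maximum(rgb, 1.0)
    od = -np.log10(I / background_intensity)
    return np.clip(od, 0.0, None).reshape(-1, 3).T


def od_to_rgb(
    od: np.ndarray,
    image_shape: tuple[int, int],
    background_intensity: float = 255.0,
) -> np.ndarray:
    """Inverse of :func:`rgb_to_od`; returns an 8-bit HxWx3 array."""
    od = np.asarray(od, dtype=float)
    rgb = background_intensity * np.power(10.0, -od)
    rgb = np.clip(np.round(rgb), 0, 255).astype(np.uint8)
    return rgb.T.reshape(image_shape + (3,))


@dataclass
class StainEstimate:
    """Result of per-patch sparse-NMF stain estimation."""

    stain_matrix: np.ndarray          # 3x2, unit columns, column 0 = hematoxylin
    concentrations: np.ndarray        # 2 x n_pixels, >= 0
    reference_maxima: np.ndarray      # 2-vector, 99th-percentile concentration
    converged: bool
    n_iter: int
    image_shape: tuple[int, int]
    background_intensity: float = 255.0
    low_tissue: bool = False
    degenerate_init: bool = False
    objective: list = field(default_factory=list, repr=False)


def _principal_od_directions(od: np.ndarray) -> np.ndarray:
    """First two principal directions of the OD cloud, made nonnegative."""
    X = od - od.mean(axis=1, keepdims=True)
    u, _, _ = np.linalg.svd(X, full_matrices=False)
    dirs = u[:, :2]
    # flip each direction into the nonnegative orthant as far as possible
    for j in range(2):
        if dirs[:, j].sum() < 0:
            dirs[:, j] *= -1
    return np.clip(dirs, 1e-6, None)


def _init_stain_matrix(
    od: np.ndarray, nuclear_mask: np.ndarray | None, informative: np.ndarray
) -> tuple[np.ndarray, bool]:
    """Mask-aided W initialization; returns (W_init, degenerate_flag).

    Column 0 starts at the mean OD direction of mask-interior pixels and
    column 1 at the mean of mask-exterior tissue pixels.  If either set is
    empty, the missing column falls back to a principal OD direction and the
    estimate is flagged.
    """
    pcs = None
    degenerate = False
    if nuclear_mask is not None:
        inside = np.asarray(nuclear_mask).ravel() > 0
    else:
        inside = np.zeros(od.shape[1], dtype=bool)
    cols = []
    for sel in (inside & informative, (~inside) & informative):
        if sel.sum() >= 10:
            cols.append(od[:, sel].mean(axis=1))
        else:
            cols.append(None)
            degenerate = True
    for j in range(2):
        if cols[j] is None:
            if pcs is None:
                pcs = _principal_od_directions(od[:, informative] if informative.any() else od)
            cols[j] = pcs[:, 1 - j] if cols[1 - j] is not None else pcs[:, j]
    W = np.column_stack(cols)
    W = np.clip(W, 1e-6, None)
    W = W / np.linalg.norm(W, axis=0, keepdims=True)
    # nudge apart if the two init directions collapsed onto each other
    if W[:, 0] @ W[:, 1] > 0.999:
        W[:, 1] = np.clip(W[:, 1] + np.array([0.0, 0.1, -0.05]), 1e-6, None)
        W[:, 1] /= np.linalg.norm(W[:, 1])
        degenerate = True
    return W, degenerate


def estimate_stain_matrix(
    od: np.ndarray,
    nuclear_mask: np.ndarray | None = None,
    l1_weight: float = 0.01,
    tol: float = 1e-6,
    max_iter: int = 500,
    seed: int = 0,
    image_shape: tuple[int, int] | None = None,
    background_intensity: float = 255.0,
) -> StainEstimate:
    """Estimate a patch's stain matrix by L1-regularized NMF.

    Minimizes ``||OD - W H||_F^2 + lam * ||H||_1`` subject to W, H >= 0 and
    unit-norm W columns, by exact block-coordinate descent: the H step solves
    the per-pixel two-variable L1-penalized NNLS in closed form, and each W
    column step has the closed-form solution ``clip(R h', 0) / ||.||`` (with
    unit-norm columns the Frobenius term is linear in the column, so the
    projection onto the nonnegative unit sphere is optimal).  Every step is
    an exact minimizer, so the objective is non-increasing by construction.
    ``l1_weight`` is relative: the effective penalty is ``l1_weight *
    mean(OD)`` so sparsity pressure does not depend on overall stain
    strength.  Channel order is finalized by :func:`order_stain_channels`.

    Patches with fewer than 100 informative pixels (OD magnitude above 0.05)
    are flagged ``low_tissue`` so the feature stage can exclude them; hitting
    ``max_iter`` returns ``converged=False`` with the estimate intact.
    """
    od = np.asarray(od, dtype=float)
    if od.ndim != 2 or od.shape[0] != 3:
        raise ValueError("od must be 3 x n_pixels")
    n_pixels = od.shape[1]
    if image_shape is None:
        side = int(round(np.sqrt(n_pixels)))
        image_shape = (side, n_pixels // side)

    informative = np.linalg.norm(od, axis=0) > INFORMATIVE_OD
    low_tissue = int(informative.sum()) < MIN_INFORMATIVE_PIXELS

    W, degenerate = _init_stain_matrix(od, nuclear_mask, informative)
    lam = l1_weight * float(od.mean())

    eps = 1e-12
    objective: list[float] = []
    converged = False
    it = 0
    H = _solve_concentrations(W, od, lam)
    for it in range(1, max_iter + 1):
        for j in range(2):
            residual = od - W[:, 1 - j : 2 - j] @ H[1 - j : 2 - j, :]
            direction = np.clip(residual @ H[j], 0.0, None)
            norm = np.linalg.norm(direction)
            if norm > eps:
                W[:, j] = direction / norm
        H = _solve_concentrations(W, od, lam)
        obj = float(np.sum((od - W @ H) ** 2) + lam * np.abs(H).sum())
        objective.append(obj)
        if it > 1 and abs(objective[-2] - obj) <= tol * max(objective[-2], eps):
            converged = True
            break

    W, H, order_flag = order_stain_channels(W, H, nuclear_mask)
    ref = np.percentile(H[:, informative], 99, axis=1) if informative.any() else H.max(axis=1)
    return StainEstimate(
        stain_matrix=W,
        concentrations=H,
        reference_maxima=np.asarray(ref, dtype=float),
        converged=converged,
        n_iter=it,
        image_shape=image_shape,
        background_intensity=background_intensity,
        low_tissue=low_tissue,
        degenerate_init=degenerate or order_flag,
        objective=objective,
    )


def _solve_concentrations(W: np.ndarray, od: np.ndarray, lam: float) -> np.ndarray:
    """Exact nonnegative, L1-penalized concentrations for a fixed 3x2 W.

    Minimizes ``||v - W h||^2 + lam * sum(h)`` per pixel.  With two channels
    the KKT solution is the best of three candidates: the interior
    stationary point and the two single-stain faces.
    """
    G = W.T @ W
    b = W.T @ od - lam / 2.0  # (2, n)
    det = G[0, 0] * G[1, 1] - G[0, 1] ** 2
    h_int = np.empty_like(b)
    h_int[0] = (G[1, 1] * b[0] - G[0, 1] * b[1]) / det
    h_int[1] = (G[0, 0] * b[1] - G[0, 1] * b[0]) / det
    candidates = [
        np.where((h_int >= 0).all(axis=0), h_int, np.nan),
        np.stack([np.clip(b[0] / G[0, 0], 0, None), np.zeros(b.shape[1])]),
        np.stack([np.zeros(b.shape[1]), np.clip(b[1] / G[1, 1], 0, None)]),
    ]

    def objective(h):
        return np.einsum("in,ij,jn->n", h, G, h) - 2.0 * np.einsum("in,in->n", b, h)

    objs = np.stack([
        np.where(np.isnan(c[0]), np.inf, objective(np.nan_to_num(c)))
        for c in candidates
    ])
    best = np.argmin(objs, axis=0)
    H = np.choose(best, [np.nan_to_num(c) for c in candidates])
    return np.clip(H, 0.0, None)


def order_stain_channels(
    W: np.ndarray, H: np.ndarray, nuclear_mask: np.ndarray | None
) -> tuple[np.ndarray, np.ndarray, bool]:
    """Put the hematoxylin channel first.

    The channel with the larger mean concentration over nucleus-interior
    pixels becomes column 0; with no usable mask the tie-break is the larger
    blue-channel OD loading (hematoxylin absorbs more blue-channel light than
    eosin).  Returns (W, H, flagged) where ``flagged`` marks tie-break-only
    ordering.
    """
    W = np.asarray(W, dtype=float)
    H = np.asarray(H, dtype=float)
    if W.shape[1] != 2 or H.shape[0] != 2:
        raise ValueError("expected a two-channel factorization")
    flagged = False
    inside = None
    if nuclear_mask is not None:
        inside = np.asarray(nuclear_mask).ravel() > 0
        if inside.sum() == 0 or inside.all():
            inside = None
    if inside is not None:
        means = H[:, inside].mean(axis=1)
        if means[0] == means[1]:
            inside = None
        else:
            first = int(np.argmax(means))
    if inside is None:
        flagged = True
        first = int(np.argmax(W[2, :]))
    if first == 1:
        W = W[:, ::-1]
        H = H[::-1, :]
    return W, H, flagged


def normalized_concentrations(
    estimate: StainEstimate, target: StainModel
) -> np.ndarray:
    """Source concentrations rescaled onto the target's concentration scale.

    Each channel is multiplied by target.max_concentration / source
    reference_maxima; a zero source maximum leaves that channel unscaled
    with a warning.
    """
    scale = np.ones(2)
    for ch in range(2):
        ref = estimate.reference_maxima[ch]
        if ref <= 0:
            warnings.warn(
                f"zero reference maximum for channel {ch}; left unscaled",
                stacklevel=2,
            )
        else:
            scale[ch] = target.max_concentration[ch] / ref
    return estimate.concentrations * scale[:, None]


def normalize_to_target(estimate: StainEstimate, target: StainModel) -> np.ndarray:
    """Re-render a patch in the target stain space as an 8-bit RGB image."""
    target.validate()
    H_scaled = normalized_concentrations(estimate, target)
    od = target.stain_matrix @ H_scaled
    return od_to_rgb(od, estimate.image_shape, target.background_intensity)


def compute_hod(
    h_hematoxylin: np.ndarray, label_mask: np.ndarray
) -> pd.DataFrame:
    """Per-nucleus mean and total hematoxylin optical density.

    ``h_hematoxylin`` is the per-pixel hematoxylin concentration, either as a
    2-D image or flat; ``label_mask`` assigns pixels to nuclei.  Total HOD is
    the sum over nucleus pixels (= mean HOD x area).
    """
    labels = np.asarray(label_mask)
    h = np.asarray(h_hematoxylin, dtype=float).reshape(labels.shape)
    ids = np.unique(labels)
    ids = ids[ids > 0]
    rows = []
    for nid in ids:
        sel = labels == nid
        vals = h[sel]
        rows.append(
            {
                "nucleus_id": int(nid),
                "mean_hod": float(vals.mean()),
                "total_hod": float(vals.sum()),
                "area": int(sel.sum()),
            }
        )
    return pd.DataFrame(rows, columns=["nucleus_id", "mean_hod", "total_hod", "area"])
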