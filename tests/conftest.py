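"""Shared fixtures and independent oracles for the test suite.

The oracles here deliberately avoid the production code paths: the earth-
mover distance is solved as an explicit linear program over the transport
polytope, and solidity is recomputed from the exact union-of-squares polygon
via shapely.
"""

from __future__ import annotations

import numpy as np
import pytest
from scipy.optimize import linprog


def lp_emd(p: np.ndarray, q: np.ndarray, centers: np.ndarray) -> float:
    """Brute-force optimal transport cost between two histograms.

    Solves min <C, T> over the transport polytope {T >= 0, T 1 = p,
    T' 1 = q} with cost C_ij = |center_i - center_j|, as a dense LP.
    """
    p = np.asarray(p, dtype=float)
    q = np.asarray(q, dtype=float)
    n = len(p)
    C = np.abs(centers[:, None] - centers[None, :]).ravel()
    A_eq = []
    for i in range(n):  # row sums = p
        row = np.zeros((n, n))
        row[i, :] = 1.0
        A_eq.append(row.ravel())
    for j in range(n):  # column sums = q
        col = np.zeros((n, n))
        col[:, j] = 1.0
        A_eq.append(col.ravel())
    b_eq = np.concatenate([p, q])
    res = linprog(C, A_eq=np.asarray(A_eq), b_eq=b_eq, bounds=(0, None), method="highs")
    assert res.success, res.message
    return float(res.fun)


def shapely_solidity(mask: np.ndarray) -> float:
    """Solidity of a pixel region from the exact union-of-squares polygon."""
    from shapely.geometry import box
    from shapely.ops import unary_union

    squares = [
        box(c - 0.5, r - 0.5, c + 0.5, r + 0.5) for r, c in zip(*np.nonzero(mask))
    ]
    union = unary_union(squares)
    return union.area / union.convex_hull.area


def hex_lattice(d: float, nx: int = 10, ny: int = 10) -> np.ndarray:
    """Hexagonal (triangular) lattice of points with nearest-neighbor spacing d."""
    pts = []
    for j in range(ny):
        for i in range(nx):
            pts.append((i * d + (j % 2) * d / 2.0, j * d * np.sqrt(3) / 2.0))
    return np.asarray(pts)


def random_pdfs(rng: np.random.Generator, n_bins: int, concentration: float = 1.0):
    """A random probability vector on n_bins bins."""
    return rng.dirichlet(np.full(n_bins, concentration))


@pytest.fixture(scope="session")
def small_cohort():
    """A 100-patient cohort with two planted subtypes differing in mean HOD."""
    from morphoscreen.synthetic import SyntheticCohortSpec, generate_cohort

    spec = SyntheticCohortSpec(n_patients=100, beta_subtype=0.7, seed=42)
    clinical, features = generate_cohort(spec)
    return spec, clinical, features
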