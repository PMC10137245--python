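"""Tumor-heterogeneity representations: patient PDFs and morphometric dictionaries.

A patient's slide is summarized one morphometric index at a time, in two
complementary ways:

* **Patient PDF** — the patient's nucleus values histogrammed on cohort-wide
  bin edges, so every patient's distribution lives on the same scale and
  distributional (not just first-order) differences are retained.
* **Dictionary / alphabets** — per-patch median profiles pooled across the
  cohort are clustered by subsampled, noise-injected k-means; the stable
  centroids ("alphabets") form a cohort vocabulary and each patient becomes
  the frequency vector of the alphabets their patches map to.

The PDF view captures globally persistent, patient-scale structure; the
dictionary view captures cohort-scale vocabulary composition.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy.optimize import linear_sum_assignment
from sklearn.cluster import KMeans
from sklearn.metrics import silhouette_score

__all__ = [
    "CohortBins",
    "PatientPDF",
    "DictionaryModel",
    "build_cohort_bins",
    "patient_pdf",
    "learn_dictionary",
    "consensus_diagnostics",
    "patient_signature",
]

DEFAULT_BINS = 64
SILHOUETTE_CAP = 800_000


@dataclass
class CohortBins:
    """Shared equal-width bin edges for one index, spanning the cohort."""

    index: str
    edges: np.ndarray  # length B + 1, strictly increasing

    @property
    def n_bins(self) -> int:
        return len(self.edges) - 1

    @property
    def centers(self) -> np.ndarray:
        return 0.5 * (self.edges[:-1] + self.edges[1:])

    @property
    def width(self) -> float:
        return float(self.edges[1] - self.edges[0])


@dataclass
class PatientPDF:
    """One patient's probability vector for one index on cohort bins."""

    patient_id: str
    index: str
    probabilities: np.ndarray
    n_values: int
    low_support: bool = False


@dataclass
class DictionaryModel:
    """Consensus k-means vocabulary for one index over per-patch profiles."""

    index: str
    k: int
    centroids: np.ndarray          # (k, d), rows ordered ascending by value
    consensus: np.ndarray          # (n, n) co-assignment frequencies
    assignments: np.ndarray        # (n,), 0..k-1
    data: np.ndarray = field(repr=False, default=None)
    mean_silhouette: float | None = None


def build_cohort_bins(
    values: np.ndarray,
    index: str = "",
    n_bins: int = DEFAULT_BINS,
    percentile_range: tuple[float, float] = (0.5, 99.5),
    min_values: int = 1000,
) -> CohortBins:
    """Equal-width bins between robust percentiles of the pooled cohort values.

    Values outside the range are later clipped into the end bins, so the
    0.5-99.5 percentile span keeps extreme outliers from stretching the grid.
    """
    v = np.asarray(values, dtype=float)
    v = v[np.isfinite(v)]
    if v.size < min_values:
        raise ValueError(f"need at least {min_values} finite values, got {v.size}")
    lo, hi = np.percentile(v, percentile_range)
    if hi <= lo:
        raise ValueError(f"index {index!r} has zero robust range; cannot bin")
    edges = np.linspace(lo, hi, n_bins + 1)
    return CohortBins(index=index, edges=edges)


def patient_pdf(
    values: np.ndarray,
    bins: CohortBins,
    patient_id: str = "",
    min_support: int = 50,
) -> PatientPDF:
    """Normalized histogram of one patient's index values on the cohort bins.

    Values beyond the edges are clipped into the first/last bin.  Patients
    with fewer than ``min_support`` nuclei are flagged low-support rather
    than rejected.
    """
    v = np.asarray(values, dtype=float)
    v = v[np.isfinite(v)]
    if v.size == 0:
        raise ValueError(f"patient {patient_id!r} has no values for {bins.index!r}")
    clipped = np.clip(v, bins.edges[0], bins.edges[-1])
    counts, _ = np.histogram(clipped, bins=bins.edges)
    probs = counts / counts.sum()
    return PatientPDF(
        patient_id=patient_id,
        index=bins.index,
        probabilities=probs,
        n_values=int(v.size),
        low_support=v.size < min_support,
    )


def _one_kmeans(
    X: np.ndarray, k: int, rng: np.random.Generator, max_retries: int = 3
) -> tuple[np.ndarray, np.ndarray]:
    """k-means that retries with a fresh seed if a cluster comes back empty."""
    for _ in range(max_retries + 1):
        seed = int(rng.integers(0, 2**31 - 1))
        km = KMeans(n_clusters=k, n_init=10, random_state=seed)
        labels = km.fit_predict(X)
        if len(np.unique(labels)) == k:
            return km.cluster_centers_, labels
    raise RuntimeError(f"k-means produced an empty cluster in {max_retries + 1} attempts")


def learn_dictionary(
    profiles: np.ndarray,
    k: int,
    index: str = "",
    subsample: int = 1000,
    repeats: int = 10,
    noise_sd_fraction: float = 0.05,
    seed: int = 0,
) -> DictionaryModel:
    """Consensus dictionary of per-patch profiles by subsampled k-means.

    Per repeat: draw up to ``subsample`` profiles without replacement, add
    Gaussian noise with sd = ``noise_sd_fraction`` x per-feature sd (the
    perturbation that separates stable from fragile clusters), and run
    k-means.  Repeat centroids are matched to repeat 0 by optimal nearest-
    centroid assignment; the final alphabet is the componentwise median of
    matched centroids, ordered ascending so labels are stable.  The consensus
    matrix holds the co-assignment frequency of every pair of profiles over
    the repeats in which both were sampled (pairs never co-sampled fall back
    to their final-assignment agreement).
    """
    X = np.atleast_2d(np.asarray(profiles, dtype=float))
    if X.shape[0] == 1 and X.shape[1] > 1 and np.ndim(profiles) == 1:
        X = X.T
    if np.ndim(profiles) == 1:
        X = np.asarray(profiles, dtype=float).reshape(-1, 1)
    n, d = X.shape
    if k < 1:
        raise ValueError("k must be >= 1")
    n_distinct = len(np.unique(X, axis=0))
    if k > n_distinct:
        raise ValueError(f"k={k} exceeds the {n_distinct} distinct profiles")

    rng = np.random.default_rng(seed)
    m = min(subsample, n)
    feat_sd = X.std(axis=0, ddof=0)

    if k == 1:
        centroids = np.median(X, axis=0, keepdims=True)
        return DictionaryModel(
            index=index,
            k=1,
            centroids=centroids,
            consensus=np.ones((n, n)),
            assignments=np.zeros(n, dtype=int),
            data=X,
        )

    co_count = np.zeros((n, n))
    together = np.zeros((n, n))
    all_centroids = np.empty((repeats, k, d))
    ref_centroids = None
    for r in range(repeats):
        idx = rng.choice(n, size=m, replace=False)
        noise = rng.normal(0.0, 1.0, size=(m, d)) * (noise_sd_fraction * feat_sd)
        centers, labels = _one_kmeans(X[idx] + noise, k, rng)
        if ref_centroids is None:
            ref_centroids = centers
            perm = np.arange(k)
        else:
            cost = np.linalg.norm(
                centers[:, None, :] - ref_centroids[None, :, :], axis=2
            )
            row, col = linear_sum_assignment(cost)
            perm = np.empty(k, dtype=int)
            perm[row] = col
        all_centroids[r] = _permute(centers, perm)
        aligned = perm[labels]
        onehot = np.zeros((m, k))
        onehot[np.arange(m), aligned] = 1.0
        together[np.ix_(idx, idx)] += 1.0
        co_count[np.ix_(idx, idx)] += onehot @ onehot.T

    centroids = np.median(all_centroids, axis=0)
    order = np.argsort(centroids[:, 0], kind="stable")
    centroids = centroids[order]

    dists = np.linalg.norm(X[:, None, :] - centroids[None, :, :], axis=2)
    assignments = np.argmin(dists, axis=1)

    consensus = np.zeros((n, n))
    seen = together > 0
    consensus[seen] = co_count[seen] / together[seen]
    same = (assignments[:, None] == assignments[None, :]).astype(float)
    consensus[~seen] = same[~seen]
    np.fill_diagonal(consensus, 1.0)
    consensus = 0.5 * (consensus + consensus.T)

    return DictionaryModel(
        index=index,
        k=k,
        centroids=centroids,
        consensus=consensus,
        assignments=assignments,
        data=X,
    )


def _permute(centers: np.ndarray, perm: np.ndarray) -> np.ndarray:
    """Reorder rows so row j holds the centroid matched to reference cluster j."""
    out = np.empty_like(centers)
    out[perm] = centers
    return out


def consensus_diagnostics(
    models: dict[int, DictionaryModel], seed: int = 0
) -> tuple[pd.DataFrame, int]:
    """Model-selection diagnostics over candidate cluster counts.

    For each k: the empirical CDF of off-diagonal consensus entries (a flat
    CDF away from {0, 1} means few ambiguously assigned pairs), its area
    under the curve and the increment over the previous k, and the mean
    silhouette of the assignments on a capped random subsample of items.
    The recommended k maximizes mean silhouette; the CDF-flatness measure is
    reported alongside.
    """
    grid = np.linspace(0.0, 1.0, 101)
    rows = []
    prev_auc = None
    for k in sorted(models):
        model = models[k]
        off = model.consensus[~np.eye(len(model.consensus), dtype=bool)]
        cdf = np.searchsorted(np.sort(off), grid, side="right") / off.size
        auc = float(np.trapezoid(cdf, grid))
        delta = np.nan if prev_auc is None else auc - prev_auc
        prev_auc = auc
        sil = np.nan
        if model.k >= 2 and model.data is not None:
            sample_size = min(SILHOUETTE_CAP, len(model.data))
            sil = float(
                silhouette_score(
                    model.data,
                    model.assignments,
                    sample_size=sample_size,
                    random_state=seed,
                )
            )
            model.mean_silhouette = sil
        rows.append(
            {"k": k, "cdf_auc": auc, "delta_auc": delta, "mean_silhouette": sil,
             "cdf_curve": cdf}
        )
    table = pd.DataFrame(rows)
    valid = table.dropna(subset=["mean_silhouette"])
    recommended = int(valid.loc[valid["mean_silhouette"].idxmax(), "k"]) if len(valid) else int(table["k"].iloc[0])
    return table, recommended


def patient_signature(
    profiles: np.ndarray, centroids: np.ndarray, patient_id: str = ""
) -> pd.Series:
    """Alphabet-frequency vector of one patient's patch profiles.

    Each profile is assigned to its nearest centroid (Euclidean); the
    signature is the normalized assignment frequency, a composition vector
    summing to one.
    """
    X = np.asarray(profiles, dtype=float)
    if X.ndim == 1:
        X = X.reshape(-1, 1)
    C = np.asarray(centroids, dtype=float)
    if C.ndim == 1:
        C = C.reshape(-1, 1)
    if X.shape[0] == 0:
        raise ValueError(f"patient {patient_id!r} has no patch profiles")
    dists = np.linalg.norm(X[:, None, :] - C[None, :, :], axis=2)
    assign = np.argmin(dists, axis=1)
    freq = np.bincount(assign, minlength=len(C)).astype(float)
    freq /= freq.sum()
    return pd.Series(freq, index=[f"alphabet_{j}" for j in range(len(C))], name=patient_id)
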