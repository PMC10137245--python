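"""Synthetic H&E cohorts with known morphometric and survival ground truth.

This module is the test bed for the whole pipeline: it renders nucleus label
masks with analytically known shape indices, converts them to RGB patches via
a Beer-Lambert forward stain model, draws pen-mark artifacts, and simulates
clinical cohorts in which survival hazard depends on age, age squared and a
planted heterogeneity subtype.  Every downstream stage (stain normalization,
morphometry, heterogeneity representations, the age-adjusted screen) can be
validated against the generating parameters.

Nuclei are ellipses, so area (pi*a*b), eccentricity (sqrt(1 - b^2/a^2)) and
solidity (1 for convex shapes) have closed forms that serve as exact oracles.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from skimage.draw import disk as _draw_disk
from skimage.draw import ellipse as _draw_ellipse
from skimage.draw import line as _draw_line

__all__ = [
    "StainModel",
    "SyntheticCohortSpec",
    "default_target_stain",
    "perturbed_stain_model",
    "generate_nuclei_patch",
    "render_he_patch",
    "add_pen_mark",
    "generate_cohort",
    "generate_imaging_cohort",
]

_MIN_STAIN_ANGLE_DEG = 5.0


@dataclass
class StainModel:
    """Two-stain Beer-Lambert model of an H&E slide.

    Attributes
    ----------
    stain_matrix : (3, 2) array
        Unit-norm optical-density column vectors; column 0 is hematoxylin,
        column 1 is eosin.
    max_concentration : (2,) array
        Per-channel reference concentration maxima (OD units) used when
        mapping concentrations between slides.
    background_intensity : float
        Intensity of unstained background, in (0, 255].
    """

    stain_matrix: np.ndarray
    max_concentration: np.ndarray
    background_intensity: float = 255.0

    def __post_init__(self) -> None:
        self.stain_matrix = np.asarray(self.stain_matrix, dtype=float)
        self.max_concentration = np.asarray(self.max_concentration, dtype=float)
        self.validate()

    def validate(self) -> None:
        W = self.stain_matrix
        if W.shape != (3, 2):
            raise ValueError(f"stain matrix must be 3x2, got {W.shape}")
        if np.any(W < 0):
            raise ValueError("stain matrix entries must be nonnegative")
        norms = np.linalg.norm(W, axis=0)
        if not np.allclose(norms, 1.0, atol=1e-6):
            raise ValueError(f"stain columns must have unit norm, got {norms}")
        cosang = float(np.clip(W[:, 0] @ W[:, 1], -1.0, 1.0))
        angle = np.degrees(np.arccos(cosang))
        if angle <= _MIN_STAIN_ANGLE_DEG:
            raise ValueError(
                f"stain columns nearly collinear (angle {angle:.2f} deg <= "
                f"{_MIN_STAIN_ANGLE_DEG} deg)"
            )
        if not (0 < self.background_intensity <= 255):
            raise ValueError("background_intensity must be in (0, 255]")
        if self.max_concentration.shape != (2,) or np.any(self.max_concentration <= 0):
            raise ValueError("max_concentration must be two positive scalars")


def default_target_stain() -> StainModel:
    """Canonical H&E target stain used as the cohort normalization template.

    The column directions are the widely used Ruifrok-Johnston H&E
    optical-density vectors, re-normalized to unit length.
    """
    W = np.array(
        [
            [0.650, 0.072],
            [0.704, 0.990],
            [0.286, 0.105],
        ]
    )
    W = W / np.linalg.norm(W, axis=0, keepdims=True)
    return StainModel(stain_matrix=W, max_concentration=np.array([1.0, 1.0]))


def perturbed_stain_model(
    base: StainModel, sd: float, seed: int, max_tries: int = 50
) -> StainModel:
    """Draw a per-slide stain model by jittering the base OD directions.

    Gaussian perturbation of magnitude ``sd`` per component, clipped to stay
    nonnegative, then renormalized.  Retries until the two columns remain
    separated by more than the collinearity limit.
    """
    rng = np.random.default_rng(seed)
    for _ in range(max_tries):
        W = base.stain_matrix + rng.normal(0.0, sd, size=(3, 2))
        W = np.clip(W, 1e-6, None)
        W = W / np.linalg.norm(W, axis=0, keepdims=True)
        try:
            return StainModel(
                stain_matrix=W,
                max_concentration=base.max_concentration.copy(),
                background_intensity=base.background_intensity,
            )
        except ValueError:
            continue
    raise RuntimeError("could not draw a valid perturbed stain model")


# ---------------------------------------------------------------------------
# nucleus patch synthesis
# ---------------------------------------------------------------------------


def generate_nuclei_patch(
    n_nuclei: int,
    shape_params: dict | None = None,
    spacing: float = 2.0,
    seed: int = 0,
    patch_shape: tuple[int, int] = (224, 224),
    max_tries_per_nucleus: int = 200,
) -> tuple[np.ndarray, pd.DataFrame]:
    """Place non-overlapping elliptical nuclei and return analytic ground truth.

    Parameters
    ----------
    n_nuclei : int
        Number of nuclei to place.
    shape_params : dict, optional
        ``semi_minor``: (lo, hi) uniform range of the minor semi-axis in px;
        ``aspect``: (lo, hi) uniform range of major/minor axis ratio.
        Defaults: semi_minor (3, 6), aspect (1.0, 2.0).
    spacing : float
        Minimum gap (px) between nucleus bounding circles.
    patch_shape : tuple
        Mask height and width.

    Returns
    -------
    mask : (H, W) uint16 label array with labels 1..n_nuclei.
    truth : DataFrame with columns nucleus_id, cy, cx, semi_major, semi_minor,
        orientation, area, eccentricity, solidity computed from the generating
        ellipse parameters (area = pi*a*b; e = sqrt(1 - (b/a)^2); solidity 1).

    Raises
    ------
    RuntimeError
        If placement fails after bounded retries, indicating the requested
        density exceeds what the patch can hold at the given spacing.
    """
    if n_nuclei < 0:
        raise ValueError("n_nuclei must be >= 0")
    params = {"semi_minor": (3.0, 6.0), "aspect": (1.0, 2.0)}
    if shape_params:
        params.update(shape_params)
    lo_b, hi_b = params["semi_minor"]
    lo_r, hi_r = params["aspect"]
    if lo_b < 1.0:
        raise ValueError("semi-axes must be >= 1 px")

    rng = np.random.default_rng(seed)
    H, W = patch_shape
    mask = np.zeros((H, W), dtype=np.uint16)
    rows: list[dict] = []
    placed: list[tuple[float, float, float]] = []  # (cy, cx, bounding radius)

    for nid in range(1, n_nuclei + 1):
        for attempt in range(max_tries_per_nucleus):
            b = rng.uniform(lo_b, hi_b)
            a = b * rng.uniform(lo_r, hi_r)
            theta = rng.uniform(0.0, np.pi)
            margin = a + 1.0
            if 2 * margin >= min(H, W):
                raise ValueError("nucleus too large for patch")
            cy = rng.uniform(margin, H - margin)
            cx = rng.uniform(margin, W - margin)
            r_bound = a + spacing / 2.0
            if all(
                np.hypot(cy - py, cx - px) >= r_bound + pr
                for py, px, pr in placed
            ):
                rr, cc = _draw_ellipse(cy, cx, b, a, shape=(H, W), rotation=theta)
                mask[rr, cc] = nid
                placed.append((cy, cx, r_bound))
                ecc = float(np.sqrt(1.0 - (b / a) ** 2))
                rows.append(
                    {
                        "nucleus_id": nid,
                        "cy": cy,
                        "cx": cx,
                        "semi_major": a,
                        "semi_minor": b,
                        "orientation": theta,
                        "area": np.pi * a * b,
                        "eccentricity": ecc,
                        "solidity": 1.0,
                    }
                )
                break
        else:
            raise RuntimeError(
                f"failed to place nucleus {nid}/{n_nuclei} after "
                f"{max_tries_per_nucleus} tries: requested density exceeds the "
                f"patch capacity at spacing {spacing} px"
            )

    columns = [
        "nucleus_id", "cy", "cx", "semi_major", "semi_minor",
        "orientation", "area", "eccentricity", "solidity",
    ]
    truth = pd.DataFrame(rows, columns=columns)
    return mask, truth


def render_he_patch(
    label_mask: np.ndarray,
    stain_model: StainModel,
    nuclear_hod: np.ndarray | float,
    noise_sd: float = 0.0,
    seed: int = 0,
    eosin_background: float = 0.15,
    eosin_nuclear: float = 0.05,
) -> np.ndarray:
    """Render an RGB H&E patch from a label mask via the Beer-Lambert law.

    The hematoxylin concentration field is ``nuclear_hod`` (per-nucleus scalar,
    or one scalar for all nuclei) inside nuclei and zero elsewhere; eosin is a
    low uniform field outside nuclei.  Gaussian noise of standard deviation
    ``noise_sd`` (OD units) is added per pixel per channel, and intensities
    are clipped to [0, 255] 8-bit.
    """
    if noise_sd < 0:
        raise ValueError("noise_sd must be >= 0")
    stain_model.validate()
    labels = np.asarray(label_mask)
    n_nuclei = int(labels.max())
    hod = np.broadcast_to(np.asarray(nuclear_hod, dtype=float), (n_nuclei,))
    if np.any(hod < 0):
        raise ValueError("nuclear_hod must be >= 0")

    lut = np.zeros(n_nuclei + 1)
    lut[1:] = hod
    c_h = lut[labels]
    c_e = np.where(labels > 0, eosin_nuclear, eosin_background)
    C = np.stack([c_h.ravel(), c_e.ravel()])  # (2, npix)

    od = stain_model.stain_matrix @ C  # (3, npix)
    if noise_sd > 0:
        rng = np.random.default_rng(seed)
        od = od + rng.normal(0.0, noise_sd, size=od.shape)
    od = np.clip(od, 0.0, None)
    rgb = stain_model.background_intensity * np.power(10.0, -od)
    rgb = np.clip(np.round(rgb), 0, 255).astype(np.uint8)
    return rgb.T.reshape(labels.shape + (3,))


def add_pen_mark(
    patch: np.ndarray,
    color: tuple[int, int, int] = (20, 60, 160),
    stroke_width: int = 6,
    seed: int = 0,
    n_waypoints: int = 5,
) -> tuple[np.ndarray, bool]:
    """Overwrite a random polyline of the given color onto a copy of the patch.

    Returns the marked patch and a ``True`` flag for classifier training.
    """
    if stroke_width < 1:
        raise ValueError("stroke_width must be >= 1")
    rng = np.random.default_rng(seed)
    out = np.array(patch, copy=True)
    H, W = out.shape[:2]
    pts = np.column_stack(
        [rng.integers(0, H, size=n_waypoints), rng.integers(0, W, size=n_waypoints)]
    )
    stroke = np.zeros((H, W), dtype=bool)
    for (r0, c0), (r1, c1) in zip(pts[:-1], pts[1:]):
        rr, cc = _draw_line(int(r0), int(c0), int(r1), int(c1))
        stroke[rr, cc] = True
    radius = stroke_width / 2.0
    if radius >= 1.0:
        # thicken by stamping a disk at every polyline pixel
        thick = np.zeros_like(stroke)
        for r, c in zip(*np.nonzero(stroke)):
            rr, cc = _draw_disk((r, c), radius, shape=(H, W))
            thick[rr, cc] = True
        stroke = thick
    out[stroke] = np.asarray(color, dtype=out.dtype)
    return out, True


# ---------------------------------------------------------------------------
# cohort simulation
# ---------------------------------------------------------------------------

DEFAULT_INDEX_DISTRIBUTIONS = {
    # Two planted heterogeneity subtypes that differ in mean HOD by one
    # within-subtype standard deviation; the remaining indices are shared.
    0: {
        "mean_hod": {"kind": "normal", "mean": 0.50, "sd": 0.10},
        "area": {"kind": "lognormal", "mean": np.log(110.0), "sd": 0.35},
        "eccentricity": {"kind": "normal", "mean": 0.60, "sd": 0.15},
    },
    1: {
        "mean_hod": {"kind": "normal", "mean": 0.60, "sd": 0.10},
        "area": {"kind": "lognormal", "mean": np.log(110.0), "sd": 0.35},
        "eccentricity": {"kind": "normal", "mean": 0.60, "sd": 0.15},
    },
}


@dataclass
class SyntheticCohortSpec:
    """Design of a simulated patient cohort.

    Survival hazard follows h(t) = h0(t) * exp(beta_age * (age - age_mean)
    + beta_age2 * (age - age_mean)^2 + beta_subtype * subtype), with an
    exponential or Weibull baseline.  Ages are drawn from a normal
    distribution.  Nucleus index values are drawn per patient from the
    subtype's index distributions; each patient contributes
    ``patches_per_patient`` patches of ``nuclei_per_patch`` nuclei.
    """

    n_patients: int = 100
    patches_per_patient: int = 20
    nuclei_per_patch: int = 30
    subtype_labels: dict[str, int] | None = None
    n_subtypes: int = 2
    index_distributions: dict = field(
        default_factory=lambda: {
            k: {n: dict(d) for n, d in v.items()}
            for k, v in DEFAULT_INDEX_DISTRIBUTIONS.items()
        }
    )
    age_mean: float = 60.0
    age_sd: float = 10.0
    beta_age: float = 0.05
    beta_age2: float = 0.0
    beta_subtype: float = 0.0
    censor_rate: float = 0.2
    baseline: str = "exponential"  # or "weibull"
    weibull_shape: float = 1.0
    baseline_rate: float = np.log(2.0) / 400.0  # median ~400 days at lp=0
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_patients < 1 or self.patches_per_patient < 1:
            raise ValueError("cohort dimensions must be positive")
        if not (0.0 <= self.censor_rate < 1.0):
            raise ValueError("censor_rate must be in [0, 1)")
        if self.baseline not in ("exponential", "weibull"):
            raise ValueError("baseline must be 'exponential' or 'weibull'")
        if self.weibull_shape <= 0:
            raise ValueError("weibull_shape must be > 0")


def _sample_index(dist: dict, n: int, rng: np.random.Generator) -> np.ndarray:
    kind = dist["kind"]
    if kind == "normal":
        return rng.normal(dist["mean"], dist["sd"], size=n)
    if kind == "lognormal":
        return rng.lognormal(dist["mean"], dist["sd"], size=n)
    if kind == "mixture_lognormal":
        # list of components with weight/mean/sd of the underlying normal
        comps = dist["components"]
        weights = np.array([c["weight"] for c in comps], dtype=float)
        weights = weights / weights.sum()
        which = rng.choice(len(comps), size=n, p=weights)
        out = np.empty(n)
        for i, c in enumerate(comps):
            sel = which == i
            out[sel] = rng.lognormal(c["mean"], c["sd"], size=int(sel.sum()))
        return out
    raise ValueError(f"unknown index distribution kind {kind!r}")


def _draw_survival(
    spec: SyntheticCohortSpec, lp: np.ndarray, rng: np.random.Generator
) -> tuple[np.ndarray, np.ndarray]:
    rate = spec.baseline_rate * np.exp(lp)
    e = rng.exponential(1.0, size=lp.shape)
    if spec.baseline == "exponential":
        times = e / rate
    else:
        times = np.power(e / rate, 1.0 / spec.weibull_shape)
    if np.max(times) <= 1e-9:
        raise ValueError("degenerate hazard: all event times at t=0")
    events = np.ones_like(times, dtype=int)
    if spec.censor_rate > 0:
        censored = rng.random(size=times.shape) < spec.censor_rate
        events[censored] = 0
        times[censored] = times[censored] * rng.random(size=int(censored.sum()))
    times = np.maximum(times, 1e-6)
    return times, events


def generate_cohort(
    spec: SyntheticCohortSpec,
) -> tuple[pd.DataFrame, dict[str, pd.DataFrame]]:
    """Simulate a clinical table and per-patient nucleus feature streams.

    Returns
    -------
    clinical : DataFrame
        Columns ``patient_id age time event subtype egfr`` plus the hidden
        ``true_subtype`` integer used downstream as the planted truth.
    features : dict
        patient_id -> DataFrame with a ``patch`` column plus one column per
        morphometric index, one row per simulated nucleus.
    """
    rng = np.random.default_rng(spec.seed)
    n = spec.n_patients
    patient_ids = [f"P{i:04d}" for i in range(n)]

    if spec.subtype_labels is not None:
        subtypes = np.array([spec.subtype_labels[p] for p in patient_ids])
    else:
        subtypes = rng.integers(0, spec.n_subtypes, size=n)

    ages = rng.normal(spec.age_mean, spec.age_sd, size=n)
    age_c = ages - spec.age_mean
    lp = spec.beta_age * age_c + spec.beta_age2 * age_c**2 + spec.beta_subtype * subtypes
    times, events = _draw_survival(spec, lp, rng)

    genomic = np.array(["mesenchymal", "proneural", "neural", "classical"])
    clinical = pd.DataFrame(
        {
            "patient_id": patient_ids,
            "age": ages,
            "time": times,
            "event": events,
            "subtype": genomic[subtypes % len(genomic)],
            "egfr": rng.lognormal(np.log(5.0) + 0.8 * subtypes, 0.4, size=n),
            "true_subtype": subtypes,
        }
    )

    features: dict[str, pd.DataFrame] = {}
    for pid, st in zip(patient_ids, subtypes):
        dists = spec.index_distributions[int(st)]
        n_nuc = spec.patches_per_patient * spec.nuclei_per_patch
        cols = {"patch": np.repeat(np.arange(spec.patches_per_patient), spec.nuclei_per_patch)}
        for index_name, dist in dists.items():
            cols[index_name] = _sample_index(dist, n_nuc, rng)
        features[pid] = pd.DataFrame(cols)
    return clinical, features


def generate_imaging_cohort(
    spec: SyntheticCohortSpec,
    stain_sd: float = 0.05,
    n_nuclei_range: tuple[int, int] = (8, 20),
    penmark_fraction: float = 0.1,
    patch_shape: tuple[int, int] = (224, 224),
) -> tuple[pd.DataFrame, list[dict]]:
    """Simulate an image-level cohort: rendered patches with per-slide stains.

    Each patient is one "slide" with its own stain matrix drawn around the
    canonical target; a fraction of patches receives a pen mark.  Per-nucleus
    mean HOD is drawn from the patient's subtype distribution so the imaging
    path carries the same planted heterogeneity as the feature-stream path.

    Returns the clinical table and a list of patch records
    ``{patient_id, slide_id, row, col, rgb, mask, truth, penmark}``.
    """
    clinical, _ = generate_cohort(spec)
    rng = np.random.default_rng(spec.seed + 1)
    target = default_target_stain()
    patches: list[dict] = []
    for i, row in clinical.iterrows():
        pid = row["patient_id"]
        st = int(row["true_subtype"])
        slide_seed = int(rng.integers(0, 2**31 - 1))
        stain = perturbed_stain_model(target, stain_sd, seed=slide_seed)
        hod_dist = spec.index_distributions[st].get(
            "mean_hod", {"kind": "normal", "mean": 0.5, "sd": 0.1}
        )
        for j in range(spec.patches_per_patient):
            n_nuc = int(rng.integers(*n_nuclei_range))
            mask, truth = generate_nuclei_patch(
                n_nuc, seed=int(rng.integers(0, 2**31 - 1)), patch_shape=patch_shape
            )
            hod = np.clip(_sample_index(hod_dist, max(n_nuc, 1), rng), 0.05, None)[:n_nuc]
            rgb = render_he_patch(
                mask, stain, hod, noise_sd=0.01,
                seed=int(rng.integers(0, 2**31 - 1)),
            )
            penmark = bool(rng.random() < penmark_fraction)
            if penmark:
                rgb, _ = add_pen_mark(rgb, seed=int(rng.integers(0, 2**31 - 1)))
            patches.append(
                {
                    "patient_id": pid,
                    "slide_id": f"S{i:04d}",
                    "row": 0,
                    "col": j,
                    "rgb": rgb,
                    "mask": mask,
                    "truth": truth,
                    "penmark": penmark,
                    "nuclear_hod": hod,
                }
            )
    return clinical, patches
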