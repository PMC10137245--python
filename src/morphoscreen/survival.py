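"""Age-adjusted survival screening of morphometric representations.

Age is the dominant predictor of outcome in GBM, and a naive screen credits
any index that merely tracks age.  Every biomarker test here therefore
compares nested Cox proportional-hazards models by likelihood ratio:

    null:        h(t) = h0(t) * exp(b1*age + b2*age^2)
    alternative: h(t) = h0(t) * exp(b1*age + b2*age^2 + g'x)

where x is the candidate representation (PDF-cluster labels as categorical
levels, dictionary signatures as continuous compositional components, or
both combined).  The quadratic age term matters: with age alone the
proportional-hazards assumption is violated when the true age effect is
nonlinear, and adding age^2 restores it.  Proportionality is checked with
scaled Schoenfeld residuals; significant screens are followed by 95%
hazard-ratio confidence intervals and pairwise Wald contrasts between
levels.  Age is centered before squaring to reduce collinearity, which
leaves hazard ratios and all tests unchanged.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from lifelines import CoxPHFitter, KaplanMeierFitter
from lifelines.statistics import multivariate_logrank_test, proportional_hazard_test
from scipy import stats

from . import heterogeneity as het
from . import subtyping

__all__ = [
    "CoxFit",
    "km_estimate",
    "fit_cox",
    "ph_test",
    "lrt_screen",
    "hazard_contrasts",
    "screen_covariate",
    "combined_screen",
    "run_screen",
]

AGE_COLS = ["age_c", "age_c2"]


@dataclass
class CoxFit:
    """A fitted Cox model plus everything the screen needs downstream."""

    params: pd.Series
    cov: pd.DataFrame
    log_likelihood: float
    n: int
    n_events: int
    covariate_names: list[str]
    fitter: CoxPHFitter = field(repr=False, default=None)
    design: pd.DataFrame = field(repr=False, default=None)
    excluded_levels: list = field(default_factory=list)
    ph_pvalues: pd.Series | None = None

    @property
    def hazard_ratios(self) -> pd.Series:
        return np.exp(self.params)


def _validate_clinical(clinical: pd.DataFrame) -> pd.DataFrame:
    df = clinical.copy()
    for col in ("time", "event", "age"):
        if col not in df.columns:
            raise ValueError(f"clinical table missing column {col!r}")
    n_nonpos = int((df["time"] <= 0).sum())
    if n_nonpos:
        warnings.warn(f"dropping {n_nonpos} patients with time <= 0", stacklevel=3)
        df = df[df["time"] > 0]
    return df


def km_estimate(
    times: np.ndarray,
    events: np.ndarray,
    groups: np.ndarray,
) -> tuple[dict, float]:
    """Kaplan-Meier curve per group plus the (unadjusted) logrank p-value.

    Returns ``{group: survival DataFrame}`` (product-limit estimate, starting
    at 1 and non-increasing) and the multivariate logrank p.  Empty groups
    are dropped with a warning.
    """
    times = np.asarray(times, dtype=float)
    events = np.asarray(events, dtype=int)
    groups = np.asarray(groups)
    if events.sum() < 1:
        raise ValueError("need at least one event")
    curves = {}
    for g in pd.unique(groups):
        sel = groups == g
        if sel.sum() == 0:
            warnings.warn(f"group {g!r} is empty; dropped", stacklevel=2)
            continue
        kmf = KaplanMeierFitter()
        kmf.fit(times[sel], events[sel], label=str(g))
        curves[g] = kmf.survival_function_
    logrank = multivariate_logrank_test(times, groups, events)
    return curves, float(logrank.p_value)


def _categorical_design(
    labels: pd.Series, name: str, events: pd.Series
) -> tuple[pd.DataFrame, list, pd.Index]:
    """Dummy-code labels with the lowest level as reference.

    Levels with zero events cannot yield a finite hazard ratio; their
    patients are excluded from the fit and the level is flagged.
    """
    labels = labels.dropna()
    levels = sorted(pd.unique(labels))
    excluded = []
    keep = pd.Series(True, index=labels.index)
    for lev in levels:
        sel = labels == lev
        if events.reindex(labels.index)[sel].sum() < 1:
            excluded.append(lev)
            keep &= ~sel
    labels = labels[keep]
    levels = [lev for lev in levels if lev not in excluded]
    if len(levels) < 2:
        raise ValueError("categorical covariate needs >= 2 estimable levels")
    cols = {
        f"{name}[{lev}]": (labels == lev).astype(float) for lev in levels[1:]
    }
    return pd.DataFrame(cols, index=labels.index), excluded, labels.index


def fit_cox(
    clinical: pd.DataFrame,
    covariate: pd.Series | pd.DataFrame | None = None,
    include_age_terms: bool = True,
    covariate_name: str = "index",
    compositional: bool = True,
    restrict_to: pd.Index | None = None,
) -> CoxFit:
    """Fit a Cox model with optional age adjustment and candidate covariate.

    ``covariate`` may be None (age-only null model), a Series of categorical
    cluster labels (dummy-coded against the lowest level), or a DataFrame of
    continuous components such as a dictionary signature (compositional: the
    first column is dropped as the reference share).  Ties are handled by
    Efron's method (lifelines' default).  Patients with non-positive survival
    time are dropped; categorical levels with no events are excluded and
    flagged rather than aborting the screen.
    """
    df = _validate_clinical(clinical)
    df = df.set_index("patient_id") if "patient_id" in df.columns else df
    design = pd.DataFrame(index=df.index)
    design["time"] = df["time"].astype(float)
    design["event"] = df["event"].astype(int)
    age_c = df["age"] - df["age"].mean()
    if include_age_terms:
        design["age_c"] = age_c
        design["age_c2"] = age_c**2

    excluded: list = []
    if covariate is not None:
        if isinstance(covariate, pd.Series):
            cov_df, excluded, keep_idx = _categorical_design(
                covariate, covariate_name, design["event"]
            )
        else:
            cov_df = covariate.astype(float).dropna()
            if compositional and cov_df.shape[1] > 1:
                cov_df = cov_df.iloc[:, 1:]
            constant = [c for c in cov_df.columns if cov_df[c].nunique() <= 1]
            if constant:
                warnings.warn(
                    f"dropping zero-variance covariates {constant}", stacklevel=2
                )
                cov_df = cov_df.drop(columns=constant)
                excluded = list(constant)
            keep_idx = cov_df.index
        design = design.loc[design.index.intersection(keep_idx)]
        design = design.join(cov_df, how="inner")

    if restrict_to is not None:
        design = design.loc[design.index.intersection(restrict_to)]

    n_events = int(design["event"].sum())
    if n_events < 10:
        raise ValueError(f"need >= 10 events, have {n_events}")

    cph = CoxPHFitter()
    cph.fit(design, duration_col="time", event_col="event")
    cov_names = [c for c in design.columns if c not in ("time", "event")]
    return CoxFit(
        params=cph.params_.copy(),
        cov=cph.variance_matrix_.copy(),
        log_likelihood=float(cph.log_likelihood_),
        n=len(design),
        n_events=n_events,
        covariate_names=cov_names,
        fitter=cph,
        design=design,
        excluded_levels=excluded,
    )


def ph_test(fit: CoxFit) -> pd.DataFrame:
    """Scaled Schoenfeld-residual proportionality test per covariate.

    Residuals are regressed against rank-transformed event time; an omnibus
    row sums the per-covariate chi-square statistics (df = number of
    covariates).  Requires at least 3 events.
    """
    if fit.n_events < 3:
        raise ValueError("proportionality test undefined with < 3 events")
    res = proportional_hazard_test(fit.fitter, fit.design, time_transform="rank")
    summary = res.summary.droplevel(1) if summary_has_multiindex(res.summary) else res.summary
    table = summary[["test_statistic", "p"]].copy()
    global_stat = float(table["test_statistic"].sum())
    global_df = len(table)
    table.loc["GLOBAL"] = [global_stat, float(stats.chi2.sf(global_stat, global_df))]
    fit.ph_pvalues = table["p"].copy()
    return table


def summary_has_multiindex(summary: pd.DataFrame) -> bool:
    return isinstance(summary.index, pd.MultiIndex)


def lrt_screen(null_fit: CoxFit, alt_fit: CoxFit) -> tuple[float, int, float]:
    """Likelihood-ratio test of nested Cox models on identical patients.

    Returns (statistic, df, p) with statistic = 2 * (ll_alt - ll_null) and
    df the number of added parameters.
    """
    if null_fit.n != alt_fit.n or null_fit.n_events != alt_fit.n_events:
        raise ValueError(
            f"models fit on different cohorts: n {null_fit.n} vs {alt_fit.n}, "
            f"events {null_fit.n_events} vs {alt_fit.n_events}"
        )
    if not set(null_fit.covariate_names) <= set(alt_fit.covariate_names):
        raise ValueError("models are not nested")
    df = len(alt_fit.covariate_names) - len(null_fit.covariate_names)
    stat = max(0.0, 2.0 * (alt_fit.log_likelihood - null_fit.log_likelihood))
    if df < 1:
        # the candidate collapsed to the null (e.g. constant covariate)
        return 0.0, 0, 1.0
    return stat, df, float(stats.chi2.sf(stat, df))


def hazard_contrasts(fit: CoxFit, z: float = 1.959963984540054) -> pd.DataFrame:
    """Per-level hazard ratios with 95% CIs and pairwise Wald contrasts.

    Covariates other than the age terms are treated as the levels of
    interest.  The reference level enters with log-HR 0 and zero variance,
    so its pairwise test against level i reduces to the Wald test of
    beta_i.  Returns a forest-plot table with columns level, hr, ci_lo,
    ci_hi, p_vs_ref plus pairwise rows.
    """
    levels = [c for c in fit.covariate_names if c not in AGE_COLS]
    if not levels:
        raise ValueError("fit has no candidate covariate levels")
    rows = []
    # an unstable level can give an infinite CI bound; report inf, don't warn
    with np.errstate(over="ignore"):
        for lev in levels:
            b = fit.params[lev]
            se = float(np.sqrt(fit.cov.loc[lev, lev]))
            p = 2 * stats.norm.sf(abs(b) / se) if se > 0 else np.nan
            rows.append(
                {"kind": "level", "a": lev, "b": "reference", "hr": float(np.exp(b)),
                 "ci_lo": float(np.exp(b - z * se)), "ci_hi": float(np.exp(b + z * se)),
                 "p": float(p)}
            )
        for i, li in enumerate(levels):
            for lj in levels[i + 1:]:
                diff = fit.params[li] - fit.params[lj]
                var = (
                    fit.cov.loc[li, li] + fit.cov.loc[lj, lj] - 2 * fit.cov.loc[li, lj]
                )
                se = float(np.sqrt(max(var, 0.0)))
                p = 2 * stats.norm.sf(abs(diff) / se) if se > 0 else np.nan
                rows.append(
                    {"kind": "pairwise", "a": li, "b": lj, "hr": float(np.exp(diff)),
                     "ci_lo": float(np.exp(diff - z * se)),
                     "ci_hi": float(np.exp(diff + z * se)), "p": float(p)}
                )
    return pd.DataFrame(rows)


def screen_covariate(
    clinical: pd.DataFrame,
    covariate: pd.Series | pd.DataFrame,
    covariate_name: str = "index",
    include_age_terms: bool = True,
    compositional: bool = True,
) -> dict:
    """Full biomarker test of one candidate representation.

    Fits the alternative model, refits the age-only null on the identical
    patients, and returns the LRT, proportionality check and (when the LRT
    is informative) hazard contrasts.
    """
    alt = fit_cox(
        clinical, covariate, include_age_terms=include_age_terms,
        covariate_name=covariate_name, compositional=compositional,
    )
    null = fit_cox(
        clinical, None, include_age_terms=include_age_terms,
        restrict_to=alt.design.index,
    )
    stat, df, p = lrt_screen(null, alt)
    result = {
        "name": covariate_name,
        "lrt_stat": stat,
        "lrt_df": df,
        "p_lrt": p,
        "n": alt.n,
        "n_events": alt.n_events,
        "excluded_levels": alt.excluded_levels,
        "alt_fit": alt,
        "null_fit": null,
    }
    try:
        ph = ph_test(alt)
        result["ph_global_p"] = float(ph.loc["GLOBAL", "p"])
    except Exception as exc:  # pragma: no cover - defensive
        result["ph_global_p"] = np.nan
        result["ph_error"] = str(exc)
    try:
        result["contrasts"] = hazard_contrasts(alt)
    except ValueError:
        result["contrasts"] = None
    return result


def combined_screen(
    pdf_labels: pd.Series,
    dict_signatures: pd.DataFrame,
    clinical: pd.DataFrame,
    covariate_name: str = "index",
) -> dict:
    """LRT of the model carrying both heterogeneity representations.

    The alternative adds the PDF cluster labels (categorical) and the
    dictionary signature components (continuous, first component dropped)
    to the age + age^2 null; df is the total number of added parameters.
    Patients missing either representation are dropped.
    """
    common = pdf_labels.dropna().index.intersection(dict_signatures.dropna().index)
    if len(common) < 2:
        raise ValueError("need at least two patients with both representations")
    clin = clinical.set_index("patient_id") if "patient_id" in clinical.columns else clinical
    dropped = len(clin.index.difference(common))
    ev = clin["event"].astype(int)
    lab_df, excluded, keep_idx = _categorical_design(
        pdf_labels.loc[common], f"{covariate_name}_pdf", ev
    )
    sig = dict_signatures.loc[common].astype(float)
    sig = sig.iloc[:, 1:] if sig.shape[1] > 1 else sig
    sig = sig.rename(columns=lambda c: f"{covariate_name}_{c}")
    combined = lab_df.join(sig, how="inner")
    # the compositional drop already happened above; keep every column here
    result = screen_covariate(
        clin.reset_index(), combined, covariate_name=covariate_name,
        compositional=False,
    )
    result["n_dropped_missing"] = dropped
    result["excluded_levels"] = excluded
    return result


# ---------------------------------------------------------------------------
# cohort-level screen over indices x representations x k x preconditions
# ---------------------------------------------------------------------------


def _per_patch_profiles(stream: pd.DataFrame, index: str, min_nuclei: int = 5) -> np.ndarray:
    med = stream.groupby("patch")[index].agg(["median", "size"])
    med = med[med["size"] >= min_nuclei]
    return med["median"].to_numpy()


def _precondition_mask(clinical: pd.DataFrame, precondition: str) -> pd.Series:
    if precondition == "none":
        return pd.Series(True, index=clinical.index)
    kind, _, value = precondition.partition(":")
    if kind == "subtype":
        return clinical["subtype"] == value
    if kind == "egfr":
        strata = subtyping.stratify_egfr(clinical.set_index("patient_id")["egfr"])
        return clinical["patient_id"].map(strata) == value
    raise ValueError(f"unknown precondition {precondition!r}")


def run_screen(
    features: dict[str, pd.DataFrame],
    clinical: pd.DataFrame,
    indices: list[str] | None = None,
    representations: tuple[str, ...] = ("pdf", "dict", "combined"),
    ks: tuple[int, ...] = (2, 3, 4),
    preconditions: tuple[str, ...] = ("none",),
    n_bins: int = het.DEFAULT_BINS,
    dict_subsample: int = 1000,
    dict_repeats: int = 10,
    noise_sd_fraction: float = 0.05,
    seed: int = 0,
    min_patients: int = 20,
    min_events: int = 10,
) -> pd.DataFrame:
    """The biomarker screen: every index x representation x k x precondition.

    For each precondition the cohort is filtered and both representations
    are rebuilt on the subcohort (cohort bins, dictionaries and EMD linkage
    are all subcohort-specific).  Each row reports the age-adjusted LRT
    p-value plus proportionality and sample-size bookkeeping; subcohorts
    with too few patients or events are recorded as skipped.
    """
    if indices is None:
        sample = next(iter(features.values()))
        indices = [c for c in sample.columns if c != "patch"]
    rows = []
    for precondition in preconditions:
        mask = _precondition_mask(clinical, precondition)
        clin_sub = clinical[mask]
        pids = [p for p in clin_sub["patient_id"] if p in features]
        clin_sub = clin_sub[clin_sub["patient_id"].isin(pids)]
        n_events = int(clin_sub["event"].sum())
        if len(pids) < min_patients or n_events < min_events:
            rows.append(
                {"index": "*", "representation": "*", "k": np.nan,
                 "precondition": precondition, "p_lrt": np.nan,
                 "status": f"skipped: {len(pids)} patients / {n_events} events"}
            )
            continue
        for index in indices:
            pooled = np.concatenate([features[p][index].to_numpy() for p in pids])
            try:
                bins = het.build_cohort_bins(pooled, index=index, n_bins=n_bins)
            except ValueError as exc:
                rows.append(
                    {"index": index, "representation": "*", "k": np.nan,
                     "precondition": precondition, "p_lrt": np.nan,
                     "status": f"skipped: {exc}"}
                )
                continue
            pdfs = [
                het.patient_pdf(features[p][index].to_numpy(), bins, patient_id=p)
                for p in pids
            ]
            D = subtyping.pairwise_distances(pdfs, bin_width=bins.width)
            medians = pd.Series(
                {p: float(np.median(features[p][index])) for p in pids}
            )
            profiles_by_patient = {
                p: _per_patch_profiles(features[p], index) for p in pids
            }
            pooled_profiles = np.concatenate(
                [v for v in profiles_by_patient.values() if len(v)]
            )
            for k in ks:
                pdf_labels = None
                signatures = None
                if "pdf" in representations or "combined" in representations:
                    pdf_labels = subtyping.linkage_subtypes(D, k, order_values=medians)
                if "dict" in representations or "combined" in representations:
                    model = het.learn_dictionary(
                        pooled_profiles, k, index=index, subsample=dict_subsample,
                        repeats=dict_repeats, noise_sd_fraction=noise_sd_fraction,
                        seed=seed,
                    )
                    signatures = pd.DataFrame(
                        {
                            p: het.patient_signature(
                                profiles_by_patient[p], model.centroids, patient_id=p
                            )
                            for p in pids
                        }
                    ).T
                for rep in representations:
                    try:
                        if rep == "pdf":
                            res = screen_covariate(clin_sub, pdf_labels, covariate_name=index)
                        elif rep == "dict":
                            res = screen_covariate(clin_sub, signatures, covariate_name=index)
                        elif rep == "combined":
                            res = combined_screen(pdf_labels, signatures, clin_sub, covariate_name=index)
                        else:
                            raise ValueError(f"unknown representation {rep!r}")
                        rows.append(
                            {"index": index, "representation": rep, "k": k,
                             "precondition": precondition, "p_lrt": res["p_lrt"],
                             "lrt_stat": res["lrt_stat"], "lrt_df": res["lrt_df"],
                             "ph_global_p": res.get("ph_global_p", np.nan),
                             "n": res["n"], "n_events": res["n_events"],
                             "status": "ok"}
                        )
                    except Exception as exc:
                        rows.append(
                            {"index": index, "representation": rep, "k": k,
                             "precondition": precondition, "p_lrt": np.nan,
                             "status": f"failed: {exc}"}
                        )
    table = pd.DataFrame(rows)
    ok = table["p_lrt"].notna()
    table["p_bh"] = np.nan
    if ok.any():
        table.loc[ok, "p_bh"] = _benjamini_hochberg(table.loc[ok, "p_lrt"].to_numpy())
    return table


def _benjamini_hochberg(p: np.ndarray) -> np.ndarray:
    order = np.argsort(p)
    m = len(p)
    adj = np.empty(m)
    running = 1.0
    for rank_from_end, idx in enumerate(order[::-1]):
        rank = m - rank_from_end
        running = min(running, p[idx] * m / rank)
        adj[idx] = running
    return adj
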