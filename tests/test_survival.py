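"""Tests of the age-adjusted Cox screening machinery."""

import warnings

import numpy as np
import pandas as pd
import pytest

from morphoscreen.survival import (
    combined_screen,
    fit_cox,
    hazard_contrasts,
    km_estimate,
    lrt_screen,
    ph_test,
    run_screen,
    screen_covariate,
)
from morphoscreen.synthetic import SyntheticCohortSpec, generate_cohort

warnings.filterwarnings("ignore", category=UserWarning)


def _cohort(n=200, beta_subtype=0.0, seed=0, **kw):
    spec = SyntheticCohortSpec(
        n_patients=n, beta_subtype=beta_subtype, seed=seed,
        patches_per_patient=1, nuclei_per_patch=1, **kw,
    )
    return generate_cohort(spec)[0]


class TestKaplanMeier:
    def test_closed_form_no_censoring(self):
        curves, _ = km_estimate([1.0, 2.0, 3.0], [1, 1, 1], ["g", "g", "g"])
        surv = curves["g"].iloc[:, 0]
        assert np.allclose(surv.loc[[1.0, 2.0, 3.0]], [2 / 3, 1 / 3, 0.0])

    def test_all_censored_curve_is_one(self):
        curves, _ = km_estimate([1.0, 2.0, 3.0, 4.0], [0, 0, 0, 1],
                                ["g", "g", "g", "g"])
        assert (curves["g"].iloc[:, 0].iloc[:-1] >= 1.0 - 1e-12).all()

    def test_identical_groups_logrank_large_p(self):
        rng = np.random.default_rng(0)
        t = rng.exponential(100, 200)
        groups = np.tile(["a", "b"], 100)
        _, p = km_estimate(t, np.ones(200, dtype=int), groups)
        assert p > 0.05


class TestFitCox:
    def test_constant_covariate_collapses_to_null(self):
        clinical = _cohort(n=100, seed=1)
        const = pd.DataFrame(
            {"c": np.ones(len(clinical))}, index=clinical["patient_id"]
        )
        with pytest.warns(UserWarning, match="zero-variance"):
            alt = fit_cox(clinical, const, compositional=False)
        null = fit_cox(clinical, None)
        stat, df, p = lrt_screen(null, alt)
        assert stat == 0.0 and df == 0 and p == 1.0

    def test_beta_age_recovery(self):
        # true log-hazard slope of 0.08/yr recovered within +-2 SE in >=90%
        hits = 0
        for r in range(100):
            clinical = _cohort(n=300, seed=100 + r, beta_age=0.08)
            fit = fit_cox(clinical, None)
            se = np.sqrt(fit.cov.loc["age_c", "age_c"])
            hits += abs(fit.params["age_c"] - 0.08) <= 2 * se
        assert hits >= 90

    def test_cluster_relabeling_preserves_lrt(self):
        clinical = _cohort(n=150, beta_subtype=0.6, seed=2)
        labels = pd.Series(
            clinical["true_subtype"].to_numpy(), index=clinical["patient_id"]
        )
        p1 = screen_covariate(clinical, labels)["p_lrt"]
        p2 = screen_covariate(clinical, 1 - labels)["p_lrt"]
        assert p1 == pytest.approx(p2, rel=1e-6)

    def test_nonpositive_times_dropped(self):
        clinical = _cohort(n=100, seed=3)
        clinical.loc[clinical.index[:5], "time"] = 0.0
        with pytest.warns(UserWarning, match="time <= 0"):
            fit = fit_cox(clinical, None)
        assert fit.n == len(clinical) - 5

    def test_level_without_events_excluded(self):
        clinical = _cohort(n=120, seed=4)
        labels = pd.Series(0, index=clinical["patient_id"])
        labels.iloc[:40] = 1
        labels.iloc[40:50] = 2
        clinical = clinical.set_index("patient_id")
        clinical.loc[labels[labels == 2].index, "event"] = 0
        fit = fit_cox(clinical.reset_index(), labels)
        assert fit.excluded_levels == [2]
        assert fit.n == 110


class TestPhTest:
    def test_too_few_events_raise(self):
        clinical = _cohort(n=60, seed=5)
        fit = fit_cox(clinical, None)
        fit.n_events = 2
        with pytest.raises(ValueError, match="3 events"):
            ph_test(fit)

    def test_proportional_data_calibrated(self):
        # under a proportional (linear-age) hazard the PH p-values are not
        # systematically small
        small = 0
        for r in range(40):
            clinical = _cohort(n=200, seed=600 + r, beta_age=0.05)
            fit = fit_cox(clinical, None)
            table = ph_test(fit)
            small += table.loc["age_c", "p"] < 0.05
        assert small <= 6


class TestLrt:
    def test_non_nested_rejected(self):
        clinical = _cohort(n=100, seed=6)
        labels = pd.Series(
            clinical["true_subtype"].to_numpy(), index=clinical["patient_id"]
        )
        alt = fit_cox(clinical, labels)
        null_other = fit_cox(clinical.iloc[:80], None)
        with pytest.raises(ValueError, match="different cohorts"):
            lrt_screen(null_other, alt)

    def test_planted_effect_detected(self):
        clinical = _cohort(n=200, beta_subtype=0.7, seed=7)
        labels = pd.Series(
            clinical["true_subtype"].to_numpy(), index=clinical["patient_id"]
        )
        res = screen_covariate(clinical, labels)
        assert res["p_lrt"] < 0.01


class TestContrasts:
    def test_two_level_pairwise_equals_wald(self):
        clinical = _cohort(n=200, beta_subtype=0.6, seed=8)
        labels = pd.Series(
            clinical["true_subtype"].to_numpy(), index=clinical["patient_id"]
        )
        fit = fit_cox(clinical, labels)
        table = hazard_contrasts(fit)
        level_rows = table[table["kind"] == "level"]
        assert len(level_rows) == 1
        b = fit.params.drop(["age_c", "age_c2"]).iloc[0]
        se = np.sqrt(np.diag(fit.cov))[list(fit.params.index).index(
            level_rows.iloc[0]["a"])]
        from scipy import stats as ss
        assert level_rows.iloc[0]["p"] == pytest.approx(
            2 * ss.norm.sf(abs(b) / se), rel=1e-9
        )

    def test_ci_excludes_one_iff_significant(self):
        clinical = _cohort(n=250, beta_subtype=0.5, seed=9)
        labels = pd.Series(
            clinical["true_subtype"].to_numpy(), index=clinical["patient_id"]
        )
        table = hazard_contrasts(fit_cox(clinical, labels))
        for _, row in table.iterrows():
            excludes = row["ci_lo"] > 1.0 or row["ci_hi"] < 1.0
            assert excludes == (row["p"] < 0.05)

    def test_re_reference_oracle(self):
        # the pairwise contrast between levels 1 and 2 equals the Wald test
        # of level 2 when level 1 is made the reference
        rng = np.random.default_rng(10)
        clinical = _cohort(n=240, seed=10)
        labels = pd.Series(
            rng.integers(0, 3, len(clinical)), index=clinical["patient_id"]
        )
        fit = fit_cox(clinical, labels)
        table = hazard_contrasts(fit)
        pair = table[(table["kind"] == "pairwise")].iloc[0]
        relabeled = labels.map({0: 2, 1: 0, 2: 1})  # old level 1 -> reference
        refit = fit_cox(clinical, relabeled)
        reref = hazard_contrasts(refit)
        match = reref[(reref["kind"] == "level") & (reref["a"] == "index[1]")]
        assert pair["p"] == pytest.approx(float(match["p"].iloc[0]), abs=1e-6)


class TestCombined:
    def test_single_patient_overlap_errors(self):
        clinical = _cohort(n=60, seed=11)
        pids = clinical["patient_id"]
        labels = pd.Series(0, index=pids[:1])
        sigs = pd.DataFrame(np.ones((1, 2)), index=pids[:1], columns=["a0", "a1"])
        with pytest.raises(ValueError, match="two patients"):
            combined_screen(labels, sigs, clinical)

    def test_combined_model_retains_dictionary_signal(self):
        # when only the dictionary signature carries signal, adding an
        # uninformative PDF clustering costs one df but the combined model
        # still detects the effect in most replicates
        detected = 0
        reps = 25
        rng = np.random.default_rng(12)
        for r in range(reps):
            clinical = _cohort(n=150, beta_subtype=0.8, seed=700 + r)
            idx = clinical["patient_id"]
            truth = clinical["true_subtype"].to_numpy()
            sig0 = np.where(truth == 1, 0.7, 0.3) + rng.normal(0, 0.05, len(idx))
            sigs = pd.DataFrame({"a0": sig0, "a1": 1 - sig0}, index=idx)
            noise_labels = pd.Series(rng.integers(0, 2, len(idx)), index=idx)
            detected += combined_screen(noise_labels, sigs, clinical)["p_lrt"] < 0.05
        assert detected / reps >= 0.8


class TestRunScreen:
    def test_unstratified_screen_detects_planted_index(self):
        # strong planted effect (log-HR 1.2 between subtypes differing in
        # mean HOD) so detection is near-certain at n = 100
        spec = SyntheticCohortSpec(n_patients=100, beta_subtype=1.2, seed=0)
        clinical, features = generate_cohort(spec)
        table = run_screen(
            features, clinical, indices=["mean_hod", "eccentricity"],
            representations=("pdf", "dict"), ks=(2,), seed=0,
        )
        ok = table[table["status"] == "ok"]
        hod = ok[(ok["index"] == "mean_hod")]
        ecc = ok[(ok["index"] == "eccentricity")]
        assert (hod["p_lrt"] < 0.05).any()
        assert not ecc.empty  # null index still screened, just not required to fire

    def test_small_subcohort_skipped(self, small_cohort):
        _, clinical, features = small_cohort
        clin = clinical.copy()
        clin["subtype"] = "mesenchymal"
        clin.loc[clin.index[:5], "subtype"] = "neural"
        table = run_screen(
            features, clin, indices=["mean_hod"], representations=("pdf",),
            ks=(2,), preconditions=("subtype:neural",), seed=0,
        )
        assert table["status"].str.startswith("skipped").all()

    def test_disjoint_preconditions_partition_patients(self, small_cohort):
        _, clinical, features = small_cohort
        clinical = clinical.copy()
        # bimodal expression so both strata clear the minimum-size gate
        rng = np.random.default_rng(1)
        clinical["egfr"] = np.where(
            np.arange(len(clinical)) % 2, rng.normal(10, 0.5, len(clinical)),
            rng.normal(2, 0.3, len(clinical)),
        )
        table = run_screen(
            features, clinical, indices=["mean_hod"], representations=("pdf",),
            ks=(2,), preconditions=("egfr:high", "egfr:low"), seed=0,
        )
        ok = table[table["status"] == "ok"]
        ns = ok.groupby("precondition")["n"].first()
        assert ns.sum() == len(clinical)
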