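"""Tests of the synthetic patch, stain and cohort generators."""

import numpy as np
import pandas as pd
import pytest
from scipy import stats

from morphoscreen import stainnorm
from morphoscreen.synthetic import (
    StainModel,
    SyntheticCohortSpec,
    add_pen_mark,
    default_target_stain,
    generate_cohort,
    generate_nuclei_patch,
    perturbed_stain_model,
    render_he_patch,
)


class TestNucleiPatch:
    def test_empty_patch(self):
        mask, truth = generate_nuclei_patch(0, seed=0)
        assert mask.max() == 0
        assert truth.empty

    def test_label_count_matches_request(self):
        mask, truth = generate_nuclei_patch(10, seed=1)
        labels = np.unique(mask)
        assert set(labels) == set(range(11))
        assert len(truth) == 10

    def test_circle_closed_form(self):
        mask, truth = generate_nuclei_patch(
            1, shape_params={"semi_minor": (10, 10), "aspect": (1.0, 1.0)}, seed=2
        )
        row = truth.iloc[0]
        assert row["eccentricity"] == 0.0
        assert row["solidity"] == 1.0
        assert row["area"] == pytest.approx(100 * np.pi, rel=1e-9)
        # rasterized pixel count agrees with the analytic area within 3%
        assert (mask > 0).sum() == pytest.approx(100 * np.pi, rel=0.03)

    def test_ellipse_eccentricity_vs_moment_oracle(self):
        # closed form e = sqrt(1 - b^2/a^2) for (a, b) = (20, 10)
        mask, truth = generate_nuclei_patch(
            1,
            shape_params={"semi_minor": (10, 10), "aspect": (2.0, 2.0)},
            seed=3,
            patch_shape=(128, 128),
        )
        assert truth["eccentricity"].iloc[0] == pytest.approx(np.sqrt(0.75), abs=1e-12)
        # independent oracle: eccentricity from raw second central moments
        ys, xs = np.nonzero(mask)
        cov = np.cov(np.stack([ys, xs]))
        evals = np.sort(np.linalg.eigvalsh(cov))
        e_oracle = np.sqrt(1.0 - evals[0] / evals[1])
        assert e_oracle == pytest.approx(np.sqrt(0.75), abs=0.02)

    def test_overcrowding_raises(self):
        with pytest.raises(RuntimeError, match="density"):
            generate_nuclei_patch(
                500,
                shape_params={"semi_minor": (8, 10), "aspect": (1.0, 1.5)},
                seed=4,
                patch_shape=(96, 96),
            )

    def test_same_seed_bitwise_identical(self):
        m1, t1 = generate_nuclei_patch(8, seed=7)
        m2, t2 = generate_nuclei_patch(8, seed=7)
        assert np.array_equal(m1, m2)
        pd.testing.assert_frame_equal(t1, t2)


class TestStainModel:
    def test_collinear_columns_rejected(self):
        w = np.array([[0.6], [0.7], [0.3]])
        W = np.hstack([w, w * 1.0])
        W = W / np.linalg.norm(W, axis=0)
        with pytest.raises(ValueError, match="collinear"):
            StainModel(stain_matrix=W, max_concentration=np.array([1.0, 1.0]))

    def test_non_unit_columns_rejected(self):
        W = default_target_stain().stain_matrix * 2
        with pytest.raises(ValueError, match="unit norm"):
            StainModel(stain_matrix=W, max_concentration=np.array([1.0, 1.0]))


class TestRender:
    def test_zero_hod_gives_uniform_near_background(self):
        mask = np.zeros((64, 64), dtype=np.uint16)
        rgb = render_he_patch(mask, default_target_stain(), np.zeros(0), noise_sd=0.0,
                              eosin_background=0.0)
        assert np.all(rgb == 255)

    def test_od_round_trip(self):
        mask, _ = generate_nuclei_patch(6, seed=5)
        model = default_target_stain()
        hod = np.linspace(0.3, 0.9, 6)
        rgb = render_he_patch(mask, model, hod, noise_sd=0.0)
        od = stainnorm.rgb_to_od(rgb)
        # forward OD field (no noise) for comparison
        lut = np.zeros(7)
        lut[1:] = hod
        C = np.stack([lut[mask].ravel(),
                      np.where(mask.ravel() > 0, 0.05, 0.15)])
        od_true = model.stain_matrix @ C
        # quantization to 8 bits: OD error bounded by d(OD)/dI * 0.5 at I>=25
        assert np.abs(od - od_true).max() < 0.02

    def test_noise_sd_monte_carlo(self):
        mask = np.zeros((128, 128), dtype=np.uint16)
        model = default_target_stain()
        rgb = render_he_patch(mask, model, np.zeros(0), noise_sd=0.02, seed=11,
                              eosin_background=0.3)
        od = stainnorm.rgb_to_od(rgb)
        od_true = (model.stain_matrix @ np.stack([np.zeros(128 * 128), np.full(128 * 128, 0.3)]))
        err_sd = (od - od_true).std()
        assert err_sd == pytest.approx(0.02, rel=0.2)

    def test_rejects_invalid_inputs(self):
        mask, _ = generate_nuclei_patch(2, seed=6)
        with pytest.raises(ValueError):
            render_he_patch(mask, default_target_stain(), [-0.1, 0.5])


class TestPenMark:
    def test_stroke_pixels_and_flag(self):
        patch = np.full((224, 224, 3), 200, dtype=np.uint8)
        color = (10, 20, 200)
        marked, flag = add_pen_mark(patch, color=color, stroke_width=5, seed=1)
        assert flag is True
        changed = np.any(marked != patch, axis=2)
        assert changed.any()
        assert np.all(marked[changed] == np.array(color))
        assert np.all(marked[~changed] == 200)

    def test_altered_fraction_monotone_in_width(self):
        patch = np.full((224, 224, 3), 200, dtype=np.uint8)
        fractions = []
        for width in (1, 4, 10, 20):
            marked, _ = add_pen_mark(patch, stroke_width=width, seed=3)
            fractions.append(np.any(marked != patch, axis=2).mean())
        assert all(a < b for a, b in zip(fractions, fractions[1:]))


class TestCohort:
    def test_censor_rate_zero_all_events(self):
        spec = SyntheticCohortSpec(n_patients=50, censor_rate=0.0, seed=1,
                                   patches_per_patient=1, nuclei_per_patch=1)
        clinical, _ = generate_cohort(spec)
        assert (clinical["event"] == 1).all()

    def test_same_seed_identical(self):
        spec = SyntheticCohortSpec(n_patients=20, seed=9)
        c1, f1 = generate_cohort(spec)
        c2, f2 = generate_cohort(spec)
        pd.testing.assert_frame_equal(c1, c2)
        for pid in f1:
            pd.testing.assert_frame_equal(f1[pid], f2[pid])

    def test_null_subtype_logrank_uniform(self):
        # with no planted effect the logrank p over replicates is U(0, 1)
        from lifelines.statistics import multivariate_logrank_test

        pvals = []
        for r in range(200):
            spec = SyntheticCohortSpec(
                n_patients=60, beta_subtype=0.0, beta_age=0.0, seed=5000 + r,
                patches_per_patient=1, nuclei_per_patch=1,
            )
            clinical, _ = generate_cohort(spec)
            res = multivariate_logrank_test(
                clinical["time"], clinical["true_subtype"], clinical["event"]
            )
            pvals.append(res.p_value)
        ks = stats.kstest(pvals, "uniform")
        assert ks.pvalue > 0.01

    def test_feature_streams_follow_subtype_distributions(self):
        spec = SyntheticCohortSpec(n_patients=60, seed=3)
        clinical, features = generate_cohort(spec)
        means = {
            st: np.concatenate(
                [features[p]["mean_hod"] for p in clinical[clinical.true_subtype == st].patient_id]
            ).mean()
            for st in (0, 1)
        }
        assert means[1] - means[0] == pytest.approx(0.1, abs=0.02)

    def test_degenerate_hazard_raises(self):
        spec = SyntheticCohortSpec(n_patients=10, seed=2, baseline_rate=1e12,
                                   patches_per_patient=1, nuclei_per_patch=1)
        with pytest.raises(ValueError, match="degenerate"):
            generate_cohort(spec)


def test_perturbed_stain_model_stays_valid():
    base = default_target_stain()
    for s in range(10):
        model = perturbed_stain_model(base, 0.08, seed=s)
        model.validate()
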