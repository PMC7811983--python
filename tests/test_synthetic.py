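"""Synthetic cohort generators: determinism, monotone coupling, bookkeeping."""

import numpy as np
import pytest

from strokeqeeg import (
    CohortConfig,
    SeverityProfile,
    bandpass_filter,
    classify_core_penumbra,
    extract_features,
    generate_cohort,
    generate_eeg,
    generate_lesion_volume,
    generate_outcomes,
    generate_perfusion_maps,
    inject_artifacts,
    scalp_average,
    select_clean_segment,
    spearman,
)


class TestSeverityProfile:
    def test_gain_monotonicity_across_severity(self):
        severities = np.linspace(0, 1, 11)
        profiles = [SeverityProfile.from_severity(s) for s in severities]
        alpha = [p.alpha_gain for p in profiles]
        delta = [p.delta_gain for p in profiles]
        assert all(a >= b for a, b in zip(alpha, alpha[1:]))
        assert all(a <= b for a, b in zip(delta, delta[1:]))

    def test_severity_out_of_range_rejected(self):
        with pytest.raises(ValueError):
            SeverityProfile.from_severity(1.5)


class TestGenerateEEG:
    def _scalp(self, severity, seed=21):
        profile = SeverityProfile.from_severity(severity)
        rec = generate_eeg(profile, duration_s=130.0, seed=seed)
        seg = select_clean_segment(bandpass_filter(rec), target_s=120.0)
        return scalp_average(extract_features(seg))

    def test_healthy_spectrum_alpha_dominant(self):
        scalp = self._scalp(0.0)
        assert scalp.rel_alpha > scalp.rel_delta

    def test_dar_increases_with_severity_same_seed(self):
        assert self._scalp(1.0).dar > self._scalp(0.0).dar

    def test_same_seed_bit_identical(self):
        profile = SeverityProfile.from_severity(0.5)
        a = generate_eeg(profile, duration_s=20.0, seed=9)
        b = generate_eeg(profile, duration_s=20.0, seed=9)
        np.testing.assert_array_equal(a.samples, b.samples)

    def test_labels_and_shape(self):
        rec = generate_eeg(SeverityProfile.from_severity(0.2), duration_s=20.0, seed=0)
        assert rec.n_channels == 19
        assert rec.channel_labels[:2] == ("Fp1", "Fp2")
        assert rec.n_samples == 20 * 128

    def test_invalid_duration_and_fs_rejected(self):
        p = SeverityProfile.from_severity(0.2)
        with pytest.raises(ValueError):
            generate_eeg(p, duration_s=5.0)
        with pytest.raises(ValueError):
            generate_eeg(p, duration_s=20.0, fs=32.0)


class TestInjectArtifacts:
    def test_zero_rate_is_identity(self):
        rec = generate_eeg(SeverityProfile.from_severity(0.4), duration_s=30.0, seed=2)
        out, flagged = inject_artifacts(rec, 0.0, seed=3)
        assert flagged == ()
        np.testing.assert_array_equal(out.samples, rec.samples)

    def test_rate_one_third_contaminates_about_a_third(self):
        rec = generate_eeg(SeverityProfile.from_severity(0.4), duration_s=300.0, seed=2)
        _, flagged = inject_artifacts(rec, 0.3, seed=3)
        assert 3 <= len(flagged) <= 16  # ~9 of 30 epochs

    def test_fixed_seed_reproduces_contamination_set(self):
        rec = generate_eeg(SeverityProfile.from_severity(0.4), duration_s=100.0, seed=2)
        _, f1 = inject_artifacts(rec, 0.4, seed=8)
        _, f2 = inject_artifacts(rec, 0.4, seed=8)
        assert f1 == f2

    def test_rate_one_rejected(self):
        rec = generate_eeg(SeverityProfile.from_severity(0.4), duration_s=30.0, seed=2)
        with pytest.raises(ValueError):
            inject_artifacts(rec, 1.0)


class TestGenerateOutcomes:
    def test_zero_severity_noise_free_all_zero(self):
        o = generate_outcomes(0.0, noise_sd=0.0, volume_scale=116.0, seed=0)
        assert (o.nihss_admission, o.nihss_7d, o.nihss_12m) == (0, 0, 0)
        assert o.mrs_12m == 0 and o.final_volume_ml == 0.0

    def test_max_severity_noise_free_hits_scale_ceiling(self):
        o = generate_outcomes(1.0, noise_sd=0.0, volume_scale=116.0, seed=0)
        assert o.nihss_admission == 42
        assert o.mrs_12m == 6  # worst configured class

    def test_severity_strongly_correlates_with_7day_nihss(self):
        severities = np.linspace(0.02, 0.98, 50)
        nihss = [
            generate_outcomes(s, noise_sd=0.5, volume_scale=116.0, seed=i).nihss_7d
            for i, s in enumerate(severities)
        ]
        assert spearman(severities, np.array(nihss, float)).rho > 0.9

    def test_noise_free_outcomes_monotone_in_severity(self):
        outs = [
            generate_outcomes(s, noise_sd=0.0, volume_scale=116.0, seed=0)
            for s in np.linspace(0, 1, 21)
        ]
        for field in ("nihss_admission", "nihss_7d", "nihss_12m", "mrs_12m",
                      "final_volume_ml"):
            vals = [getattr(o, field) for o in outs]
            assert all(a <= b for a, b in zip(vals, vals[1:])), field


class TestGenerateLesionVolume:
    def test_zero_volume_empty_mask(self):
        vol = generate_lesion_volume(0.0, seed=1)
        assert vol.mask.sum() == 0

    def test_median_cohort_volume_voxel_count(self):
        # 4.6 ml on a 1 mm isotropic grid → exactly 4600 inserted voxels
        vol = generate_lesion_volume(
            4.6, grid_shape=(100, 100, 100), spacing=(1, 1, 1), seed=4
        )
        assert vol.mask.sum() == 4600

    def test_ground_truth_bookkeeping_exact(self):
        vol = generate_lesion_volume(10.0, seed=5)
        recorded = vol.mask.sum() * vol.voxel_volume_mm3 / 1000.0
        assert recorded == pytest.approx(10.0, rel=0.001)

    def test_different_seeds_same_volume_different_shape(self):
        a = generate_lesion_volume(8.0, seed=1)
        b = generate_lesion_volume(8.0, seed=2)
        assert a.mask.sum() == b.mask.sum()
        assert not np.array_equal(a.mask, b.mask)

    def test_lesion_confined_to_one_side_of_midline(self):
        vol = generate_lesion_volume(50.0, seed=3, midline_axis=0)
        half = vol.mask.shape[0] // 2
        assert vol.mask[:half].sum() == 0

    def test_oversized_lesion_rejected(self):
        with pytest.raises(ValueError, match="does not fit"):
            generate_lesion_volume(500.0, grid_shape=(32, 32, 32), spacing=(1, 1, 1))

    def test_lesion_intensity_separated_from_background(self):
        vol = generate_lesion_volume(10.0, seed=6)
        assert vol.voxels[vol.mask].min() > 70.0
        assert vol.voxels[~vol.mask].max() < 70.0


class TestGeneratePerfusionMaps:
    def test_core_fraction_extremes_via_classifier(self):
        lesion = generate_lesion_volume(20.0, seed=7)
        all_penumbra = classify_core_penumbra(
            generate_perfusion_maps(lesion, core_fraction=0.0, seed=8)
        )
        assert all_penumbra.core_ml == 0.0
        assert all_penumbra.total_hypoperfused_ml > 0
        all_core = classify_core_penumbra(
            generate_perfusion_maps(lesion, core_fraction=1.0, seed=8)
        )
        assert all_core.penumbra_ml == 0.0
        assert all_core.core_ml == pytest.approx(
            all_penumbra.total_hypoperfused_ml
        )

    def test_empty_lesion_nothing_hypoperfused(self):
        lesion = generate_lesion_volume(0.0, seed=9)
        res = classify_core_penumbra(generate_perfusion_maps(lesion, 0.5, seed=9))
        assert res.total_hypoperfused_ml == 0.0

    def test_hypoperfused_region_equals_lesion(self):
        lesion = generate_lesion_volume(15.0, seed=10)
        maps = generate_perfusion_maps(lesion, 0.4, seed=11)
        res = classify_core_penumbra(maps)
        np.testing.assert_array_equal(
            res.core_mask | res.penumbra_mask, lesion.mask
        )


class TestGenerateCohort:
    def test_cohort_is_deterministic_and_consistent(self):
        cfg = CohortConfig(n_patients=3, duration_s=130.0, artifact_rate=0.0, seed=5)
        a = generate_cohort(cfg)
        b = generate_cohort(cfg)
        assert [p.patient_id for p in a] == ["P001", "P002", "P003"]
        for pa, pb in zip(a, b):
            np.testing.assert_array_equal(pa.recording.samples, pb.recording.samples)
            assert pa.outcomes == pb.outcomes
            # volume bookkeeping: mask voxels × voxel volume = recorded truth
            assert pa.true_volume_ml == pytest.approx(
                pa.volume_image.mask.sum() * pa.volume_image.voxel_volume_mm3 / 1000.0
            )

    def test_config_validation(self):
        with pytest.raises(ValueError):
            CohortConfig(n_patients=1)
        with pytest.raises(ValueError):
            CohortConfig(duration_s=100.0)
        with pytest.raises(ValueError):
            CohortConfig(fs=50.0)
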