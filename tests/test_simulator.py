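"""Cohort generation, artifacts and QC, and the speckle forward model."""

import numpy as np
import pytest
from scipy.ndimage import gaussian_filter
from scipy.stats import spearmanr

from palsyflow.errors import ValidationError
from palsyflow.perfusion_features import regional_mean_flow
from palsyflow.simulator import (
    SimulationConfig,
    build_synthetic_model,
    inject_motion_artifact,
    perfusion_multiplier,
    qc_filter,
    render_blood_frame,
    simulate_cohort,
    speckle_forward,
    true_label_image,
)


class TestBuildSyntheticModel:
    def test_deterministic_per_seed(self):
        a = build_synthetic_model(600, 4, seed=5)
        b = build_synthetic_model(600, 4, seed=5)
        assert np.array_equal(a.mean_shape, b.mean_shape)
        assert np.array_equal(a.basis, b.basis)
        assert np.array_equal(a.landmark_corr, b.landmark_corr)

    def test_basis_columns_orthonormal(self, model):
        gram = model.basis.T @ model.basis
        assert np.abs(gram - np.eye(model.n_components)).max() < 1e-10

    def test_different_seeds_differ(self):
        a = build_synthetic_model(600, 4, seed=1)
        b = build_synthetic_model(600, 4, seed=2)
        assert not np.array_equal(a.basis, b.basis)


class TestPerfusionMultiplier:
    def test_healthy_grade_is_symmetric(self):
        assert perfusion_multiplier(1, 0.09) == 1.0

    def test_grade_six_closed_form(self):
        m = perfusion_multiplier(6, 0.09)
        assert m == pytest.approx(0.55)
        assert 1.0 / m == pytest.approx(1.8181818, rel=1e-6)

    def test_strictly_decreasing_in_grade(self):
        for delta in (0.01, 0.09, 0.15):
            ms = [perfusion_multiplier(g, delta) for g in range(1, 7)]
            assert np.all(np.diff(ms) < 0)

    def test_nonpositive_multiplier_rejected(self):
        with pytest.raises(ValidationError):
            perfusion_multiplier(6, 0.21)


class TestSimulateCohort:
    def test_default_composition_counts(self):
        config = SimulationConfig(seed=3)
        assert config.n_patients == 80
        cohort = simulate_cohort(config)
        assert len(cohort.records) == 80
        assert cohort.n_frames == 8000
        by_grade = np.bincount([r.hb_grade for r in cohort.records], minlength=7)[1:]
        assert tuple(by_grade) == (8, 17, 16, 13, 16, 10)

    def test_same_seed_reproduces_flux_tables(self, small_config):
        a = simulate_cohort(small_config)
        b = simulate_cohort(small_config)
        for ra, rb in zip(a.records, b.records):
            assert np.array_equal(ra.frame_flux, rb.frame_flux)
            assert np.array_equal(ra.camera.C, rb.camera.C)

    def test_grade_one_patients_use_right_side(self, default_cohort):
        assert all(
            r.ill_side == "R" for r in default_cohort.records if r.hb_grade == 1
        )

    def test_flux_tables_positive(self, small_cohort):
        for r in small_cohort.records:
            assert r.frame_flux.min() > 0
            assert np.isfinite(r.frame_flux).all()

    def test_rendered_frame_positive_and_matches_flux_table(self, small_cohort):
        """Regional means measured on a rendered raster agree with the
        generating flux table (rendering adds only blur and pixel noise)."""
        cohort = small_cohort
        record = cohort.records[0]
        frame = render_blood_frame(cohort.model, record, 0, cohort.config)
        assert frame.min() > 0
        truth = true_label_image(cohort.model, record, cohort.config)
        means = regional_mean_flow(frame, truth)
        for i, region in enumerate(range(1, 8)):
            for j, side in enumerate(("L", "R")):
                measured = means[(region, side)]
                expected = record.frame_flux[0, i, j]
                assert abs(measured / expected - 1.0) < 0.25

    def test_rendering_is_reproducible(self, small_cohort):
        cohort = small_cohort
        a = render_blood_frame(cohort.model, cohort.records[1], 3, cohort.config)
        b = render_blood_frame(cohort.model, cohort.records[1], 3, cohort.config)
        assert np.array_equal(a, b)


class TestArtifactsAndQC:
    def test_amplitude_doubles_mean_before_blur(self, rng):
        frame = rng.uniform(0.5, 2.0, size=(32, 32))
        out = inject_motion_artifact(frame, 2.0, blur_sigma=0.0)
        assert out.mean() == pytest.approx(2.0 * frame.mean())

    def test_artifact_mean_exceeds_clean_mean(self, rng):
        frame = rng.uniform(0.5, 2.0, size=(32, 32))
        assert inject_motion_artifact(frame, 1.5).mean() > frame.mean()

    def test_amplitude_at_or_below_one_rejected(self, rng):
        with pytest.raises(ValidationError, match="amplitude"):
            inject_motion_artifact(np.ones((8, 8)), 1.0)

    def test_qc_flags_exactly_the_injected_frames(self):
        rng = np.random.default_rng(42)
        clean = [np.full((16, 16), 1.0) * f for f in rng.lognormal(0, 0.1, 100)]
        frames = clean[:95] + [inject_motion_artifact(c, 2.0) for c in clean[95:]]
        kept, flagged = qc_filter(frames, 3.0)
        assert list(flagged) == [95, 96, 97, 98, 99]
        assert len(kept) == 95

    def test_clean_frames_rarely_flagged(self):
        rng = np.random.default_rng(2718)
        frames = [np.full((16, 16), 1.0) * f for f in rng.lognormal(0, 0.1, 100)]
        _, flagged = qc_filter(frames, 3.0)
        assert len(flagged) <= 2

    def test_constant_frames_none_flagged(self, caplog):
        import logging

        with caplog.at_level(logging.WARNING, logger="palsyflow.simulator"):
            kept, flagged = qc_filter([np.ones((8, 8))] * 10, 3.0)
        assert len(flagged) == 0 and len(kept) == 10
        assert any("dispersion" in rec.message for rec in caplog.records)

    def test_fewer_than_five_frames_rejected(self):
        with pytest.raises(ValidationError, match="at least 5"):
            qc_filter([np.ones((4, 4))] * 4)


class TestSpeckleForward:
    def test_uniform_flow_gives_uniform_contrast(self):
        flow = np.full((256, 256), 2.0)
        _, K, _ = speckle_forward(flow, window=7, seed=1)
        interior = K[8:-8, 8:-8]
        assert interior.std() / interior.mean() < 0.05
        assert abs(interior.mean() - 1 / np.sqrt(3.0)) < 0.05

    def test_higher_flow_lowers_contrast(self):
        flow = np.full((128, 128), 1.0)
        flow[:, 64:] = 6.0
        _, K, _ = speckle_forward(flow, window=7, seed=2)
        assert K[8:-8, 8:56].mean() > K[8:-8, 72:-8].mean()

    def test_inverse_square_contrast_tracks_flow(self):
        """Rank correlation between 1/K^2 and true flow on a smooth field."""
        rng = np.random.default_rng(3)
        g = gaussian_filter(rng.normal(size=(256, 256)), 12)
        g = (g - g.mean()) / g.std()
        flow = 2.0 * np.exp(0.8 * g)
        _, _, flow_est = speckle_forward(flow, window=7, seed=4)
        b = 8
        rc = spearmanr(flow_est[b:-b, b:-b].ravel(), flow[b:-b, b:-b].ravel()).statistic
        assert rc > 0.95

    def test_nonpositive_flow_rejected(self):
        with pytest.raises(ValidationError, match="positive"):
            speckle_forward(np.zeros((16, 16)) - 1.0)

    def test_even_window_rejected(self):
        with pytest.raises(ValidationError, match="odd"):
            speckle_forward(np.ones((16, 16)), window=6)
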