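import numpy as np
import pytest

from nirsmap import indices, mapping, preprocess, stats, synthetic
from nirsmap.types import RawSpectrum, RelativeSpectrum, ValidationError

from .conftest import make_conditioned


class TestForwardModel:
    def test_truth_recovered_by_calibration(self, rng, optics):
        """calibrate() applied to noiseless counts returns the ground-truth
        relative reflectance exactly."""
        quiet = synthetic.TissueOpticsParams(noise_sd=0.0)
        cal = synthetic.simulate_calibration(quiet, rng)
        raw, truth = synthetic.simulate_spectrum("lesion", quiet, rng=rng)
        wl, rel = preprocess.calibrate(raw, cal)
        np.testing.assert_allclose(rel, truth, rtol=1e-10)

    def test_reflectance_positive_and_finite(self, rng, optics):
        counts, truth = synthetic.simulate_spectra_batch(
            rng.random(30) < 0.5,
            rng.random(30) < 0.8,
            rng.uniform(0, 60, 30),
            "blood",
            optics,
            rng,
        )
        assert np.all(np.isfinite(counts)) and np.all(counts >= 0)
        assert np.all(truth > 0)

    def test_lesion_changes_morphology(self, rng):
        quiet = synthetic.TissueOpticsParams(
            noise_sd=0.0, power_sample_sd=0.0,
            bands=tuple(
                synthetic.Band(b.center, b.width, b.strength, b.lesion_delta, 0.0, 0.0)
                for b in synthetic.TissueOpticsParams().bands
            ),
        )
        _, t_les = synthetic.simulate_spectrum("lesion", quiet, rng=rng)
        _, t_non = synthetic.simulate_spectrum("nonlesion", quiet, rng=rng)
        ratio = t_les / t_non
        assert np.ptp(ratio) > 0.01  # not a pure intensity scale

    def test_angle_is_pure_intensity_scale_by_default(self, rng):
        """With angle_effect=0 the contact angle multiplies intensity by
        cos(angle) and leaves spectral shape (hence Rrel) unchanged."""
        quiet = synthetic.TissueOpticsParams(noise_sd=0.0, power_sample_sd=0.0)
        pe = {"power": np.zeros(2), "bands": np.zeros((2, 4))}
        _, truth = synthetic.simulate_spectra_batch(
            np.zeros(2, bool), np.ones(2, bool), np.array([0.0, 45.0]),
            "PBS", quiet, rng, point_effects=pe,
        )
        np.testing.assert_allclose(
            truth[1] / truth[0], np.cos(np.radians(45.0)), rtol=1e-12
        )

    def test_zero_effect_removes_lesion_contrast(self, rng, optics):
        null = optics.zero_effect()
        pe = {"power": np.zeros(2), "bands": np.zeros((2, 4))}
        quiet = synthetic.TissueOpticsParams(
            noise_sd=0.0,
            lesion_scatter_gain=null.lesion_scatter_gain,
            lesion_power_delta=null.lesion_power_delta,
            bands=null.bands,
        )
        _, truth = synthetic.simulate_spectra_batch(
            np.array([True, False]), np.ones(2, bool), np.zeros(2),
            "PBS", quiet, rng, point_effects=pe,
        )
        np.testing.assert_allclose(truth[0], truth[1], rtol=1e-12)

    def test_noncontact_absorber_visible_at_764(self, rng):
        quiet = synthetic.TissueOpticsParams(noise_sd=0.0, power_sample_sd=0.0)
        pe = {"power": np.zeros(2), "bands": np.zeros((2, 4))}
        _, truth = synthetic.simulate_spectra_batch(
            np.zeros(2, bool), np.array([True, False]), np.zeros(2),
            "PBS", quiet, rng, point_effects=pe,
        )
        i764 = int(np.argmin(np.abs(synthetic.RAW_WL - 764)))
        i700 = int(np.argmin(np.abs(synthetic.RAW_WL - 700)))
        dip = (truth[1] / truth[0])[i764] / (truth[1] / truth[0])[i700]
        assert dip < 0.9  # pronounced absorption dip at 764 nm

    def test_shared_point_effects_correlate_media(self, rng, optics):
        """The same point effects passed to both media makes paired truth
        spectra nearly identical (in PBS vs blood, for contact points)."""
        n = 5
        pe = synthetic.draw_point_effects(n, optics, rng)
        quiet = synthetic.TissueOpticsParams(noise_sd=0.0)
        args = (np.zeros(n, bool), np.ones(n, bool), np.zeros(n))
        _, t_pbs = synthetic.simulate_spectra_batch(*args, "PBS", quiet, rng, point_effects=pe)
        _, t_blood = synthetic.simulate_spectra_batch(*args, "blood", quiet, rng, point_effects=pe)
        np.testing.assert_allclose(t_pbs, t_blood, rtol=1e-12)

    def test_single_index_aucs_in_working_range(self, rng, optics):
        """Default optics yield single-index lesion AUCs that are useful
        but not trivially perfect."""
        n = 400
        lesion = np.arange(n) < n // 2
        cal = synthetic.simulate_calibration(optics, rng)
        counts, _ = synthetic.simulate_spectra_batch(
            lesion, np.ones(n, bool), rng.uniform(0, 60, n), "PBS", optics, rng
        )
        rel = optics.phantom_factor * counts / cal.standard.counts[None, :]
        rrel = preprocess.condition_batch(synthetic.RAW_WL, rel)
        mat = indices.index_matrix(rrel)
        for name in ("loi0", "soi1"):
            auc, _, _ = stats.roc_auc(mat[name].to_numpy(), lesion)
            auc = max(auc, 1 - auc)
            assert 0.65 < auc < 0.95, (name, auc)


class TestAngleExperiment:
    def test_only_detector_noise_varies(self, rng):
        quiet = synthetic.TissueOpticsParams(noise_sd=0.0)
        out = synthetic.simulate_angle_experiment(
            quiet, np.array([30.0, 30.0, 30.0]), rng
        )
        for state in ("lesion", "nonlesion"):
            np.testing.assert_allclose(out[state][0], out[state][1], rtol=1e-12)

    def test_conditioned_indices_angle_invariant(self, rng, optics):
        """Conditioned-index curves stay flat across 0-60 deg because the
        normalization at 600 nm removes the cosine intensity factor."""
        angles = np.repeat(np.arange(0.0, 61.0, 10.0), 20)
        out = synthetic.simulate_angle_experiment(optics, angles, rng)
        cal = synthetic.simulate_calibration(optics, rng)
        curves = {}
        for state, counts in out.items():
            rel = optics.phantom_factor * counts / cal.standard.counts[None, :]
            rrel = preprocess.condition_batch(synthetic.RAW_WL, rel)
            curves[state] = indices.index_matrix(rrel)["loi0"].to_numpy()
        for state, v in curves.items():
            by_angle = np.array([v[angles == a].mean() for a in np.unique(angles)])
            se = np.std(v) / np.sqrt(20)
            # flat curve: per-angle means differ only by sampling noise
            assert np.ptp(by_angle) < 5 * se, state


class TestSessionStructure:
    def test_deterministic_given_seed(self):
        cfg = synthetic.SessionConfig(n_hearts=1, points_per_heart=20, seed=11)
        s1 = synthetic.simulate_session(cfg)
        s2 = synthetic.simulate_session(cfg)
        for a, b in zip(s1.samples, s2.samples):
            assert a.sample_id == b.sample_id
            np.testing.assert_array_equal(a.spectrum.counts, b.spectrum.counts)
            assert a.pose == b.pose

    def test_sample_count_and_media_pairing(self, small_session):
        cfg = small_session.config
        assert len(small_session.samples) == cfg.n_hearts * cfg.points_per_heart * 2
        by_medium = {}
        for s in small_session.samples:
            by_medium.setdefault(s.medium, []).append(s)
        assert set(by_medium) == {"PBS", "blood"}
        # paired acquisitions carry the same point index and label
        pbs = {s.sample_id.replace("-PBS-", "-"): s for s in by_medium["PBS"]}
        blood = {s.sample_id.replace("-blood-", "-"): s for s in by_medium["blood"]}
        assert pbs.keys() == blood.keys()
        assert all(pbs[k].label == blood[k].label for k in pbs)

    def test_no_points_inside_vein(self, small_session):
        cfg = small_session.config
        vx, vy = cfg.vein_center
        for heart in small_session.hearts.values():
            d2 = (heart.points[:, 0] - vx) ** 2 + (heart.points[:, 1] - vy) ** 2
            assert np.all(d2 > cfg.vein_radius**2)

    def test_labels_match_truth_probability(self, small_session):
        for heart in small_session.hearts.values():
            p = heart.truth_probability(heart.points[:, 0], heart.points[:, 1])
            np.testing.assert_array_equal(p, heart.lesion_prob)
        for s in small_session.samples[:50]:
            heart = small_session.hearts[s.heart_id]
            assert s.label in ("lesion", "nonlesion")

    def test_lesion_fraction_near_design_value(self):
        cfg = synthetic.SessionConfig(n_hearts=4, points_per_heart=500, seed=3)
        session = synthetic.simulate_session(cfg)
        frac = np.mean([s.label == "lesion" for s in session.samples])
        assert 0.06 < frac < 0.20

    def test_control_points_exactly_consistent_with_homography(self, small_session):
        cps = small_session.control_points
        H = small_session.true_homography
        np.testing.assert_allclose(cps.pixels, H.apply(cps.physical), atol=1e-9)
        fitted = mapping.fit_projective(cps)
        np.testing.assert_allclose(fitted.matrix, H.matrix, atol=1e-6)

    def test_reference_image_shape_and_content(self, small_session):
        img = small_session.reference_image
        assert img.shape == synthetic.IMAGE_SHAPE
        assert img.dtype == np.uint8
        assert {40, 60, 110, 190} <= set(np.unique(img))

    def test_true_contact_fraction_near_config(self):
        cfg = synthetic.SessionConfig(n_hearts=3, points_per_heart=400, seed=5)
        session = synthetic.simulate_session(cfg)
        fail = 1.0 - np.mean(list(session.true_contact.values()))
        assert abs(fail - cfg.noncontact_fraction) < 0.04

    def test_contact_failures_correlated_between_media(self):
        cfg = synthetic.SessionConfig(
            n_hearts=2, points_per_heart=600, seed=9, contact_correlation=0.7
        )
        session = synthetic.simulate_session(cfg)
        co_occur = []
        for h in range(1, 3):
            for i in range(600):
                a = session.true_contact[f"H{h:02d}-PBS-{i:04d}"]
                b = session.true_contact[f"H{h:02d}-blood-{i:04d}"]
                if not a or not b:  # at least one medium failed here
                    co_occur.append(not a and not b)
        # with 70% site-driven failures most failures hit both media
        assert np.mean(co_occur) > 0.45

    def test_config_validation(self):
        with pytest.raises(ValidationError):
            synthetic.SessionConfig(noncontact_fraction=1.5)
        with pytest.raises(ValidationError):
            synthetic.SessionConfig(contact_correlation=-0.1)
        with pytest.raises(ValidationError):
            synthetic.SessionConfig(n_hearts=0)

    def test_boundary_ramp_softens_truth(self):
        e = synthetic.LesionEllipse(0.0, 0.0, 4.0, 3.0, 0.0)
        x = np.array([0.0, 4.5, 20.0])
        y = np.zeros(3)
        hard = synthetic._truth_probability([e], x, y, 0.0)
        soft = synthetic._truth_probability([e], x, y, 2.0)
        np.testing.assert_array_equal(hard, [1.0, 0.0, 0.0])
        assert soft[0] == 1.0
        assert 0.0 < soft[1] < 1.0
        assert soft[2] == 0.0
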