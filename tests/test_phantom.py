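"""Phantom generators: bolus model fidelity, painting arithmetic,
projector conservation, cohort distributions, determinism."""

import dataclasses

import numpy as np
import pytest

from mibgquant import phantom as ph
from mibgquant.projector import ParallelProjector


class TestDynamicSeries:
    def test_zero_dose_gives_zero_frames(self, noiseless_config):
        cfg = dataclasses.replace(noiseless_config, dose_scale=0.0)
        series = ph.make_dynamic_series(cfg)
        assert np.all(series.frames == 0)

    def test_noiseless_pa_trace_equals_bolus_model_exactly(self, noiseless_config):
        series = ph.make_dynamic_series(noiseless_config)
        r, c = (int(v) for v in noiseless_config.pa_center)
        trace = series.frames[:, r, c]
        expected = ph.bolus_curve(series.times, noiseless_config.bolus)
        np.testing.assert_array_equal(trace, expected * noiseless_config.frame_duration_s)

    def test_same_seed_is_bit_identical(self):
        cfg = ph.PhantomConfig(noise=True)
        a = ph.make_dynamic_series(cfg, seed=7)
        b = ph.make_dynamic_series(cfg, seed=7)
        np.testing.assert_array_equal(a.frames, b.frames)
        c = ph.make_dynamic_series(cfg, seed=8)
        assert not np.array_equal(a.frames, c.frames)

    def test_invalid_config_rejected(self):
        cfg = dataclasses.replace(ph.PhantomConfig(), n_frames=0)
        with pytest.raises(ValueError):
            ph.make_dynamic_series(cfg)
        bad_bolus = dataclasses.replace(
            ph.PhantomConfig(), bolus=ph.BolusParams(recirc_fraction=1.0)
        )
        with pytest.raises(ValueError):
            ph.make_dynamic_series(bad_bolus)

    def test_poisson_stage_preserves_the_mean(self):
        # 1000 noisy realizations of a constant-100 field stay within 1%
        rng = np.random.default_rng(42)
        draws = rng.poisson(100.0, size=(1000, 50))
        assert abs(draws.mean() - 100.0) / 100.0 < 0.01


class TestPlanarImage:
    def test_heart_mediastinum_ratio_by_construction(self):
        # bare heart and mediastinum over zero background: ratio is exact
        cfg = ph.PhantomConfig(
            noise=False, body_planar=0.0, lung_planar=0.0, liver_planar=0.0,
            mediastinum_planar=0.5, heart_planar_coeff=1.0,
        )
        img = ph.make_planar_image(cfg, 1.0)
        heart = img.counts[cfg.pl_heart.mask(img.counts.shape)]
        med = img.counts[cfg.pl_mediastinum.mask(img.counts.shape)]
        assert heart.mean() / med.mean() == pytest.approx(2.0)

    def test_zero_concentration_heart_equals_background(self, noiseless_config):
        img = ph.make_planar_image(noiseless_config, 0.0)
        shape = img.counts.shape
        heart = noiseless_config.pl_heart.mask(shape)
        # compare against body pixels away from any other organ
        body = noiseless_config.pl_body.mask(shape).copy()
        for organ in ("pl_lung_r", "pl_lung_l", "pl_mediastinum", "pl_liver", "pl_heart"):
            body &= ~getattr(noiseless_config, organ).mask(shape)
        assert np.unique(img.counts[heart]).size == 1
        assert img.counts[heart].mean() == pytest.approx(img.counts[body].mean())

    def test_negative_concentration_rejected(self, noiseless_config):
        with pytest.raises(ValueError):
            ph.make_planar_image(noiseless_config, -1.0)

    def test_fixed_seed_reproducible(self):
        cfg = ph.PhantomConfig(noise=True)
        a = ph.make_planar_image(cfg, 1.0, seed=3)
        b = ph.make_planar_image(cfg, 1.0, seed=3)
        np.testing.assert_array_equal(a.counts, b.counts)


class TestMyocardialVolume:
    def test_mask_voxels_equal_shell_concentration(self, clean_shell_config):
        c = 2.5
        vol = ph.make_myocardial_volume(clean_shell_config, c)
        assert np.allclose(vol.concentration[vol.myocardial_mask], c)

    def test_total_activity_counts_mask_voxels(self, clean_shell_config):
        # binary painting: total activity = c * n_mask * voxel volume
        cfg = dataclasses.replace(clean_shell_config, supersample=1)
        c = 1.7
        vol = ph.make_myocardial_volume(cfg, c)
        shell = vol.concentration > 0
        expected = c * shell.sum() * vol.voxel_volume_ml
        assert vol.total_activity() == pytest.approx(expected, rel=1e-12)
        np.testing.assert_array_equal(shell, vol.myocardial_mask | shell)

    def test_defect_scales_shell_by_one_minus_depth(self, clean_shell_config):
        cfg = dataclasses.replace(clean_shell_config, supersample=1)
        defect = ph.DefectSpec(center_angle_deg=0.0, extent_deg=90.0, depth=0.25)
        vol = ph.make_myocardial_volume(cfg, 1.0, defect=defect)
        ref = ph.make_myocardial_volume(cfg, 1.0)
        zz, yy, xx = np.nonzero(ref.concentration > 0)
        ang = np.rad2deg(np.arctan2(yy - cfg.myo_outer.center[1], xx - cfg.myo_outer.center[2]))
        in_sector = np.abs((ang + 180) % 360 - 180) <= 45.0
        vals = vol.concentration[zz, yy, xx]
        assert np.allclose(vals[in_sector], 0.75)
        assert np.allclose(vals[~in_sector], 1.0)

    def test_invalid_defect_extent_rejected(self, clean_shell_config):
        with pytest.raises(ValueError):
            ph.make_myocardial_volume(
                clean_shell_config, 1.0, defect=ph.DefectSpec(extent_deg=400.0)
            )


class TestForwardProjector:
    def test_count_conservation_on_arbitrary_volume(self, rng):
        vol = np.zeros((16, 32, 32))
        # random blobs inside the inscribed circle
        yy, xx = np.meshgrid(np.arange(32), np.arange(32), indexing="ij")
        inside = (yy - 15.5) ** 2 + (xx - 15.5) ** 2 <= 12.0**2
        vol[:, inside] = rng.random((16, int(inside.sum())))
        proj = ph.forward_project(ph.ActivityVolume(vol), n_views=24, count_scale=1.0)
        sums = proj.views.sum(axis=(1, 2))
        assert np.all(np.abs(sums - vol.sum()) / vol.sum() < 0.005)

    def test_centered_compact_source_views_agree(self):
        # a centered compact source projects identically in every view
        yy, xx = np.meshgrid(np.arange(33), np.arange(33), indexing="ij")
        spot = 100.0 * np.exp(-(((yy - 16) ** 2 + (xx - 16) ** 2) / (2 * 1.5**2)))
        vol = np.zeros((8, 33, 33))
        vol[4] = spot
        proj = ph.forward_project(ph.ActivityVolume(vol), n_views=60, count_scale=1.0)
        totals = proj.views.sum(axis=(1, 2))
        assert np.all(np.abs(totals - spot.sum()) / spot.sum() < 0.005)
        # and the view profiles themselves agree across angles
        spread = proj.views.std(axis=0).max() / proj.views.max()
        assert spread < 0.01

    def test_zero_volume_projects_to_zero(self):
        proj = ph.forward_project(ph.ActivityVolume(np.zeros((4, 16, 16))), n_views=8)
        assert np.all(proj.views == 0)

    def test_adjoint_property(self, rng):
        # backprojector is the exact transpose of the forward projector
        P = ParallelProjector(16, [0.0, 33.0, 175.0])
        x = rng.random((4, 16, 16))
        y = rng.random((3, 4, 16))
        assert np.vdot(P.forward(x), y) == pytest.approx(np.vdot(x, P.back(y)), rel=1e-12)

    def test_noise_applied_iff_seed_given(self, unit_shell_volume):
        a = ph.forward_project(unit_shell_volume, n_views=12)
        b = ph.forward_project(unit_shell_volume, n_views=12, seed=5)
        c = ph.forward_project(unit_shell_volume, n_views=12, seed=5)
        assert not np.array_equal(a.views, b.views)
        np.testing.assert_array_equal(b.views, c.views)
        assert np.all(b.views == np.floor(b.views))


class TestCohort:
    def test_group_sizes(self):
        subjects = ph.make_cohort(3, 4, seed=0, images=False)
        groups = [s.group for s in subjects]
        assert groups.count("LBD") == 3 and groups.count("non-LBD") == 4

    def test_sample_medians_match_group_law(self):
        subjects = ph.make_cohort(2000, 2000, seed=11, images=False)
        lbd = np.array([s.true_concentration for s in subjects if s.group == "LBD"])
        non = np.array([s.true_concentration for s in subjects if s.group == "non-LBD"])
        assert abs(np.median(lbd) - 0.63) / 0.63 < 0.03
        assert abs(np.median(non) - 1.70) / 1.70 < 0.03

    def test_same_seed_identical_cohort(self):
        cfg = ph.PhantomConfig()
        a = ph.make_cohort(2, 2, seed=5, config=cfg)
        b = ph.make_cohort(2, 2, seed=5, config=cfg)
        for sa, sb in zip(a, b):
            assert sa.true_concentration == sb.true_concentration
            np.testing.assert_array_equal(sa.dynamic.frames, sb.dynamic.frames)
            np.testing.assert_array_equal(sa.planar.counts, sb.planar.counts)
            np.testing.assert_array_equal(sa.projections.views, sb.projections.views)

    def test_nonpositive_distribution_scale_rejected(self):
        bad = {"LBD": ph.GroupDistribution(median=-1.0, q1=0.5, q3=0.8)}
        with pytest.raises(ValueError):
            ph.make_cohort(2, 2, group_params=bad, images=False)

    def test_generators_nonnegative(self):
        cfg = ph.PhantomConfig(noise=True)
        series = ph.make_dynamic_series(cfg, seed=1)
        img = ph.make_planar_image(cfg, 0.8, seed=1)
        vol = ph.make_myocardial_volume(cfg, 0.8)
        proj = ph.forward_project(vol, n_views=12, seed=1)
        for arr in (series.frames, img.counts, vol.concentration, proj.views):
            assert arr.min() >= 0
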