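"""Synthetic cohort generator: covariate moments, shapes, voxelization."""

import dataclasses

import numpy as np
import pytest

from amygshape import meshes, synthetic, volumetry
from amygshape.synthetic import CohortConfig


class TestCovariates:
    def test_stai_moments_match_configuration(self):
        cfg = CohortConfig(n_subjects=10000, seed=1)
        cov = synthetic.sample_covariates(cfg)
        n = len(cov)
        se_mean = cfg.stai_sd / np.sqrt(n)
        se_sd = cfg.stai_sd / np.sqrt(2 * n)
        assert abs(cov.stai_t.mean() - 40.0) < 3 * se_mean
        assert abs(cov.stai_t.std(ddof=1) - 7.56) < 3 * se_sd

    def test_correlation_construction(self):
        # closed-form bivariate construction: population corr = rho exactly
        cfg = CohortConfig(n_subjects=100000, sds_stai_corr=0.5, seed=2)
        cov = synthetic.sample_covariates(cfg)
        assert np.corrcoef(cov.stai_t, cov.sds)[0, 1] == pytest.approx(0.5, abs=0.01)

    def test_zero_correlation(self):
        cfg = CohortConfig(n_subjects=100000, sds_stai_corr=0.0, seed=3)
        cov = synthetic.sample_covariates(cfg)
        assert abs(np.corrcoef(cov.stai_t, cov.sds)[0, 1]) < 0.01

    def test_invalid_correlation_rejected(self):
        with pytest.raises(ValueError, match="sds_stai_corr"):
            CohortConfig(sds_stai_corr=1.0)

    def test_deterministic(self):
        a = synthetic.sample_covariates(CohortConfig(seed=7))
        b = synthetic.sample_covariates(CohortConfig(seed=7))
        assert a.equals(b)


class TestBaseShape:
    def test_volume_enforced(self):
        for seed in (0, 5):
            m = synthetic.make_base_shape("left", 1895.0, seed=seed, level=3)
            assert 1876 <= m.volume <= 1914  # within 1% of target
            assert meshes.euler_characteristic(m) == 2

    def test_unperturbed_is_exact_ellipsoid(self):
        m = synthetic.make_base_shape("left", 1000.0, seed=0, level=3,
                                      perturb_amplitude=0.0)
        # after volume rescale the semi-axes keep ratios 1.4:1.1:1
        ext = m.vertices.max(axis=0) - m.vertices.min(axis=0)
        assert ext / ext[2] == pytest.approx([1.4, 1.1, 1.0], rel=1e-9)
        assert m.volume == pytest.approx(1000.0, rel=1e-9)

    def test_sides_are_mirrored(self):
        l = synthetic.make_base_shape("left", 1895.0, seed=4, level=3)
        r = synthetic.make_base_shape("right", 1895.0, seed=4, level=3)
        assert np.allclose(r.vertices[:, 0], -l.vertices[:, 0])
        assert np.allclose(r.vertices[:, 1:], l.vertices[:, 1:])
        assert r.volume > 0 and l.volume > 0  # both outward-oriented


class TestDeformation:
    def test_zero_amplitude_is_identity(self):
        cfg = CohortConfig(noise_sd=0.0)
        m = synthetic.make_base_shape("left", 1895.0, seed=1, level=3)
        out = synthetic.apply_covariate_deformation(m, cfg.stai_mean, cfg,
                                                    seed=0, side="left")
        assert np.allclose(out.vertices, m.vertices)

    def test_peak_displacement_formula(self):
        # gain 0.5 mm/SD at stai = mean + 2 SD -> exactly 1 mm at a vertex
        # sitting exactly on the bump axis of the unperturbed ellipsoid
        cfg = CohortConfig(noise_sd=0.0, bump_gain=0.5, bump_center=(1, 0, 0))
        m = synthetic.make_base_shape("left", 1895.0, seed=1, level=3,
                                      perturb_amplitude=0.0)
        out = synthetic.apply_covariate_deformation(
            m, cfg.stai_mean + 2 * cfg.stai_sd, cfg, seed=0, side="left")
        disp = np.linalg.norm(out.vertices - m.vertices, axis=1)
        tip = int(np.argmax(m.vertices[:, 0]))
        assert disp[tip] == pytest.approx(1.0, abs=1e-9)

    def test_truncation_outside_radius(self):
        cfg = CohortConfig(noise_sd=0.0, bump_center=(1, 0, 0),
                           bump_angular_radius=0.5)
        m = synthetic.make_base_shape("left", 1895.0, seed=1, level=3,
                                      perturb_amplitude=0.0)
        out = synthetic.apply_covariate_deformation(
            m, cfg.stai_mean + 2 * cfg.stai_sd, cfg, seed=0, side="left")
        far = ~synthetic.bump_region(m, cfg, side="left")
        disp = np.linalg.norm(out.vertices - m.vertices, axis=1)
        assert disp[far].max() == 0.0

    def test_excessive_deformation_reported(self):
        # an extreme inward spike drives vertices through the far wall,
        # flipping faces: the parameter-range violation must be reported
        cfg = CohortConfig(noise_sd=0.0, bump_gain=20.0,
                           bump_angular_radius=0.15)
        m = synthetic.make_base_shape("left", 1895.0, seed=1, level=3)
        with pytest.raises(ValueError, match="self-intersection"):
            synthetic.apply_covariate_deformation(
                m, cfg.stai_mean - 3 * cfg.stai_sd, cfg, seed=0, side="left")


class TestVoxelize:
    def test_axis_aligned_cube_exact_count(self):
        import trimesh

        box = trimesh.creation.box(extents=(10, 10, 10))
        mask = synthetic.voxelize(meshes.as_mesh(box.vertices, box.faces), 1.0)
        assert int(mask.grid.sum()) == 1000
        assert volumetry.compute_volume(mask) == pytest.approx(1000.0)

    def test_sphere_matches_bruteforce_lattice_count(self):
        r = 7.7
        sphere = meshes.icosphere(4, radius=r)
        mask = synthetic.voxelize(sphere, 1.0)
        analytic = 4 / 3 * np.pi * r ** 3
        assert abs(volumetry.compute_volume(mask) - analytic) / analytic < 0.02
        # independent oracle: count lattice points inside the ball directly
        origin = mask.affine[:3, 3]
        idx = np.indices(mask.grid.shape, dtype=float)
        centers = np.stack([origin[i] + idx[i] for i in range(3)], axis=-1)
        inside = (np.linalg.norm(centers, axis=-1) <= r).sum()
        # icosphere slightly under-fills the ball; counts agree to < 1%
        assert abs(int(mask.grid.sum()) - int(inside)) / inside < 0.01

    def test_open_mesh_rejected(self, ico3):
        open_mesh = meshes.as_mesh(ico3.vertices, np.asarray(ico3.faces)[:-1])
        with pytest.raises(ValueError):
            synthetic.voxelize(open_mesh, 1.0)

    def test_single_component_after_topology_fix(self):
        m = synthetic.make_base_shape("right", 1937.0, seed=2, level=3)
        fixed, _ = volumetry.fix_topology(synthetic.voxelize(m, 1.0))
        from scipy import ndimage

        _, n = ndimage.label(fixed.grid,
                             structure=ndimage.generate_binary_structure(3, 1))
        assert n == 1


class TestCohort:
    def test_generate_cohort_deterministic_and_complete(self, tmp_path):
        cfg = CohortConfig(n_subjects=3, seed=9)
        t1 = synthetic.generate_cohort(cfg, level=3)
        t2 = synthetic.generate_cohort(cfg, level=3)
        assert t1.drop(columns="mask_path").equals(t2.drop(columns="mask_path"))
        for key in t1.attrs["masks"]:
            assert np.array_equal(t1.attrs["masks"][key].grid,
                                  t2.attrs["masks"][key].grid)
        assert t1.id.nunique() == 3 and len(t1) == 6
        assert not t1[["stai_t", "sds"]].isna().any().any()
        # bump amplitude recorded on the bump side only
        assert (t1[t1.side == "left"].true_bump_amplitude == 0).all()

    def test_config_json_roundtrip(self, tmp_path):
        cfg = CohortConfig(n_subjects=5, bump_gain=0.3, seed=13)
        cfg.to_json(tmp_path / "c.json")
        back = CohortConfig.from_json(tmp_path / "c.json")
        assert back == cfg

    def test_nifti_roundtrip(self, tmp_path):
        m = synthetic.make_base_shape("left", 1895.0, seed=1, level=3)
        mask = synthetic.voxelize(m, 1.0)
        mask.save(tmp_path / "m.nii")
        from amygshape.masks import BinaryMask

        back = BinaryMask.load(tmp_path / "m.nii")
        assert np.array_equal(back.grid, mask.grid)
        assert np.allclose(back.affine, mask.affine)
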