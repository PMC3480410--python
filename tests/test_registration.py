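"""FOE alignment, template construction and rigid registration."""

import numpy as np
import pytest
from scipy.spatial.transform import Rotation

from amygshape import meshes, registration as reg, spharm


def _ellipsoid_model(axes, sampling, R=None, t=None):
    verts = sampling.vertices * np.asarray(axes, dtype=float)
    if R is not None:
        verts = verts @ np.asarray(R).T
    if t is not None:
        verts = verts + np.asarray(t)
    th, ph = spharm.sphere_angles(sampling.vertices)
    return spharm.fit_coefficients(meshes.as_mesh(verts, sampling.faces),
                                   th, ph, 3)


class TestAlignFoe:
    def test_already_aligned_is_fixed_point(self, ico3):
        model = _ellipsoid_model((3, 2, 1), ico3)
        aligned, xf = reg.align_foe(model)
        assert np.allclose(xf.rotation, np.eye(3), atol=1e-6)
        assert np.allclose(xf.translation, 0, atol=1e-6)
        assert np.allclose(aligned.coefficients, model.coefficients, atol=1e-6)

    def test_known_rotation_recovered(self, ico3):
        R = Rotation.from_euler("xyz", [0.4, -0.2, 0.9]).as_matrix()
        t = np.array([5.0, -3.0, 2.0])
        model = _ellipsoid_model((3, 2, 1), ico3, R=R, t=t)
        aligned, xf = reg.align_foe(model)
        assert np.abs(np.abs(xf.rotation @ R) - np.eye(3)).max() < 1e-6
        foe = spharm.first_order_ellipsoid(aligned)
        assert np.allclose(foe.center, 0, atol=1e-6)
        assert np.allclose(np.abs(foe.axes), np.eye(3), atol=1e-6)

    def test_degenerate_foe_warns(self, ico3):
        model = _ellipsoid_model((2, 2, 2), ico3, t=[1.0, 0, 0])
        with pytest.warns(UserWarning, match="degenerate"):
            aligned, xf = reg.align_foe(model)
        # still centered even without rotation
        foe = spharm.first_order_ellipsoid(aligned)
        assert np.allclose(foe.center, 0, atol=1e-6)


class TestTemplate:
    def test_mean_of_identical_inputs(self, ico3):
        atlas = reg.build_template([ico3, ico3, ico3], side="left")
        assert np.allclose(atlas.mesh.vertices, ico3.vertices)

    def test_concentric_spheres_average(self, ico3):
        s1 = meshes.as_mesh(ico3.vertices * 1.0, ico3.faces)
        s3 = meshes.as_mesh(ico3.vertices * 3.0, ico3.faces)
        atlas = reg.build_template([s1, s3], side="left")
        assert np.allclose(np.linalg.norm(atlas.mesh.vertices, axis=1), 2.0,
                           atol=1e-9)

    def test_shift_linearity(self, ico3):
        t = np.array([1.0, 2.0, -0.5])
        shifted = meshes.as_mesh(ico3.vertices + t, ico3.faces)
        atlas = reg.build_template([ico3, shifted], side="left")
        assert np.allclose(atlas.mesh.vertices, ico3.vertices + t / 2)

    def test_mismatched_triangulations_rejected(self, ico3, ico4):
        with pytest.raises(ValueError, match="triangulation"):
            reg.build_template([ico3, ico4], side="left")

    def test_normals_outward_unit(self, ellipsoid211):
        atlas = reg.build_template([ellipsoid211, ellipsoid211], side="left")
        n = atlas.normals
        assert np.allclose(np.linalg.norm(n, axis=1), 1.0, atol=1e-9)
        assert (np.einsum("ij,ij->i", n, atlas.mesh.vertices) > 0).all()


class TestProcrustes:
    def test_matches_independent_svd_oracle(self):
        rng = np.random.default_rng(3)
        src = rng.standard_normal((40, 3))
        R = Rotation.random(random_state=1).as_matrix()
        t = np.array([0.3, -2.0, 1.0])
        dst = src @ R.T + t + 0.01 * rng.standard_normal((40, 3))
        xf = reg.procrustes_rigid(src, dst)

        # independent closed-form solve (Umeyama without scaling)
        mu_s, mu_d = src.mean(0), dst.mean(0)
        C = (dst - mu_d).T @ (src - mu_s) / len(src)
        U, _, Vt = np.linalg.svd(C)
        S = np.diag([1, 1, np.sign(np.linalg.det(U @ Vt))])
        R_o = U @ S @ Vt
        t_o = mu_d - R_o @ mu_s
        assert np.abs(xf.rotation - R_o).max() < 1e-9
        assert np.abs(xf.translation - t_o).max() < 1e-9


class TestShrec:
    def test_identity_on_perfect_match(self, ellipsoid211):
        atlas = reg.build_template([ellipsoid211, ellipsoid211], side="left")
        regd, xf, msd = reg.register_shrec(ellipsoid211, atlas)
        assert msd < 1e-20
        assert np.allclose(xf.rotation, np.eye(3), atol=1e-9)

    def test_known_transform_inverted(self, ellipsoid211):
        R = Rotation.from_euler("zxy", [0.3, 0.1, -0.4]).as_matrix()
        t = np.array([4.0, 1.0, -2.0])
        moved = meshes.as_mesh(ellipsoid211.vertices @ R.T + t,
                               ellipsoid211.faces)
        atlas = reg.build_template([ellipsoid211, ellipsoid211], side="left")
        regd, xf, msd = reg.register_shrec(moved, atlas)
        assert msd < 1e-10
        assert np.abs(xf.rotation @ R - np.eye(3)).max() < 1e-6

    def test_volume_preserved_exactly(self, ellipsoid211):
        moved = meshes.as_mesh(ellipsoid211.vertices + [0.5, 0.2, -0.1],
                               ellipsoid211.faces)
        atlas = reg.build_template([ellipsoid211, ellipsoid211], side="left")
        regd, _, _ = reg.register_shrec(moved, atlas)
        assert regd.volume == pytest.approx(moved.volume, rel=1e-9)

    def test_msd_never_increases(self, ico3):
        rng = np.random.default_rng(5)
        noisy = meshes.as_mesh(
            ico3.vertices * 2 + 0.1 * rng.standard_normal((len(ico3.vertices), 3)),
            ico3.faces)
        atlas = reg.build_template(
            [meshes.as_mesh(ico3.vertices * 2, ico3.faces)] * 2, side="left")
        before = float(((noisy.vertices - atlas.mesh.vertices) ** 2)
                       .sum(axis=1).mean())
        _, _, after = reg.register_shrec(noisy, atlas)
        assert after <= before

    def test_param_rotation_search_restores_indexing(self, ico3):
        perms = reg._param_permutations(np.asarray(ico3.vertices))
        assert len(perms) == 60
        # re-index the ellipsoid by one nontrivial sampling rotation;
        # the search must recover near-zero MSD
        ell = meshes.as_mesh(ico3.vertices * np.array([2.0, 1.0, 1.0]),
                             ico3.faces)
        perm = perms[7]
        scrambled = meshes.as_mesh(np.asarray(ell.vertices)[perm], ico3.faces)
        atlas = reg.build_template([ell, ell], side="left")
        _, _, msd_no = reg.register_shrec(scrambled, atlas)
        _, _, msd_yes = reg.register_shrec(
            scrambled, atlas, param_rotation_search=True,
            sampling_points=np.asarray(ico3.vertices))
        assert msd_yes <= msd_no + 1e-12
        assert msd_yes < 1e-10


def test_icosahedral_group_is_closed():
    G = reg.icosahedral_rotations()
    assert len(G) == 60
    for R in G[:10]:
        assert np.abs(R @ R.T - np.eye(3)).max() < 1e-9
        assert np.linalg.det(R) == pytest.approx(1.0)


def test_rigid_transform_json_roundtrip(tmp_path):
    xf = reg.RigidTransform(Rotation.from_euler("z", 0.5).as_matrix(),
                            np.array([1.0, 2.0, 3.0]))
    xf.to_json(tmp_path / "t.json")
    import json

    with open(tmp_path / "t.json") as fh:
        d = json.load(fh)
    assert np.allclose(d["rotation"], xf.rotation)
    assert np.allclose(d["translation"], xf.translation)
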