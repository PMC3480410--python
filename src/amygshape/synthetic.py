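"""Synthetic amygdala-like cohorts with known ground truth.

The generator emulates the statistical structure a surface-morphometry
study of trait anxiety rests on: n subjects with a trait-anxiety score
(STAI-T, Normal(40, 7.56^2) by default), a depression score (SDS)
positively correlated with it, bilateral genus-0 masks at amygdala scale
(~1900 mm^3), and — as recoverable ground truth — a localized outward
surface deformation whose amplitude is linear in the standardized
STAI-T score.

The base shape is a perturbed ellipsoid, not an anatomical atlas: only
the topology (genus 0), the scale, and bilaterality matter to the
pipeline, so an ellipsoid with smooth low-order radial perturbation is
the simplest shape family exercising every downstream stage.
"""

from __future__ import annotations

import dataclasses
import json
from dataclasses import dataclass

import numpy as np
import pandas as pd
import trimesh

from ._heat import HeatSmoother
from .masks import BinaryMask
from .meshes import as_mesh, icosphere
from .spharm import real_sph_harm_basis

#: semi-axis ratios of the base ellipsoid (longest axis roughly
#: anterior-posterior, mirrored between hemispheres)
AXIS_RATIOS = np.array([1.4, 1.1, 1.0])


@dataclass
class CohortConfig:
    """Study-design parameters of a simulated cohort.

    Scores: ``stai_mean``/``stai_sd`` are the STAI-T population moments;
    ``sds_stai_corr`` the population correlation between SDS and STAI-T.
    Geometry: per-side mean volumes and a common between-subject volume
    SD (mm^3).  Ground truth: a bump at unit direction ``bump_center``
    (from the shape centroid), angular radius ``bump_angular_radius``
    (radians), amplitude ``bump_gain`` mm per STAI-T SD, applied to
    ``bump_side`` only.  ``noise_sd`` (mm) is the scale of smooth
    per-vertex surface noise with spatial smoothness ``noise_fwhm`` (mm).
    """

    n_subjects: int = 24
    stai_mean: float = 40.0
    stai_sd: float = 7.56
    sds_stai_corr: float = 0.5
    sds_mean: float = 40.0
    sds_sd: float = 8.0
    volume_mean_left: float = 1895.0
    volume_mean_right: float = 1937.0
    volume_sd: float = 168.0
    bump_center: tuple = (0.9, 0.35, 0.25)
    bump_angular_radius: float = 0.8
    bump_gain: float = 0.6
    bump_side: str = "right"
    noise_fwhm: float = 5.0
    noise_sd: float = 0.25
    voxel_size: float = 1.0
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_subjects < 3:
            raise ValueError("n_subjects must be >= 3")
        if self.stai_sd <= 0:
            raise ValueError("stai_sd must be > 0")
        if not abs(self.sds_stai_corr) < 1:
            raise ValueError("|sds_stai_corr| must be < 1")
        if self.bump_angular_radius <= 0:
            raise ValueError("bump_angular_radius must be > 0")
        if self.voxel_size <= 0:
            raise ValueError("voxel_size must be > 0")
        if self.bump_side not in ("left", "right"):
            raise ValueError("bump_side must be 'left' or 'right'")
        c = np.asarray(self.bump_center, dtype=float)
        self.bump_center = tuple(c / np.linalg.norm(c))

    def to_json(self, path) -> None:
        with open(path, "w") as fh:
            json.dump(dataclasses.asdict(self), fh, indent=2)

    @classmethod
    def from_json(cls, path) -> "CohortConfig":
        with open(path) as fh:
            d = json.load(fh)
        d["bump_center"] = tuple(d["bump_center"])
        return cls(**d)


def sample_covariates(config: CohortConfig) -> pd.DataFrame:
    """Draw per-subject STAI-T and SDS scores.

    STAI-T ~ Normal(stai_mean, stai_sd^2).  SDS is built from the same
    latent normal by the bivariate construction
    z_sds = rho z_stai + sqrt(1-rho^2) z2, so the population correlation
    equals ``sds_stai_corr`` exactly.  Deterministic given config.seed.
    """
    rng = np.random.default_rng(config.seed)
    z1 = rng.standard_normal(config.n_subjects)
    z2 = rng.standard_normal(config.n_subjects)
    rho = config.sds_stai_corr
    stai = config.stai_mean + config.stai_sd * z1
    sds = config.sds_mean + config.sds_sd * (rho * z1 + np.sqrt(1 - rho ** 2) * z2)
    ids = [f"sub-{i + 1:03d}" for i in range(config.n_subjects)]
    return pd.DataFrame({"id": ids, "stai_t": stai, "sds": sds})


def make_base_shape(side: str, volume_target: float, seed: int,
                    level: int = 4, perturb_amplitude: float = 0.04,
                    perturb_degree: int = 4) -> trimesh.Trimesh:
    """A closed genus-0 amygdala-scale shape on the icosphere sampling.

    An ellipsoid with semi-axis ratios 1.4:1.1:1 (x mirrored for the
    right side) perturbed radially by a random band-limited field of
    spherical harmonics with 2 <= l <= ``perturb_degree`` and relative
    amplitude ``perturb_amplitude``; finally rescaled so the enclosed
    volume matches ``volume_target`` to numerical precision.

    Vertices correspond across subjects and sides (same icosphere
    triangulation), which is what the downstream template stage assumes
    once surfaces are remeshed onto the shared parameter sampling.
    """
    if volume_target <= 0:
        raise ValueError("volume_target must be > 0")
    if side not in ("left", "right"):
        raise ValueError("side must be 'left' or 'right'")
    sphere = icosphere(level=level)
    u = np.asarray(sphere.vertices)

    radial = np.ones(len(u))
    if perturb_amplitude > 0:
        rng = np.random.default_rng(seed)
        theta = np.arccos(np.clip(u[:, 2], -1, 1))
        phi = np.mod(np.arctan2(u[:, 1], u[:, 0]), 2 * np.pi)
        B = real_sph_harm_basis(theta, phi, perturb_degree)
        coef = rng.standard_normal(B.shape[1])
        coef[:4] = 0.0  # keep l=0 (scale) and l=1 (offset) clean
        field = B @ coef
        field = field / (np.abs(field).max() + 1e-30)
        radial = 1.0 + perturb_amplitude * field

    v = u * radial[:, None] * AXIS_RATIOS
    faces = np.asarray(sphere.faces)
    if side == "right":
        v = v * np.array([-1.0, 1.0, 1.0])
        faces = faces[:, ::-1]  # restore outward orientation after mirror
    mesh = as_mesh(v, faces)
    scale = (volume_target / mesh.volume) ** (1.0 / 3.0)
    return as_mesh(mesh.vertices * scale, faces)


def _unit_directions(mesh: trimesh.Trimesh) -> np.ndarray:
    d = mesh.vertices - mesh.vertices.mean(axis=0)
    return d / np.linalg.norm(d, axis=1, keepdims=True)


def bump_profile(mesh: trimesh.Trimesh, config: CohortConfig,
                 side: str | None = None) -> np.ndarray:
    """Per-vertex Gaussian bump profile G in [0, 1].

    G = exp(-gamma^2 / (2 sigma^2)) truncated to 0 beyond the angular
    radius, with sigma = radius / 2.5 and gamma the angle between the
    vertex direction (from the centroid) and ``bump_center``.  The bump
    center direction is mirrored in x for the right side.
    """
    center = np.asarray(config.bump_center, dtype=float)
    if (side or config.bump_side) == "right":
        center = center * np.array([-1.0, 1.0, 1.0])
    gamma = np.arccos(np.clip(_unit_directions(mesh) @ center, -1, 1))
    sigma = config.bump_angular_radius / 2.5
    g = np.exp(-gamma ** 2 / (2 * sigma ** 2))
    g[gamma > config.bump_angular_radius] = 0.0
    return g


def bump_region(mesh: trimesh.Trimesh, config: CohortConfig,
                side: str | None = None) -> np.ndarray:
    """Boolean mask of vertices inside the injected bump's angular radius."""
    center = np.asarray(config.bump_center, dtype=float)
    if (side or config.bump_side) == "right":
        center = center * np.array([-1.0, 1.0, 1.0])
    gamma = np.arccos(np.clip(_unit_directions(mesh) @ center, -1, 1))
    return gamma <= config.bump_angular_radius


def apply_covariate_deformation(mesh: trimesh.Trimesh, stai_t: float,
                                config: CohortConfig, seed: int,
                                side: str | None = None,
                                smoother: HeatSmoother | None = None,
                                ) -> trimesh.Trimesh:
    """Displace vertices along outward normals by the ground-truth field.

    displacement = a * G + eps, where a = bump_gain * (stai_t -
    stai_mean) / stai_sd, G the truncated angular-Gaussian profile, and
    eps smooth noise of scale ``noise_sd`` built by heat-smoothing
    per-vertex white noise at ``noise_fwhm`` on the same mesh diffusion
    operator the analysis uses.  Raises if the deformation flips any
    face (the mesh self-intersects locally).
    """
    amplitude = config.bump_gain * (stai_t - config.stai_mean) / config.stai_sd
    disp = amplitude * bump_profile(mesh, config, side=side)
    if config.noise_sd > 0:
        rng = np.random.default_rng(seed)
        white = rng.standard_normal(len(mesh.vertices))
        if smoother is None:
            smoother = HeatSmoother(mesh)
        eps = smoother.smooth(white, config.noise_fwhm)
        eps = eps - eps.mean()
        eps = eps / (eps.std() + 1e-30) * config.noise_sd
        disp = disp + eps
    out = as_mesh(mesh.vertices + disp[:, None] * mesh.vertex_normals,
                  mesh.faces)
    flipped = np.einsum("ij,ij->i", out.face_normals, mesh.face_normals) < 0
    if flipped.any():
        raise ValueError(
            f"deformation flips {int(flipped.sum())} faces (self-intersection; "
            "parameter range violation)")
    return out


def true_bump_amplitude(stai_t: float, config: CohortConfig) -> float:
    """Ground-truth peak displacement (mm) for one subject."""
    return config.bump_gain * (stai_t - config.stai_mean) / config.stai_sd


def voxelize(mesh: trimesh.Trimesh, voxel_size: float, pad: int = 2) -> BinaryMask:
    """Binary mask of voxel centers inside a closed mesh.

    Point-in-polyhedron by ray-crossing parity: for every (y, z) voxel
    column a ray along +x collects triangle crossings; centers between
    consecutive crossing pairs are foreground.  The grid origin carries
    a tiny deterministic irrational offset so rays never hit mesh edges
    or vertices exactly.
    """
    from .meshes import check_closed_oriented

    check_closed_oriented(mesh)
    h = float(voxel_size)
    lo = mesh.vertices.min(axis=0)
    hi = mesh.vertices.max(axis=0)
    # centers at origin + idx*h; irrational sub-voxel shift avoids degeneracy
    shift = h * np.array([np.sqrt(2), np.sqrt(3), np.sqrt(5)]) * 1e-4
    origin = lo - pad * h + shift
    nx, ny, nz = (np.ceil((hi - origin) / h).astype(int) + pad + 1)

    tv = mesh.vertices[mesh.faces]  # (F, 3, 3)
    grid = np.zeros((nx, ny, nz), dtype=np.uint8)

    ys = origin[1] + np.arange(ny) * h
    zs = origin[2] + np.arange(nz) * h

    col_idx: list[np.ndarray] = []
    col_x: list[np.ndarray] = []
    for tri in tv:
        p0, p1, p2 = tri
        ymin, ymax = tri[:, 1].min(), tri[:, 1].max()
        zmin, zmax = tri[:, 2].min(), tri[:, 2].max()
        j0 = max(0, int(np.ceil((ymin - origin[1]) / h)))
        j1 = min(ny - 1, int(np.floor((ymax - origin[1]) / h)))
        k0 = max(0, int(np.ceil((zmin - origin[2]) / h)))
        k1 = min(nz - 1, int(np.floor((zmax - origin[2]) / h)))
        if j1 < j0 or k1 < k0:
            continue
        yy, zz = np.meshgrid(ys[j0:j1 + 1], zs[k0:k1 + 1], indexing="ij")
        # barycentric in the (y, z) projection
        d = ((p1[1] - p0[1]) * (p2[2] - p0[2])
             - (p2[1] - p0[1]) * (p1[2] - p0[2]))
        if abs(d) < 1e-14:
            continue  # triangle parallel to the ray
        w1 = ((yy - p0[1]) * (p2[2] - p0[2]) - (p2[1] - p0[1]) * (zz - p0[2])) / d
        w2 = ((p1[1] - p0[1]) * (zz - p0[2]) - (yy - p0[1]) * (p1[2] - p0[2])) / d
        w0 = 1.0 - w1 - w2
        inside = (w0 >= 0) & (w1 >= 0) & (w2 >= 0)
        if not inside.any():
            continue
        xcross = w0 * p0[0] + w1 * p1[0] + w2 * p2[0]
        jj, kk = np.nonzero(inside)
        col_idx.append((j0 + jj) * nz + (k0 + kk))
        col_x.append(xcross[inside])

    if col_idx:
        cols = np.concatenate(col_idx)
        xs = np.concatenate(col_x)
        order = np.lexsort((xs, cols))
        cols, xs = cols[order], xs[order]
        starts = np.flatnonzero(np.r_[True, cols[1:] != cols[:-1]])
        ends = np.r_[starts[1:], len(cols)]
        for s, e in zip(starts, ends):
            cx = xs[s:e]
            # merge numerically duplicate crossings (shared-edge hits)
            keep = np.r_[True, np.diff(cx) > 1e-9 * max(1.0, h)]
            cx = cx[keep]
            if len(cx) % 2:
                continue  # degenerate grazing hit; skip the odd column
            j, k = divmod(int(cols[s]), nz)
            for a, b in cx.reshape(-1, 2):
                i0 = int(np.ceil((a - origin[0]) / h))
                i1 = int(np.floor((b - origin[0]) / h))
                if i1 >= i0:
                    grid[max(i0, 0):i1 + 1, j, k] = 1

    affine = np.eye(4)
    affine[:3, :3] *= h
    affine[:3, 3] = origin
    return BinaryMask(grid=grid, affine=affine)


def generate_cohort(config: CohortConfig, out_dir=None,
                    level: int = 4) -> pd.DataFrame:
    """Full cohort: covariates plus bilateral masks (NIfTI if out_dir given).

    Returns the cohort table with one row per subject-side carrying
    id, stai_t, sds, side, mask_path and the subject's ground-truth peak
    bump amplitude in mm (0 on the non-bump side).  Deterministic given
    config.seed; per-subject seeds are drawn from a seed sequence.
    """
    from pathlib import Path

    cov = sample_covariates(config)
    ss = np.random.SeedSequence(config.seed)
    subj_seeds = ss.generate_state(4 * config.n_subjects) % (2 ** 31)
    rows = []
    masks = {}
    for i, rec in cov.iterrows():
        for j, side in enumerate(("left", "right")):
            s_shape = int(subj_seeds[4 * i + 2 * j])
            s_noise = int(subj_seeds[4 * i + 2 * j + 1])
            vol_mean = (config.volume_mean_left if side == "left"
                        else config.volume_mean_right)
            rng_v = np.random.default_rng(s_shape + 1)
            vol = max(200.0, vol_mean + config.volume_sd * rng_v.standard_normal())
            base = make_base_shape(side, vol, seed=s_shape, level=level)
            gain_here = config.bump_gain if side == config.bump_side else 0.0
            cfg_side = dataclasses.replace(config, bump_gain=gain_here)
            deformed = apply_covariate_deformation(
                base, float(rec.stai_t), cfg_side, seed=s_noise, side=side)
            mask = voxelize(deformed, config.voxel_size)
            mask_path = ""
            if out_dir is not None:
                out_dir = Path(out_dir)
                out_dir.mkdir(parents=True, exist_ok=True)
                mask_path = str(out_dir / f"{rec.id}_{side}_mask.nii")
                mask.save(mask_path)
            masks[(rec.id, side)] = mask
            rows.append({
                "id": rec.id, "stai_t": rec.stai_t, "sds": rec.sds,
                "side": side, "mask_path": mask_path,
                "true_bump_amplitude": true_bump_amplitude(rec.stai_t, cfg_side),
            })
    table = pd.DataFrame(rows)
    table.attrs["masks"] = masks
    return table


def simulate_surface_cohort(config: CohortConfig, level: int = 3,
                            side: str | None = None,
                            ) -> tuple[list[trimesh.Trimesh], pd.DataFrame, np.ndarray]:
    """Desk-scale cohort directly on the shared surface sampling.

    Generates one side's subject surfaces on a common base shape (so
    vertices correspond by construction) with the same ground-truth
    deformation model as the full mask route.  Used for statistical
    calibration and parameter-recovery studies where the voxel round
    trip is not under test.  Returns (meshes, covariate table, boolean
    bump-region vertex mask).
    """
    side = side or config.bump_side
    cov = sample_covariates(config)
    vol_mean = (config.volume_mean_left if side == "left"
                else config.volume_mean_right)
    base = make_base_shape(side, vol_mean, seed=config.seed, level=level)
    smoother = HeatSmoother(base)
    gain_here = config.bump_gain if side == config.bump_side else 0.0
    cfg_side = dataclasses.replace(config, bump_gain=gain_here)
    ss = np.random.SeedSequence(config.seed + 1)
    noise_seeds = ss.generate_state(config.n_subjects) % (2 ** 31)
    meshes = [
        apply_covariate_deformation(base, float(rec.stai_t), cfg_side,
                                    seed=int(noise_seeds[i]), side=side,
                                    smoother=smoother)
        for i, rec in cov.iterrows()
    ]
    region = bump_region(base, config, side=side)
    return meshes, cov, region
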