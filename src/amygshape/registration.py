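"""Cross-subject surface alignment and template construction.

Alignment proceeds in the three classical SPHARM steps: (1) each
subject's first-order ellipsoid (FOE) is moved to a canonical pose,
which establishes initial correspondence through the shared parameter
sampling; (2) aligned surfaces are averaged into a per-side template
atlas; (3) each surface is rigidly registered to the template by
ICP-style minimization of the mean squared distance between
corresponding points.  Registration is rigid only — no scaling or
shear — so displacement metrics keep their mm units and volume is
preserved exactly.
"""

from __future__ import annotations

import json
import warnings
from dataclasses import dataclass, field

import numpy as np
import trimesh

from .meshes import as_mesh
from .spharm import (
    SpharmModel,
    first_order_ellipsoid,
    rotate_model,
    translate_model,
)


@dataclass
class RigidTransform:
    """Proper rigid motion x -> R x + t."""

    rotation: np.ndarray
    translation: np.ndarray

    def __post_init__(self) -> None:
        R = np.asarray(self.rotation, dtype=float)
        if np.abs(R @ R.T - np.eye(3)).max() > 1e-9 or np.linalg.det(R) < 0:
            raise ValueError("rotation must be orthonormal with det +1")
        self.rotation = R
        self.translation = np.asarray(self.translation, dtype=float)

    def apply(self, points: np.ndarray) -> np.ndarray:
        return points @ self.rotation.T + self.translation

    def compose(self, other: "RigidTransform") -> "RigidTransform":
        """self after other: x -> self(other(x))."""
        return RigidTransform(self.rotation @ other.rotation,
                              self.rotation @ other.translation + self.translation)

    def to_json(self, path) -> None:
        with open(path, "w") as fh:
            json.dump({"rotation": self.rotation.tolist(),
                       "translation": self.translation.tolist()}, fh)

    @classmethod
    def identity(cls) -> "RigidTransform":
        return cls(np.eye(3), np.zeros(3))


@dataclass
class SurfaceAtlas:
    """Per-side template surface on the shared sampling."""

    mesh: trimesh.Trimesh
    side: str
    subjects: list = field(default_factory=list)
    iterations: int = 1

    @property
    def normals(self) -> np.ndarray:
        """Area-weighted outward unit vertex normals."""
        return np.asarray(self.mesh.vertex_normals)


def align_foe(model: SpharmModel, reference_axes: np.ndarray | None = None
              ) -> tuple[SpharmModel, RigidTransform]:
    """Move a SPHARM surface to its canonical FOE pose.

    Translates the FOE center to the origin and rotates the sorted FOE
    axes onto +x, +y, +z.  The axis-sign ambiguity is resolved by
    requiring positive dot products with ``reference_axes`` (the
    previous subject's pre-alignment axes) when given; otherwise by the
    deterministic largest-component-positive, det +1 rule.  Returns the
    aligned model and the applied transform.  Warns and returns the
    model untranslated-but-unrotated if the FOE is degenerate (two
    near-equal semi-axes), leaving alignment to the ICP stage.
    """
    foe = first_order_ellipsoid(model)
    U = foe.axes.copy()
    if reference_axes is not None:
        for k in range(3):
            if U[:, k] @ reference_axes[:, k] < 0:
                U[:, k] = -U[:, k]
        if np.linalg.det(U) < 0:
            # flip the axis least aligned with its reference
            k = int(np.argmin([abs(U[:, j] @ reference_axes[:, j])
                               for j in range(3)]))
            U[:, k] = -U[:, k]
    if foe.degenerate:
        warnings.warn("near-degenerate FOE (two semi-axes within 2%); "
                      "rotation alignment skipped, relying on ICP")
        xf = RigidTransform(np.eye(3), -foe.center)
        return translate_model(model, -foe.center), xf
    R = U.T  # rotates FOE axes onto the coordinate frame
    xf = RigidTransform(R, -R @ foe.center)
    aligned = rotate_model(translate_model(model, -foe.center), R)
    return aligned, xf


def build_template(surfaces: list[trimesh.Trimesh], side: str,
                   iterations: int = 1) -> SurfaceAtlas:
    """Arithmetic vertex-wise mean of aligned surfaces on the shared
    sampling.  All inputs must share one triangulation."""
    if len(surfaces) < 2:
        raise ValueError("need >= 2 surfaces to build a template")
    f0 = np.asarray(surfaces[0].faces)
    for s in surfaces[1:]:
        if len(s.vertices) != len(surfaces[0].vertices) or \
                not np.array_equal(np.asarray(s.faces), f0):
            raise ValueError("surfaces do not share the sampling triangulation")
    mean_v = np.mean([np.asarray(s.vertices) for s in surfaces], axis=0)
    return SurfaceAtlas(mesh=as_mesh(mean_v, f0), side=side,
                        subjects=list(range(len(surfaces))),
                        iterations=iterations)


def procrustes_rigid(source: np.ndarray, target: np.ndarray
                     ) -> RigidTransform:
    """Closed-form least-squares rigid motion (no scaling) mapping
    source points onto target points with fixed correspondence (Kabsch)."""
    source = np.asarray(source, dtype=float)
    target = np.asarray(target, dtype=float)
    cs = source.mean(axis=0)
    ct = target.mean(axis=0)
    H = (source - cs).T @ (target - ct)
    U, _, Vt = np.linalg.svd(H)
    d = np.sign(np.linalg.det(Vt.T @ U.T))
    R = Vt.T @ np.diag([1.0, 1.0, d]) @ U.T
    return RigidTransform(R, ct - R @ cs)


def icosahedral_rotations() -> np.ndarray:
    """The 60 rotation matrices of the icosahedral group, generated by
    closure from a 5-fold and a 2-fold axis of the icosahedron."""
    gold = (1 + np.sqrt(5)) / 2
    # a vertex (5-fold axis) and an edge midpoint (2-fold axis)
    v5 = np.array([0.0, 1.0, gold])
    v5 /= np.linalg.norm(v5)
    v2 = np.array([0.0, 0.0, 1.0])

    def rot(axis, angle):
        K = np.array([[0, -axis[2], axis[1]],
                      [axis[2], 0, -axis[0]],
                      [-axis[1], axis[0], 0]])
        return np.eye(3) + np.sin(angle) * K + (1 - np.cos(angle)) * K @ K

    gens = [rot(v5, 2 * np.pi / 5), rot(v2, np.pi)]
    group = [np.eye(3)]
    changed = True
    while changed:
        changed = False
        for g in gens:
            for h in list(group):
                c = g @ h
                if not any(np.abs(c - k).max() < 1e-8 for k in group):
                    group.append(c)
                    changed = True
    assert len(group) == 60
    return np.array(group)


def _param_permutations(sampling_points: np.ndarray) -> np.ndarray:
    """Vertex permutations of the icosphere sampling induced by
    icosahedral rotations of the parameter sphere."""
    from scipy.spatial import cKDTree

    tree = cKDTree(sampling_points)
    perms = []
    for R in icosahedral_rotations():
        d, idx = tree.query(sampling_points @ R.T)
        if d.max() > 1e-6 or len(np.unique(idx)) != len(idx):
            continue  # rotation does not map the sampling onto itself
        perms.append(idx)
    return np.array(perms)


def register_shrec(surface: trimesh.Trimesh, atlas: SurfaceAtlas,
                   param_rotation_search: bool = False,
                   sampling_points: np.ndarray | None = None,
                   max_iter: int = 50, tol: float = 1e-8
                   ) -> tuple[trimesh.Trimesh, RigidTransform, float]:
    """Rigid ICP-style registration of a surface to the atlas.

    Alternates closed-form rigid Procrustes on the index-wise point
    correspondence with, optionally, a discrete search over icosahedral
    rotations of the parameter sphere that re-indexes the
    correspondence.  Returns (registered surface, total transform,
    final mean squared distance in mm^2); MSD never increases.
    """
    if len(surface.vertices) != len(atlas.mesh.vertices):
        raise ValueError("surface and atlas do not share the sampling")
    target = np.asarray(atlas.mesh.vertices)
    pts = np.asarray(surface.vertices, dtype=float)
    perm = np.arange(len(pts))
    total = RigidTransform.identity()

    perms = None
    if param_rotation_search:
        if sampling_points is None:
            raise ValueError("param_rotation_search needs the sampling points")
        perms = _param_permutations(sampling_points)

    def msd(p, idx):
        return float(((p[idx] - target) ** 2).sum(axis=1).mean())

    best = msd(pts, perm)
    for _ in range(max_iter):
        xf = procrustes_rigid(pts[perm], target)
        cand = xf.apply(pts)
        cur = msd(cand, perm)
        if cur <= best:
            pts = cand
            total = xf.compose(total)
            improved = best - cur
            best = cur
        else:
            improved = 0.0
        if perms is not None:
            # evaluate every candidate re-indexing at its own Procrustes
            # optimum, so the discrete search can escape ICP local minima
            for p in perms:
                xfp = procrustes_rigid(pts[p], target)
                mp = msd(xfp.apply(pts), p)
                if mp < best - tol:
                    improved += best - mp
                    best = mp
                    perm = p
                    pts = xfp.apply(pts)
                    total = xfp.compose(total)
        if improved < tol:
            break
    reg = as_mesh(pts[perm], atlas.mesh.faces)
    return reg, total, best
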