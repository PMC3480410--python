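"""Spherical-harmonic (SPHARM) expansion of genus-0 surfaces.

A surface with a bijective spherical parameterization is described by
expanding each coordinate function x, y, z over the sphere in real
orthonormal spherical harmonics.  Truncating the expansion at degree 1
gives the first-order ellipsoid (FOE), whose axes establish the initial
cross-subject alignment.

Real-harmonic convention (no Condon-Shortley phase):

    Y_{l,0}            = N_{l0} P_l^0(cos theta)
    Y_{l,m},  m > 0    = sqrt(2) N_{lm} P_l^m(cos theta) cos(m phi)
    Y_{l,-m}, m > 0    = sqrt(2) N_{lm} P_l^m(cos theta) sin(m phi)

with N_lm the full orthonormalization constant, so in particular
Y_0^0 = 1/sqrt(4 pi) and Y_1^0 = sqrt(3/(4 pi)) cos(theta), and on the
unit sphere (Y_{1,-1}, Y_{1,0}, Y_{1,1}) = sqrt(3/(4 pi)) (y, z, x).
"""

from __future__ import annotations

import json
from dataclasses import dataclass

import numpy as np
import trimesh
from scipy.special import sph_harm_y

from .meshes import as_mesh, icosphere

_Y1 = np.sqrt(3.0 / (4.0 * np.pi))  # degree-1 normalization


def real_sph_harm_basis(theta: np.ndarray, phi: np.ndarray, L: int) -> np.ndarray:
    """Design matrix of real orthonormal harmonics, shape (n, (L+1)^2).

    Columns are ordered (l, m) lexicographically: (0,0), (1,-1), (1,0),
    (1,1), (2,-2), ...
    """
    theta = np.asarray(theta, dtype=float).ravel()
    phi = np.asarray(phi, dtype=float).ravel()
    n = len(theta)
    B = np.empty((n, (L + 1) ** 2))
    col = 0
    for l in range(L + 1):
        # complex harmonics for m >= 0; scipy includes Condon-Shortley,
        # cancelled below by the (-1)^m factor
        ylm = [sph_harm_y(l, m, theta, phi) for m in range(l + 1)]
        for m in range(-l, l + 1):
            am = abs(m)
            sgn = (-1.0) ** am
            if m < 0:
                B[:, col] = np.sqrt(2.0) * sgn * ylm[am].imag
            elif m == 0:
                B[:, col] = ylm[0].real
            else:
                B[:, col] = np.sqrt(2.0) * sgn * ylm[am].real
            col += 1
    return B


def sphere_angles(unit_points: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    """(theta, phi) of unit vectors; theta colatitude, phi in [0, 2pi)."""
    p = np.asarray(unit_points, dtype=float)
    theta = np.arccos(np.clip(p[:, 2], -1.0, 1.0))
    phi = np.mod(np.arctan2(p[:, 1], p[:, 0]), 2.0 * np.pi)
    return theta, phi


@dataclass
class SpharmModel:
    """Per-coordinate SPHARM coefficients up to degree ``degree``.

    ``coefficients`` has shape (3, (degree+1)^2), rows x/y/z in mm,
    columns in (l, m) lexicographic order under the real-harmonic
    convention of this module.  ``residual_rms`` is the per-coordinate
    RMS of the least-squares fitting residual.
    """

    degree: int
    coefficients: np.ndarray
    residual_rms: np.ndarray | None = None
    convention: str = "real-orthonormal-csfree"

    def __post_init__(self) -> None:
        self.coefficients = np.asarray(self.coefficients, dtype=float)
        if self.coefficients.shape != (3, (self.degree + 1) ** 2):
            raise ValueError("coefficient array shape does not match degree")

    def to_json(self, path) -> None:
        with open(path, "w") as fh:
            json.dump({"degree": self.degree,
                       "convention": self.convention,
                       "coefficients": self.coefficients.tolist(),
                       "residual_rms": (None if self.residual_rms is None
                                        else list(self.residual_rms))}, fh)

    @classmethod
    def from_json(cls, path) -> "SpharmModel":
        with open(path) as fh:
            d = json.load(fh)
        rr = d.get("residual_rms")
        return cls(degree=d["degree"], coefficients=np.array(d["coefficients"]),
                   residual_rms=None if rr is None else np.array(rr),
                   convention=d.get("convention", "real-orthonormal-csfree"))


@dataclass
class FirstOrderEllipsoid:
    """Center, semi-axes (sorted descending, mm) and orthonormal axis frame
    (columns of ``axes``) of the degree-1 SPHARM reconstruction."""

    center: np.ndarray
    semi_axes: np.ndarray
    axes: np.ndarray
    degenerate: bool = False


def fit_coefficients(mesh: trimesh.Trimesh, theta: np.ndarray,
                     phi: np.ndarray, L: int) -> SpharmModel:
    """Least-squares SPHARM fit of mesh coordinates at parameter angles.

    Solves basis @ c = coords per coordinate channel via one QR-based
    solve; requires at least (L+1)^2 vertices.
    """
    n_coef = (L + 1) ** 2
    if len(mesh.vertices) < n_coef:
        raise ValueError(
            f"underdetermined SPHARM system: degree {L} needs >= {n_coef} "
            f"vertices, got {len(mesh.vertices)}")
    B = real_sph_harm_basis(theta, phi, L)
    coef, *_ = np.linalg.lstsq(B, np.asarray(mesh.vertices), rcond=None)
    resid = np.asarray(mesh.vertices) - B @ coef
    rms = np.sqrt((resid ** 2).mean(axis=0))
    return SpharmModel(degree=L, coefficients=coef.T, residual_rms=rms)


def reconstruct(model: SpharmModel, degree: int | None = None,
                sampling: trimesh.Trimesh | None = None,
                sampling_level: int = 4) -> trimesh.Trimesh:
    """Evaluate the truncated expansion on a template sphere sampling.

    ``sampling`` must be a sphere triangulation (defaults to the shared
    icosphere at ``sampling_level``); its connectivity carries over to
    the reconstruction, establishing cross-subject correspondence.
    """
    d = model.degree if degree is None else degree
    if d > model.degree:
        raise ValueError(f"requested degree {d} exceeds model degree {model.degree}")
    if sampling is None:
        sampling = icosphere(level=sampling_level)
    theta, phi = sphere_angles(sampling.vertices)
    B = real_sph_harm_basis(theta, phi, d)
    coords = B @ model.coefficients[:, :(d + 1) ** 2].T
    return as_mesh(coords, sampling.faces)


def evaluate(model: SpharmModel, theta: np.ndarray, phi: np.ndarray,
             degree: int | None = None) -> np.ndarray:
    """Surface points of the truncated expansion at arbitrary angles."""
    d = model.degree if degree is None else degree
    if d > model.degree:
        raise ValueError("degree exceeds model degree")
    B = real_sph_harm_basis(theta, phi, d)
    return B @ model.coefficients[:, :(d + 1) ** 2].T


def first_order_ellipsoid(model: SpharmModel,
                          degenerate_ratio: float = 0.02) -> FirstOrderEllipsoid:
    """Extract the first-order ellipsoid from degree-0/1 coefficients.

    The degree-1 part of the expansion is p(u) = center + M u with u the
    unit parameter direction; SVD of M gives the orthonormal axis frame
    and semi-axes.  Axis signs are fixed deterministically (largest
    component positive, right-handed frame).  ``degenerate`` is set when
    two semi-axes agree within ``degenerate_ratio``, in which case the
    axis frame is unreliable for alignment.
    """
    if model.degree < 1:
        raise ValueError("FOE requires degree >= 1")
    c = model.coefficients
    center = c[:, 0] / np.sqrt(4.0 * np.pi)
    # columns (1,-1),(1,0),(1,1) multiply (y, z, x): reorder to (x, y, z)
    M = _Y1 * c[:, [3, 1, 2]]
    U, S, Vt = np.linalg.svd(M)
    order = np.argsort(S)[::-1]
    S = S[order]
    U = U[:, order]
    for k in range(3):
        j = np.argmax(np.abs(U[:, k]))
        if U[j, k] < 0:
            U[:, k] = -U[:, k]
    if np.linalg.det(U) < 0:
        U[:, 2] = -U[:, 2]
    ratios = S[:-1] / np.maximum(S[1:], 1e-30)
    degenerate = bool((ratios < 1.0 + degenerate_ratio).any())
    return FirstOrderEllipsoid(center=center, semi_axes=S, axes=U,
                               degenerate=degenerate)


def canonical_param_rotation(model: SpharmModel) -> np.ndarray:
    """Parameter-sphere rotation putting the degree-1 map in standard
    position.

    The degree-1 expansion maps parameter direction u to center + M u.
    With M = U S V^T (axes sign-fixed as in ``first_order_ellipsoid``),
    re-parameterizing by u' = V^T u turns the map into U S u': every
    subject's parameter x/y/z axes then point to the same (sorted)
    ellipsoid axes, which is what makes "same parameter location" a
    consistent correspondence across subjects.  Apply as
    ``param.points @ V`` before refitting.
    """
    foe = first_order_ellipsoid(model)
    M = _Y1 * model.coefficients[:, [3, 1, 2]]
    V = M.T @ foe.axes @ np.diag(1.0 / np.maximum(foe.semi_axes, 1e-12))
    # orthonormalize against numerical drift
    Uq, _, Vq = np.linalg.svd(V)
    V = Uq @ Vq
    if np.linalg.det(V) < 0:
        raise ValueError("orientation-reversing parameterization; the "
                         "spherical map must be orientation-preserving")
    return V


def translate_model(model: SpharmModel, t: np.ndarray) -> SpharmModel:
    """Translate the represented surface by t (only c_0^0 changes)."""
    c = model.coefficients.copy()
    c[:, 0] = c[:, 0] + np.asarray(t, dtype=float) * np.sqrt(4.0 * np.pi)
    return SpharmModel(degree=model.degree, coefficients=c,
                       residual_rms=model.residual_rms)


def rotate_model(model: SpharmModel, R: np.ndarray) -> SpharmModel:
    """Rotate the represented surface in object space by R.

    Object-space rotation mixes only the x/y/z coefficient channels:
    c_lm -> R c_lm for every (l, m); the parameterization is untouched.
    """
    R = np.asarray(R, dtype=float)
    return SpharmModel(degree=model.degree, coefficients=R @ model.coefficients,
                       residual_rms=model.residual_rms)
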