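"""Bijective spherical parameterization with distortion control.

A genus-0 mesh is mapped one-to-one onto the unit sphere.  The initial
map solves two discrete Laplace problems in the style of the classical
quadrilateral-net parameterization: a latitude field between two pole
vertices (remapped through its area CDF so latitude bands carry equal
object area, which makes the map near-identity for spherical inputs)
and a longitude field on the mesh cut open along a pole-to-pole date
line.  The map is then improved by CALD-style local optimization that
reduces the area distortion cost (ADC) while keeping the worst average
length distortion cost (LDC) capped and never flipping a spherical
triangle.

Distortion costs (for face k let o_k be its fraction of total object
area and s_k its fraction of total spherical area 4 pi; for edge e let
r_e be the spherical/object normalized length ratio):

    ADC = mean_k max(s_k / o_k, o_k / s_k)
    LDC = max over vertices of mean over incident edges of max(r_e, 1/r_e)

Both equal 1 exactly when the mesh is a uniformly scaled sphere sampled
by the same triangulation.
"""

from __future__ import annotations

import json
import warnings
from dataclasses import dataclass, field

import numpy as np
import trimesh
from scipy import sparse
from scipy.sparse.csgraph import shortest_path
from scipy.sparse.linalg import spsolve

from .meshes import check_closed_oriented, euler_characteristic


@dataclass
class SphericalParameterization:
    """Unit-sphere positions of mesh vertices, sharing the mesh faces."""

    points: np.ndarray  # (n, 3) unit vectors
    faces: np.ndarray

    def __post_init__(self) -> None:
        self.points = np.asarray(self.points, dtype=float)
        self.points = self.points / np.linalg.norm(self.points, axis=1, keepdims=True)
        self.faces = np.asarray(self.faces, dtype=np.int64)

    @property
    def theta(self) -> np.ndarray:
        return np.arccos(np.clip(self.points[:, 2], -1.0, 1.0))

    @property
    def phi(self) -> np.ndarray:
        return np.mod(np.arctan2(self.points[:, 1], self.points[:, 0]), 2 * np.pi)

    def spherical_areas(self) -> np.ndarray:
        """Signed solid angles of the spherical triangles (sum 4 pi)."""
        return _solid_angles(self.points, self.faces)

    def n_flipped(self) -> int:
        return int((self.spherical_areas() <= 0).sum())

    def save_tsv(self, path) -> None:
        th, ph = self.theta, self.phi
        with open(path, "w") as fh:
            fh.write("vertex\ttheta\tphi\n")
            for i, (t, p) in enumerate(zip(th, ph)):
                fh.write(f"{i}\t{t:.12g}\t{p:.12g}\n")


@dataclass
class DistortionReport:
    adc: float
    ldc: float
    face_area_ratios: np.ndarray = field(repr=False)
    edge_length_ratios: np.ndarray = field(repr=False)
    iterations: int = 0

    def to_json(self, path) -> None:
        with open(path, "w") as fh:
            json.dump({"adc": self.adc, "ldc": self.ldc,
                       "iterations": self.iterations,
                       "face_area_ratios": self.face_area_ratios.tolist(),
                       "edge_length_ratios": self.edge_length_ratios.tolist()},
                      fh)


def _solid_angles(points: np.ndarray, faces: np.ndarray) -> np.ndarray:
    v1 = points[faces[:, 0]]
    v2 = points[faces[:, 1]]
    v3 = points[faces[:, 2]]
    det = np.einsum("ij,ij->i", v1, np.cross(v2, v3))
    denom = (1.0 + np.einsum("ij,ij->i", v1, v2)
             + np.einsum("ij,ij->i", v2, v3)
             + np.einsum("ij,ij->i", v3, v1))
    return 2.0 * np.arctan2(det, denom)


def _uniform_laplacian(n: int, edges: np.ndarray) -> sparse.csr_matrix:
    rows = np.concatenate([edges[:, 0], edges[:, 1]])
    cols = np.concatenate([edges[:, 1], edges[:, 0]])
    A = sparse.csr_matrix((np.ones(len(rows)), (rows, cols)), shape=(n, n))
    return (sparse.diags(np.asarray(A.sum(axis=1)).ravel()) - A).tocsr()


def _solve_dirichlet(L: sparse.csr_matrix, fixed_idx: np.ndarray,
                     fixed_val: np.ndarray) -> np.ndarray:
    n = L.shape[0]
    free = np.setdiff1d(np.arange(n), fixed_idx)
    x = np.zeros(n)
    x[fixed_idx] = fixed_val
    rhs = -L[free][:, fixed_idx] @ fixed_val
    x[free] = spsolve(L[free][:, free].tocsc(), rhs)
    return x


def _vertex_ring_successors(mesh: trimesh.Trimesh, v: int) -> dict[int, int]:
    """For faces (v, x, y) (CCW), map x -> y; traversing gives the
    one-ring neighbors of v in cyclic order."""
    succ = {}
    for f in mesh.vertex_faces[v]:
        if f < 0:
            continue
        tri = list(mesh.faces[f])
        i = tri.index(v)
        succ[tri[(i + 1) % 3]] = tri[(i + 2) % 3]
    return succ


def _faces_between(mesh: trimesh.Trimesh, v: int, start: int, stop: int
                   ) -> set[int]:
    """Face ids of the fan around v walked CCW from neighbor ``start``
    up to (and excluding the fan beyond) neighbor ``stop``."""
    succ = _vertex_ring_successors(mesh, v)
    face_of_pair = {}
    for f in mesh.vertex_faces[v]:
        if f < 0:
            continue
        tri = list(mesh.faces[f])
        i = tri.index(v)
        face_of_pair[tri[(i + 1) % 3]] = f
    out = set()
    x = start
    guard = 0
    while x != stop:
        out.add(face_of_pair[x])
        x = succ[x]
        guard += 1
        if guard > len(succ) + 1:
            raise RuntimeError("broken one-ring walk")
    return out


def initial_map(mesh: trimesh.Trimesh,
                pole_axes: tuple[int, ...] = (2, 0, 1),
                untangle_sweeps: int = 50) -> SphericalParameterization:
    """Initial bijective spherical map of a closed genus-0 mesh.

    Vertices already lying on a common sphere about their centroid map
    by radial projection (the exact solution).  Otherwise: latitude by
    a Laplace solve between extremal-axis pole vertices, remapped
    through the object-area CDF; longitude by a Laplace solve on the
    mesh cut along a pole-to-pole date line; local untangling sweeps
    remove any flipped spherical triangles.  Raises if no candidate
    pole axis yields a flip-free map.
    """
    check_closed_oriented(mesh)
    if euler_characteristic(mesh) != 2:
        raise ValueError("spherical parameterization requires a genus-0 mesh")

    v = np.asarray(mesh.vertices, dtype=float)
    centered = v - v.mean(axis=0)
    radii = np.linalg.norm(centered, axis=1)
    if radii.std() / radii.mean() < 1e-9:
        return SphericalParameterization(points=centered / radii[:, None],
                                         faces=mesh.faces)

    last_err: Exception | None = None
    for axis in pole_axes:
        try:
            param = _laplace_initial_map(mesh, axis)
        except (RuntimeError, ValueError) as err:  # degenerate cut for this axis
            last_err = err
            continue
        if param.n_flipped() > 0:
            param = _untangle(param, sweeps=untangle_sweeps)
        if param.n_flipped() == 0:
            return param
        last_err = ValueError(
            f"{param.n_flipped()} flipped spherical triangles remain "
            f"(pole axis {axis})")
    raise ValueError(f"could not build a bijective spherical map: {last_err}")


def _laplace_initial_map(mesh: trimesh.Trimesh, axis: int
                         ) -> SphericalParameterization:
    v = np.asarray(mesh.vertices, dtype=float)
    n = len(v)
    faces = np.asarray(mesh.faces)
    edges = mesh.edges_unique
    north = int(np.lexsort((np.arange(n), -v[:, axis]))[0])
    south = int(np.lexsort((np.arange(n), v[:, axis]))[0])
    if north == south:
        raise ValueError("degenerate pole pair")

    L = _uniform_laplacian(n, edges)
    lat = _solve_dirichlet(L, np.array([north, south]), np.array([0.0, 1.0]))

    # equal-area latitude: remap the scalar through the object-area CDF
    # so cos(theta) is uniform in accumulated area
    lumped = np.zeros(n)
    np.add.at(lumped, faces.ravel(), np.repeat(mesh.area_faces / 3.0, 3))
    order = np.argsort(lat, kind="stable")
    cdf = np.empty(n)
    cdf[order] = np.cumsum(lumped[order]) - 0.5 * lumped[order]
    cdf /= lumped.sum()
    theta = np.arccos(np.clip(1.0 - 2.0 * cdf, -1.0, 1.0))
    theta[north], theta[south] = 0.0, np.pi

    # date line: graph shortest path north -> south (euclidean weights)
    w = np.linalg.norm(v[edges[:, 0]] - v[edges[:, 1]], axis=1)
    G = sparse.csr_matrix(
        (np.r_[w, w], (np.r_[edges[:, 0], edges[:, 1]],
                       np.r_[edges[:, 1], edges[:, 0]])), shape=(n, n))
    _, pred = shortest_path(G, indices=north, return_predecessors=True)
    path = [south]
    while path[-1] != north:
        p = pred[path[-1]]
        if p < 0:
            raise RuntimeError("poles are not connected")
        path.append(int(p))
    path = path[::-1]  # north ... south
    if len(path) < 3:
        raise ValueError("date line has no interior vertex")
    interior = path[1:-1]

    # cut the mesh along the path: west-side faces use duplicated indices
    west_faces: set[int] = set()
    for i, vi in enumerate(interior, start=1):
        east = _faces_between(mesh, vi, path[i - 1], path[i + 1])
        all_f = {int(f) for f in mesh.vertex_faces[vi] if f >= 0}
        west_faces |= (all_f - east)
    dup = {vi: n + k for k, vi in enumerate(interior)}
    faces_cut = faces.copy()
    for f in west_faces:
        for c in range(3):
            if int(faces_cut[f, c]) in dup:
                faces_cut[f, c] = dup[int(faces_cut[f, c])]
    n_cut = n + len(interior)

    e0 = np.sort(np.concatenate([faces_cut[:, [0, 1]], faces_cut[:, [1, 2]],
                                 faces_cut[:, [2, 0]]]), axis=1)
    e0 = np.unique(e0, axis=0)
    # drop pole-incident edges: poles carry no longitude
    keep = ~np.isin(e0, (north, south)).any(axis=1)
    Lc = _uniform_laplacian(n_cut, e0[keep])

    fixed_idx = np.array(interior + [dup[vi] for vi in interior]
                         + [north, south])
    fixed_val = np.r_[np.zeros(len(interior)),
                      np.full(len(interior), 2 * np.pi), 0.0, 0.0]
    phi_cut = _solve_dirichlet(Lc, fixed_idx, fixed_val)
    phi = phi_cut[:n]

    pts = np.column_stack([np.sin(theta) * np.cos(phi),
                           np.sin(theta) * np.sin(phi),
                           np.cos(theta)])
    # fix the longitude handedness so the map is orientation-preserving
    if _solid_angles(pts, faces).sum() < 0:
        pts[:, 1] = -pts[:, 1]
    return SphericalParameterization(points=pts, faces=faces)


def _build_rings(faces: np.ndarray, n: int):
    """vertex -> incident faces and vertex -> neighbor vertices."""
    vf = [[] for _ in range(n)]
    nb = [set() for _ in range(n)]
    for fi, (a, b, c) in enumerate(faces):
        vf[a].append(fi); vf[b].append(fi); vf[c].append(fi)
        nb[a] |= {b, c}; nb[b] |= {a, c}; nb[c] |= {a, b}
    return ([np.array(x) for x in vf],
            [np.array(sorted(x)) for x in nb])


def _untangle(param: SphericalParameterization, sweeps: int = 50
              ) -> SphericalParameterization:
    """Jacobi sweeps of neighbor averaging on vertices touching flipped
    spherical triangles, projected back to the sphere."""
    pts = param.points.copy()
    faces = param.faces
    vf, nb = _build_rings(faces, len(pts))
    for _ in range(sweeps):
        areas = _solid_angles(pts, faces)
        bad = np.nonzero(areas <= 0)[0]
        if len(bad) == 0:
            break
        verts = np.unique(faces[bad].ravel())
        new = pts.copy()
        for vi in verts:
            m = pts[nb[vi]].mean(axis=0)
            nm = np.linalg.norm(m)
            if nm > 1e-12:
                new[vi] = m / nm
        pts = new
    return SphericalParameterization(points=pts, faces=faces)


def distortion_report(param: SphericalParameterization,
                      mesh: trimesh.Trimesh,
                      iterations: int = 0) -> DistortionReport:
    """ADC/LDC distortion costs of a parameterization."""
    o = mesh.area_faces / mesh.area
    s = param.spherical_areas() / (4 * np.pi)
    s = np.maximum(s, 1e-300)
    face_ratio = np.maximum(s / o, o / s)
    adc = float(face_ratio.mean())

    edges = mesh.edges_unique
    lo = np.linalg.norm(mesh.vertices[edges[:, 0]] - mesh.vertices[edges[:, 1]],
                        axis=1)
    dots = np.einsum("ij,ij->i", param.points[edges[:, 0]],
                     param.points[edges[:, 1]])
    ls = np.arccos(np.clip(dots, -1.0, 1.0))
    r = (ls / ls.sum()) / (lo / lo.sum())
    r = np.maximum(r, 1e-300)
    edge_cost = np.maximum(r, 1.0 / r)
    n = len(mesh.vertices)
    sums = np.zeros(n)
    counts = np.zeros(n)
    np.add.at(sums, edges.ravel(), np.repeat(edge_cost, 2))
    np.add.at(counts, edges.ravel(), 1)
    ldc = float((sums / np.maximum(counts, 1)).max())
    return DistortionReport(adc=adc, ldc=ldc, face_area_ratios=face_ratio,
                            edge_length_ratios=edge_cost, iterations=iterations)


def optimize_cald(param: SphericalParameterization, mesh: trimesh.Trimesh,
                  max_iter: int = 100, ldc_cap: float = 8.0,
                  rel_tol: float = 1e-4
                  ) -> tuple[SphericalParameterization, DistortionReport]:
    """CALD-style local optimization of the spherical map.

    Sweeps over vertices; each vertex is pulled toward the spherical
    centroids of its incident faces weighted by their object/spherical
    area imbalance, with step halving.  A move is accepted only if the
    summed area-distortion cost of the incident faces decreases, no
    incident triangle flips, and the vertex's length-distortion cost
    stays within ``ldc_cap``.  ADC is therefore non-increasing across
    sweeps; terminates at ``max_iter`` sweeps or relative ADC
    improvement below ``rel_tol``.
    """
    rep0 = distortion_report(param, mesh)
    if rep0.ldc > ldc_cap:
        warnings.warn(f"initial LDC {rep0.ldc:.3g} exceeds cap {ldc_cap:.3g}; "
                      "cap relaxed to initial LDC")
        ldc_cap = rep0.ldc

    pts = param.points.copy()
    faces = param.faces
    n = len(pts)
    vf, nb = _build_rings(faces, n)
    o_frac = mesh.area_faces / mesh.area  # fixed object-area fractions

    edges = mesh.edges_unique
    lo = np.linalg.norm(mesh.vertices[edges[:, 0]] - mesh.vertices[edges[:, 1]],
                        axis=1)
    lo_frac = lo / lo.sum()
    ve = [[] for _ in range(n)]
    for ei, (a, b) in enumerate(edges):
        ve[a].append(ei); ve[b].append(ei)
    ve = [np.array(x) for x in ve]

    def face_cost(p, fidx):
        s = _solid_angles(p, faces[fidx]) / (4 * np.pi)
        if (s <= 0).any():
            return np.inf
        o = o_frac[fidx]
        return np.maximum(s / o, o / s).sum()

    adc_prev = rep0.adc
    it = 0
    for it in range(1, max_iter + 1):
        ls_all = np.arccos(np.clip(
            np.einsum("ij,ij->i", pts[edges[:, 0]], pts[edges[:, 1]]), -1, 1))
        ls_total = ls_all.sum()  # sweep-constant normalization for LDC

        for vi in range(n):
            fidx = vf[vi]
            tri = pts[faces[fidx]]
            cents = tri.mean(axis=1)
            cents /= np.linalg.norm(cents, axis=1, keepdims=True)
            s = np.abs(_solid_angles(pts, faces[fidx])) / (4 * np.pi)
            wgt = o_frac[fidx] / np.maximum(s, 1e-30)
            target = (cents * wgt[:, None]).sum(axis=0)
            tn = np.linalg.norm(target)
            if tn < 1e-12:
                continue
            target /= tn
            base = face_cost(pts, fidx)
            old = pts[vi].copy()
            step = 0.5
            for _ in range(3):
                cand = old + step * (target - old)
                cand /= np.linalg.norm(cand)
                pts[vi] = cand
                new_cost = face_cost(pts, fidx)
                if new_cost < base:
                    eidx = ve[vi]
                    ls = np.arccos(np.clip(np.einsum(
                        "ij,ij->i", pts[edges[eidx, 0]], pts[edges[eidx, 1]]),
                        -1, 1))
                    r = (ls / ls_total) / lo_frac[eidx]
                    r = np.maximum(r, 1e-300)
                    if np.maximum(r, 1.0 / r).mean() <= ldc_cap:
                        break
                pts[vi] = old
                step *= 0.5
            else:
                pts[vi] = old

        cur = SphericalParameterization(points=pts, faces=faces)
        adc = distortion_report(cur, mesh).adc
        if adc_prev - adc < rel_tol * adc_prev:
            adc_prev = adc
            break
        adc_prev = adc

    out = SphericalParameterization(points=pts, faces=faces)
    rep = distortion_report(out, mesh, iterations=it)
    return out, rep
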