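"""Sliding semilandmarks by bending-energy minimization.

Semilandmarks have no exact anatomical homology along their curve or surface;
their along-structure positions are free parameters. Sliding relaxes them so
that the thin-plate-spline bending energy of the map from a template to the
specimen is minimal, with each semilandmark confined to its local tangent
line (curve points, direction from ordinal neighbours) or tangent plane
(surface points, normal from the mesh or from a local PCA of the k nearest
points). After the algebraic slide along tangents, points are projected back
onto the curve polyline or the mesh surface.

The energy of an interpolating TPS with fixed sources S and targets Y is the
quadratic form -tr(Y^T B Y) with B the bending-energy matrix of S, so the
constrained minimization over tangent offsets is a sparse-structured linear
solve, not an iterative optimization.
"""

from __future__ import annotations

import numpy as np

import trimesh

from .landmarks import LandmarkConfiguration, LandmarkKind
from .tps import bending_energy_matrix


class CurveTopologyError(ValueError):
    """Raised when a curve semilandmark lacks ordered neighbours."""


def project_to_curve(point: np.ndarray, polyline: np.ndarray) -> np.ndarray:
    """Nearest point on a piecewise-linear curve (Euclidean metric).

    Ties between segments are broken toward the lower segment index.
    """
    poly = np.atleast_2d(np.asarray(polyline, dtype=float))
    if len(poly) == 0:
        raise ValueError("empty polyline")
    if len(poly) == 1:
        return poly[0].copy()
    p = np.asarray(point, dtype=float).reshape(3)
    a, b = poly[:-1], poly[1:]
    ab = b - a
    denom = (ab ** 2).sum(axis=1)
    denom[denom == 0] = 1.0
    t = np.clip(((p - a) * ab).sum(axis=1) / denom, 0.0, 1.0)
    cand = a + t[:, None] * ab
    d2 = ((cand - p) ** 2).sum(axis=1)
    return cand[int(np.argmin(d2))].copy()  # argmin takes the first (lowest) index


def _closest_on_triangle(p: np.ndarray, a: np.ndarray, b: np.ndarray,
                         c: np.ndarray) -> np.ndarray:
    # Ericson, Real-Time Collision Detection, 5.1.5
    ab, ac, ap = b - a, c - a, p - a
    d1, d2 = ab @ ap, ac @ ap
    if d1 <= 0 and d2 <= 0:
        return a
    bp = p - b
    d3, d4 = ab @ bp, ac @ bp
    if d3 >= 0 and d4 <= d3:
        return b
    vc = d1 * d4 - d3 * d2
    if vc <= 0 and d1 >= 0 and d3 <= 0:
        v = d1 / (d1 - d3)
        return a + v * ab
    cp = p - c
    d5, d6 = ab @ cp, ac @ cp
    if d6 >= 0 and d5 <= d6:
        return c
    vb = d5 * d2 - d1 * d6
    if vb <= 0 and d2 >= 0 and d6 <= 0:
        w = d2 / (d2 - d6)
        return a + w * ac
    va = d3 * d6 - d5 * d4
    if va <= 0 and (d4 - d3) >= 0 and (d5 - d6) >= 0:
        w = (d4 - d3) / ((d4 - d3) + (d5 - d6))
        return b + w * (c - b)
    denom = 1.0 / (va + vb + vc)
    v = vb * denom
    w = vc * denom
    return a + ab * v + ac * w


def project_to_surface(point: np.ndarray, mesh: trimesh.Trimesh,
                       return_face: bool = False):
    """Nearest point on a triangle mesh; ties go to the lower face index."""
    if len(mesh.faces) == 0:
        raise ValueError("empty mesh")
    p = np.asarray(point, dtype=float).reshape(3)
    tri = mesh.triangles
    best = None
    best_face = 0
    best_d2 = np.inf
    for f in range(len(tri)):
        q = _closest_on_triangle(p, tri[f, 0], tri[f, 1], tri[f, 2])
        d2 = float(((q - p) ** 2).sum())
        if best is None or d2 < best_d2:
            best_d2, best, best_face = d2, q, f
    if return_face:
        return np.asarray(best), best_face
    return np.asarray(best)


def _curve_tangent(coords: np.ndarray, pos: int, curve_positions: list[int]
                   ) -> np.ndarray:
    k = curve_positions.index(pos)
    if len(curve_positions) < 2:
        raise CurveTopologyError("curve has a single point; no tangent")
    if k == 0:
        d = coords[curve_positions[1]] - coords[curve_positions[0]]
    elif k == len(curve_positions) - 1:
        d = coords[curve_positions[-1]] - coords[curve_positions[-2]]
    else:
        d = coords[curve_positions[k + 1]] - coords[curve_positions[k - 1]]
    n = np.linalg.norm(d)
    if n == 0:
        raise CurveTopologyError("degenerate curve tangent (coincident neighbours)")
    return d / n


def _surface_tangent_basis(coords: np.ndarray, pos: int,
                           mesh: trimesh.Trimesh | None, k: int = 8
                           ) -> np.ndarray:
    p = coords[pos]
    if mesh is not None and len(mesh.faces) > 0:
        _, fid = project_to_surface(p, mesh, return_face=True)
        normal = mesh.face_normals[int(fid)]
    else:
        d2 = ((coords - p) ** 2).sum(axis=1)
        order = np.argsort(d2)
        nbr = coords[order[1:k + 1]]
        nbr = nbr - nbr.mean(axis=0)
        _, _, Vt = np.linalg.svd(nbr, full_matrices=False)
        normal = Vt[-1]
    # complete an orthonormal tangent basis
    ref = np.array([1.0, 0.0, 0.0])
    if abs(normal @ ref) > 0.9:
        ref = np.array([0.0, 1.0, 0.0])
    t1 = np.cross(normal, ref)
    t1 /= np.linalg.norm(t1)
    t2 = np.cross(normal, t1)
    return np.column_stack([t1, t2])


def _config_energy(B: np.ndarray, Y: np.ndarray) -> float:
    return max(-float(np.trace(Y.T @ B @ Y)), 0.0)


def slide_semilandmarks(config: LandmarkConfiguration,
                        template: LandmarkConfiguration, *,
                        iterations: int = 3,
                        mesh: trimesh.Trimesh | None = None,
                        curves: dict[str, np.ndarray] | None = None,
                        knn: int = 8) -> LandmarkConfiguration:
    """Slide semilandmarks of ``config`` to minimize TPS bending energy
    against ``template``.

    Anatomical landmarks never move. Curve semilandmarks slide along the
    tangent of their ordered neighbours and are projected back onto the curve
    polyline (``curves`` maps curve_id to a polyline array; defaults to the
    input semilandmark chain itself). Surface semilandmarks slide in their
    tangent plane and are projected back onto ``mesh`` when one is given.
    Tangents are recomputed each iteration. Bending energy with respect to
    the template is non-increasing across iterations: an iteration whose
    back-projection would raise the energy is rolled back and sliding stops.
    """
    if iterations < 1:
        raise ValueError("iterations must be >= 1")
    tpl = template
    if config.template.ids != tpl.template.ids:
        raise ValueError("config and template must share a landmark template")
    slide_pos = [i for i, d in enumerate(config.template)
                 if d.kind is not LandmarkKind.ANATOMICAL]
    if not slide_pos:
        return config.copy()
    for i in slide_pos:
        if not (config.present[i] and tpl.present[i]):
            raise ValueError("sliding requires the sliding subset complete "
                             "in both config and template")
    curve_map = config.template.curves()
    curve_positions = {cid: [config.template.index_of(l) for l in lids]
                       for cid, lids in curve_map.items()}
    if curves is None:
        curves = {cid: config.coords[pos_list].copy()
                  for cid, pos_list in curve_positions.items()}

    B = bending_energy_matrix(tpl.coords)
    Q = -B  # PSD on the side-condition subspace
    Y = config.coords.copy()
    energy = _config_energy(B, Y)

    for _ in range(iterations):
        # tangent bases, recomputed from current positions
        bases: dict[int, np.ndarray] = {}
        for i in slide_pos:
            d = config.template.defs[i]
            if d.kind is LandmarkKind.CURVE_SEMILANDMARK and d.curve_id:
                t = _curve_tangent(Y, i, curve_positions[d.curve_id])
                bases[i] = t[:, None]
            else:
                bases[i] = _surface_tangent_basis(Y, i, mesh, k=knn)
        dims = [bases[i].shape[1] for i in slide_pos]
        offsets = np.concatenate([[0], np.cumsum(dims)])
        D = offsets[-1]
        H = np.zeros((D, D))
        g = np.zeros(D)
        QY = Q @ Y
        for a_k, i in enumerate(slide_pos):
            Ti = bases[i]
            g[offsets[a_k]:offsets[a_k + 1]] = Ti.T @ QY[i]
            for b_k, j in enumerate(slide_pos):
                H[offsets[a_k]:offsets[a_k + 1], offsets[b_k]:offsets[b_k + 1]] = \
                    Q[i, j] * (Ti.T @ bases[j])
        t_opt, *_ = np.linalg.lstsq(H, -g, rcond=None)
        Y_new = Y.copy()
        for a_k, i in enumerate(slide_pos):
            Y_new[i] = Y[i] + bases[i] @ t_opt[offsets[a_k]:offsets[a_k + 1]]
        # project back onto the geometry
        for i in slide_pos:
            d = config.template.defs[i]
            if d.kind is LandmarkKind.CURVE_SEMILANDMARK and d.curve_id:
                Y_new[i] = project_to_curve(Y_new[i], curves[d.curve_id])
            elif mesh is not None:
                Y_new[i] = project_to_surface(Y_new[i], mesh)
        new_energy = _config_energy(B, Y_new)
        if new_energy > energy + 1e-12 * max(energy, 1.0):
            break  # projection undid the gain; keep the previous state
        Y, energy = Y_new, new_energy

    return config.with_coords(Y)
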