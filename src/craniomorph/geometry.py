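"""Procrustes superimposition, shape PCA, midplane estimation, reflection.

Ordinary Procrustes alignment (OPA) follows the SVD/Umeyama construction;
reflections are disallowed by default because anatomical chirality must be
preserved. Generalized Procrustes analysis (GPA) iterates align-to-consensus
with the consensus kept centred and, under the scaling convention, at unit
centroid size.

The Procrustes distance between partially overlapping configurations is the
partial Procrustes distance on the mutually present landmark subset: both
subsets are centred, scaled to unit centroid size, optimally rotated, and the
root summed squared difference is returned.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .landmarks import (
    BilateralPairing,
    LandmarkConfiguration,
    PairingError,
    Plane,
    Side,
)


class DegenerateGeometryError(ValueError):
    """Raised when input geometry is too degenerate for an operation."""


@dataclass(frozen=True)
class SimilarityTransform:
    """x -> scale * rotation @ x + translation."""

    rotation: np.ndarray
    scale: float
    translation: np.ndarray
    reflection_allowed: bool = False

    def __post_init__(self) -> None:
        R = np.asarray(self.rotation, dtype=float).reshape(3, 3)
        if np.abs(R @ R.T - np.eye(3)).max() > 1e-10:
            raise ValueError("rotation matrix is not orthogonal")
        if self.scale <= 0:
            raise ValueError("scale must be positive")
        object.__setattr__(self, "rotation", R)
        object.__setattr__(
            self, "translation", np.asarray(self.translation, float).reshape(3)
        )

    def apply(self, points: np.ndarray) -> np.ndarray:
        pts = np.atleast_2d(np.asarray(points, dtype=float))
        return self.scale * pts @ self.rotation.T + self.translation

    def compose(self, other: "SimilarityTransform") -> "SimilarityTransform":
        """Transform equivalent to applying ``other`` first, then ``self``."""
        return SimilarityTransform(
            rotation=self.rotation @ other.rotation,
            scale=self.scale * other.scale,
            translation=self.scale * self.rotation @ other.translation
            + self.translation,
            reflection_allowed=self.reflection_allowed or other.reflection_allowed,
        )

    @classmethod
    def identity(cls) -> "SimilarityTransform":
        return cls(np.eye(3), 1.0, np.zeros(3))


def centroid_size(coords: np.ndarray) -> float:
    """Square root of summed squared distances to the centroid."""
    pts = np.atleast_2d(np.asarray(coords, dtype=float))
    if len(pts) < 2:
        raise DegenerateGeometryError("centroid size requires at least 2 points")
    centred = pts - pts.mean(axis=0)
    return float(np.sqrt((centred ** 2).sum()))


def _optimal_rotation(source_c: np.ndarray, target_c: np.ndarray,
                      allow_reflection: bool) -> np.ndarray:
    """Rotation R minimizing ||target - source @ R.T||_F for centred inputs."""
    H = target_c.T @ source_c
    U, s, Vt = np.linalg.svd(H)
    d = np.sign(np.linalg.det(U @ Vt))
    if allow_reflection or d > 0:
        return U @ Vt
    D = np.diag([1.0, 1.0, -1.0])
    return U @ D @ Vt


def opa_align(source: np.ndarray, target: np.ndarray, *,
              allow_scaling: bool = True, allow_reflection: bool = False,
              ) -> tuple[SimilarityTransform, float]:
    """Least-squares similarity alignment of source onto target.

    Returns the optimal :class:`SimilarityTransform` and the residual RMS in
    source units. Collinear point sets produce a valid but ill-conditioned
    solution; a count mismatch raises.
    """
    src = np.atleast_2d(np.asarray(source, dtype=float))
    tgt = np.atleast_2d(np.asarray(target, dtype=float))
    if src.shape != tgt.shape:
        raise ValueError(f"point count mismatch: {src.shape} vs {tgt.shape}")
    if len(src) < 3:
        raise DegenerateGeometryError("OPA requires at least 3 points")
    mu_s, mu_t = src.mean(axis=0), tgt.mean(axis=0)
    sc, tc = src - mu_s, tgt - mu_t
    R = _optimal_rotation(sc, tc, allow_reflection)
    if allow_scaling:
        denom = (sc ** 2).sum()
        if denom == 0:
            raise DegenerateGeometryError("source points are coincident")
        scale = float((tc * (sc @ R.T)).sum() / denom)
        scale = max(scale, np.finfo(float).tiny)
    else:
        scale = 1.0
    t = mu_t - scale * R @ mu_s
    xform = SimilarityTransform(R, scale, t,
                                reflection_allowed=allow_reflection)
    resid = xform.apply(src) - tgt
    rms = float(np.sqrt((resid ** 2).sum() / len(src)))
    return xform, rms


def procrustes_distance(a: LandmarkConfiguration | np.ndarray,
                        b: LandmarkConfiguration | np.ndarray, *,
                        shared_only: bool = True,
                        allow_reflection: bool = False) -> float:
    """Partial Procrustes distance between two configurations.

    Both point sets (restricted to mutually present landmarks when
    ``shared_only``) are centred and scaled to unit centroid size, then
    optimally rotated; the root summed squared difference is returned.
    """
    if isinstance(a, LandmarkConfiguration) and isinstance(b, LandmarkConfiguration):
        if shared_only:
            mask = a.present & b.present
        else:
            mask = np.ones(a.n_landmarks, dtype=bool)
            if not (a.is_complete and b.is_complete):
                raise ValueError("shared_only=False requires complete configurations")
        pa, pb = a.coords[mask], b.coords[mask]
    else:
        pa = np.atleast_2d(np.asarray(a, dtype=float))
        pb = np.atleast_2d(np.asarray(b, dtype=float))
    if len(pa) < 3:
        raise DegenerateGeometryError(
            f"need >=3 shared present landmarks, got {len(pa)}"
        )
    ca = (pa - pa.mean(axis=0)) / centroid_size(pa)
    cb = (pb - pb.mean(axis=0)) / centroid_size(pb)
    R = _optimal_rotation(ca, cb, allow_reflection)
    return float(np.sqrt(((ca @ R.T - cb) ** 2).sum()))


@dataclass
class GPAResult:
    """Output of generalized Procrustes analysis."""

    aligned: list[np.ndarray]
    consensus: np.ndarray
    centroid_sizes: np.ndarray
    iterations: int
    converged: bool
    scaled: bool


def gpa(shapes: list[np.ndarray] | list[LandmarkConfiguration], *,
        scale: bool = True, tol: float = 1e-10, max_iter: int = 100,
        allow_reflection: bool = False) -> GPAResult:
    """Generalized Procrustes analysis of complete configurations.

    Iteratively aligns every shape to the current consensus and re-estimates
    the consensus until it moves by less than ``tol`` (RMS) or ``max_iter``
    iterations. Under ``scale=True`` (full Procrustes, the default) each shape
    is scaled in its alignment step and the consensus is normalised to unit
    centroid size; the consensus is always centred at the origin.
    """
    arrs = []
    for s in shapes:
        if isinstance(s, LandmarkConfiguration):
            if not s.is_complete:
                raise ValueError(f"GPA requires complete configurations "
                                 f"({s.specimen_id!r} has missing landmarks)")
            arrs.append(np.array(s.coords, dtype=float))
        else:
            arrs.append(np.array(s, dtype=float))
    if len(arrs) < 2:
        raise ValueError("GPA requires at least 2 configurations")
    sizes = np.array([centroid_size(a) for a in arrs])

    def _norm(x: np.ndarray) -> np.ndarray:
        x = x - x.mean(axis=0)
        return x / centroid_size(x) if scale else x

    base = [_norm(a) for a in arrs]
    aligned = list(base)
    consensus = _norm(np.mean(aligned, axis=0))
    converged = False
    it = 0
    for it in range(1, max_iter + 1):
        # re-align the normalized originals (not cumulatively) so a fixed
        # point of the iteration exists
        for k, a in enumerate(base):
            xform, _ = opa_align(a, consensus, allow_scaling=scale,
                                 allow_reflection=allow_reflection)
            aligned[k] = xform.apply(a)
        new_consensus = _norm(np.mean(aligned, axis=0))
        # pin the rotational indeterminacy: orient the new consensus on the
        # previous one, otherwise the whole constellation may drift
        xform, _ = opa_align(new_consensus, consensus, allow_scaling=False,
                             allow_reflection=allow_reflection)
        new_consensus = _norm(xform.apply(new_consensus))
        move = np.sqrt(((new_consensus - consensus) ** 2).mean())
        consensus = new_consensus
        if move < tol:
            converged = True
            break
    return GPAResult(aligned=aligned, consensus=consensus,
                     centroid_sizes=sizes, iterations=it,
                     converged=converged, scaled=scale)


def shape_pca(gpa_result: GPAResult) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    """PCA of vectorized aligned coordinates about the consensus.

    Returns (scores, components, explained_variance_fractions); fractions sum
    to 1 over the non-trivial components.
    """
    X = np.array([a.ravel() for a in gpa_result.aligned])
    if len(X) < 3:
        raise ValueError("shape PCA requires at least 3 shapes")
    mean = gpa_result.consensus.ravel()
    Xc = X - mean
    # residual mean may be slightly off the consensus; centre exactly
    Xc = Xc - Xc.mean(axis=0)
    U, s, Vt = np.linalg.svd(Xc, full_matrices=False)
    var = s ** 2
    total = var.sum()
    if total == 0:
        frac = np.zeros_like(var)
    else:
        frac = var / total
    scores = U * s
    return scores, Vt, frac


def estimate_midplane(config: LandmarkConfiguration) -> Plane:
    """Estimate the midsagittal plane by PCA of present midline landmarks.

    The plane passes through the midline centroid and is spanned by the first
    two principal axes; the normal is the third axis, with its sign chosen so
    the mean of present left-side landmarks lies at positive signed distance
    (when any left-side landmarks are present).
    """
    mid_idx = [i for i, d in enumerate(config.template)
               if d.side is Side.MIDLINE and config.present[i]]
    if len(mid_idx) < 3:
        raise DegenerateGeometryError(
            f"midplane estimation needs >=3 present midline landmarks, "
            f"got {len(mid_idx)}"
        )
    pts = config.coords[mid_idx]
    centroid = pts.mean(axis=0)
    _, s, Vt = np.linalg.svd(pts - centroid, full_matrices=False)
    if s[1] < 1e-9 * max(s[0], 1.0):
        raise DegenerateGeometryError("midline landmarks are collinear")
    normal = Vt[2]
    left_idx = [i for i, d in enumerate(config.template)
                if d.side is Side.LEFT and config.present[i]]
    if left_idx:
        left_mean = config.coords[left_idx].mean(axis=0)
        if (left_mean - centroid) @ normal < 0:
            normal = -normal
    return Plane(point=centroid, normal=normal)


def reflect_and_relabel(config: LandmarkConfiguration, plane: Plane,
                        pairing: BilateralPairing) -> LandmarkConfiguration:
    """Mirror a configuration: reflect across a plane, then swap L/R labels.

    The Householder reflection flips geometry; the id relabelling by the
    bilateral pairing restores anatomical labels so the result is again a
    valid configuration on the same template (left data now describing the
    right side and vice versa). Present flags travel with the relabelled ids.
    Applying the operation twice with the same plane is the identity.
    """
    pairing.validate_against(config.template)
    reflected = plane.reflect(config.coords)
    swap = pairing.swap_map()
    n = config.n_landmarks
    new_coords = np.full((n, 3), np.nan)
    new_present = np.zeros(n, dtype=bool)
    for i, d in enumerate(config.template):
        j = config.template.index_of(swap[d.id])
        new_coords[j] = reflected[i]
        new_present[j] = config.present[i]
    return LandmarkConfiguration(
        template=config.template,
        coords=new_coords,
        present=new_present,
        specimen_id=config.specimen_id,
        metadata=dict(config.metadata),
    )
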