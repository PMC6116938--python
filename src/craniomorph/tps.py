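"""Three-dimensional thin-plate splines.

The interpolant minimizing the integral bending energy in three dimensions
uses the biharmonic fundamental-solution kernel U(r) = r (the 2D kernel
r^2 log r does not apply). Given M control-point pairs, the map is

    f(x) = A [1; x] + sum_i w_i U(|x - s_i|)

with the weights W subject to the side conditions P^T W = 0 (P = [1 | S]),
obtained from the bordered linear system

    [ K + lam*I   P ] [ W ]   [ T ]
    [   P^T       0 ] [ A ] = [ 0 ]

where K_ij = U(|s_i - s_j|). With lam = 0 the map interpolates the control
points exactly; lam > 0 trades interpolation for smoothness.

Under the side conditions the quadratic form W^T K W is non-positive for this
kernel, so the (non-negative) bending energy is reported as -tr(W^T K W);
it vanishes exactly when the map is affine.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy.spatial.distance import cdist


class TPSRankError(ValueError):
    """Raised when control points cannot support a TPS fit."""


@dataclass(frozen=True)
class TPSModel:
    """A fitted 3D thin-plate spline map."""

    control_source: np.ndarray  # (M, 3)
    control_target: np.ndarray  # (M, 3)
    affine: np.ndarray          # (4, 3): row 0 translation, rows 1-3 linear
    weights: np.ndarray         # (M, 3) non-affine coefficients
    regularization: float = 0.0

    def __call__(self, points: np.ndarray) -> np.ndarray:
        return tps_apply(self, points)


def _kernel_matrix(a: np.ndarray, b: np.ndarray) -> np.ndarray:
    return cdist(a, b)  # U(r) = r


def tps_fit(source: np.ndarray, target: np.ndarray,
            regularization: float = 0.0) -> TPSModel:
    """Fit a 3D TPS mapping source control points to target control points.

    Requires M >= 4 pairwise-distinct, non-coplanar source points (coplanar
    sources leave the affine part under-determined). ``regularization`` is the
    smoothing parameter added to the kernel diagonal.
    """
    src = np.atleast_2d(np.asarray(source, dtype=float))
    tgt = np.atleast_2d(np.asarray(target, dtype=float))
    if src.shape != tgt.shape or src.shape[1] != 3:
        raise ValueError(f"control shapes mismatch: {src.shape} vs {tgt.shape}")
    M = len(src)
    if M < 4:
        raise TPSRankError(f"TPS needs >=4 control points, got {M}")
    if regularization < 0:
        raise ValueError("regularization must be non-negative")
    D = _kernel_matrix(src, src)
    offdiag = D[~np.eye(M, dtype=bool)]
    if offdiag.min() <= 0:
        raise TPSRankError("duplicate source control points")
    scale = offdiag.mean()
    P = np.hstack([np.ones((M, 1)), src])
    # coplanarity check: P must have full column rank 4
    if np.linalg.matrix_rank(P, tol=1e-9 * max(scale, 1.0)) < 4:
        raise TPSRankError(
            "source control points are coplanar (affine part ambiguous)"
        )
    L = np.zeros((M + 4, M + 4))
    # smoothing for energy -w^T K w enters the stationarity system as K - lam*I
    L[:M, :M] = D - regularization * np.eye(M)
    L[:M, M:] = P
    L[M:, :M] = P.T
    rhs = np.zeros((M + 4, 3))
    rhs[:M] = tgt
    try:
        sol = np.linalg.solve(L, rhs)
    except np.linalg.LinAlgError as exc:
        raise TPSRankError(f"TPS system is singular: {exc}") from exc
    return TPSModel(control_source=src.copy(), control_target=tgt.copy(),
                    weights=sol[:M], affine=sol[M:],
                    regularization=float(regularization))


def tps_apply(model: TPSModel, points: np.ndarray) -> np.ndarray:
    """Evaluate a fitted TPS at arbitrary points."""
    pts = np.atleast_2d(np.asarray(points, dtype=float))
    U = _kernel_matrix(pts, model.control_source)
    Q = np.hstack([np.ones((len(pts), 1)), pts])
    out = U @ model.weights + Q @ model.affine
    return out.reshape(np.asarray(points, dtype=float).shape)


def bending_energy(model: TPSModel) -> float:
    """Non-negative bending energy -tr(W^T K W); zero iff the map is affine."""
    K = _kernel_matrix(model.control_source, model.control_source)
    e = -float(np.trace(model.weights.T @ K @ model.weights))
    return max(e, 0.0)


def bending_energy_matrix(source: np.ndarray) -> np.ndarray:
    """Bending-energy matrix B of a control-point set.

    For targets Y the energy of the interpolating TPS is -tr(Y^T B Y) with B
    the upper-left M x M block of the inverse bordered system; B is symmetric
    and (negative semi-)definite on the subspace orthogonal to {1, x, y, z}.
    Used by semilandmark sliding, where energy must be minimized over target
    positions without refitting a spline per candidate.
    """
    src = np.atleast_2d(np.asarray(source, dtype=float))
    M = len(src)
    if M < 4:
        raise TPSRankError(f"TPS needs >=4 control points, got {M}")
    D = _kernel_matrix(src, src)
    P = np.hstack([np.ones((M, 1)), src])
    L = np.zeros((M + 4, M + 4))
    L[:M, :M] = D
    L[:M, M:] = P
    L[M:, :M] = P.T
    Linv = np.linalg.inv(L)
    B = Linv[:M, :M]
    return 0.5 * (B + B.T)
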