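"""Missing-cell imputation for measurement tables.

Imputation uses regularized iterative PCA: columns are centred and scaled on
their observed cells, missing cells start at the column means, and the table
is repeatedly reconstructed from a truncated SVD whose singular values are
shrunk by the estimated residual variance — the shrinkage keeps the
algorithm from overfitting noise in the observed cells. Only missing cells
are ever refilled; observed values pass through bit-identical.

Because an imputed value is an estimate, a specimen with many (or
influential) missing cells has an uncertain position in the measurement
space. Multiple stochastic imputations quantify this: each draw perturbs the
fitted values at the missing cells by the residual noise, every completed
draw is projected onto the PCA of the point-estimate completion, and the
area of the 95% ellipse of a specimen's draws on PC1-PC2 is its uncertainty
score. Specimens whose score exceeds a set fraction of the whole sample's
ellipse area are excluded from downstream analyses — dropping only the most
uncertain specimens rather than every incomplete one.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .measurements import LABEL_COLUMNS, measurement_columns
from .validation import confidence_ellipse


@dataclass
class ImputationResult:
    completed: pd.DataFrame
    n_iterations: int
    converged: bool
    missing_mask: pd.DataFrame


def _split(table: pd.DataFrame) -> tuple[pd.DataFrame, list[str]]:
    cols = measurement_columns(table)
    return table[cols], cols


def impute_iterative_pca(table: pd.DataFrame, ncomp: int = 2, *,
                         tol: float = 1e-8, max_iter: int = 500,
                         ) -> ImputationResult:
    """Complete a measurement table by regularized iterative PCA.

    ``ncomp`` is the rank of the reconstruction (must be < min(rows, cols));
    iteration stops when the largest absolute change of any imputed cell
    (on the standardized scale) falls below ``tol``.
    """
    values_df, cols = _split(table)
    X = values_df.to_numpy(dtype=float)
    n, p = X.shape
    if not (1 <= ncomp < min(n, p)):
        raise ValueError(f"ncomp must be in [1, {min(n, p) - 1}], got {ncomp}")
    miss = np.isnan(X)
    if miss.all(axis=1).any():
        raise ValueError("a row has no observed values")
    if miss.all(axis=0).any():
        bad = [cols[j] for j in np.flatnonzero(miss.all(axis=0))]
        raise ValueError(f"columns with no observed values: {bad}")

    sd = np.nanstd(X, axis=0, ddof=0)
    sd[sd == 0] = 1.0
    Xc = X.copy()
    Xc[miss] = np.broadcast_to(np.nanmean(X, axis=0), X.shape)[miss]

    converged = False
    it = 0
    for it in range(1, max_iter + 1):
        # re-estimate column means from the current completion so the
        # centring converges with the imputation (fixed observed-cell means
        # would leave a rank-raising offset in the centred matrix)
        mu = Xc.mean(axis=0)
        Z = (Xc - mu) / sd
        U, d, Vt = np.linalg.svd(Z, full_matrices=False)
        # residual variance from the discarded spectrum (regularization)
        tail = d[ncomp:]
        dof = max((n - 1) * p - n * ncomp, 1)
        sigma2 = float((tail ** 2).sum() / dof)
        d_shrunk = np.maximum(d[:ncomp] - sigma2 / np.maximum(d[:ncomp], 1e-12),
                              0.0)
        fitted = ((U[:, :ncomp] * d_shrunk) @ Vt[:ncomp]) * sd + mu
        sd_cells = np.broadcast_to(sd, Xc.shape)[miss]
        delta = (np.abs(fitted[miss] - Xc[miss]) / sd_cells).max() \
            if miss.any() else 0.0
        Xc[miss] = fitted[miss]
        if delta < tol:
            converged = True
            break

    completed_values = Xc
    completed_values[~miss] = X[~miss]  # observed cells bit-identical
    out = table.copy()
    out[cols] = completed_values
    mask = pd.DataFrame(miss, index=table.index, columns=cols)
    return ImputationResult(completed=out, n_iterations=it,
                            converged=converged, missing_mask=mask)


def _pca_fit(values: np.ndarray) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    mu = values.mean(axis=0)
    sd = values.std(axis=0, ddof=0)
    sd[sd == 0] = 1.0
    Z = (values - mu) / sd
    _, _, Vt = np.linalg.svd(Z, full_matrices=False)
    return mu, sd, Vt


def multiple_imputation_uncertainty(table: pd.DataFrame, ncomp: int = 2, *,
                                    n_draws: int = 100, seed: int = 0,
                                    tol: float = 1e-8, max_iter: int = 500,
                                    ) -> pd.Series:
    """Per-specimen positional uncertainty from multiple imputation.

    Returns the area of the 95% ellipse of each specimen's ``n_draws``
    PC1-PC2 positions, where each draw re-perturbs the imputed cells by the
    residual noise of the rank-``ncomp`` fit and is projected onto the PCA
    of the point-estimate completion. Complete specimens score exactly 0.
    """
    if n_draws < 20:
        raise ValueError("multiple imputation needs at least 20 draws")
    point = impute_iterative_pca(table, ncomp, tol=tol, max_iter=max_iter)
    values_df, cols = _split(point.completed)
    values = values_df.to_numpy(dtype=float)
    miss = point.missing_mask.to_numpy()
    mu, sd, Vt = _pca_fit(values)
    axes = Vt[:2]

    # residual scale of the rank-ncomp fit (standardized scale), used for
    # the parametric residual bootstrap of the observed cells
    Z = (values - mu) / sd
    U, d, Vt_full = np.linalg.svd(Z, full_matrices=False)
    fitted = (U[:, :ncomp] * d[:ncomp]) @ Vt_full[:ncomp]
    resid = (Z - fitted)[~miss]
    sigma = float(resid.std(ddof=0)) if resid.size else 0.0

    ss = np.random.SeedSequence(seed)
    child_seeds = ss.spawn(n_draws)
    n = len(values)
    positions = np.zeros((n_draws, n, 2))
    raw = table[cols].to_numpy(dtype=float)
    work = table.copy()
    for b in range(n_draws):
        rng = np.random.default_rng(child_seeds[b])
        # perturb the observed cells, re-run the imputation, then restore
        # the observed cells: the spread of the re-imputed missing cells
        # carries both residual and model-estimation uncertainty
        Xb = raw + rng.normal(0.0, sigma, size=raw.shape) * sd
        Xb[miss] = np.nan
        work[cols] = Xb
        redone = impute_iterative_pca(work, ncomp, tol=max(tol, 1e-6),
                                      max_iter=max_iter)
        comp = redone.completed[cols].to_numpy(dtype=float)
        comp[~miss] = raw[~miss]
        positions[b] = ((comp - mu) / sd) @ axes.T

    areas = np.zeros(n)
    for i in range(n):
        if not miss[i].any():
            continue  # complete specimen: all draws identical, area 0
        areas[i] = confidence_ellipse(positions[:, i, :]).area
    return pd.Series(areas, index=table.index, name="uncertainty_area")


def filter_uncertain(table: pd.DataFrame, scores: pd.Series, *,
                     threshold_fraction: float = 0.25, ncomp: int = 2,
                     ) -> tuple[pd.DataFrame, list[str]]:
    """Exclude specimens whose uncertainty ellipse exceeds a fraction of the
    whole-sample 95% ellipse area on PC1-PC2 of the completed table.

    At ``threshold_fraction = 0`` no imputation uncertainty is tolerated:
    every specimen with a missing cell is excluded, including those whose
    draw scatter is degenerate (a single missing cell yields a line segment
    of zero ellipse area).
    """
    point = impute_iterative_pca(table, ncomp)
    values_df, _ = _split(point.completed)
    values = values_df.to_numpy(dtype=float)
    mu, sd, Vt = _pca_fit(values)
    sample_scores = ((values - mu) / sd) @ Vt[:2].T
    sample_area = confidence_ellipse(sample_scores).area
    limit = threshold_fraction * sample_area
    incomplete = point.missing_mask.any(axis=1)
    excluded = [str(i) for i in table.index
                if scores.loc[i] > limit
                or (limit == 0 and bool(incomplete.loc[i]))]
    retained = table.drop(index=excluded)
    return retained, excluded
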