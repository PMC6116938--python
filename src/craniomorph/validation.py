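"""Reconstruction-uncertainty validation.

The ensemble of reconstructions is superimposed jointly with the reference
sample; a shape PCA shows where the reconstructions fall within the sample's
variation (with 95% confidence ellipses per group on PC1-PC2), and a
two-group Procrustes ANOVA expresses the ensemble's spread as a fraction of
the total shape variation and of the total centroid-size variation. Small
fractions mean the choice of reference subsample hardly matters compared to
ordinary between-individual variation.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy.stats import chi2

from .geometry import GPAResult, centroid_size, gpa, shape_pca
from .landmarks import LandmarkConfiguration, ReferenceSample
from .reconstruction import ReconstructionResult

CHI2_95_2DF = float(chi2.ppf(0.95, df=2))


@dataclass
class Ellipse2D:
    """A 95% confidence ellipse on two PC axes."""

    center: np.ndarray
    semi_axes: tuple[float, float]
    angle: float  # radians, major axis vs first PC axis
    area: float
    n: int


@dataclass
class ValidationPCA:
    scores: np.ndarray          # (n_total, n_components)
    explained: np.ndarray       # variance fractions
    groups: list[str]           # per-row group label
    ellipses: dict[str, Ellipse2D | None]
    gpa_result: GPAResult


@dataclass
class ProcrustesAnovaResult:
    ss_total_shape: float
    ss_reconstruction_shape: float
    shape_fraction: float
    var_total_size: float
    var_reconstruction_size: float
    size_fraction: float
    n_reconstructions: int
    n_reference: int


def _as_arrays(reconstructions, sample):
    recs = [r.completed if isinstance(r, ReconstructionResult) else r
            for r in reconstructions]
    for r in recs:
        if not r.is_complete:
            raise ValueError("validation requires complete reconstructions")
    return [np.array(r.coords, float) for r in recs], \
           [np.array(c.coords, float) for c in sample]


def confidence_ellipse(points2d: np.ndarray, level_chi2: float = CHI2_95_2DF
                       ) -> Ellipse2D:
    """95% (by default) covariance ellipse of 2D points."""
    pts = np.atleast_2d(np.asarray(points2d, dtype=float))
    n = len(pts)
    center = pts.mean(axis=0)
    if n < 2:
        return Ellipse2D(center, (0.0, 0.0), 0.0, 0.0, n)
    cov = np.cov(pts.T, ddof=1)
    evals, evecs = np.linalg.eigh(np.atleast_2d(cov))
    evals = np.clip(evals, 0.0, None)
    order = np.argsort(evals)[::-1]
    evals, evecs = evals[order], evecs[:, order]
    a = float(np.sqrt(level_chi2 * evals[0]))
    b = float(np.sqrt(level_chi2 * evals[1]))
    angle = float(np.arctan2(evecs[1, 0], evecs[0, 0]))
    return Ellipse2D(center, (a, b), angle, float(np.pi * a * b), n)


def validation_pca(reconstructions, sample: ReferenceSample,
                   ) -> ValidationPCA:
    """Joint GPA + shape PCA of reconstructions and reference specimens.

    Rows are labelled ``"reconstruction"`` or ``"reference"``; a 95%
    confidence ellipse on PC1-PC2 is computed per group (``None`` and a flag
    when a group has fewer than 3 members).
    """
    rec_arrays, ref_arrays = _as_arrays(reconstructions, sample)
    all_arrays = rec_arrays + ref_arrays
    if len(all_arrays) < 3:
        raise ValueError("need at least 3 configurations in total")
    res = gpa(all_arrays, scale=True)
    scores, _, explained = shape_pca(res)
    groups = (["reconstruction"] * len(rec_arrays)
              + ["reference"] * len(ref_arrays))
    ellipses: dict[str, Ellipse2D | None] = {}
    for g in ("reconstruction", "reference"):
        idx = [i for i, lab in enumerate(groups) if lab == g]
        if len(idx) < 3:
            ellipses[g] = None
        else:
            ellipses[g] = confidence_ellipse(scores[idx][:, :2])
    return ValidationPCA(scores=scores, explained=explained, groups=groups,
                         ellipses=ellipses, gpa_result=res)


def procrustes_anova(reconstructions, sample: ReferenceSample, *,
                     include_reconstructions_in_total: bool = True,
                     ) -> ProcrustesAnovaResult:
    """Two-group shape/size variance decomposition after joint GPA.

    ``ss_total_shape`` is the summed squared deviation of every superimposed
    configuration from the grand mean over all coordinates;
    ``ss_reconstruction_shape`` the deviation of the reconstructions from
    their own group mean; ``shape_fraction`` the ratio. The same decomposition
    on centroid sizes gives ``size_fraction``. By default the grand mean runs
    over the union of reconstructions and reference specimens; a switch
    excludes the reconstructions from the total for sensitivity analysis.
    """
    rec_arrays, ref_arrays = _as_arrays(reconstructions, sample)
    if len(rec_arrays) < 2 or len(ref_arrays) < 2:
        raise ValueError("need >=2 reconstructions and >=2 reference specimens")
    res = gpa(rec_arrays + ref_arrays, scale=True)
    n_rec = len(rec_arrays)
    X = np.array([a.ravel() for a in res.aligned])
    rec = X[:n_rec]
    total_pool = X if include_reconstructions_in_total else X[n_rec:]
    ss_total = float(((total_pool - total_pool.mean(axis=0)) ** 2).sum())
    ss_rec = float(((rec - rec.mean(axis=0)) ** 2).sum())

    sizes = res.centroid_sizes
    rec_sizes = sizes[:n_rec]
    size_pool = sizes if include_reconstructions_in_total else sizes[n_rec:]
    var_total = float(((size_pool - size_pool.mean()) ** 2).sum())
    var_rec = float(((rec_sizes - rec_sizes.mean()) ** 2).sum())
    return ProcrustesAnovaResult(
        ss_total_shape=ss_total,
        ss_reconstruction_shape=ss_rec,
        shape_fraction=ss_rec / ss_total if ss_total > 0 else 0.0,
        var_total_size=var_total,
        var_reconstruction_size=var_rec,
        size_fraction=var_rec / var_total if var_total > 0 else 0.0,
        n_reconstructions=n_rec,
        n_reference=len(ref_arrays),
    )
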