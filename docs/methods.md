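# Methods

## The problem

A fossil cranium usually arrives fragmented and incomplete. Before any
quantitative comparison it must be virtually reconstructed: detached
fragments rearticulated, unilaterally missing regions completed from the
preserved side, and regions missing on both sides estimated from a reference
sample of complete crania. Every one of those choices injects uncertainty,
so the reconstruction must also be validated — and only then can the
completed specimen be measured and classified against comparative samples.

`craniomorph` implements that full desk pipeline on 3D landmark
configurations (anatomical landmarks plus curve and surface semilandmarks),
with a synthetic-data generator supplying populations of known ground truth
for every stage.

## Shape mathematics

**Procrustes.** Ordinary Procrustes alignment (OPA) is the SVD/Umeyama
least-squares similarity fit; reflections are disallowed everywhere by
default because anatomical chirality is meaningful. Generalized Procrustes
analysis (GPA) iterates align-to-consensus over the translation/rotation
(/scale)-normalized shapes; the consensus is centred, unit-centroid-size
(when scaling), and rotationally pinned to its previous iterate — without
the pinning the whole constellation can drift and the iteration has no fixed
point. Convergence is declared when the consensus moves less than 1e-10
(RMS); realistic samples converge in a handful of iterations, and
non-convergence within 100 iterations is flagged on the result rather than
raised. The distance between two possibly-incomplete configurations is the
partial Procrustes distance on the mutually present landmark subset (both
subsets centred, unit-scaled, optimally rotated; root summed squared
difference). "Closest reference specimens" are ranked by this distance with
ties broken by specimen id.

**Thin-plate splines.** The 3D interpolant uses the biharmonic
fundamental-solution kernel U(r) = r (not the 2D r² log r). Under the side
conditions PᵀW = 0 this kernel's quadratic form is non-positive, so the
bending energy is reported as −tr(WᵀKW); it is zero exactly for affine maps.
The same sign convention propagates into smoothing: minimizing
‖f(sᵢ) − tᵢ‖² + λ·energy leads to the bordered system with K − λI on the
kernel block. λ defaults to 0 (pure interpolation) at every pipeline stage
and is exposed per stage.

**Midplane.** The midsagittal plane is the best-fit plane of the present
midline landmarks (centroid + first two principal axes); the normal's sign
is chosen so the left-side landmark mean has positive signed distance.
Mirroring is a Householder reflection followed by left/right id relabelling
via the bilateral pairing, an involution that carries presence flags with
the relabelled ids.

## Semilandmark sliding

Semilandmarks have no exact homology along their curve or surface, so their
along-structure positions are relaxed to minimize the TPS bending energy
against a template. Writing the energy of an interpolant with sources S and
targets Y as −tr(YᵀBY), with B the bending-energy matrix of S, the
constrained minimization over tangent offsets (tangent lines for curve
points, from ordinal neighbours; tangent planes for surface points, normal
from the mesh or a k = 8 local PCA) is a single linear solve per iteration.
After each algebraic slide, points are projected back onto the curve
polyline or mesh (exhaustive closest-point-on-triangle; ties to the lower
index). Three iterations by default, tangents recomputed each iteration. The
projection can in principle undo part of the algebraic gain, so an iteration
that would raise the energy is rolled back and sliding stops — making the
energy non-increasing by construction.

## Reconstruction

The pipeline follows a preserved-morphology-first phasing:

1. **Asymmetry-preserving mirror completion.** Estimate the midplane,
   reflect-and-relabel to get the mirror configuration, fit a TPS from the
   mirror to the original on the landmarks present in both, and apply it to
   the mirror positions of the missing landmarks. On a symmetric specimen
   the warp is the identity; on an asymmetric one it transports the
   preserved side's asymmetry onto the completion, which is why it
   outperforms naive reflection whenever the asymmetry is smooth.
2. **Rearticulation.** Detached fragments are rigidly registered onto anchor
   landmarks (no scaling). The mandible-style constrained variant aligns the
   moving midplane onto the fixed one (normal rotation + in-plane/along-
   normal translation split between the plane and the contact landmarks) and
   resolves the one remaining degree of freedom — rotation about the
   transverse axis, i.e. the common midplane normal through the contact
   point — by a closed-form 1D rotation fit over secondary landmarks.
3. **Reference-based completion.** The reference subsample is superimposed
   by GPA; the consensus is similarity-aligned (no reflection) onto the
   target's present landmarks; a TPS from the aligned consensus's present
   subset to the target carries the consensus positions of the missing
   landmarks into the target frame. Mirror-filled landmarks count as present
   here. A single-specimen subsample is its own consensus.

Per-landmark provenance (original | mirrored | reference_estimated)
partitions the template; original coordinates are never modified by any
filling step. Running step 3 once per named subsample (all / recent / males
/ females / closest-10 / closest-1 / single fossil — the seven-subsample
pattern of the reference design) yields the reconstruction ensemble. A
donor mesh is transported onto a completed configuration by the TPS between
the donor's landmarks and the completion, applied to every vertex.

## Validation

The ensemble is superimposed jointly with the reference sample; a shape PCA
of the aligned coordinates shows the reconstructions inside the sample's
variation, with per-group 95% confidence ellipses on PC1–PC2 (chi-square
quantile, 2 df, group covariance; groups under 3 members are flagged
instead). The Procrustes ANOVA is a two-group sum-of-squares decomposition:
the ensemble's deviation from its own mean as a fraction of the total
deviation from the grand mean, computed identically for vectorized shape
coordinates and for centroid sizes. The grand mean includes the
reconstructions by default (switchable for sensitivity); both fractions are
invariant to global similarity transforms of all inputs.

## Measurements, size adjustment, imputation

Measurements are classical numbered linear dimensions: point-to-point
distances, polyline arcs over ordered landmark chains, and closed-polyline
circumferences, in mm; a measurement touching a missing landmark yields a
missing cell with a warning. Size adjustment divides each row by its
geometric mean over the selected columns and takes logs (log-shape ratios);
rows then sum to zero and the transform is invariant to row scaling.

Missing cells are imputed by regularized iterative PCA: columns standardized
(means re-estimated from the current completion each iteration — keeping
them fixed at the observed-cell means leaves a rank-raising offset), missing
cells refilled from a rank-`ncomp` truncated SVD whose singular values are
shrunk by the estimated residual variance. Observed cells pass through
bit-identical. `ncomp` defaults to 2.

Positional uncertainty from imputation is estimated by multiple imputation:
each of B draws perturbs the observed cells by the residual scale of the
rank-`ncomp` fit, re-runs the imputation, restores the observed cells, and
projects the completion onto the PCA of the point-estimate completion; a
specimen's score is the 95%-ellipse area of its B positions on PC1–PC2.
Re-imputing per draw (rather than only jittering the fitted values) is what
lets a nearly-empty row show its genuinely large uncertainty. Complete
specimens score exactly 0. Specimens whose score exceeds a quarter (default)
of the whole-sample ellipse area are excluded; at threshold 0 any specimen
with a missing cell is excluded, since a single missing cell produces a
degenerate (zero-area) line of draws.

## Classification

**Affinity.** LDA with pooled within-class covariance on the log-shape
ratios of the 13 Howells-comparable codes, five groups (three recent
population samples, pre- and post-LGM fossils), hence four discriminant
functions. Reported: loadings, leave-one-out confusion (row-stochastic
probabilities plus absolute counts), and per-target posteriors. Priors are
equal by default — reference group sizes reflect preservation history, not
prevalence.

**Sex.** Raw measurements (size carries dimorphism). A bagged
decision-tree forest (1000 trees by default, √p feature subsampling, own
bootstrap bookkeeping for determinism) ranks variables by out-of-bag
permutation importance; forward selection over ranking prefixes picks the
subset with the best LOOCV LDA accuracy (ties to the smaller subset); the
final LDA reports banded LOOCV confusion at 0.5 and 0.95 posterior
thresholds (sub-threshold rows count as indeterminate; the 0.95 band is a
reliability report, not a decision rule) and target posteriors, plus a PCA
of the selected variables with the targets projected. Because the selected
subset maximizes a cross-validated accuracy, that accuracy is optimistic
under weak signal; `nested=True` re-selects the subset size inside every
leave-one-out fold (the RF ranking is computed once), which restores
chance-level accuracy on null data at extra cost. Non-nested is the default,
matching the two-stage procedure the pipeline models.

## Synthetic data

The generator builds a schematic cranium: midline landmarks on a parabolic
sagittal arc, bilateral pairs, one ordered curve per side and a surface
patch per side on an ellipsoid shell (70 × 90 × 65 mm semi-axes), exactly
symmetric across x = 0 — 61 landmarks under the defaults. Populations
compose smooth low-rank TPS fields on the template: a per-group field, a sex
field plus a male centroid-size multiplier, and a fixed directional-
asymmetry field applied to the left side, plus isotropic Gaussian landmark
noise. Because every effect is a TPS of at most 10 control displacements,
the asymmetry is exactly the kind of smooth deformation the mirror warp
assumes — a fair test of its superiority claim, and a bound on what passing
tests show: real asymmetry need not be TPS-representable, real reference
samples are not draws around the target's own template, and real
measurement error is not isotropic Gaussian.

Default study-shaped conditions: 30 recent crania (15/15 by sex) plus one
contemporaneous fossil as the reference, one fragmented target (a left-vault
region of 55 mm radius and an anterior midline region of 35 mm radius
deleted, emulating left-side and mid-face loss), landmark noise 0.5 mm,
directional asymmetry 2 mm, male size factor 1.05. Measurement tables are
simulated directly on the log scale around classical raw-measurement means:
three recent population samples of 100, pre-LGM 31 and post-LGM 27, group
effects 0.04 (log units) along fixed random directions, latent size CV
0.035, residual CV 0.025, male size factor 1.06, MCAR cell deletion. Under
these defaults the five-group LOOCV accuracy sits in the 45–60% range —
deliberately weak separation; recovery tests that need planted signal raise
the group effect locally. All randomness flows from one master seed through
spawned sequences; everything downstream is bitwise reproducible.

## Numerical choices and limitations

- Tolerances: GPA consensus movement 1e-10 (100 iterations); TPS
  interpolation residual 1e-8 asserted; imputation convergence 1e-8 on the
  standardized scale (500 iterations); projection ties to the lower index.
- Degenerate inputs raise typed errors: coplanar TPS sources, collinear
  midlines, <3 shared landmarks, empty subsamples, singular-coverage
  pairings.
- The template is schematic: measurement definitions map classical codes
  onto it structurally (lengths/breadths/arcs/one circumference), not
  anatomically. Arcs are polylines through landmark chains, not geodesics.
- Validation problem sizes are chosen for single-CPU runs: 61-landmark
  configurations, ~30-specimen references, tens of simulation replicates
  per property; the generator scales to larger designs by spec fields.
- No mesh-to-mesh registration, no statistical-shape-model completion, no
  visual sex-scoring standards: out of scope by design.
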