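"""Virtual reconstruction of incomplete cranial landmark configurations.

The pipeline has two phases. The preserved-morphology phase exploits the
specimen's own bilateral structure: missing unilateral landmarks are filled
by reflecting the configuration across its estimated midsagittal plane,
relabelling left/right, and warping the mirror onto the preserved landmarks
with a thin-plate spline — so the completion preserves the individual's
directional asymmetry rather than imposing perfect symmetry. Detached
fragments are rearticulated by rigid registration onto anchor landmarks, or
by a midplane-and-contact constraint that leaves a single rotational degree
of freedom (about the transverse axis) to be optimized.

The reference-based phase fills whatever remains from a sample of complete
crania: the sample is superimposed by GPA, its consensus is similarity-
aligned onto the target's preserved landmarks, and a TPS from the aligned
consensus to the target carries the consensus positions of the missing
landmarks into the target. Running this against several named subsamples of
the reference collection yields an ensemble of reconstructions whose spread
measures the uncertainty of the procedure.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from enum import Enum
from typing import Sequence

import numpy as np
import trimesh

from .geometry import (
    DegenerateGeometryError,
    SimilarityTransform,
    estimate_midplane,
    gpa,
    opa_align,
    procrustes_distance,
    reflect_and_relabel,
)
from .landmarks import (
    BilateralPairing,
    LandmarkConfiguration,
    Plane,
    ReferenceSample,
)
from .tps import TPSModel, tps_apply, tps_fit


class ReconstructionError(ValueError):
    """Raised when a reconstruction step cannot proceed."""


class Provenance(str, Enum):
    ORIGINAL = "original"
    MIRRORED = "mirrored"
    REFERENCE_ESTIMATED = "reference_estimated"


@dataclass
class ReconstructionResult:
    """A completed configuration with per-landmark provenance."""

    completed: LandmarkConfiguration
    provenance: dict[int, Provenance]
    subsample_name: str = ""
    donor_specimen: str | None = None
    transforms: dict[str, SimilarityTransform] = field(default_factory=dict)

    def ids_with(self, prov: Provenance) -> list[int]:
        return [i for i, p in self.provenance.items() if p is prov]


def _check_noncoplanar(points: np.ndarray, context: str) -> None:
    pts = np.atleast_2d(points)
    if len(pts) < 4:
        raise ReconstructionError(
            f"{context}: need >=4 points, got {len(pts)}"
        )
    c = pts - pts.mean(axis=0)
    s = np.linalg.svd(c, compute_uv=False)
    if s[2] < 1e-8 * max(s[0], 1.0):
        raise ReconstructionError(f"{context}: points are coplanar")


def mirror_reconstruct(config: LandmarkConfiguration,
                       pairing: BilateralPairing, *,
                       regularization: float = 0.0,
                       plane: Plane | None = None) -> ReconstructionResult:
    """Asymmetry-preserving mirror completion.

    Reflects the configuration across its midsagittal plane and relabels
    sides, fits a TPS from the mirror to the original on the landmarks
    present in both, and applies that warp to the mirror positions of the
    landmarks missing from the original. Only missing landmarks are filled;
    originals are never moved. On a perfectly symmetric specimen the warp is
    the identity and the fill is exact; on an asymmetric one the warp carries
    the preserved side's asymmetry onto the completion.
    """
    if plane is None:
        plane = estimate_midplane(config)
    mirror = reflect_and_relabel(config, plane, pairing)
    both = config.present & mirror.present
    n_overlap = int(both.sum())
    if n_overlap < 4:
        raise ReconstructionError(
            f"insufficient bilateral overlap for mirror warp: {n_overlap} "
            "landmarks present in both original and mirror"
        )
    _check_noncoplanar(config.coords[both], "mirror warp controls")
    model = tps_fit(mirror.coords[both], config.coords[both],
                    regularization=regularization)
    fill = (~config.present) & mirror.present
    coords = config.coords.copy()
    coords[fill] = tps_apply(model, mirror.coords[fill])
    present = config.present | fill
    provenance = {}
    for i, d in enumerate(config.template):
        if config.present[i]:
            provenance[d.id] = Provenance.ORIGINAL
        elif fill[i]:
            provenance[d.id] = Provenance.MIRRORED
    completed = LandmarkConfiguration(
        template=config.template, coords=coords, present=present,
        specimen_id=config.specimen_id, metadata=dict(config.metadata),
    )
    return ReconstructionResult(completed=completed, provenance=provenance,
                                subsample_name="")


def mirror_across_midplane(fragment_ids: Sequence[int],
                           config: LandmarkConfiguration,
                           pairing: BilateralPairing, *,
                           plane: Plane | None = None,
                           overwrite: bool = False) -> ReconstructionResult:
    """Fill the contralateral counterparts of a present landmark block by
    plain reflection across the midplane (no warp)."""
    if plane is None:
        plane = estimate_midplane(config)
    swap = pairing.swap_map()
    coords = config.coords.copy()
    present = config.present.copy()
    provenance = {d.id: Provenance.ORIGINAL
                  for i, d in enumerate(config.template) if config.present[i]}
    for fid in fragment_ids:
        i = config.template.index_of(fid)
        if not config.present[i]:
            raise ReconstructionError(f"fragment landmark {fid} is not present")
        cid = swap[fid]
        if cid == fid:
            continue  # midline points have no contralateral counterpart
        j = config.template.index_of(cid)
        if present[j] and not overwrite:
            raise ReconstructionError(
                f"contralateral landmark {cid} already present "
                "(pass overwrite=True to replace it)"
            )
        coords[j] = plane.reflect(coords[i][None, :])[0]
        present[j] = True
        provenance[cid] = Provenance.MIRRORED
    completed = LandmarkConfiguration(
        template=config.template, coords=coords, present=present,
        specimen_id=config.specimen_id, metadata=dict(config.metadata),
    )
    return ReconstructionResult(completed=completed, provenance=provenance)


def rearticulate_fragment(fragment: LandmarkConfiguration,
                          anchors: LandmarkConfiguration,
                          ) -> tuple[SimilarityTransform, LandmarkConfiguration]:
    """Rigidly register a detached fragment onto anchor positions.

    Landmarks present in both the fragment and the anchor configuration drive
    a rigid (no-scaling) OPA; the transform is applied to the whole fragment.
    """
    shared = fragment.present & anchors.present
    n_shared = int(shared.sum())
    if n_shared < 3:
        raise ReconstructionError(
            f"rearticulation needs >=3 shared landmarks, got {n_shared}"
        )
    xform, _ = opa_align(fragment.coords[shared], anchors.coords[shared],
                         allow_scaling=False, allow_reflection=False)
    moved = fragment.coords.copy()
    moved[fragment.present] = xform.apply(fragment.coords[fragment.present])
    return xform, fragment.with_coords(moved)


def _rotation_about_axis(axis: np.ndarray, angle: float) -> np.ndarray:
    a = axis / np.linalg.norm(axis)
    K = np.array([[0, -a[2], a[1]], [a[2], 0, -a[0]], [-a[1], a[0], 0]])
    return np.eye(3) + np.sin(angle) * K + (1 - np.cos(angle)) * (K @ K)


def align_by_midplane_and_contact(moving: LandmarkConfiguration,
                                  fixed: LandmarkConfiguration,
                                  contact_ids: Sequence[int], *,
                                  secondary_ids: Sequence[int] | None = None,
                                  ) -> SimilarityTransform:
    """Rigid alignment constrained by coincident midplanes and a contact
    point, leaving only rotation about the transverse axis free.

    The moving configuration's midsagittal plane is rotated onto the fixed
    one's and made coplanar; the contact landmarks are brought into
    coincidence; the residual rotation about the transverse axis (the common
    midplane normal) through the contact point is set by minimizing the
    summed squared distance of secondary landmarks (all shared present
    landmarks by default) to their fixed positions.
    """
    if not contact_ids:
        raise ReconstructionError("contact_ids must not be empty")
    plane_m = estimate_midplane(moving)
    plane_f = estimate_midplane(fixed)

    # rotate moving normal onto fixed normal
    n_m, n_f = plane_m.normal, plane_f.normal
    v = np.cross(n_m, n_f)
    c = float(n_m @ n_f)
    if np.linalg.norm(v) < 1e-14:
        R1 = np.eye(3) if c > 0 else _rotation_about_axis(
            _any_perpendicular(n_m), np.pi)
    else:
        s = np.linalg.norm(v)
        R1 = _rotation_about_axis(v / s, float(np.arctan2(s, c)))

    def _apply(R: np.ndarray, t: np.ndarray, pts: np.ndarray) -> np.ndarray:
        return pts @ R.T + t

    # translate so the moving plane point lands on the fixed plane, and the
    # contact point coincides with its fixed anchor position
    contact_idx = moving.template.indices_of(contact_ids)
    for i in contact_idx:
        if not (moving.present[i] and fixed.present[i]):
            raise ReconstructionError("contact landmark missing on one side")
    pc_m = moving.coords[contact_idx].mean(axis=0)
    pc_f = fixed.coords[contact_idx].mean(axis=0)
    n_f2 = plane_f.normal
    # along-normal translation makes the midplanes coplanar; in-plane
    # translation brings the contact points into coincidence
    along = n_f2 * (n_f2 @ (plane_f.point - R1 @ plane_m.point))
    inplane_delta = pc_f - R1 @ pc_m
    inplane = inplane_delta - n_f2 * (n_f2 @ inplane_delta)
    t1 = along + inplane
    # then the free rotation about the transverse axis (fixed normal) through
    # the contact point
    if secondary_ids is None:
        shared = moving.present & fixed.present
        secondary_idx = np.flatnonzero(shared)
    else:
        secondary_idx = moving.template.indices_of(secondary_ids)
    A = _apply(R1, t1, moving.coords[secondary_idx]) - pc_f
    Bm = fixed.coords[secondary_idx] - pc_f
    n = n_f
    # closed-form angle: minimize sum |R(theta) a - b|^2 for rotation about n
    A_perp = A - (A @ n)[:, None] * n
    B_perp = Bm - (Bm @ n)[:, None] * n
    num = float(np.sum(np.cross(A_perp, B_perp) @ n))
    den = float(np.sum(A_perp * B_perp))
    theta = float(np.arctan2(num, den)) if (num != 0 or den != 0) else 0.0
    R2 = _rotation_about_axis(n, theta)
    R = R2 @ R1
    t = R2 @ (t1 - pc_f) + pc_f
    return SimilarityTransform(R, 1.0, t)


def _any_perpendicular(v: np.ndarray) -> np.ndarray:
    ref = np.array([1.0, 0.0, 0.0])
    if abs(v @ ref) > 0.9:
        ref = np.array([0.0, 1.0, 0.0])
    p = np.cross(v, ref)
    return p / np.linalg.norm(p)


def estimate_missing_from_reference(target: LandmarkConfiguration,
                                    subsample: Sequence[LandmarkConfiguration],
                                    *, regularization: float = 0.0,
                                    subsample_name: str = "",
                                    base_provenance: dict | None = None,
                                    ) -> ReconstructionResult:
    """Fill missing landmarks from a reference subsample.

    The subsample is superimposed by GPA (a single specimen is its own
    consensus); the consensus is similarity-aligned (no reflection) onto the
    target's present landmarks; a TPS from the aligned consensus's present
    subset to the target's present landmarks then carries the consensus
    positions of the missing landmarks into the target frame.
    """
    if len(subsample) == 0:
        raise ReconstructionError("empty reference subsample")
    for c in subsample:
        if c.template.ids != target.template.ids:
            raise ReconstructionError(
                f"reference specimen {c.specimen_id!r} not homologous with target"
            )
    if len(subsample) == 1:
        consensus = np.array(subsample[0].coords, dtype=float)
    else:
        consensus = gpa(list(subsample), scale=True).consensus
    pres = target.present
    if int(pres.sum()) < 4:
        raise ReconstructionError("target has fewer than 4 present landmarks")
    _check_noncoplanar(target.coords[pres], "reference estimation overlap")
    xform, _ = opa_align(consensus[pres], target.coords[pres],
                         allow_scaling=True, allow_reflection=False)
    aligned = xform.apply(consensus)
    model = tps_fit(aligned[pres], target.coords[pres],
                    regularization=regularization)
    fill = ~pres
    coords = target.coords.copy()
    if fill.any():
        coords[fill] = tps_apply(model, aligned[fill])
    provenance = dict(base_provenance or {})
    for i, d in enumerate(target.template):
        if pres[i]:
            provenance.setdefault(d.id, Provenance.ORIGINAL)
        else:
            provenance[d.id] = Provenance.REFERENCE_ESTIMATED
    completed = LandmarkConfiguration(
        template=target.template, coords=coords,
        present=np.ones(target.n_landmarks, dtype=bool),
        specimen_id=target.specimen_id, metadata=dict(target.metadata),
    )
    return ReconstructionResult(
        completed=completed, provenance=provenance,
        subsample_name=subsample_name,
        transforms={"consensus_to_target": xform},
    )


def select_closest(target: LandmarkConfiguration, sample: ReferenceSample,
                   k: int) -> list[tuple[str, float]]:
    """Rank reference specimens by partial Procrustes distance to the
    target's present landmarks; return the closest k as (id, distance).

    Ties are broken by specimen id for determinism.
    """
    if k < 1:
        raise ValueError("k must be positive")
    if k > len(sample):
        raise ValueError(f"k={k} exceeds sample size {len(sample)}")
    ranked = sorted(
        ((c.specimen_id, procrustes_distance(target, c)) for c in sample),
        key=lambda pair: (pair[1], pair[0]),
    )
    return ranked[:k]


# -- subsample specifications ------------------------------------------------

@dataclass(frozen=True)
class SubsampleSpec:
    """A named selector over a reference sample.

    selector is one of ``"all"``, ``"filter"`` (with ``where`` metadata
    equalities), ``"closest"`` (with ``k``, ranked by Procrustes distance to
    the target), or ``"ids"`` (with an explicit specimen id list).
    """

    name: str
    selector: str
    where: tuple[tuple[str, str], ...] = ()
    k: int = 0
    ids: tuple[str, ...] = ()


def resolve_subsample(spec: SubsampleSpec, sample: ReferenceSample,
                      target: LandmarkConfiguration
                      ) -> list[LandmarkConfiguration]:
    if spec.selector == "all":
        return list(sample)
    if spec.selector == "filter":
        subset = sample.filter(**dict(spec.where))
        if not subset:
            raise ReconstructionError(
                f"subsample {spec.name!r}: filter matched no specimens"
            )
        return subset
    if spec.selector == "closest":
        pool = sample if not spec.where else ReferenceSample(
            sample.filter(**dict(spec.where)))
        ranked = select_closest(target, pool, spec.k)
        return [pool.specimen(sid) for sid, _ in ranked]
    if spec.selector == "ids":
        try:
            return [sample.specimen(sid) for sid in spec.ids]
        except KeyError as exc:
            raise ReconstructionError(
                f"subsample {spec.name!r}: {exc.args[0]}"
            ) from exc
    raise ReconstructionError(
        f"subsample {spec.name!r}: unknown selector {spec.selector!r}"
    )


def reconstruct_ensemble(target: LandmarkConfiguration,
                         sample: ReferenceSample,
                         subsample_specs: Sequence[SubsampleSpec],
                         pairing: BilateralPairing, *,
                         regularization: float = 0.0,
                         ) -> list[ReconstructionResult]:
    """Run the full reconstruction chain once per subsample spec.

    The preserved-morphology phase (asymmetry-preserving mirror completion)
    is specimen-intrinsic, so it is computed once; landmarks it fills count
    as present for the reference-based phase. Each subsample then drives one
    reference-based completion, yielding an ensemble of reconstructions in
    spec order. The procedure is fully deterministic.
    """
    try:
        mirrored = mirror_reconstruct(target, pairing,
                                      regularization=regularization)
        base = mirrored.completed
        base_prov = dict(mirrored.provenance)
    except (ReconstructionError, DegenerateGeometryError):
        base = target
        base_prov = {d.id: Provenance.ORIGINAL
                     for i, d in enumerate(target.template)
                     if target.present[i]}
    results = []
    for spec in subsample_specs:
        subset = resolve_subsample(spec, sample, base)
        res = estimate_missing_from_reference(
            base, subset, regularization=regularization,
            subsample_name=spec.name, base_provenance=base_prov,
        )
        results.append(res)
    return results


def warp_donor_mesh(donor_mesh: trimesh.Trimesh,
                    donor_landmarks: LandmarkConfiguration,
                    completed: LandmarkConfiguration) -> trimesh.Trimesh:
    """Warp a complete donor specimen's mesh onto a completed configuration
    via the TPS between their landmark sets; connectivity is unchanged."""
    if donor_landmarks.template.ids != completed.template.ids:
        raise ReconstructionError("donor and completed templates differ")
    if not (donor_landmarks.is_complete and completed.is_complete):
        raise ReconstructionError("donor and completed must both be complete")
    model = tps_fit(donor_landmarks.coords, completed.coords)
    vertices = tps_apply(model, np.asarray(donor_mesh.vertices, dtype=float))
    return trimesh.Trimesh(vertices=vertices,
                           faces=donor_mesh.faces.copy(), process=False)
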