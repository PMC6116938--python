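"""Domain types for 3D landmark configurations.

A cranium is represented as a named, typed set of 3D points (landmarks and
semilandmarks) with per-point presence flags. Bilateral structure (left/right
pairing and midsagittal membership) is carried separately so that mirroring
operations can relabel points without touching geometry.

Coordinates are millimetres in an arbitrary right-handed Cartesian frame; the
pipeline is invariant to global pose, so no anatomical axis convention is
imposed. Landmark ids are 1-based and stable across specimens; the template
owns the mapping to 0-based array positions.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from enum import Enum
from typing import Iterable, Mapping, Sequence

import numpy as np


class LandmarkKind(str, Enum):
    ANATOMICAL = "anatomical"
    CURVE_SEMILANDMARK = "curve_semilandmark"
    SURFACE_SEMILANDMARK = "surface_semilandmark"


class Side(str, Enum):
    LEFT = "left"
    RIGHT = "right"
    MIDLINE = "midline"


class HomologyError(ValueError):
    """Raised when configurations do not share a landmark template."""


class PairingError(ValueError):
    """Raised when a bilateral pairing does not cover a template."""


@dataclass(frozen=True)
class LandmarkDef:
    """Definition of one landmark within a template.

    Parameters
    ----------
    id : int
        1-based identifier, stable across specimens.
    name : str
        Short anatomical name (e.g. ``"bregma"``).
    kind : LandmarkKind
        Anatomical landmark or curve/surface semilandmark.
    side : Side
        Bilateral side; midline points must have ``Side.MIDLINE``.
    curve_id : str, optional
        Curve membership for curve semilandmarks.
    curve_ordinal : int, optional
        Strict ordering along the curve.
    surface_id : str, optional
        Surface patch membership for surface semilandmarks.
    """

    id: int
    name: str
    kind: LandmarkKind = LandmarkKind.ANATOMICAL
    side: Side = Side.MIDLINE
    curve_id: str | None = None
    curve_ordinal: int | None = None
    surface_id: str | None = None

    def __post_init__(self) -> None:
        if self.id < 1:
            raise ValueError(f"landmark id must be a positive integer, got {self.id}")


@dataclass(frozen=True)
class Template:
    """An ordered collection of LandmarkDefs with unique ids."""

    defs: tuple[LandmarkDef, ...]

    def __post_init__(self) -> None:
        ids = [d.id for d in self.defs]
        seen: set[int] = set()
        for i in ids:
            if i in seen:
                raise ValueError(f"duplicate landmark id {i} in template")
            seen.add(i)
        # curve semilandmarks need a strict ordinal ordering per curve
        by_curve: dict[str, list[int]] = {}
        for d in self.defs:
            if d.kind is LandmarkKind.CURVE_SEMILANDMARK and d.curve_id is not None:
                by_curve.setdefault(d.curve_id, []).append(
                    -1 if d.curve_ordinal is None else d.curve_ordinal
                )
        for cid, ords in by_curve.items():
            if len(set(ords)) != len(ords) or -1 in ords:
                raise ValueError(f"curve {cid!r} lacks a strict ordinal ordering")

    def __len__(self) -> int:
        return len(self.defs)

    def __iter__(self):
        return iter(self.defs)

    @property
    def ids(self) -> tuple[int, ...]:
        return tuple(d.id for d in self.defs)

    def index_of(self, landmark_id: int) -> int:
        """0-based array position of a 1-based landmark id."""
        try:
            return self._id_to_pos[landmark_id]
        except AttributeError:
            object.__setattr__(
                self, "_id_to_pos", {d.id: i for i, d in enumerate(self.defs)}
            )
            return self._id_to_pos[landmark_id]

    def indices_of(self, landmark_ids: Iterable[int]) -> np.ndarray:
        return np.array([self.index_of(i) for i in landmark_ids], dtype=int)

    def select(self, **attrs) -> list[LandmarkDef]:
        out = []
        for d in self.defs:
            if all(getattr(d, k) == v for k, v in attrs.items()):
                out.append(d)
        return out

    def curves(self) -> dict[str, list[int]]:
        """Map curve_id -> landmark ids ordered by curve_ordinal."""
        by_curve: dict[str, list[LandmarkDef]] = {}
        for d in self.defs:
            if d.curve_id is not None:
                by_curve.setdefault(d.curve_id, []).append(d)
        return {
            cid: [d.id for d in sorted(ds, key=lambda d: d.curve_ordinal or 0)]
            for cid, ds in by_curve.items()
        }


@dataclass(frozen=True)
class BilateralPairing:
    """Left/right id pairs plus midline ids; together they cover a template.

    Relabelling by the pairing is an involution: applying it twice returns the
    original id ordering.
    """

    pairs: tuple[tuple[int, int], ...]
    midline_ids: tuple[int, ...]

    def __post_init__(self) -> None:
        all_ids = [i for p in self.pairs for i in p] + list(self.midline_ids)
        if len(set(all_ids)) != len(all_ids):
            raise PairingError("an id appears more than once in the pairing")

    def covers(self, template: Template) -> bool:
        covered = {i for p in self.pairs for i in p} | set(self.midline_ids)
        return covered == set(template.ids)

    def swap_map(self) -> dict[int, int]:
        """id -> contralateral id (midline ids map to themselves)."""
        m = {i: i for i in self.midline_ids}
        for left, right in self.pairs:
            m[left] = right
            m[right] = left
        return m

    def validate_against(self, template: Template) -> None:
        if not self.covers(template):
            covered = {i for p in self.pairs for i in p} | set(self.midline_ids)
            missing = sorted(set(template.ids) - covered)
            extra = sorted(covered - set(template.ids))
            raise PairingError(
                f"pairing does not cover template (uncovered ids {missing}, "
                f"foreign ids {extra})"
            )


@dataclass(frozen=True)
class Plane:
    """A plane given by a point and a unit normal."""

    point: np.ndarray
    normal: np.ndarray

    def __post_init__(self) -> None:
        p = np.asarray(self.point, dtype=float).reshape(3)
        n = np.asarray(self.normal, dtype=float).reshape(3)
        norm = np.linalg.norm(n)
        if abs(norm - 1.0) > 1e-12:
            if norm == 0:
                raise ValueError("plane normal must be non-zero")
            n = n / norm
        object.__setattr__(self, "point", p)
        object.__setattr__(self, "normal", n)

    def signed_distance(self, points: np.ndarray) -> np.ndarray:
        pts = np.atleast_2d(np.asarray(points, dtype=float))
        return (pts - self.point) @ self.normal

    def reflect(self, points: np.ndarray) -> np.ndarray:
        """Householder reflection of points across the plane."""
        pts = np.atleast_2d(np.asarray(points, dtype=float))
        d = self.signed_distance(pts)
        return pts - 2.0 * d[:, None] * self.normal[None, :]


@dataclass
class LandmarkConfiguration:
    """One specimen's landmark coordinates on a template.

    ``coords`` is an (N, 3) array in mm; ``present`` a boolean mask. Missing
    points have undefined coordinates (stored as NaN). Coordinates must be
    finite wherever ``present`` is true.
    """

    template: Template
    coords: np.ndarray
    present: np.ndarray | None = None
    specimen_id: str = ""
    metadata: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        self.coords = np.asarray(self.coords, dtype=float)
        n = len(self.template)
        if self.coords.shape != (n, 3):
            raise ValueError(
                f"coords shape {self.coords.shape} does not match template length {n}"
            )
        if self.present is None:
            self.present = np.isfinite(self.coords).all(axis=1)
        self.present = np.asarray(self.present, dtype=bool).reshape(n)
        if not np.isfinite(self.coords[self.present]).all():
            raise ValueError("non-finite coordinates at present landmarks")

    # -- convenience ---------------------------------------------------------
    @property
    def n_landmarks(self) -> int:
        return len(self.template)

    @property
    def is_complete(self) -> bool:
        return bool(self.present.all())

    @property
    def present_ids(self) -> list[int]:
        return [d.id for d, p in zip(self.template, self.present) if p]

    @property
    def missing_ids(self) -> list[int]:
        return [d.id for d, p in zip(self.template, self.present) if not p]

    def coords_of(self, landmark_ids: Iterable[int]) -> np.ndarray:
        return self.coords[self.template.indices_of(landmark_ids)]

    def with_coords(self, coords: np.ndarray, present: np.ndarray | None = None
                    ) -> "LandmarkConfiguration":
        return LandmarkConfiguration(
            template=self.template,
            coords=np.array(coords, dtype=float),
            present=self.present.copy() if present is None else np.asarray(present, bool),
            specimen_id=self.specimen_id,
            metadata=dict(self.metadata),
        )

    def copy(self) -> "LandmarkConfiguration":
        return self.with_coords(self.coords.copy())


@dataclass
class ReferenceSample:
    """A collection of complete, mutually homologous configurations.

    Used as the donor pool for reference-based missing-landmark estimation.
    Named subsample selectors (``all``, metadata filters, ``closest_k``,
    explicit id lists) are resolved by :mod:`craniomorph.reconstruction`.
    """

    configurations: list[LandmarkConfiguration]

    def __post_init__(self) -> None:
        if not self.configurations:
            raise ValueError("reference sample is empty")
        t0 = self.configurations[0].template
        for c in self.configurations:
            if c.template.ids != t0.ids:
                raise HomologyError(
                    f"specimen {c.specimen_id!r} does not share the sample template"
                )
            if not c.is_complete:
                raise ValueError(
                    f"reference specimen {c.specimen_id!r} is incomplete "
                    f"(missing ids {c.missing_ids})"
                )

    @property
    def template(self) -> Template:
        return self.configurations[0].template

    def __len__(self) -> int:
        return len(self.configurations)

    def __iter__(self):
        return iter(self.configurations)

    def specimen(self, specimen_id: str) -> LandmarkConfiguration:
        for c in self.configurations:
            if c.specimen_id == specimen_id:
                return c
        raise KeyError(f"no specimen {specimen_id!r} in reference sample")

    def filter(self, **metadata) -> list[LandmarkConfiguration]:
        return [
            c for c in self.configurations
            if all(c.metadata.get(k) == v for k, v in metadata.items())
        ]


def validate_homology(sample: ReferenceSample,
                      target: LandmarkConfiguration) -> dict:
    """Check that a target shares the sample template; summarise its gaps.

    Returns a report dict with the target's missing ids grouped by side and
    by curve. Raises :class:`HomologyError` on template mismatch, naming the
    offending ids.
    """
    sample_ids = set(sample.template.ids)
    target_ids = set(target.template.ids)
    if sample_ids != target_ids:
        extra = sorted(target_ids - sample_ids)
        absent = sorted(sample_ids - target_ids)
        raise HomologyError(
            f"template mismatch: target has foreign ids {extra}, "
            f"lacks ids {absent}"
        )
    missing = target.missing_ids
    by_side: dict[str, list[int]] = {}
    by_curve: dict[str, list[int]] = {}
    for lid in missing:
        d = target.template.defs[target.template.index_of(lid)]
        by_side.setdefault(d.side.value, []).append(lid)
        if d.curve_id is not None:
            by_curve.setdefault(d.curve_id, []).append(lid)
    return {
        "n_landmarks": target.n_landmarks,
        "n_missing": len(missing),
        "missing_ids": missing,
        "missing_by_side": by_side,
        "missing_by_curve": by_curve,
        "errors": [],
    }
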