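"""Synthetic skull-like data with known ground truth.

Real cranial CT landmark data and literature-collected fossil measurements
are not redistributable, so every pipeline stage is exercised on generated
data instead. The generator builds a schematic but geometrically reasonable
cranium: midline landmarks on a parabolic sagittal arc, bilateral landmark
pairs on an ellipsoid shell mirrored exactly across x = 0 (left is +x),
plus paired curve and surface semilandmarks. Populations are simulated by
composing smooth low-rank TPS deformation fields on top of that symmetric
template:

* a per-group shape field (group mean differences),
* a sex shape field plus a centroid-size multiplier for males,
* a fixed directional-asymmetry field displacing the left side,
* independent isotropic Gaussian landmark noise.

Because every effect field is itself a TPS from at most 10 control
displacements, the asymmetry is exactly the kind of smooth deformation the
asymmetry-preserving mirror reconstruction assumes — making its superiority
over naive mirroring a fair, well-posed test. Fragmentation (contiguous
missing regions around centre landmarks) emulates taphonomic damage; MCAR
cell deletion emulates differential preservation of measurement tables.

All randomness flows from a single master seed through spawned seed
sequences, so every downstream product is bitwise reproducible.
"""

from __future__ import annotations

from dataclasses import dataclass, field as dc_field
from typing import Sequence

import numpy as np
import pandas as pd

from .landmarks import (
    BilateralPairing,
    LandmarkConfiguration,
    LandmarkDef,
    LandmarkKind,
    ReferenceSample,
    Side,
    Template,
)
from .measurements import MeasurementDef, MeasurementType, measurement_columns
from .reconstruction import SubsampleSpec
from .tps import tps_apply, tps_fit

# Table-like raw cranial measurement scale (mm) used as the base mean vector
# for directly simulated measurement tables.
BASE_MEASUREMENT_MEANS = {
    "M1": 190.0, "M5": 100.0, "M8": 140.0, "M9": 97.0, "M10": 120.0,
    "M17": 130.0, "M20": 112.0, "M23": 540.0, "M26": 130.0, "M27": 125.0,
    "M28": 118.0, "M40": 96.0, "M45": 130.0, "M48": 66.0, "M51": 42.0,
    "M52": 33.0, "M54": 25.0, "M55": 50.0, "M61": 62.0, "M63": 38.0,
}


@dataclass
class SimulationSpec:
    """Parameters of the synthetic skull population."""

    n_midline: int = 9
    n_bilateral_pairs: int = 12
    n_curve_semis: int = 6       # per side
    n_surface_semis: int = 8     # per side
    n_specimens: dict[str, int] = dc_field(
        default_factory=lambda: {"recent": 30, "fossil": 1})
    group_effects: dict[str, float] = dc_field(
        default_factory=lambda: {"recent": 0.0, "fossil": 3.0})
    sex_size_factor: float = 1.05
    sex_shape_magnitude: float = 1.0
    directional_asymmetry_magnitude: float = 2.0
    noise_sd: float = 0.5
    fragmentation: list[tuple[int, float]] = dc_field(default_factory=list)
    measurement_missing_rate: float = 0.0
    master_seed: int = 0

    def __post_init__(self) -> None:
        for v in (self.sex_shape_magnitude,
                  self.directional_asymmetry_magnitude, self.noise_sd):
            if v < 0:
                raise ValueError("effect magnitudes must be non-negative")
        if not (0 <= self.measurement_missing_rate < 1):
            raise ValueError("missing rate must be in [0, 1)")
        if self.sex_size_factor <= 0:
            raise ValueError("sex_size_factor must be positive")


@dataclass
class SyntheticTruth:
    """Ground truth of a simulated population."""

    true_configurations: list[LandmarkConfiguration]
    labels: pd.DataFrame
    masks: dict[str, np.ndarray] = dc_field(default_factory=dict)
    true_measurements: pd.DataFrame | None = None


# -- template ----------------------------------------------------------------

SEMI_AXES = np.array([70.0, 90.0, 65.0])  # left-right, front-back, vertical


def _shell_point(u: float, v: float) -> np.ndarray:
    """Point on the ellipsoid shell; u is longitude from +y, v latitude."""
    return SEMI_AXES * np.array([
        np.cos(v) * np.sin(u), np.cos(v) * np.cos(u), np.sin(v),
    ])


def make_template(spec: SimulationSpec
                  ) -> tuple[LandmarkConfiguration, BilateralPairing,
                             dict[str, list[int]]]:
    """Construct the exactly symmetric template configuration.

    Midline landmarks lie on a parabolic arc in x = 0; each bilateral pair is
    (left at +x, right at -x) on the ellipsoid shell. Curve semilandmarks
    form one ordered arc per side, surface semilandmarks a scattered patch
    per side. Returns the template configuration, its bilateral pairing and
    the curve topology (curve_id -> ordered landmark ids).
    """
    if spec.n_midline < 3 or spec.n_bilateral_pairs < 4:
        raise ValueError("need >=3 midline landmarks and >=4 bilateral pairs")
    defs: list[LandmarkDef] = []
    coords: list[np.ndarray] = []
    pairs: list[tuple[int, int]] = []
    midline_ids: list[int] = []
    next_id = 1

    # midline: parabolic arc in the y-z plane, front (+y) to back (-y)
    ys = np.linspace(90.0, -90.0, spec.n_midline)
    for k, y in enumerate(ys):
        z = 60.0 - (y ** 2) / 135.0
        defs.append(LandmarkDef(id=next_id, name=f"mid_{k + 1}",
                                kind=LandmarkKind.ANATOMICAL,
                                side=Side.MIDLINE))
        coords.append(np.array([0.0, y, z]))
        midline_ids.append(next_id)
        next_id += 1

    # bilateral anatomical pairs on the shell
    n = spec.n_bilateral_pairs
    golden = np.pi * (3 - np.sqrt(5))
    for k in range(n):
        u = 0.35 + 0.55 * ((k * golden) % (np.pi / 1.6))  # keep x > 0
        v = -0.5 + 1.2 * (k + 0.5) / n
        p_left = _shell_point(u, v)
        for side, sign, tag in ((Side.LEFT, 1.0, "l"), (Side.RIGHT, -1.0, "r")):
            defs.append(LandmarkDef(id=next_id, name=f"pair_{k + 1}_{tag}",
                                    kind=LandmarkKind.ANATOMICAL, side=side))
            coords.append(p_left * np.array([sign, 1.0, 1.0]))
            next_id += 1
        pairs.append((next_id - 2, next_id - 1))

    # one ordered curve per side (temporal-line analogue)
    curves: dict[str, list[int]] = {"temporal_l": [], "temporal_r": []}
    for k in range(spec.n_curve_semis):
        v = -0.2 + 0.9 * k / max(spec.n_curve_semis - 1, 1)
        p_left = _shell_point(0.9, v)
        for cid, side, sign, tag in (("temporal_l", Side.LEFT, 1.0, "l"),
                                     ("temporal_r", Side.RIGHT, -1.0, "r")):
            defs.append(LandmarkDef(
                id=next_id, name=f"curve_{k + 1}_{tag}",
                kind=LandmarkKind.CURVE_SEMILANDMARK, side=side,
                curve_id=cid, curve_ordinal=k + 1))
            coords.append(p_left * np.array([sign, 1.0, 1.0]))
            curves[cid].append(next_id)
            next_id += 1
        pairs.append((next_id - 2, next_id - 1))

    # scattered surface patch per side
    for k in range(spec.n_surface_semis):
        u = 0.45 + 0.8 * ((k * golden) % 1.0)
        v = -0.35 + 1.0 * ((k * 0.37 + 0.13) % 1.0)
        p_left = _shell_point(u, v)
        for side, sign, tag in ((Side.LEFT, 1.0, "l"), (Side.RIGHT, -1.0, "r")):
            defs.append(LandmarkDef(
                id=next_id, name=f"surf_{k + 1}_{tag}",
                kind=LandmarkKind.SURFACE_SEMILANDMARK, side=side,
                surface_id="vault"))
            coords.append(p_left * np.array([sign, 1.0, 1.0]))
            next_id += 1
        pairs.append((next_id - 2, next_id - 1))

    template = LandmarkConfiguration(
        template=Template(tuple(defs)),
        coords=np.array(coords), specimen_id="template",
    )
    pairing = BilateralPairing(pairs=tuple(pairs),
                               midline_ids=tuple(midline_ids))
    return template, pairing, curves


# -- smooth deformation fields ----------------------------------------------

def _smooth_field(base_coords: np.ndarray, magnitude: float,
                  rng: np.random.Generator, n_controls: int = 8):
    """A smooth TPS displacement field with control displacements of the
    given RMS magnitude (mm); returns a callable points -> displacements."""
    lo, hi = base_coords.min(axis=0), base_coords.max(axis=0)
    controls = rng.uniform(lo - 10, hi + 10, size=(n_controls, 3))
    disp = rng.normal(size=(n_controls, 3))
    disp *= magnitude / max(np.sqrt((disp ** 2).sum(axis=1).mean()), 1e-12)
    if magnitude == 0:
        return lambda pts: np.zeros_like(np.atleast_2d(pts))
    model = tps_fit(controls, controls + disp)
    return lambda pts: tps_apply(model, pts) - np.atleast_2d(pts)


def simulate_population(spec: SimulationSpec
                        ) -> tuple[list[LandmarkConfiguration], pd.DataFrame,
                                   SyntheticTruth]:
    """Simulate a labelled population of complete configurations.

    Specimens are allocated to groups per ``spec.n_specimens`` with sexes
    alternating within each group. Effect fields (group, sex, asymmetry) are
    fixed across the population; only the landmark noise is per-specimen.
    """
    template, pairing, curves = make_template(spec)
    base = template.coords
    ss = np.random.SeedSequence(spec.master_seed)
    field_rng, noise_rng = [np.random.default_rng(s) for s in ss.spawn(2)]

    group_fields = {
        g: _smooth_field(base, mag, field_rng)
        for g, mag in sorted(spec.group_effects.items())
    }
    sex_field = _smooth_field(base, spec.sex_shape_magnitude, field_rng)
    asym_field = _smooth_field(base, spec.directional_asymmetry_magnitude,
                               field_rng)
    left_mask = np.array([d.side is Side.LEFT for d in template.template])

    configs: list[LandmarkConfiguration] = []
    rows = []
    for group in sorted(spec.n_specimens):
        n_g = spec.n_specimens[group]
        gf = group_fields.get(group,
                              _smooth_field(base, 0.0, field_rng))
        for k in range(n_g):
            sex = "M" if k % 2 == 0 else "F"
            coords = base + gf(base)
            if sex == "M":
                coords = coords + sex_field(coords)
                centroid = coords.mean(axis=0)
                coords = centroid + spec.sex_size_factor * (coords - centroid)
            disp = asym_field(coords)
            coords = coords + np.where(left_mask[:, None], disp, 0.0)
            coords = coords + noise_rng.normal(0.0, spec.noise_sd,
                                               size=coords.shape)
            sid = f"{group}_{k + 1:03d}"
            configs.append(LandmarkConfiguration(
                template=template.template, coords=coords,
                specimen_id=sid, metadata={"sex": sex, "group": group},
            ))
            rows.append({"specimen_id": sid, "sex": sex, "group": group})
    labels = pd.DataFrame(rows).set_index("specimen_id")
    truth = SyntheticTruth(true_configurations=[c.copy() for c in configs],
                           labels=labels)
    return configs, labels, truth


def apply_fragmentation(config: LandmarkConfiguration,
                        fragmentation: Sequence[tuple[int, float]],
                        ) -> tuple[LandmarkConfiguration, np.ndarray]:
    """Mark missing every landmark within ``radius`` mm of each centre id.

    Returns the damaged configuration and the boolean deletion mask.
    Idempotent: damaging an already-damaged configuration with the same spec
    changes nothing further.
    """
    mask = np.zeros(config.n_landmarks, dtype=bool)
    for center_id, radius in fragmentation:
        i = config.template.index_of(center_id)
        if not np.isfinite(config.coords[i]).all():
            continue
        d = np.linalg.norm(config.coords - config.coords[i], axis=1)
        mask |= d <= radius
    coords = config.coords.copy()
    coords[mask] = np.nan
    damaged = LandmarkConfiguration(
        template=config.template, coords=coords,
        present=config.present & ~mask,
        specimen_id=config.specimen_id, metadata=dict(config.metadata),
    )
    return damaged, mask


# -- measurement tables ------------------------------------------------------

def default_measurement_defs(template: LandmarkConfiguration
                             ) -> list[MeasurementDef]:
    """The 20 classical codes mapped onto the schematic template.

    The mapping is structural (lengths, breadths, sagittal arcs, one
    horizontal circumference), not a claim of anatomical fidelity.
    """
    t = template.template
    name_to_id = {d.name: d.id for d in t}
    mid = [name_to_id[f"mid_{k + 1}"]
           for k in range(len(t.select(side=Side.MIDLINE)))]
    n_pairs_total = sum(1 for d in t if d.name.startswith("pair_")) // 2
    pl = [name_to_id[f"pair_{k + 1}_l"] for k in range(n_pairs_total)]
    pr = [name_to_id[f"pair_{k + 1}_r"] for k in range(n_pairs_total)]
    m = len(mid)
    D, A, C = (MeasurementType.DISTANCE, MeasurementType.ARC,
               MeasurementType.CIRCUMFERENCE)
    q = m // 2
    ring = [mid[0]] + pl[:4] + [mid[-1]] + pr[:4][::-1]
    defs = [
        MeasurementDef("M1", D, (mid[0], mid[-1])),
        MeasurementDef("M5", D, (mid[1], mid[-2])),
        MeasurementDef("M8", D, (pl[0], pr[0])),
        MeasurementDef("M9", D, (pl[1], pr[1])),
        MeasurementDef("M10", D, (pl[2], pr[2])),
        MeasurementDef("M17", D, (mid[q], mid[-1])),
        MeasurementDef("M20", D, (mid[q], pl[3])),
        MeasurementDef("M23", C, tuple(ring)),
        MeasurementDef("M26", A, tuple(mid[:q + 1])),
        MeasurementDef("M27", A, tuple(mid[q:])),
        MeasurementDef("M28", A, (mid[0], mid[q], mid[-1])),
        MeasurementDef("M40", D, (mid[0], mid[1])),
        MeasurementDef("M45", D, (pl[4], pr[4])),
        MeasurementDef("M48", D, (mid[0], mid[q])),
        MeasurementDef("M51", D, (pl[5], pr[5])),
        MeasurementDef("M52", D, (pl[6], pr[6])),
        MeasurementDef("M54", D, (pl[7], pr[7])),
        MeasurementDef("M55", D, (mid[1], mid[q])),
        MeasurementDef("M61", D, (pl[8], pr[8])),
        MeasurementDef("M63", D, (pl[9], pr[9])),
    ]
    return defs


def make_measurement_table(configs: Sequence[LandmarkConfiguration],
                           defs: Sequence[MeasurementDef]) -> pd.DataFrame:
    from .measurements import measurement_table
    return measurement_table(configs, defs)


def inject_missingness(table: pd.DataFrame, rate: float, seed: int
                       ) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Delete measurement cells independently (MCAR) at the given rate.

    Returns (damaged table, boolean deletion mask over measurement columns).
    """
    if not (0 <= rate < 1):
        raise ValueError("rate must be in [0, 1)")
    cols = measurement_columns(table)
    rng = np.random.default_rng(seed)
    mask = rng.random(size=(len(table), len(cols))) < rate
    out = table.copy()
    values = out[cols].to_numpy(dtype=float)
    values[mask] = np.nan
    out[cols] = values
    return out, pd.DataFrame(mask, index=table.index, columns=cols)


def simulate_measurement_table(
    n_per_group: dict[str, int] | None = None, *,
    group_effect: float = 0.04,
    sex_size_factor: float = 1.06,
    sex_shape_effect: float = 0.03,
    noise_cv: float = 0.025,
    size_cv: float = 0.035,
    missing_rate: float = 0.0,
    seed: int = 0,
    codes: Sequence[str] | None = None,
) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Directly simulate a craniometric measurement table.

    Log-measurements are a base mean vector plus a shared latent size factor
    (coefficient of variation ``size_cv``; males additionally multiplied by
    ``sex_size_factor``), a fixed random group direction of log-magnitude
    ``group_effect`` per group, a fixed sex shape direction of magnitude
    ``sex_shape_effect``, and independent noise of CV ``noise_cv``. Returns
    the (possibly MCAR-damaged) table and the complete truth table. Group
    sizes default to the study-like pattern of three recent population
    samples of about a hundred crania each plus pre- and post-LGM fossil
    groups of a few dozen.
    """
    if n_per_group is None:
        n_per_group = {"recent:austrian": 100, "recent:hungarian": 100,
                       "recent:norse": 100, "pre-LGM": 31, "post-LGM": 27}
    codes = list(codes) if codes is not None else list(BASE_MEASUREMENT_MEANS)
    mu = np.log([BASE_MEASUREMENT_MEANS[c] for c in codes])
    p = len(codes)
    ss = np.random.SeedSequence(seed)
    rng_dir, rng_noise, rng_miss = [np.random.default_rng(s)
                                    for s in ss.spawn(3)]
    group_dirs = {}
    for g in sorted(n_per_group):
        d = rng_dir.normal(size=p)
        group_dirs[g] = d / np.linalg.norm(d)
    sex_dir = rng_dir.normal(size=p)
    sex_dir /= np.linalg.norm(sex_dir)

    rows, meta = [], []
    for g in sorted(n_per_group):
        for k in range(n_per_group[g]):
            sex = "M" if k % 2 == 0 else "F"
            s = rng_noise.normal(0.0, size_cv)
            logv = mu + s + group_effect * group_dirs[g]
            if sex == "M":
                logv = logv + np.log(sex_size_factor) \
                    + sex_shape_effect * sex_dir
            logv = logv + rng_noise.normal(0.0, noise_cv, size=p)
            rows.append(np.exp(logv))
            meta.append({"specimen_id": f"{g}_{k + 1:03d}",
                         "sex": sex, "group": g})
    truth = pd.DataFrame(rows, columns=codes,
                         index=pd.Index([m["specimen_id"] for m in meta],
                                        name="specimen_id"))
    truth.insert(0, "sex", [m["sex"] for m in meta])
    truth.insert(1, "group", [m["group"] for m in meta])
    table = truth
    if missing_rate > 0:
        table, _ = inject_missingness(
            truth, missing_rate, int(rng_miss.integers(0, 2 ** 31 - 1)))
    return table, truth


# -- the study-shaped reconstruction scenario --------------------------------

def default_fragmentation(template: LandmarkConfiguration
                          ) -> list[tuple[int, float]]:
    """Left-side and mid-face damage analogous to the target's preservation:
    a large left-vault region and an anterior midline region go missing."""
    t = template.template
    name_to_id = {d.name: d.id for d in t}
    left_center = name_to_id["surf_1_l"]
    face_center = name_to_id["mid_2"]
    return [(left_center, 55.0), (face_center, 35.0)]


def table1_subsample_specs() -> list[SubsampleSpec]:
    """The seven reference subsamples of the reconstruction ensemble: all,
    recent, recent males, recent females, closest 10, closest 1, and the
    single contemporaneous fossil."""
    return [
        SubsampleSpec("all", "all"),
        SubsampleSpec("recent", "filter", where=(("group", "recent"),)),
        SubsampleSpec("recent_males", "filter",
                      where=(("group", "recent"), ("sex", "M"))),
        SubsampleSpec("recent_females", "filter",
                      where=(("group", "recent"), ("sex", "F"))),
        SubsampleSpec("closest_10", "closest", k=10,
                      where=(("group", "recent"),)),
        SubsampleSpec("closest_1", "closest", k=1,
                      where=(("group", "recent"),)),
        SubsampleSpec("fossil", "filter", where=(("group", "fossil"),)),
    ]


def default_reconstruction_scenario(seed: int = 0, *,
                                    noise_sd: float = 0.5,
                                    asymmetry: float = 2.0,
                                    ) -> dict:
    """Generate the study-shaped scenario: 30 recent crania + 1 fossil as
    the reference sample, and one fragmented target specimen.

    Returns a dict with the target (damaged), its complete ground truth, the
    reference sample, pairing, curves, subsample specs, and the deletion
    mask.
    """
    spec = SimulationSpec(
        n_specimens={"recent": 30, "fossil": 1, "target": 1},
        group_effects={"recent": 0.0, "fossil": 3.0, "target": 2.0},
        noise_sd=noise_sd,
        directional_asymmetry_magnitude=asymmetry,
        master_seed=seed,
    )
    configs, labels, truth = simulate_population(spec)
    template, pairing, curves = make_template(spec)
    reference = ReferenceSample([c for c in configs
                                 if c.metadata["group"] != "target"])
    target_true = next(c for c in configs if c.metadata["group"] == "target")
    frag = default_fragmentation(template)
    target, mask = apply_fragmentation(target_true, frag)
    return {
        "spec": spec,
        "template": template,
        "pairing": pairing,
        "curves": curves,
        "reference": reference,
        "target": target,
        "target_truth": target_true,
        "deleted_mask": mask,
        "subsample_specs": table1_subsample_specs(),
        "labels": labels,
    }
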