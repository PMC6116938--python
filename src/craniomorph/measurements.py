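"""Linear craniometric measurements and size adjustment.

Measurements follow the classical numbered conventions (M1 maximum cranial
length, M45 bi-zygomatic breadth, ...): straight-line distances between two
landmarks, arcs as polyline lengths over an ordered landmark chain, and
circumferences as closed polylines. Values are millimetres.

Size adjustment uses log-shape ratios: each measurement is divided by the
specimen's geometric mean over the selected measurement set and logged, so
every row of the transformed table sums to zero and isometric size is
removed while shape contrasts remain.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass
from enum import Enum
from typing import Iterable, Sequence

import numpy as np
import pandas as pd

from .landmarks import LandmarkConfiguration

LABEL_COLUMNS = ["sex", "group"]


class MeasurementType(str, Enum):
    DISTANCE = "distance"
    ARC = "arc"
    CIRCUMFERENCE = "circumference"


@dataclass(frozen=True)
class MeasurementDef:
    """A named linear measurement over template landmark ids."""

    code: str
    type: MeasurementType
    endpoints: tuple[int, ...]

    def __post_init__(self) -> None:
        if self.type is MeasurementType.DISTANCE and len(self.endpoints) != 2:
            raise ValueError(f"{self.code}: distance needs exactly 2 endpoints")
        if self.type is not MeasurementType.DISTANCE and len(self.endpoints) < 3:
            raise ValueError(f"{self.code}: arc/circumference needs >=3 points")


def _polyline_length(points: np.ndarray, closed: bool) -> float:
    segs = np.diff(points, axis=0)
    total = float(np.linalg.norm(segs, axis=1).sum())
    if closed:
        total += float(np.linalg.norm(points[0] - points[-1]))
    return total


def compute_measurements(config: LandmarkConfiguration,
                         defs: Sequence[MeasurementDef]) -> dict[str, float]:
    """Evaluate measurement definitions on one configuration.

    A measurement whose landmarks are not all present yields NaN with a
    warning rather than an error (missing cells are imputed downstream).
    """
    out: dict[str, float] = {}
    for d in defs:
        idx = config.template.indices_of(d.endpoints)
        if not config.present[idx].all():
            warnings.warn(
                f"measurement {d.code}: referenced landmarks missing; "
                "cell set to NaN", stacklevel=2)
            out[d.code] = np.nan
            continue
        pts = config.coords[idx]
        if d.type is MeasurementType.DISTANCE:
            out[d.code] = float(np.linalg.norm(pts[0] - pts[1]))
        elif d.type is MeasurementType.ARC:
            out[d.code] = _polyline_length(pts, closed=False)
        else:
            out[d.code] = _polyline_length(pts, closed=True)
    return out


def measurement_table(configs: Iterable[LandmarkConfiguration],
                      defs: Sequence[MeasurementDef]) -> pd.DataFrame:
    """Specimens x measurements table with sex/group label columns."""
    rows = []
    index = []
    for c in configs:
        row = {"sex": c.metadata.get("sex", "unknown"),
               "group": c.metadata.get("group", "unknown")}
        row.update(compute_measurements(c, defs))
        rows.append(row)
        index.append(c.specimen_id)
    return pd.DataFrame(rows, index=pd.Index(index, name="specimen_id"))


def measurement_columns(table: pd.DataFrame) -> list[str]:
    return [c for c in table.columns if c not in LABEL_COLUMNS]


def log_shape_ratios(table: pd.DataFrame,
                     columns: Sequence[str] | None = None) -> pd.DataFrame:
    """Size-adjust measurements: v -> ln(v / geometric mean of the row).

    Rows with a missing cell among the selected columns are dropped with a
    warning (impute first); non-positive values are an error. Label columns
    pass through untouched. Each transformed row sums to zero, and the
    transform is invariant to scaling a row by any positive constant.
    """
    cols = list(columns) if columns is not None else measurement_columns(table)
    values = table[cols].to_numpy(dtype=float)
    keep = ~np.isnan(values).any(axis=1)
    if not keep.all():
        dropped = list(table.index[~keep])
        warnings.warn(f"rows with missing cells skipped: {dropped}",
                      stacklevel=2)
    values = values[keep]
    if (values <= 0).any():
        i, j = np.argwhere(values <= 0)[0]
        raise ValueError(
            f"non-positive measurement at specimen "
            f"{table.index[keep][i]!r}, column {cols[j]!r}"
        )
    logv = np.log(values)
    lsr = logv - logv.mean(axis=1, keepdims=True)
    out = table.loc[keep, [c for c in LABEL_COLUMNS if c in table.columns]].copy()
    for j, c in enumerate(cols):
        out[c] = lsr[:, j]
    return out


# -- default measurement sets ------------------------------------------------
# The shipped template (see craniomorph.synthetic) is schematic, so these
# definitions map the classical codes onto its ids rather than onto a real
# digitization protocol. The 13-code subset is the set shared with the
# Howells database columns (GOL, BNL, XCB, XFB, BBH, BPL, ZYB, NPH, OBB,
# OBH, NLB, NLH, MAB).
HOWELLS_TO_MARTIN = {
    "GOL": "M1", "BNL": "M5", "XCB": "M8", "XFB": "M10", "BBH": "M17",
    "BPL": "M40", "ZYB": "M45", "NPH": "M48", "OBB": "M51", "OBH": "M52",
    "NLB": "M54", "NLH": "M55", "MAB": "M61",
}
HOWELLS_COMPARABLE_CODES = tuple(HOWELLS_TO_MARTIN.values())


def read_measurement_csv(path) -> pd.DataFrame:
    """Read a measurement table CSV: specimen_id, sex, group, then codes."""
    df = pd.read_csv(path, index_col="specimen_id")
    for col in LABEL_COLUMNS:
        if col not in df.columns:
            df[col] = "unknown"
    return df


def read_howells_csv(path) -> pd.DataFrame:
    """Import a Howells-format CSV, renaming its columns to Martin codes."""
    df = pd.read_csv(path)
    if "ID" in df.columns:
        df = df.set_index("ID")
        df.index.name = "specimen_id"
    rename = {k: v for k, v in HOWELLS_TO_MARTIN.items() if k in df.columns}
    df = df.rename(columns=rename)
    if "SEX" in df.columns:
        df = df.rename(columns={"SEX": "sex"})
    if "POP" in df.columns:
        df = df.rename(columns={"POP": "group"})
    keep = [c for c in LABEL_COLUMNS if c in df.columns] + list(rename.values())
    return df[keep]


def write_measurement_csv(table: pd.DataFrame, path) -> None:
    table.to_csv(path)
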