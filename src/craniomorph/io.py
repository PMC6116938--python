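"""Readers and writers for landmark configurations and meshes.

Canonical CSV dialect: columns ``id,name,kind,side,curve_id,surface_id,x,y,z``
(plus an optional ``curve_ordinal``), one row per landmark, UTF-8, ``.``
decimal separator. Missing points are rows with empty coordinate cells —
never numeric sentinels, whose magnitudes would silently corrupt Procrustes
fits.

The classic morphometrics TPS dialect (``LM3=<n>`` blocks of whitespace-
separated coordinate triplets with an optional ``ID=<specimen>`` footer) is
supported for complete configurations; the dialect has no missing-data
convention, so export of incomplete configurations is refused.

Meshes (PLY/OBJ triangles) are delegated to :mod:`trimesh`.
"""

from __future__ import annotations

import csv
from pathlib import Path

import numpy as np
import trimesh

from .landmarks import (
    LandmarkConfiguration,
    LandmarkDef,
    LandmarkKind,
    Side,
    Template,
)

CSV_COLUMNS = ["id", "name", "kind", "side", "curve_id", "curve_ordinal",
               "surface_id", "x", "y", "z"]


class FormatError(ValueError):
    """Raised on malformed landmark files."""


def read_landmark_csv(path: str | Path) -> LandmarkConfiguration:
    """Read one configuration from the canonical CSV dialect."""
    path = Path(path)
    defs: list[LandmarkDef] = []
    coords: list[list[float]] = []
    present: list[bool] = []
    seen_ids: set[int] = set()
    with path.open(newline="", encoding="utf-8") as fh:
        reader = csv.DictReader(fh)
        if reader.fieldnames is None or "id" not in reader.fieldnames:
            raise FormatError(f"{path}: missing header row with 'id' column")
        for row in reader:
            try:
                lid = int(row["id"])
            except (TypeError, ValueError):
                raise FormatError(f"{path}: non-integer id {row.get('id')!r}")
            if lid in seen_ids:
                raise FormatError(f"{path}: duplicate landmark id {lid}")
            seen_ids.add(lid)
            cells = [row.get(ax, "") or "" for ax in ("x", "y", "z")]
            if all(c.strip() == "" for c in cells):
                coords.append([np.nan] * 3)
                present.append(False)
            else:
                try:
                    coords.append([float(c) for c in cells])
                except ValueError:
                    raise FormatError(
                        f"{path}: non-numeric coordinate for id {lid}: {cells}"
                    )
                present.append(True)
            defs.append(LandmarkDef(
                id=lid,
                name=row.get("name", "") or f"lm{lid}",
                kind=LandmarkKind(row.get("kind") or "anatomical"),
                side=Side(row.get("side") or "midline"),
                curve_id=(row.get("curve_id") or None),
                curve_ordinal=(int(row["curve_ordinal"])
                               if row.get("curve_ordinal") else None),
                surface_id=(row.get("surface_id") or None),
            ))
    return LandmarkConfiguration(
        template=Template(tuple(defs)),
        coords=np.array(coords, dtype=float),
        present=np.array(present, dtype=bool),
        specimen_id=path.stem,
    )


def write_landmark_csv(config: LandmarkConfiguration, path: str | Path) -> None:
    """Write a configuration in the canonical CSV dialect.

    Output is bit-stable for identical inputs; coordinates use repr-precision
    so CSV round-trips are lossless.
    """
    path = Path(path)
    with path.open("w", newline="", encoding="utf-8") as fh:
        writer = csv.writer(fh)
        writer.writerow(CSV_COLUMNS)
        for d, xyz, p in zip(config.template, config.coords, config.present):
            cells = [format(v, ".17g") for v in xyz] if p else ["", "", ""]
            writer.writerow([
                d.id, d.name, d.kind.value, d.side.value,
                d.curve_id or "", d.curve_ordinal if d.curve_ordinal is not None else "",
                d.surface_id or "", *cells,
            ])


def read_tps_file(path: str | Path) -> list[LandmarkConfiguration]:
    """Read configurations from a classic TPS file (3D ``LM3=`` blocks).

    2D ``LM=`` blocks raise an unsupported-dimension error. Each block yields
    a complete configuration with all-anatomical landmark kinds.
    """
    path = Path(path)
    configs: list[LandmarkConfiguration] = []
    lines = path.read_text(encoding="utf-8").splitlines()
    i = 0
    block_no = 0
    while i < len(lines):
        line = lines[i].strip()
        i += 1
        if not line:
            continue
        upper = line.upper()
        if upper.startswith("LM3="):
            block_no += 1
            try:
                n = int(line.split("=", 1)[1])
            except ValueError:
                raise FormatError(f"{path}: bad LM3 count in {line!r}")
            rows: list[list[float]] = []
            while i < len(lines) and len(rows) < n:
                s = lines[i].strip()
                if s.upper().startswith(("LM3=", "LM=", "ID=", "IMAGE=", "SCALE=")):
                    break
                i += 1
                if not s:
                    continue
                parts = s.split()
                if len(parts) != 3:
                    raise FormatError(
                        f"{path}: expected 3 coordinates, got {s!r}"
                    )
                rows.append([float(p) for p in parts])
            if len(rows) != n:
                raise FormatError(
                    f"{path}: block {block_no} declares LM3={n} but has "
                    f"{len(rows)} coordinate rows"
                )
            specimen_id = f"{path.stem}_{block_no}"
            # optional footer lines
            while i < len(lines):
                s = lines[i].strip()
                if s.upper().startswith("ID="):
                    specimen_id = s.split("=", 1)[1].strip()
                    i += 1
                elif s.upper().startswith(("IMAGE=", "SCALE=")) or not s:
                    i += 1
                else:
                    break
            defs = tuple(
                LandmarkDef(id=k + 1, name=f"lm{k + 1}") for k in range(n)
            )
            configs.append(LandmarkConfiguration(
                template=Template(defs),
                coords=np.array(rows, dtype=float),
                specimen_id=specimen_id,
            ))
        elif upper.startswith("LM="):
            raise FormatError(
                f"{path}: 2D LM= blocks are not supported (3D LM3= required)"
            )
        elif upper.startswith(("ID=", "IMAGE=", "SCALE=")):
            continue
        else:
            raise FormatError(f"{path}: unexpected line {line!r}")
    return configs


def write_tps_file(configs: list[LandmarkConfiguration] | LandmarkConfiguration,
                   path: str | Path) -> None:
    """Write complete configurations as concatenated ``LM3=`` blocks."""
    if isinstance(configs, LandmarkConfiguration):
        configs = [configs]
    path = Path(path)
    out: list[str] = []
    for c in configs:
        if not c.is_complete:
            raise FormatError(
                "TPS dialect has no missing-data convention; configuration "
                f"{c.specimen_id!r} is incomplete"
            )
        out.append(f"LM3={c.n_landmarks}")
        for xyz in c.coords:
            out.append(" ".join(format(v, ".17g") for v in xyz))
        out.append(f"ID={c.specimen_id}")
    path.write_text("\n".join(out) + "\n", encoding="utf-8")


def read_mesh(path: str | Path) -> trimesh.Trimesh:
    """Load a PLY/OBJ triangle mesh (vertices in mm)."""
    path = Path(path)
    try:
        mesh = trimesh.load_mesh(path, process=False)
    except Exception as exc:  # trimesh raises various types on corrupt input
        raise FormatError(f"{path}: cannot read mesh ({exc})") from exc
    if not isinstance(mesh, trimesh.Trimesh) or len(mesh.faces) == 0:
        raise FormatError(f"{path}: not a triangle mesh")
    return mesh


def write_mesh(mesh: trimesh.Trimesh, path: str | Path) -> None:
    path = Path(path)
    mesh.export(path)
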