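"""Result writers: metadata-carrying CSV, legacy ASCII VTK, run manifests.

Every output directory gets exactly one ``manifest.yaml`` recording the
config hash, seed, software version and per-stage solver diagnostics;
re-running with the same config reproduces the CSVs byte-identically.
"""

from __future__ import annotations

import io as _io
from datetime import datetime, timezone
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from ._mac import MacGrid

__all__ = ["write_table", "read_table", "write_vtk_rectilinear",
           "write_manifest", "write_results"]


def write_table(df: pd.DataFrame, path, metadata: dict | None = None) -> None:
    """RFC-4180-style CSV preceded by a ``#``-commented metadata block."""
    path = Path(path)
    path.parent.mkdir(parents=True, exist_ok=True)
    buf = _io.StringIO()
    for k, v in (metadata or {}).items():
        buf.write(f"# {k}: {v}\n")
    df.to_csv(buf, index=False, lineterminator="\n", float_format="%.10g")
    path.write_text(buf.getvalue(), encoding="utf-8")


def read_table(path) -> tuple[pd.DataFrame, dict]:
    """Read a metadata-carrying CSV back; returns (frame, metadata)."""
    meta = {}
    with open(path, "r", encoding="utf-8") as fh:
        pos = fh.tell()
        while True:
            line = fh.readline()
            if line.startswith("#"):
                body = line[1:].strip()
                if ":" in body:
                    k, v = body.split(":", 1)
                    meta[k.strip()] = v.strip()
                pos = fh.tell()
            else:
                fh.seek(pos)
                break
        df = pd.read_csv(fh)
    return df, meta


def write_vtk_rectilinear(path, grid: MacGrid, cell_fields: dict,
                          title: str = "moabsim fields") -> None:
    """Legacy ASCII VTK rectilinear (structured) grid with cell data.

    ``cell_fields`` maps names to (nx, ny, nz) arrays; NaN is written as
    0 with a companion ``<name>_valid`` mask when present.
    """
    path = Path(path)
    path.parent.mkdir(parents=True, exist_ok=True)
    nx, ny, nz = grid.shape
    lines = ["# vtk DataFile Version 3.0", title[:255], "ASCII",
             "DATASET RECTILINEAR_GRID",
             f"DIMENSIONS {nx + 1} {ny + 1} {nz + 1}"]

    def coords(name, arr):
        lines.append(f"{name}_COORDINATES {arr.size} float")
        lines.append(" ".join(f"{v:.9g}" for v in arr))

    coords("X", grid.xf)
    coords("Y", grid.yf)
    coords("Z", grid.zf)
    lines.append(f"CELL_DATA {nx * ny * nz}")
    for name, field in cell_fields.items():
        field = np.asarray(field)
        if field.shape != (nx, ny, nz):
            raise ValueError(f"field {name!r} shape {field.shape} does not "
                             f"match grid {grid.shape}")
        isint = np.issubdtype(field.dtype, np.integer) or field.dtype == bool
        vtype = "int" if isint else "float"
        lines.append(f"SCALARS {name} {vtype} 1")
        lines.append("LOOKUP_TABLE default")
        flat = np.nan_to_num(field.astype(int if isint else float),
                             nan=0.0).ravel(order="F")
        fmt = "{:d}" if isint else "{:.9g}"
        for start in range(0, flat.size, 9):
            lines.append(" ".join(fmt.format(v) for v in flat[start:start + 9]))
    path.write_text("\n".join(lines) + "\n", encoding="utf-8")


def write_manifest(out_dir, config_hash: str, seed: int | None,
                   stages: dict, config: dict | None = None) -> Path:
    """One manifest per output directory."""
    from . import __version__
    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    manifest = {
        "software": "moabsim",
        "version": __version__,
        "config_hash": config_hash,
        "seed": seed,
        "stages": stages,
        "written_utc": datetime.now(timezone.utc).isoformat(timespec="seconds"),
    }
    if config is not None:
        manifest["config"] = config
    p = out_dir / "manifest.yaml"
    with open(p, "w", encoding="utf-8") as fh:
        yaml.safe_dump(manifest, fh, sort_keys=True)
    return p


def write_results(tables: dict, out_dir, metadata: dict | None = None,
                  fields: dict | None = None, grid: MacGrid | None = None,
                  seed: int | None = None, config_hash: str = "",
                  stages: dict | None = None) -> list:
    """Write a set of DataFrames (+ optional VTK fields) deterministically."""
    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    written = []
    for name in sorted(tables):
        p = out_dir / f"{name}.csv"
        write_table(tables[name], p, metadata)
        written.append(p)
    if fields:
        if grid is None:
            raise ValueError("fields given without a grid")
        p = out_dir / "fields.vtk"
        write_vtk_rectilinear(p, grid, fields)
        written.append(p)
    written.append(write_manifest(out_dir, config_hash, seed, stages or {}))
    return written
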