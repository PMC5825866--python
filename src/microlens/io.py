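"""File formats: TSV expression matrices, GMT gene sets, TIFF/JSON focal stacks.

Expression matrices travel as TSV with gene symbols in the first column and a
header row of sample labels. Gene sets use the standard GMT layout (set name,
description, tab-separated members). Focal stacks are five single-plane TIFF
files plus a JSON sidecar carrying z offsets, lens geometry, the background
annulus and the pixel scale.
"""
from __future__ import annotations

import json
import logging
import warnings
from pathlib import Path

import numpy as np
import pandas as pd
import tifffile

from .errors import InputError, ValidationError
from .matrix import ExpressionMatrix
from .optics import FocalStack

log = logging.getLogger("microlens")


# ---------------------------------------------------------------------------
# expression TSV
# ---------------------------------------------------------------------------

def read_expression_tsv(path: str | Path, unit: str = "rpm") -> ExpressionMatrix:
    """Parse a genes x samples TSV; errors name the offending line (1-based)."""
    path = Path(path)
    try:
        frame = pd.read_csv(path, sep="\t", index_col=0)
    except pd.errors.EmptyDataError as exc:
        raise InputError(f"{path}: empty file") from exc
    except pd.errors.ParserError as exc:
        raise InputError(f"{path}: malformed TSV ({exc})") from exc
    if frame.shape[1] == 0:
        raise InputError(f"{path}: no sample columns")
    if frame.index.has_duplicates:
        dup = frame.index[frame.index.duplicated()][0]
        line = int(np.nonzero(frame.index == dup)[0][1]) + 2  # +1 header, +1 one-based
        raise InputError(f"{path}:{line}: duplicate gene symbol {dup!r}")
    values = frame.to_numpy()
    if not np.issubdtype(values.dtype, np.number):
        bad = frame.columns[[not np.issubdtype(d, np.number) for d in frame.dtypes]][0]
        raise InputError(f"{path}: non-numeric values in column {bad!r}")
    if (values < 0).any():
        row = int(np.nonzero((values < 0).any(axis=1))[0][0]) + 2
        raise InputError(f"{path}:{row}: negative expression value")
    try:
        return ExpressionMatrix(frame, unit=unit)
    except ValidationError as exc:
        raise InputError(f"{path}: {exc}") from exc


def write_expression_tsv(matrix: ExpressionMatrix, path: str | Path) -> None:
    frame = matrix.data.copy()
    frame.index.name = frame.index.name or "gene"
    frame.to_csv(path, sep="\t", lineterminator="\n")


# ---------------------------------------------------------------------------
# GMT gene sets
# ---------------------------------------------------------------------------

def read_gmt(path: str | Path) -> dict[str, frozenset[str]]:
    """Parse a GMT file into an ordered name -> gene-set map.

    Duplicate members within a set are collapsed with a warning; duplicate set
    names are an error.
    """
    path = Path(path)
    sets: dict[str, frozenset[str]] = {}
    with open(path) as fh:
        for lineno, raw in enumerate(fh, start=1):
            line = raw.rstrip("\n")
            if not line.strip():
                continue
            fields = line.split("\t")
            if len(fields) < 3:
                raise InputError(f"{path}:{lineno}: GMT line needs name, description, >=1 member")
            name, members = fields[0], [m for m in fields[2:] if m]
            if name in sets:
                raise InputError(f"{path}:{lineno}: duplicate set name {name!r}")
            if len(set(members)) < len(members):
                log.warning("%s:%d: duplicate members in set %r collapsed", path, lineno, name)
            sets[name] = frozenset(members)
    if not sets:
        raise InputError(f"{path}: no gene sets")
    return sets


def write_gmt(sets: dict[str, frozenset[str]], path: str | Path, description: str = "na") -> None:
    with open(path, "w") as fh:
        for name, members in sets.items():
            fh.write("\t".join([name, description, *sorted(members)]) + "\n")


# ---------------------------------------------------------------------------
# focal stacks (TIFF planes + JSON sidecar)
# ---------------------------------------------------------------------------

def write_focal_stack(stack: FocalStack, out_dir: str | Path, stem: str = "stack") -> Path:
    """Write five single-plane TIFFs and a JSON sidecar; returns sidecar path."""
    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    plane_files = []
    for i, plane in enumerate(stack.planes):
        name = f"{stem}_z{i}.tif"
        data = plane if plane.dtype == np.uint8 else plane.astype(np.float32)
        tifffile.imwrite(out_dir / name, data)
        plane_files.append(name)
    sidecar = {
        "planes": plane_files,
        "z_offsets_um": [float(z) for z in stack.z_offsets],
        "lens_center": [float(c) for c in stack.lens_center],
        "lens_diameter_px": float(stack.lens_diameter),
        "background_region": [float(r) for r in stack.background_region],
        "pixel_scale_um_per_px": float(stack.pixel_scale),
    }
    sidecar_path = out_dir / f"{stem}.json"
    with open(sidecar_path, "w") as fh:
        json.dump(sidecar, fh, indent=2)
        fh.write("\n")
    return sidecar_path


def read_focal_stack(sidecar_path: str | Path) -> FocalStack:
    sidecar_path = Path(sidecar_path)
    try:
        with open(sidecar_path) as fh:
            meta = json.load(fh)
    except json.JSONDecodeError as exc:
        raise InputError(f"{sidecar_path}: invalid JSON sidecar ({exc})") from exc
    try:
        planes = np.stack(
            [tifffile.imread(sidecar_path.parent / name) for name in meta["planes"]]
        )
        return FocalStack(
            planes=planes,
            z_offsets=np.array(meta["z_offsets_um"], dtype=float),
            lens_center=tuple(meta["lens_center"]),
            lens_diameter=float(meta["lens_diameter_px"]),
            background_region=tuple(meta["background_region"]),
            pixel_scale=float(meta.get("pixel_scale_um_per_px", 1.0)),
        )
    except KeyError as exc:
        raise InputError(f"{sidecar_path}: sidecar missing field {exc}") from exc
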