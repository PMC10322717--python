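"""Readers and writers for the package's interchange formats.

CSV is the interchange format for tabular objects (area matrices, trajectories,
partitions); a compressed ``.npz`` container serves as the binary format for
area matrices. Image stacks are read from multipage TIFFs or globs of
PNG/TIFF frames, ordered by natural sort of the filename.
"""

from __future__ import annotations

import glob
import json
import re
from pathlib import Path

import numpy as np
import pandas as pd
import tifffile
import imageio.v3 as iio

from .core import AreaMatrix, ComponentPartition, FeatureTrajectory, PCABasis

__all__ = [
    "read_area_matrix",
    "write_area_matrix",
    "read_image_stack",
    "write_image_stack",
    "read_trajectory",
    "write_trajectory",
    "read_partition",
    "write_partition",
    "natural_sort_key",
]


def natural_sort_key(name: str) -> list:
    """Sort key splitting digit runs so frame_2 precedes frame_10."""
    return [int(tok) if tok.isdigit() else tok for tok in re.split(r"(\d+)", str(name))]


# ---------------------------------------------------------------- AreaMatrix


def write_area_matrix(am: AreaMatrix, path: str | Path, format: str = "csv") -> Path:
    """Write an AreaMatrix as CSV (header row of chrom_ids, NA on invalid
    frames) or as an npz binary container."""
    path = Path(path)
    if format == "csv":
        vals = am.values.astype(object).copy()
        vals[~am.valid_mask, :] = np.nan
        df = pd.DataFrame(vals.astype(float), columns=am.chrom_ids)
        # %.17g round-trips float64 exactly
        df.to_csv(path, index=False, na_rep="NA", float_format="%.17g")
    elif format in ("binary-container", "npz"):
        np.savez_compressed(
            path,
            values=am.values,
            rate=np.array([am.rate]),
            valid_mask=am.valid_mask,
            chrom_ids=am.chrom_ids,
        )
    else:
        raise ValueError(f"unknown format {format!r}")
    return path


def read_area_matrix(path: str | Path, format: str = "csv", rate: float = 25.0) -> AreaMatrix:
    """Read an AreaMatrix.

    CSV: first row is the header of chromatophore ids; cells that fail to
    parse ("NA", empty) invalidate their whole frame rather than becoming
    zeros. Negative areas raise a validation error naming the first offending
    row.
    """
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(path)
    if format in ("binary-container", "npz"):
        with np.load(path) as z:
            return AreaMatrix(
                z["values"],
                rate=float(z["rate"][0]),
                valid_mask=z["valid_mask"],
                chrom_ids=z["chrom_ids"],
            )
    if format != "csv":
        raise ValueError(f"unknown format {format!r}")
    try:
        df = pd.read_csv(path, na_values=["NA"], float_precision="round_trip")
    except Exception as exc:  # pragma: no cover - pandas error text varies
        raise ValueError(f"malformed area table {path}: {exc}") from exc
    try:
        chrom_ids = np.array([int(c) for c in df.columns])
    except ValueError as exc:
        raise ValueError(f"header row of {path} must contain integer chrom_ids") from exc
    values = df.to_numpy(dtype=float)
    bad = np.isnan(values)
    valid_mask = ~bad.any(axis=1)
    neg_rows = np.flatnonzero((values < 0).any(axis=1) & valid_mask)
    if neg_rows.size:
        raise ValueError(f"negative area at row {neg_rows[0]} of {path}")
    return AreaMatrix(values, rate=rate, valid_mask=valid_mask, chrom_ids=chrom_ids)


# --------------------------------------------------------------- image stacks


def _to_uint8(frame: np.ndarray) -> np.ndarray:
    """Rescale rule: 8-bit passthrough; 16-bit divided by 257 (full-range map);
    floats clipped to [0, 255]."""
    if frame.dtype == np.uint8:
        return frame
    if frame.dtype == np.uint16:
        return (frame.astype(np.float64) / 257.0).round().astype(np.uint8)
    return np.clip(np.asarray(frame, dtype=float), 0, 255).round().astype(np.uint8)


def read_image_stack(path_glob: str | Path) -> np.ndarray:
    """Read a (T, H, W) uint8 grayscale stack from a glob of frames or a
    single multipage TIFF. Frames are ordered by natural sort of filename."""
    pattern = str(path_glob)
    files = sorted(glob.glob(pattern), key=natural_sort_key)
    if not files and Path(pattern).exists():
        files = [pattern]
    if not files:
        raise FileNotFoundError(f"no input: pattern {pattern!r} matched 0 files")
    frames: list[np.ndarray] = []
    names: list[str] = []
    for f in files:
        if f.lower().endswith((".tif", ".tiff")):
            arr = tifffile.imread(f)
        else:
            arr = iio.imread(f)
        if arr.ndim == 3 and arr.shape[-1] in (3, 4):  # RGB(A) -> gray
            arr = arr[..., :3].mean(axis=-1)
        if arr.ndim == 2:
            arr = arr[None]
        for page in arr:
            frames.append(_to_uint8(np.asarray(page)))
            names.append(f)
    shapes = {fr.shape for fr in frames}
    if len(shapes) > 1:
        ref = frames[0].shape
        bad = next(n for fr, n in zip(frames, names) if fr.shape != ref)
        raise ValueError(f"mixed frame dimensions: {bad} has shape != {ref}")
    return np.stack(frames)


def write_image_stack(stack: np.ndarray, path: str | Path) -> Path:
    """Write a (T, H, W) stack as a multipage TIFF."""
    path = Path(path)
    tifffile.imwrite(path, np.asarray(stack, dtype=np.uint8), photometric="minisblack")
    return path


# ---------------------------------------------------------------- trajectories


def write_trajectory(traj: FeatureTrajectory, path: str | Path) -> Path:
    path = Path(path)
    df = pd.DataFrame(traj.coords, columns=[f"d{i}" for i in range(traj.n_dims)])
    df.to_csv(path, index=False)
    meta = {"rate": traj.rate, "label": traj.label}
    if traj.basis is not None:
        meta["explained_variance_ratio"] = traj.basis.explained_variance_ratio.tolist()
        np.savez_compressed(
            path.with_suffix(".basis.npz"),
            components=traj.basis.components,
            mean=traj.basis.mean,
            explained_variance_ratio=traj.basis.explained_variance_ratio,
        )
    path.with_suffix(".meta.json").write_text(json.dumps(meta))
    return path


def read_trajectory(path: str | Path) -> FeatureTrajectory:
    path = Path(path)
    coords = pd.read_csv(path).to_numpy(dtype=float)
    meta_path = path.with_suffix(".meta.json")
    rate, label, basis = 25.0, "", None
    if meta_path.exists():
        meta = json.loads(meta_path.read_text())
        rate = float(meta.get("rate", 25.0))
        label = meta.get("label", "")
    basis_path = path.with_suffix(".basis.npz")
    if basis_path.exists():
        with np.load(basis_path) as z:
            basis = PCABasis(z["components"], z["explained_variance_ratio"], z["mean"])
    return FeatureTrajectory(coords, rate=rate, basis=basis, label=label)


# ------------------------------------------------------------------ partitions


def write_partition(part: ComponentPartition, path: str | Path) -> Path:
    path = Path(path)
    pd.DataFrame({"chrom_id": part.chrom_ids, "label": part.labels}).to_csv(
        path, index=False
    )
    path.with_suffix(".params.json").write_text(
        json.dumps({"params": part.params, "source": part.source})
    )
    return path


def read_partition(path: str | Path) -> ComponentPartition:
    path = Path(path)
    df = pd.read_csv(path)
    params, source = {}, ""
    pjson = path.with_suffix(".params.json")
    if pjson.exists():
        meta = json.loads(pjson.read_text())
        params, source = meta.get("params", {}), meta.get("source", "")
    return ComponentPartition(
        df["label"].to_numpy(int), params=params, source=source,
        chrom_ids=df["chrom_id"].to_numpy(int),
    )
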