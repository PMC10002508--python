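"""Reading and writing the package's file formats.

Images travel as single- or multi-frame 16-bit TIFF (via tifffile); tabular
results as tidy CSV with a schema-version header comment; scene descriptions
as JSON sidecars; traces as two-column CSV of (row, col) pixel coordinates.
"""

from __future__ import annotations

import json
from pathlib import Path

import numpy as np
import pandas as pd
import tifffile

from .imaging import ParticleSet
from .synthetic import GroundTruth, SceneSpec
from .trace import AxonTrace

SCHEMA_VERSION = "mitospread-v1"

__all__ = [
    "write_image", "read_image", "write_scene", "read_trace_csv",
    "write_trace_csv", "write_particles_csv", "read_particles_csv",
    "read_positions_csv",
]


def write_image(path, image: np.ndarray) -> None:
    """Write a single- or multi-frame image as 16-bit unsigned TIFF."""
    tifffile.imwrite(str(path), np.asarray(image, dtype=np.uint16))


def read_image(path) -> np.ndarray:
    return tifffile.imread(str(path))


def write_scene(out_dir, image: np.ndarray, truth: GroundTruth,
                spec: SceneSpec, stem: str = "scene") -> dict:
    """Write an image, its ground-truth CSV and a SceneSpec JSON sidecar.

    The ground truth has one row per particle: position_um, row_px, col_px,
    area_um2. Returns the mapping of written paths.
    """
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    paths = {
        "image": out / f"{stem}.tif",
        "truth": out / f"{stem}_truth.csv",
        "spec": out / f"{stem}_spec.json",
    }
    write_image(paths["image"], image)
    df = pd.DataFrame({
        "position_um": truth.positions_um,
        "row_px": truth.centroids_px[:, 0],
        "col_px": truth.centroids_px[:, 1],
        "area_um2": truth.areas_um2,
    })
    _write_csv(paths["truth"], df)
    meta = spec.to_dict()
    meta["axon_length_um"] = truth.axon_length_um
    meta["schema"] = SCHEMA_VERSION
    paths["spec"].write_text(json.dumps(meta, indent=2))
    return {k: str(v) for k, v in paths.items()}


def _write_csv(path, df: pd.DataFrame) -> None:
    with open(path, "w") as fh:
        fh.write(f"# schema: {SCHEMA_VERSION}\n")
        df.to_csv(fh, index=False)


def _read_csv(path) -> pd.DataFrame:
    return pd.read_csv(path, comment="#")


def write_trace_csv(path, trace: AxonTrace) -> None:
    _write_csv(path, pd.DataFrame(trace.control_points_px,
                                  columns=["row_px", "col_px"]))


def read_trace_csv(path, pixel_size_um: float = 1.0) -> AxonTrace:
    """Load a trace from a two-column (row, col) pixel-coordinate CSV."""
    df = _read_csv(path)
    return AxonTrace(df[["row_px", "col_px"]].to_numpy(dtype=float),
                     pixel_size_um)


def write_particles_csv(path, particles: ParticleSet) -> None:
    df = pd.DataFrame({
        "row_px": particles.centroids_px[:, 0],
        "col_px": particles.centroids_px[:, 1],
        "area_um2": particles.areas_um2,
    })
    if particles.positions_um is not None:
        df["position_um"] = particles.positions_um
    _write_csv(path, df)


def read_particles_csv(path) -> ParticleSet:
    df = _read_csv(path)
    return ParticleSet(
        centroids_px=df[["row_px", "col_px"]].to_numpy(dtype=float),
        areas_um2=df["area_um2"].to_numpy(dtype=float),
        positions_um=(df["position_um"].to_numpy(dtype=float)
                      if "position_um" in df else None))


def read_positions_csv(path) -> np.ndarray:
    """Load sorted 1-D positions from a one-column CSV (position_um)."""
    df = _read_csv(path)
    col = "position_um" if "position_um" in df else df.columns[0]
    return np.sort(df[col].to_numpy(dtype=float))
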