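"""Table and image I/O.

All tabular interchange uses TSV with a fixed schema so that simulated and
image-derived colony tables are indistinguishable downstream.  Grid rows and
columns are 0-based in memory and 1-based on disk (stated in the header
comment of every written file).  Stacks travel as multi-page TIFF, channel
first, with voxel sizes in a TSV sidecar.
"""

from __future__ import annotations

import hashlib
from pathlib import Path

import numpy as np
import pandas as pd
import tifffile

__all__ = [
    "read_colony_table",
    "write_colony_table",
    "read_table",
    "write_table",
    "read_stack",
    "write_stack",
    "sha256_of",
]

_GRID_COLS = ("row", "col")
_HEADER_NOTE = "# rows/cols are 1-based in this file, 0-based in memory\n"


def write_colony_table(table: pd.DataFrame, path: str | Path) -> Path:
    """Write a colony/layout table as TSV, shifting grid indices to 1-based."""
    path = Path(path)
    out = table.copy()
    for col in _GRID_COLS:
        if col in out.columns:
            out[col] = out[col] + 1
    with open(path, "w") as fh:
        fh.write(_HEADER_NOTE)
        out.to_csv(fh, sep="\t", index=False)
    return path


def read_colony_table(path: str | Path) -> pd.DataFrame:
    """Read a TSV colony/layout table back to 0-based grid indices."""
    df = pd.read_csv(path, sep="\t", comment="#")
    for col in _GRID_COLS:
        if col in df.columns:
            df[col] = df[col] - 1
    return df


def write_table(table: pd.DataFrame, path: str | Path) -> Path:
    path = Path(path)
    table.to_csv(path, sep="\t", index=False)
    return path


def read_table(path: str | Path) -> pd.DataFrame:
    return pd.read_csv(path, sep="\t")


def write_stack(
    stack: np.ndarray,
    path: str | Path,
    voxel_xy_nm: float,
    voxel_z_nm: float,
) -> tuple[Path, Path]:
    """Write a (channels, z, y, x) stack as multi-page TIFF plus a voxel-size sidecar."""
    path = Path(path)
    tifffile.imwrite(path, np.asarray(stack, dtype=np.float32))
    sidecar = path.with_suffix(".voxels.tsv")
    pd.DataFrame(
        {"axis": ["x", "y", "z"], "nm": [voxel_xy_nm, voxel_xy_nm, voxel_z_nm]}
    ).to_csv(sidecar, sep="\t", index=False)
    return path, sidecar


def read_stack(path: str | Path) -> tuple[np.ndarray, float, float]:
    """Read a stack and its voxel sizes; returns (array, voxel_xy_nm, voxel_z_nm)."""
    path = Path(path)
    arr = tifffile.imread(path)
    sidecar = path.with_suffix(".voxels.tsv")
    if sidecar.exists():
        sizes = pd.read_csv(sidecar, sep="\t").set_index("axis")["nm"]
        return np.asarray(arr, dtype=float), float(sizes["x"]), float(sizes["z"])
    return np.asarray(arr, dtype=float), float("nan"), float("nan")


def sha256_of(path: str | Path) -> str:
    h = hashlib.sha256()
    with open(path, "rb") as fh:
        for chunk in iter(lambda: fh.read(1 << 16), b""):
            h.update(chunk)
    return h.hexdigest()
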