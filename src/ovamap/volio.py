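"""Volume and table I/O, and the anatomical axis frame.

MicroCT reconstructions arrive either as a multi-page TIFF or as a directory
of equally sized numbered 2D sections (TIFF/PNG/JPG).  Volumes are held as a
:class:`VoxelVolume`: a 3D intensity array with an isotropic voxel size in
micrometres and an :class:`AxisFrame` naming the anatomical role of each
array axis.  Isotropy (cubic voxels) is a hard precondition of everything
downstream — it is what makes 3D morphometry on these stacks meaningful.

Conventions (fixed, documented, unambiguous):

* array axis order is (stack, in-plane-1, in-plane-2);
* the stack axis runs dorsal->ventral, in-plane-1 anterior->posterior,
  in-plane-2 medial->lateral (orientation flags in :class:`AxisFrame` say
  which end of each axis is dorsal / anterior / medial);
* voxel indices are 0-based and a voxel's physical coordinate (um) is the
  coordinate of its centre, origin at the volume corner: ``x_um = index *
  voxel_size``.

JPG is accepted on input (reconstructed stacks are commonly exported that
way) but all outputs are lossless: TIFF for volumes, CSV/JSON for tables and
reports.
"""

from __future__ import annotations

import os
import re
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Sequence

import imageio.v3 as iio
import numpy as np
import pandas as pd
import tifffile

from .rubric import STAGES

__all__ = [
    "AxisFrame",
    "VoxelVolume",
    "read_stack",
    "write_stack",
    "read_follicle_table",
    "write_follicle_table",
    "FOLLICLE_TABLE_COLUMNS",
]

_SLICE_EXTENSIONS = {".tif", ".tiff", ".png", ".jpg", ".jpeg"}


@dataclass(frozen=True)
class AxisFrame:
    """Mapping from array axes to anatomical axes.

    ``stack_axis`` is the dorsal-ventral axis, ``ap_axis`` the
    anterior-posterior axis and ``ml_axis`` the medial-lateral axis; the
    three must be a permutation of (0, 1, 2).  The boolean flags state which
    *end* (low index or high index) of each axis is dorsal / anterior /
    medial.
    """

    stack_axis: int = 0
    ap_axis: int = 1
    ml_axis: int = 2
    dorsal_low: bool = True
    anterior_low: bool = True
    medial_low: bool = True

    def __post_init__(self) -> None:
        if sorted((self.stack_axis, self.ap_axis, self.ml_axis)) != [0, 1, 2]:
            raise ValueError(
                "stack_axis, ap_axis and ml_axis must be a permutation of 0,1,2"
            )

    def to_dict(self) -> dict:
        return {
            "stack_axis": self.stack_axis,
            "ap_axis": self.ap_axis,
            "ml_axis": self.ml_axis,
            "dorsal_low": self.dorsal_low,
            "anterior_low": self.anterior_low,
            "medial_low": self.medial_low,
        }

    @classmethod
    def from_dict(cls, d: dict) -> "AxisFrame":
        return cls(**{k: d[k] for k in (
            "stack_axis", "ap_axis", "ml_axis",
            "dorsal_low", "anterior_low", "medial_low") if k in d})


@dataclass
class VoxelVolume:
    """A 3D grayscale image with isotropic voxel size (um) and axis frame."""

    data: np.ndarray
    voxel_size: float
    frame: AxisFrame = field(default_factory=AxisFrame)

    def __post_init__(self) -> None:
        self.data = np.asarray(self.data)
        if self.data.ndim != 3:
            raise ValueError(f"volume must be 3D, got shape {self.data.shape}")
        if not self.voxel_size > 0:
            raise ValueError("voxel_size must be positive (um)")

    @property
    def shape(self) -> tuple[int, int, int]:
        return self.data.shape  # type: ignore[return-value]


def _numeric_key(name: str):
    """Sort key putting numbered files in numeric order (slice_2 < slice_10)."""
    parts = re.split(r"(\d+)", name)
    return [int(p) if p.isdigit() else p for p in parts]


def read_stack(
    path: str | os.PathLike,
    voxel_size: float,
    frame: AxisFrame | None = None,
) -> VoxelVolume:
    """Read a volume from a multi-page TIFF or a directory of 2D sections.

    Directory slices are stacked in (numeric-aware) filename order along the
    stack axis.  Bit depth is preserved.  Raises ``ValueError`` on an empty
    directory or on slices of inconsistent shape (the offending file is
    named).
    """
    frame = frame or AxisFrame()
    p = Path(path)
    if p.is_dir():
        files = sorted(
            (f for f in p.iterdir() if f.suffix.lower() in _SLICE_EXTENSIONS),
            key=lambda f: _numeric_key(f.name),
        )
        if not files:
            raise ValueError(f"no image slices found in directory {p}")
        slices = []
        shape0 = None
        for f in files:
            img = iio.imread(f)
            if img.ndim == 3:  # RGB(A) -> luminance-free channel collapse
                img = img[..., 0] if img.shape[-1] <= 4 else img
            if shape0 is None:
                shape0 = img.shape
            elif img.shape != shape0:
                raise ValueError(
                    f"slice shape mismatch: {f.name} has shape {img.shape}, "
                    f"expected {shape0} (from {files[0].name})"
                )
            slices.append(img)
        data = np.stack(slices, axis=0)
    elif p.is_file():
        data = tifffile.imread(p)
        if data.ndim == 2:
            data = data[None]
    else:
        raise ValueError(f"no such file or directory: {p}")
    return VoxelVolume(data=data, voxel_size=voxel_size, frame=frame)


def write_stack(vol: VoxelVolume | np.ndarray, path: str | os.PathLike,
                voxel_size: float | None = None) -> None:
    """Write a volume as a multi-page TIFF (lossless; other formats refused).

    16-bit data is preserved.  Raises ``ValueError`` for empty volumes and
    for lossy/non-TIFF output extensions (labels written through JPG would
    be silently corrupted).
    """
    data = vol.data if isinstance(vol, VoxelVolume) else np.asarray(vol)
    if data.size == 0:
        raise ValueError("refusing to write an empty volume")
    p = Path(path)
    if p.suffix.lower() not in (".tif", ".tiff"):
        raise ValueError(
            f"volumes are written as TIFF only (lossless); got {p.suffix!r}"
        )
    p.parent.mkdir(parents=True, exist_ok=True)
    tifffile.imwrite(p, data, photometric="minisblack")


#: Mandatory columns of the follicle table, in canonical order.
FOLLICLE_TABLE_COLUMNS = [
    "id", "stage", "x_um", "y_um", "z_um", "diameter_um",
    "n_antra", "has_zp", "sector_true",
]

_VALID_STAGES = set(STAGES) | {"unclassified", ""}


def write_follicle_table(records: pd.DataFrame | Iterable[dict],
                         path: str | os.PathLike,
                         header_comment: str | None = None) -> None:
    """Write follicle records to CSV (header always present, even if empty)."""
    df = records if isinstance(records, pd.DataFrame) else pd.DataFrame(list(records))
    if df.empty and not len(df.columns):
        df = pd.DataFrame(columns=FOLLICLE_TABLE_COLUMNS)
    p = Path(path)
    p.parent.mkdir(parents=True, exist_ok=True)
    with open(p, "w") as fh:
        if header_comment:
            fh.write(f"# {header_comment}\n")
        df.to_csv(fh, index=False)


def read_follicle_table(path: str | os.PathLike,
                        required: Sequence[str] | None = None) -> pd.DataFrame:
    """Read a follicle CSV, validating mandatory columns and stage labels."""
    df = pd.read_csv(path, comment="#")
    required = list(required) if required is not None else ["id", "stage"]
    missing = [c for c in required if c not in df.columns]
    if missing:
        raise ValueError(f"follicle table {path} is missing columns: {missing}")
    if "stage" in df.columns and len(df):
        bad = set(df["stage"].astype(str).fillna("")) - _VALID_STAGES
        if bad:
            raise ValueError(f"unknown stage labels in {path}: {sorted(bad)}")
    return df
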