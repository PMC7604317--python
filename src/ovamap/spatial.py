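"""Virtual sector partition of the ovary and follicle-to-sector assignment.

The organ is split into two halves along the dorsal-ventral (stack) axis and
each half into four equal quadrants by the anterior-posterior and
medial-lateral midplanes of the organ bounding box, giving eight sectors
D-I..D-IV (dorsal) and V-I..V-IV (ventral).  Quadrants I and IV lie on the
anterior side, II and III on the posterior side; I/II are medial, IV/III
lateral (the medial-lateral reading of the remaining in-plane axis is a
labeling convention).

A follicle is attributed to the sector holding strictly more than half of
its voxel volume; when no sector reaches a majority (large follicles
straddling midplanes) the sector with maximal overlap is used and the
assignment is flagged.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .rubric import STAGES
from .volio import AxisFrame

__all__ = [
    "SECTOR_LABELS",
    "DORSAL_SECTORS",
    "VENTRAL_SECTORS",
    "ANTERIOR_SECTORS",
    "POSTERIOR_SECTORS",
    "SectorPartition",
    "build_sector_partition",
    "assign_sector",
    "sector_of_points",
    "tabulate_counts",
    "sector_totals",
    "half_totals",
]

#: Canonical sector order; also the tie-break order for assignments.
SECTOR_LABELS = ("D-I", "D-II", "D-III", "D-IV", "V-I", "V-II", "V-III", "V-IV")

DORSAL_SECTORS = ("D-I", "D-II", "D-III", "D-IV")
VENTRAL_SECTORS = ("V-I", "V-II", "V-III", "V-IV")
#: Quadrants I and IV sit on the anterior side in both halves.
ANTERIOR_SECTORS = ("D-I", "D-IV", "V-I", "V-IV")
POSTERIOR_SECTORS = ("D-II", "D-III", "V-II", "V-III")
_MEDIAL_QUADRANTS = ("I", "II")  # quadrants I/II medial, III/IV lateral


def _sector_label(dorsal: bool, anterior: bool, medial: bool) -> str:
    half = "D" if dorsal else "V"
    if anterior:
        quadrant = "I" if medial else "IV"
    else:
        quadrant = "II" if medial else "III"
    return f"{half}-{quadrant}"


#: label index (1..8 into SECTOR_LABELS) for each (dorsal, anterior, medial).
_SIDE_TO_INDEX = np.zeros((2, 2, 2), dtype=np.uint8)
for _d in (0, 1):
    for _a in (0, 1):
        for _m in (0, 1):
            _SIDE_TO_INDEX[_d, _a, _m] = (
                SECTOR_LABELS.index(_sector_label(bool(_d), bool(_a), bool(_m))) + 1
            )


@dataclass
class SectorPartition:
    """Eight-sector geometry over an organ bounding box.

    ``label_volume`` holds 1..8 (index into :data:`SECTOR_LABELS`) inside
    the organ bounding box and 0 outside it.  ``midplanes_um`` are the three
    splitting planes in micrometres (voxel-centre convention), in array-axis
    order.
    """

    label_volume: np.ndarray
    midplanes_um: tuple[float, float, float]
    frame: AxisFrame
    voxel_size: float

    @property
    def labels(self) -> tuple[str, ...]:
        return SECTOR_LABELS

    def label_name(self, index: int) -> str:
        return SECTOR_LABELS[index - 1]


def _sides_from_coords(coords: np.ndarray, mid: float, low_flag: bool) -> np.ndarray:
    """True where the coordinate is on the flagged anatomical side.

    Values exactly on the midplane go to the lower-index side.
    """
    on_low = coords <= mid
    return on_low if low_flag else ~on_low


def build_sector_partition(
    organ_mask: np.ndarray,
    frame: AxisFrame | None = None,
    voxel_size: float = 1.0,
    mode: str = "bbox",
) -> SectorPartition:
    """Partition the organ bounding box into the eight anatomical sectors.

    Parameters
    ----------
    organ_mask
        Non-empty binary organ mask.
    frame
        Anatomical axis frame; defaults to the canonical frame.
    voxel_size
        Isotropic voxel size in um (used only to express midplanes in um).
    mode
        ``"bbox"`` (default) splits at the centres of the organ bounding
        box; ``"centroid"`` splits at the organ mask centroid instead.

    Raises
    ------
    ValueError
        If the mask is empty or degenerate (flat along any axis).
    """
    frame = frame or AxisFrame()
    organ_mask = np.asarray(organ_mask, dtype=bool)
    if organ_mask.ndim != 3:
        raise ValueError("organ mask must be 3D")
    idx = np.nonzero(organ_mask)
    if idx[0].size == 0:
        raise ValueError("organ mask is empty")
    lo = [int(ax.min()) for ax in idx]
    hi = [int(ax.max()) for ax in idx]
    if any(h == l for l, h in zip(lo, hi)):
        raise ValueError(f"degenerate organ mask: flat along an axis (bbox {lo}..{hi})")
    if mode == "bbox":
        mids = [(l + h) / 2.0 for l, h in zip(lo, hi)]
    elif mode == "centroid":
        mids = [float(ax.mean()) for ax in idx]
    else:
        raise ValueError(f"unknown partition mode {mode!r}")

    label = np.zeros(organ_mask.shape, dtype=np.uint8)
    ax_coords = [
        np.arange(organ_mask.shape[a], dtype=float).reshape(
            [-1 if i == a else 1 for i in range(3)]
        )
        for a in range(3)
    ]
    dorsal = _sides_from_coords(ax_coords[frame.stack_axis],
                                mids[frame.stack_axis], frame.dorsal_low)
    anterior = _sides_from_coords(ax_coords[frame.ap_axis],
                                  mids[frame.ap_axis], frame.anterior_low)
    medial = _sides_from_coords(ax_coords[frame.ml_axis],
                                mids[frame.ml_axis], frame.medial_low)
    d, a, m = np.broadcast_arrays(dorsal, anterior, medial)
    full = _SIDE_TO_INDEX[d.astype(int), a.astype(int), m.astype(int)]
    box = tuple(slice(l, h + 1) for l, h in zip(lo, hi))
    label[box] = full[box]
    midplanes_um = tuple(m_ * voxel_size for m_ in mids)
    return SectorPartition(label_volume=label, midplanes_um=midplanes_um,
                           frame=frame, voxel_size=voxel_size)


def sector_of_points(points_um: np.ndarray,
                     midplanes_um: tuple[float, float, float],
                     frame: AxisFrame | None = None) -> np.ndarray:
    """Vectorised sector labels for point coordinates (um, array-axis order).

    Used by the phantom generator, where follicle centres are known
    analytically.  Points exactly on a midplane go to the lower-index side,
    matching the voxel rule.
    """
    frame = frame or AxisFrame()
    pts = np.atleast_2d(np.asarray(points_um, dtype=float))
    dorsal = _sides_from_coords(pts[:, frame.stack_axis],
                                midplanes_um[frame.stack_axis], frame.dorsal_low)
    anterior = _sides_from_coords(pts[:, frame.ap_axis],
                                  midplanes_um[frame.ap_axis], frame.anterior_low)
    medial = _sides_from_coords(pts[:, frame.ml_axis],
                                midplanes_um[frame.ml_axis], frame.medial_low)
    idx = _SIDE_TO_INDEX[dorsal.astype(int), anterior.astype(int),
                         medial.astype(int)]
    return np.array([SECTOR_LABELS[i - 1] for i in idx])


def assign_sector(region_mask: np.ndarray,
                  partition: SectorPartition) -> tuple[str, bool]:
    """Attribute a region to the sector holding >50% of its voxels.

    Returns ``(sector, majority_flag)``.  When no sector holds a strict
    majority, the sector with maximal overlap wins (ties broken in
    :data:`SECTOR_LABELS` order) and the flag is False.
    """
    region_mask = np.asarray(region_mask, dtype=bool)
    total = int(region_mask.sum())
    if total == 0:
        raise ValueError("cannot assign an empty region to a sector")
    lab = partition.label_volume[region_mask]
    counts = np.bincount(lab, minlength=9)[1:]  # drop label 0 (outside bbox)
    best = int(np.argmax(counts))  # argmax takes the first (lowest) index on ties
    majority = counts[best] * 2 > total
    return SECTOR_LABELS[best], bool(majority)


_STAGE_ORDER = [s for s in STAGES] + ["unclassified"]


def tabulate_counts(records: pd.DataFrame,
                    ovary_ids=None,
                    stages=None) -> pd.DataFrame:
    """Cross-tabulate follicle records into an ovary x sector x stage table.

    ``records`` needs columns ``ovary``, ``sector`` and ``stage``.  The
    result has one row per ovary and a (sector, stage) column MultiIndex
    covering the full grid (absent combinations are zero), so marginal sums
    always conserve the total record count.
    """
    if ovary_ids is None:
        ovary_ids = sorted(records["ovary"].unique()) if len(records) else []
    if stages is None:
        present = set(records["stage"]) if len(records) else set()
        stages = [s for s in _STAGE_ORDER if s in present] or ["T4"]
    cols = pd.MultiIndex.from_product([SECTOR_LABELS, stages],
                                      names=["sector", "stage"])
    table = pd.DataFrame(0, index=pd.Index(ovary_ids, name="ovary"),
                         columns=cols, dtype=int)
    if len(records):
        grouped = records.groupby(["ovary", "sector", "stage"]).size()
        for (ov, sec, st), n in grouped.items():
            if (sec, st) in table.columns and ov in table.index:
                table.loc[ov, (sec, st)] = n
    return table


def sector_totals(table: pd.DataFrame) -> pd.DataFrame:
    """Per-ovary total counts in each sector (summed over stages)."""
    return table.T.groupby(level="sector").sum().T[list(SECTOR_LABELS)]


def half_totals(table: pd.DataFrame, axis: str) -> pd.DataFrame:
    """Per-ovary totals in the two halves along ``"ap"`` or ``"dv"``.

    Anterior = quadrants I and IV of both halves; dorsal = the D sectors.
    """
    tot = sector_totals(table)
    if axis == "ap":
        a = tot[list(ANTERIOR_SECTORS)].sum(axis=1)
        b = tot[list(POSTERIOR_SECTORS)].sum(axis=1)
        names = ("anterior", "posterior")
    elif axis == "dv":
        a = tot[list(DORSAL_SECTORS)].sum(axis=1)
        b = tot[list(VENTRAL_SECTORS)].sum(axis=1)
        names = ("dorsal", "ventral")
    else:
        raise ValueError("axis must be 'ap' or 'dv'")
    return pd.DataFrame({names[0]: a, names[1]: b})
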