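"""Digital ovary phantom: contrast-microCT-like volumes with exact ground truth.

The phantom emulates the image statistics a contrast-enhanced microCT scan
of an adult mouse ovary presents to the analysis pipeline: an ellipsoidal
organ with a brighter cortex shell and dimmer medulla core, quasi-spherical
follicles of stages T1-T8 and corpora lutea with stage-dependent internal
structure (granulosa, antral cavities, zona pellucida ring, oocyte with a
darker nucleus), dark tubular vessels (a ~150 um hilum trunk and ~35 um
medulla branches) and additive Gaussian noise.  Every follicle is known
analytically (:class:`TrueFollicle`), and the rendered label volume gives a
voxel-exact ground truth for segmentation and staging tests.

Placement follows the biological null model the downstream statistics
assume: follicle centres are uniform over the admissible region of the
organ (early stages restricted to the cortex shell, where recruitment
happens), with hard non-overlap.  A ``sector_biased`` mode multiplies the
placement density in one chosen sector, providing a controlled alternative
for power studies; ``bias_factor=1`` reproduces the homogeneous mode
bit-for-bit at equal seed because both run the same acceptance loop.

Stage diameters are drawn from the staging rubric's Normal(mean, SD),
truncated at +/-2 SD so the phantom's ground truth stays inside each
stage's diameter support.  Corpora lutea, for which no printed size
statistics exist, default to Uniform(280, 450) um — an explicit assumption,
not a measured value.
"""

from __future__ import annotations

import dataclasses
import json
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from .rubric import DEFAULT_RUBRIC, StageRubric
from .spatial import SECTOR_LABELS, sector_of_points
from .volio import AxisFrame, VoxelVolume, write_follicle_table, write_stack

__all__ = [
    "PhantomIntensities",
    "PhantomSpec",
    "TrueFollicle",
    "GroundTruth",
    "VesselSpec",
    "PackingError",
    "sample_follicle_population",
    "render_follicle",
    "build_phantom",
    "add_noise",
    "write_phantom",
]


class PackingError(RuntimeError):
    """Raised when a follicle cannot be placed without overlap."""


#: Nominal diameters (um) for the stages the rubric does not cover.  T1-T3
#: are below the microCT detection limit; they exist in the phantom only so
#: that volumes can contain structures the pipeline is *not* expected to
#: find.  CL sizes are an assumption (see module docstring).
_SMALL_STAGE_DIAMETERS = {"T1": (14.0, 1.5), "T2": (20.0, 2.0), "T3": (38.0, 4.0)}

#: Stages whose centres are restricted to the cortex shell (recruitment
#: happens in the cortex; antral stages and CL may sit anywhere).
_CORTEX_STAGES = {"T1", "T2", "T3", "T4", "T5"}

_PLACEMENT_ORDER = ["CL", "T8", "T7", "T6", "T5", "T4", "T3", "T2", "T1"]


@dataclass(frozen=True)
class PhantomIntensities:
    """8-bit rendering intensities.

    The ordering mirrors the radiopacity contrast the iodine stain
    produces: granulosa brightest, antral fluid and vessels darkest, the
    zona pellucida a thin dark ring, T4 follicles at globally reduced
    contrast.  Exact values are arbitrary and configurable.
    """

    background: int = 0
    stroma: int = 110
    cortex: int = 130
    granulosa: int = 190
    oocyte: int = 150
    nucleus: int = 90
    antrum: int = 60
    zp: int = 70
    vessel: int = 50
    cl: int = 160
    t4_contrast: float = 0.6
    t123_contrast: float = 0.7


@dataclass(frozen=True)
class VesselSpec:
    """A tubular vessel: polyline path (points in um, array-axis order) + diameter."""

    path: tuple[tuple[float, float, float], ...]
    diameter: float


@dataclass(frozen=True)
class PhantomSpec:
    """Full parameterisation of one phantom ovary.

    ``organ_semi_axes`` are the ellipsoid semi-axes in um, in array-axis
    order (stack, in-plane-1, in-plane-2).  ``per_stage_counts`` requests
    follicles per stage; the defaults reproduce a realistic adult ovary
    (334 detectable structures, T5/T6 most numerous, T8 scarcest).
    ``vessel_specs=None`` asks for the default vasculature (one 150 um
    hilum trunk plus 35 um medulla branches); pass ``()`` for no vessels.
    """

    organ_semi_axes: tuple[float, float, float] = (1250.0, 1000.0, 750.0)
    voxel_size: float = 1.5
    per_stage_counts: dict[str, int] = field(
        default_factory=lambda: {
            "T4": 64, "T5": 96, "T6": 90, "T7": 58, "T8": 16, "CL": 10,
        }
    )
    placement_mode: str = "homogeneous"
    bias_sector: str | None = None
    bias_factor: float = 1.0
    noise_sd: float = 0.0
    seed: int = 0
    vessel_specs: tuple[VesselSpec, ...] | None = None
    rubric: StageRubric = field(default_factory=lambda: DEFAULT_RUBRIC)
    cl_diameter_range: tuple[float, float] = (280.0, 450.0)
    cortex_fraction: float = 0.25
    min_gap_um: float | None = None  # default: one voxel
    max_attempts: int = 5000
    intensities: PhantomIntensities = field(default_factory=PhantomIntensities)
    frame: AxisFrame = field(default_factory=AxisFrame)
    pad_voxels: int = 4
    size_cap_voxels: int = 250_000_000

    def __post_init__(self) -> None:
        if any(a <= 0 for a in self.organ_semi_axes):
            raise ValueError("organ_semi_axes must all be positive")
        if self.voxel_size <= 0:
            raise ValueError("voxel_size must be positive")
        if any(n < 0 for n in self.per_stage_counts.values()):
            raise ValueError("per_stage_counts must be non-negative")
        if self.placement_mode not in ("homogeneous", "sector_biased"):
            raise ValueError(f"unknown placement_mode {self.placement_mode!r}")
        if self.bias_factor < 1.0:
            raise ValueError("bias_factor must be >= 1")
        if self.placement_mode == "sector_biased":
            if self.bias_sector not in SECTOR_LABELS:
                raise ValueError(
                    f"bias_sector must be one of {SECTOR_LABELS}, got "
                    f"{self.bias_sector!r}"
                )
        if self.noise_sd < 0:
            raise ValueError("noise_sd must be >= 0")

    @property
    def gap_um(self) -> float:
        return self.voxel_size if self.min_gap_um is None else self.min_gap_um

    def organ_volume_um3(self) -> float:
        a, b, c = self.organ_semi_axes
        return 4.0 / 3.0 * np.pi * a * b * c

    def to_dict(self) -> dict:
        d = dataclasses.asdict(self)
        d["frame"] = self.frame.to_dict()
        return d


@dataclass(frozen=True)
class TrueFollicle:
    """Generator-side ground truth for one follicle."""

    id: int
    stage: str
    center: tuple[float, float, float]  # um, volume coordinates
    diameter: float  # um
    has_zp: bool
    n_antra: int
    antrum_fraction: float
    sector_true: str

    @property
    def radius(self) -> float:
        return self.diameter / 2.0


@dataclass
class GroundTruth:
    """Follicle list plus matching label volume and organ mask."""

    follicles: list[TrueFollicle]
    label_volume: np.ndarray  # uint16, 0 = background/stroma
    organ_mask: np.ndarray  # bool

    def to_frame(self) -> pd.DataFrame:
        rows = [
            {
                "id": f.id, "stage": f.stage,
                "x_um": f.center[0], "y_um": f.center[1], "z_um": f.center[2],
                "diameter_um": f.diameter, "n_antra": f.n_antra,
                "has_zp": f.has_zp, "sector_true": f.sector_true,
                "antrum_fraction": f.antrum_fraction,
            }
            for f in self.follicles
        ]
        return pd.DataFrame(
            rows,
            columns=["id", "stage", "x_um", "y_um", "z_um", "diameter_um",
                     "n_antra", "has_zp", "sector_true", "antrum_fraction"],
        )


def _stage_morphology(stage: str, rng: np.random.Generator) -> tuple[bool, int, float]:
    """(has_zp, n_antra, antrum_fraction) for a freshly sampled follicle."""
    if stage in ("T1", "T2", "T3", "T4", "CL"):
        return False, 0, 0.0
    if stage == "T5":
        return True, 0, 0.0
    if stage == "T6":
        return True, int(rng.integers(2, 5)), 0.0
    if stage == "T7":
        return True, 1, float(rng.uniform(0.10, 0.18))
    if stage == "T8":
        return True, 1, float(rng.uniform(0.35, 0.45))
    raise ValueError(f"unknown stage {stage!r}")


def _draw_diameter(stage: str, spec: PhantomSpec, rng: np.random.Generator) -> float:
    if stage == "CL":
        return float(rng.uniform(*spec.cl_diameter_range))
    if stage in _SMALL_STAGE_DIAMETERS:
        mean, sd = _SMALL_STAGE_DIAMETERS[stage]
        nsd = 2.0
    else:
        mean = spec.rubric.diameter_mean[stage]
        sd = spec.rubric.diameter_sd[stage]
        nsd = spec.rubric.n_sd_support
    while True:  # truncated normal at +/- nsd SD, by rejection
        d = float(rng.normal(mean, sd))
        if abs(d - mean) <= nsd * sd and d > 0:
            return d


class _GridHash:
    """Uniform-grid spatial hash for sphere overlap queries."""

    def __init__(self, cell: float):
        self.cell = max(cell, 1.0)
        self.cells: dict[tuple[int, int, int], list[tuple[np.ndarray, float]]] = {}

    def _key(self, p: np.ndarray) -> tuple[int, int, int]:
        return tuple(int(np.floor(c / self.cell)) for c in p)

    def ok(self, p: np.ndarray, r: float) -> bool:
        k = self._key(p)
        for dz in (-1, 0, 1):
            for dy in (-1, 0, 1):
                for dx in (-1, 0, 1):
                    for q, rq in self.cells.get((k[0] + dz, k[1] + dy, k[2] + dx), ()):
                        dd = p - q
                        lim = r + rq
                        if dd @ dd < lim * lim:
                            return False
        return True

    def add(self, p: np.ndarray, r: float) -> None:
        self.cells.setdefault(self._key(p), []).append((p, r))


def sample_follicle_population(
    spec: PhantomSpec, seed: int | None = None
) -> list[TrueFollicle]:
    """Draw a non-overlapping follicle population for one phantom ovary.

    Centres are uniform over the admissible region (rejection sampling with
    hard non-overlap and a one-voxel clearance); diameters come from the
    rubric's truncated normals.  In ``sector_biased`` mode candidate centres
    falling in ``bias_sector`` are accepted with relative weight
    ``bias_factor`` (thinning against the maximal weight, which renormalises
    the density).  Deterministic given ``seed`` (defaults to ``spec.seed``).

    Stages are placed largest-first to keep rejection packing feasible.
    Follicle centres are reported in volume coordinates: the organ centre
    sits at ``pad_voxels * voxel_size + organ_semi_axes``.

    Raises
    ------
    PackingError
        If the requested follicle volume exceeds 40% of the organ volume,
        or a follicle cannot be placed within ``spec.max_attempts``
        attempts (the message names the stage).
    """
    rng = np.random.default_rng(spec.seed if seed is None else seed)
    semi = np.asarray(spec.organ_semi_axes, dtype=float)
    offset = spec.pad_voxels * spec.voxel_size + semi  # centred -> volume coords

    # Draw all diameters first so the 40% budget check sees actual sizes.
    requests: list[tuple[str, float]] = []
    for stage in _PLACEMENT_ORDER:
        for _ in range(int(spec.per_stage_counts.get(stage, 0))):
            requests.append((stage, _draw_diameter(stage, spec, rng)))
    if not requests:
        return []
    total_vol = sum(np.pi / 6.0 * d**3 for _, d in requests)
    if total_vol >= 0.40 * spec.organ_volume_um3():
        raise PackingError(
            f"requested follicle volume ({total_vol:.3g} um^3) is "
            f">= 40% of the organ volume ({spec.organ_volume_um3():.3g} um^3); "
            "packing infeasible"
        )

    # Largest spheres first: best rejection-packing behaviour.  The sort is
    # stable, so determinism given the seed is preserved.
    requests.sort(key=lambda sd: -sd[1])
    gap = spec.gap_um
    max_d = max(d for _, d in requests)
    grid = _GridHash(cell=max_d + gap)
    biased = spec.placement_mode == "sector_biased" and spec.bias_factor > 0
    inv_bias = 1.0 / spec.bias_factor
    rho_min_cortex = 1.0 - spec.cortex_fraction

    follicles: list[TrueFollicle] = []
    fid = 0
    batch = 32
    for stage, d in requests:
        r = d / 2.0
        shrunk = semi - r - gap  # centres inside this ellipsoid keep the sphere inside
        if np.any(shrunk <= 0):
            raise PackingError(
                f"packing infeasible: stage {stage} follicle of diameter "
                f"{d:.1f} um does not fit inside the organ"
            )
        # Cortex rule: early-stage centres sit in the outer radial shell.
        # In scaled-down organs the shell can be thinner than the follicle
        # radius, so the threshold adapts to the outermost reachable
        # normalised radius (full-scale organs are unaffected).
        rho_reachable = float((shrunk / semi).max())
        rho_min = min(rho_min_cortex, 0.9 * rho_reachable)
        placed = None
        attempts = 0
        while attempts < spec.max_attempts:
            pts = rng.uniform(-shrunk, shrunk, size=(batch, 3))
            u = rng.random(batch)  # bias thinning (consumed in every mode)
            inside = ((pts / shrunk) ** 2).sum(axis=1) <= 1.0
            if stage in _CORTEX_STAGES:
                rho = np.sqrt(((pts / semi) ** 2).sum(axis=1))
                inside &= rho >= rho_min
            if biased:
                sectors = sector_of_points(pts + offset,
                                           tuple(offset), spec.frame)
                w = np.where(sectors == spec.bias_sector, 1.0, inv_bias)
                inside &= u < w
            else:
                inside &= u < 1.0  # always true; keeps RNG use identical
            for i in np.nonzero(inside)[0]:
                attempts += 1
                p = pts[i]
                if grid.ok(p, r + gap / 2.0):
                    placed = p
                    break
            else:
                attempts += int(batch - inside.sum())
                continue
            break
        if placed is None:
            raise PackingError(
                f"packing infeasible: could not place a {stage} follicle "
                f"(diameter {d:.1f} um) after {spec.max_attempts} attempts"
            )
        grid.add(placed, r + gap / 2.0)
        fid += 1
        center_vol = placed + offset
        sector = sector_of_points(center_vol[None, :], tuple(offset), spec.frame)[0]
        has_zp, n_antra, frac = _stage_morphology(stage, rng)
        follicles.append(
            TrueFollicle(
                id=fid, stage=stage, center=tuple(float(c) for c in center_vol),
                diameter=d, has_zp=has_zp, n_antra=n_antra,
                antrum_fraction=frac, sector_true=str(sector),
            )
        )
    return follicles


def _follicle_rng(f: TrueFollicle) -> np.random.Generator:
    # Orientation and cavity layout are a deterministic function of the
    # follicle identity, so render_follicle is reproducible in isolation.
    return np.random.default_rng((f.id * 2654435761 + 97) % (2**31 - 1))


def _unit_vectors(rng: np.random.Generator, n: int, min_angle_deg: float) -> np.ndarray:
    """n random unit vectors with pairwise angular separation >= min_angle."""
    cos_lim = np.cos(np.deg2rad(min_angle_deg))
    out: list[np.ndarray] = []
    for _ in range(500):
        v = rng.normal(size=3)
        v /= np.linalg.norm(v)
        if all(v @ w < cos_lim for w in out):
            out.append(v)
            if len(out) == n:
                return np.array(out)
    # Fall back to axis-aligned directions (cannot fail for n <= 6).
    axes = np.array([[1, 0, 0], [-1, 0, 0], [0, 1, 0],
                     [0, -1, 0], [0, 0, 1], [0, 0, -1]], dtype=float)
    return axes[:n]


def _zp_thickness(voxel_size: float) -> float:
    return max(5.0, 2.0 * voxel_size)


def render_follicle(
    f: TrueFollicle,
    voxel_size: float,
    intensities: PhantomIntensities | None = None,
) -> tuple[np.ndarray, np.ndarray]:
    """Render one follicle as an intensity patch plus its label mask.

    Returns ``(patch, mask)`` where ``patch`` is a float array of 8-bit
    intensities and ``mask`` the boolean sphere of the follicle.  The patch
    is centred: voxel ``(n//2, n//2, n//2)`` is the follicle centre.

    Stage-dependent structure:

    * T1-T3: featureless, mildly contrasted tissue (below detection limit);
    * T4: granulosa + oocyte without a zona ring, whole patch blended
      toward stroma (``t4_contrast``) to mimic its lower radiopacity;
    * T5: oocyte + dark zona ring + nucleus in uniform granulosa, no antrum;
    * T6: additionally ``n_antra`` (>= 2) disjoint small dark cavities;
    * T7: one off-centre antrum (modest volume fraction), oocyte opposite;
    * T8: one large central antrum (fraction >= 0.3), the oocyte embedded in
      a granulosa cumulus connected to the wall by a granulosa stalk;
    * CL: homogeneous mid-bright tissue, no oocyte/zona/antrum.
    """
    ints = intensities or PhantomIntensities()
    R = f.radius
    n = int(np.ceil(2 * R / voxel_size)) + 3
    c = (n - 1) / 2.0
    ax = (np.arange(n) - c) * voxel_size
    zz, yy, xx = np.meshgrid(ax, ax, ax, indexing="ij")
    rr = np.sqrt(zz**2 + yy**2 + xx**2)
    mask = rr <= R
    patch = np.full((n, n, n), float(ints.granulosa))

    def ball(center: np.ndarray, radius: float) -> np.ndarray:
        return (
            (zz - center[0]) ** 2 + (yy - center[1]) ** 2 + (xx - center[2]) ** 2
        ) <= radius**2

    def draw_oocyte(center: np.ndarray, r_o: float, with_zp: bool) -> None:
        th = _zp_thickness(voxel_size)
        if with_zp:
            d2 = ((zz - center[0]) ** 2 + (yy - center[1]) ** 2
                  + (xx - center[2]) ** 2)
            ring = (d2 > r_o**2) & (d2 <= (r_o + th) ** 2)
            patch[ring] = ints.zp
        oo = ball(center, r_o)
        patch[oo] = ints.oocyte
        if with_zp:
            patch[ball(center, 0.4 * r_o)] = ints.nucleus

    rng = _follicle_rng(f)
    zero = np.zeros(3)

    if f.stage == "CL":
        patch[:] = ints.cl
    elif f.stage in ("T1", "T2", "T3"):
        patch[:] = ints.stroma + ints.t123_contrast * (ints.granulosa - ints.stroma)
    elif f.stage == "T4":
        draw_oocyte(zero, 0.5 * R, with_zp=False)
        patch = ints.stroma + ints.t4_contrast * (patch - ints.stroma)
    elif f.stage == "T5":
        draw_oocyte(zero, 0.45 * R, with_zp=True)
    elif f.stage == "T6":
        dirs = _unit_vectors(rng, f.n_antra, min_angle_deg=60.0)
        for v in dirs:
            patch[ball(0.68 * R * v, 0.17 * R)] = ints.antrum
        draw_oocyte(zero, 0.25 * R, with_zp=True)
    elif f.stage in ("T7", "T8"):
        u = _unit_vectors(rng, 1, 60.0)[0]
        th = _zp_thickness(voxel_size)
        if f.stage == "T7":
            r_a = f.antrum_fraction ** (1.0 / 3.0) * R
            a_center, o_center, r_o = 0.35 * R * u, -0.5 * R * u, 0.2 * R
        else:
            r_a = f.antrum_fraction ** (1.0 / 3.0) * R
            a_center, o_center, r_o = 0.05 * R * u, -0.55 * R * u, 0.18 * R
        patch[ball(a_center, r_a)] = ints.antrum
        # cumulus buffer: granulosa repainted around the oocyte so the zona
        # ring never touches (and never merges with) the dark antrum
        r_buf = r_o + th + 2.0 * voxel_size
        patch[ball(o_center, r_buf)] = ints.granulosa
        if f.stage == "T8":
            # granulosa stalk anchoring the cumulus to the follicle wall
            w = o_center / np.linalg.norm(o_center)
            t = zz * w[0] + yy * w[1] + xx * w[2]
            perp2 = rr**2 - t**2
            stalk = (t >= np.linalg.norm(o_center)) & (perp2 <= (0.8 * r_o) ** 2)
            patch[stalk] = ints.granulosa
        draw_oocyte(o_center, r_o, with_zp=True)
        # digitisation of the stalk/cumulus surfaces can strand single
        # antrum voxels; keep only the main cavity
        from scipy import ndimage
        lab, ncomp = ndimage.label(patch == ints.antrum)
        if ncomp > 1:
            sizes = np.bincount(lab.ravel())[1:]
            keep = 1 + int(np.argmax(sizes))
            patch[(lab > 0) & (lab != keep)] = ints.granulosa
    # other stages: uniform granulosa (not reachable via _stage_morphology)

    patch = np.where(mask, patch, 0.0)
    return patch, mask


class VolumeCapError(MemoryError):
    """Raised when a phantom voxel grid would exceed the configured cap."""


def _default_vessels(spec: PhantomSpec) -> tuple[VesselSpec, ...]:
    """One 150 um hilum trunk entering along the medial-lateral axis, plus
    two 35 um medulla branches."""
    a = np.asarray(spec.organ_semi_axes)
    off = spec.pad_voxels * spec.voxel_size + a
    def pt(z, y, x):  # centred um -> volume um
        return tuple(float(v) for v in (np.array([z, y, x]) + off))
    hilum = VesselSpec(
        path=(pt(0, 0, a[2]), pt(0, 0, 0.15 * a[2])), diameter=150.0,
    )
    branch1 = VesselSpec(
        path=(pt(0, 0, 0.2 * a[2]), pt(0.25 * a[0], 0.3 * a[1], 0)),
        diameter=35.0,
    )
    branch2 = VesselSpec(
        path=(pt(0, 0, 0.2 * a[2]), pt(-0.2 * a[0], -0.35 * a[1], 0.1 * a[2])),
        diameter=35.0,
    )
    return (hilum, branch1, branch2)


def _paint_tube(vol: np.ndarray, free: np.ndarray, p0: np.ndarray,
                p1: np.ndarray, radius_vox: float, value: int) -> None:
    """Paint voxels within radius of segment p0-p1 (voxel coords) where free."""
    lo = np.maximum(np.floor(np.minimum(p0, p1) - radius_vox - 1).astype(int), 0)
    hi = np.minimum(np.ceil(np.maximum(p0, p1) + radius_vox + 1).astype(int) + 1,
                    vol.shape)
    if np.any(lo >= hi):
        return
    grids = np.meshgrid(*[np.arange(l, h) for l, h in zip(lo, hi)], indexing="ij")
    pts = np.stack([g.astype(float) for g in grids], axis=-1)
    d = p1 - p0
    L2 = float(d @ d)
    if L2 == 0:
        dist2 = ((pts - p0) ** 2).sum(axis=-1)
    else:
        t = np.clip(((pts - p0) @ d) / L2, 0.0, 1.0)
        proj = p0 + t[..., None] * d
        dist2 = ((pts - proj) ** 2).sum(axis=-1)
    sel = dist2 <= radius_vox**2
    box = tuple(slice(l, h) for l, h in zip(lo, hi))
    sel &= free[box]
    vol[box][sel] = value


def build_phantom(
    spec: PhantomSpec, seed: int | None = None
) -> tuple[VoxelVolume, GroundTruth]:
    """Voxelise a full phantom ovary and its ground truth.

    The organ is a two-level ellipsoid (bright cortex shell over the outer
    ``cortex_fraction`` of the normalised radius, dimmer medulla core);
    follicles are composited via :func:`render_follicle`; vessels are dark
    tubes along ``vessel_specs`` drawn only over unlabelled tissue; noise is
    added last.  Intensities lie in [0, 255] before noise.

    Raises :class:`VolumeCapError` if the voxel grid would exceed
    ``spec.size_cap_voxels`` (memory guard), and :class:`PackingError` from
    the placement stage.
    """
    vsz = spec.voxel_size
    semi = np.asarray(spec.organ_semi_axes, dtype=float)
    shape = tuple(int(np.ceil(2 * (s / vsz + spec.pad_voxels))) for s in semi)
    n_vox = int(np.prod(shape))
    if n_vox > spec.size_cap_voxels:
        raise VolumeCapError(
            f"phantom grid {shape} = {n_vox} voxels exceeds the size cap "
            f"({spec.size_cap_voxels}); increase voxel_size or the cap"
        )
    ints = spec.intensities
    center_vox = spec.pad_voxels + semi / vsz

    rho2 = np.zeros(shape, dtype=np.float32)
    for a in range(3):
        coord = (np.arange(shape[a], dtype=np.float32) - center_vox[a]) * vsz
        coord /= semi[a]
        rho2 += (coord**2).reshape([-1 if i == a else 1 for i in range(3)])
    organ_mask = rho2 <= 1.0
    vol = np.full(shape, ints.background, dtype=np.uint8)
    vol[organ_mask] = ints.stroma
    vol[organ_mask & (rho2 >= (1.0 - spec.cortex_fraction) ** 2)] = ints.cortex
    del rho2

    follicles = sample_follicle_population(spec, seed=seed)
    labels = np.zeros(shape, dtype=np.uint16)
    for f in follicles:
        patch, mask = render_follicle(f, vsz, ints)
        n = patch.shape[0]
        cv = np.asarray(f.center) / vsz  # voxel coords of the centre
        lo = np.round(cv - (n - 1) / 2.0).astype(int)
        hi = lo + n
        slo = np.maximum(lo, 0)
        shi = np.minimum(hi, shape)
        box = tuple(slice(l, h) for l, h in zip(slo, shi))
        pbox = tuple(slice(l2 - l, n - (h - h2))
                     for l, h, l2, h2 in zip(lo, hi, slo, shi))
        m = mask[pbox]
        vol[box][m] = np.clip(np.round(patch[pbox][m]), 0, 255).astype(np.uint8)
        labels[box][m] = f.id

    vessel_specs = spec.vessel_specs
    if vessel_specs is None:
        vessel_specs = _default_vessels(spec)
    free = organ_mask & (labels == 0)
    for vs in vessel_specs:
        pts = [np.asarray(p, dtype=float) / vsz for p in vs.path]
        r_vox = vs.diameter / 2.0 / vsz
        for p0, p1 in zip(pts, pts[1:]):
            _paint_tube(vol, free, p0, p1, r_vox, ints.vessel)

    volume = VoxelVolume(data=vol, voxel_size=vsz, frame=spec.frame)
    if spec.noise_sd > 0:
        noise_seed = int(
            np.random.SeedSequence(
                [spec.seed if seed is None else seed, 7919]
            ).generate_state(1)[0] % (2**31 - 1)
        )
        volume = add_noise(volume, spec.noise_sd, noise_seed)
    gt = GroundTruth(follicles=follicles, label_volume=labels,
                     organ_mask=organ_mask)
    return volume, gt


def add_noise(vol: VoxelVolume, noise_sd: float, seed: int) -> VoxelVolume:
    """Additive Gaussian noise, clipped to the dtype intensity range.

    ``noise_sd=0`` returns an identical copy; equal seeds give identical
    outputs.
    """
    if noise_sd < 0:
        raise ValueError("noise_sd must be >= 0")
    data = vol.data
    if noise_sd == 0:
        return VoxelVolume(data.copy(), vol.voxel_size, vol.frame)
    rng = np.random.default_rng(seed)
    lo, hi = 0, np.iinfo(data.dtype).max
    noisy = data.astype(np.float32) + rng.normal(
        0.0, noise_sd, size=data.shape
    ).astype(np.float32)
    out = np.clip(np.round(noisy), lo, hi).astype(data.dtype)
    return VoxelVolume(out, vol.voxel_size, vol.frame)


def write_phantom(out_dir: str | Path, vol: VoxelVolume, gt: GroundTruth,
                  spec: PhantomSpec, comment: str | None = None) -> dict[str, Path]:
    """Write phantom artifacts: volume + label TIFFs, truth CSV, spec JSON."""
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    paths = {
        "volume": out / "phantom.tif",
        "labels": out / "truth_labels.tif",
        "truth": out / "truth.csv",
        "spec": out / "phantom_spec.json",
    }
    write_stack(vol, paths["volume"])
    write_stack(gt.label_volume, paths["labels"])
    write_follicle_table(gt.to_frame(), paths["truth"], header_comment=comment)
    with open(paths["spec"], "w") as fh:
        json.dump(spec.to_dict(), fh, indent=2, default=str)
    return paths
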