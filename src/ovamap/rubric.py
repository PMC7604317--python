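"""Stage rubric and deterministic follicle staging.

Mouse folliculogenesis is conventionally described by the Pedersen-Peters
types T1-T8 plus corpora lutea (CL).  Contrast-enhanced microCT resolves
follicles from the secondary T4 stage upward; T1-T3 are below the practical
detection limit and are therefore never assigned by this classifier (they
fall through to ``"unclassified"``).

The rubric combines, for each detectable stage, the diameter distribution
(mean +/- SD, in micrometres) with the morphological signature of the stage:

========  ==================  ==============================================
stage     diameter (um)       morphology
========  ==================  ==============================================
T4        53.2 +/- 12.7       no zona pellucida space, reduced radiopacity
T5        89.0 +/- 11.2       zona pellucida present, no antrum
T6        137.0 +/- 24.9      several small scattered antral cavities
T7        218.9 +/- 36.9      one antrum cavity, modest relative volume
T8        321.0 +/- 21.3      one large antrum (>= 30% of follicle volume)
CL        >= 250 (assumed)    no oocyte, no zona, no antrum
========  ==================  ==============================================

Morphology outranks diameter throughout: adjacent stage diameter ranges
overlap (T7 at +2 SD exceeds the T7/T8 midpoint), so the antrum count,
antrum volume fraction and zona-pellucida flag decide the stage, and the
diameter acts only as a support bound for T4 and CL and as a fallback when
the antrum fraction cannot be measured.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

__all__ = [
    "STAGES",
    "GROWING_STAGES",
    "StageRubric",
    "DEFAULT_RUBRIC",
    "class_boundaries",
    "classify_follicle",
]

#: All labels a detected object may carry, in canonical order.
STAGES = ("T1", "T2", "T3", "T4", "T5", "T6", "T7", "T8", "CL")

#: Stages the microCT pipeline can actually resolve and stage.
GROWING_STAGES = ("T4", "T5", "T6", "T7", "T8")


@dataclass(frozen=True)
class StageRubric:
    """Per-stage diameter statistics and morphological decision parameters.

    Parameters
    ----------
    diameter_mean, diameter_sd
        Mean and standard deviation of the stage diameter in micrometres,
        keyed by stage label ``T4``..``T8``.
    cl_min_diameter
        Minimum diameter (um) for a corpus luteum call.  The literature the
        rubric encodes gives no CL size criterion; this default is an
        explicit, configurable assumption and is flagged as such in reports.
    large_antrum_fraction
        Antrum-volume fraction at or above which a single-antrum follicle is
        considered fully grown (T8 rather than T7).
    n_sd_support
        Half-width, in SD units, of each stage's diameter support.  Used for
        the lower T4 bound and the upper T4 bound.
    """

    diameter_mean: dict[str, float] = field(
        default_factory=lambda: {
            "T4": 53.2, "T5": 89.0, "T6": 137.0, "T7": 218.9, "T8": 321.0,
        }
    )
    diameter_sd: dict[str, float] = field(
        default_factory=lambda: {
            "T4": 12.7, "T5": 11.2, "T6": 24.9, "T7": 36.9, "T8": 21.3,
        }
    )
    cl_min_diameter: float = 250.0
    large_antrum_fraction: float = 0.3
    n_sd_support: float = 2.0

    def __post_init__(self) -> None:
        means = [self.diameter_mean[s] for s in GROWING_STAGES]
        if any(b <= a for a, b in zip(means, means[1:])):
            raise ValueError(
                "stage diameter means must be strictly increasing T4..T8, "
                f"got {means}"
            )
        if any(self.diameter_sd[s] < 0 for s in GROWING_STAGES):
            raise ValueError("stage diameter SDs must be non-negative")
        if self.cl_min_diameter <= 0:
            raise ValueError("cl_min_diameter must be positive")

    def support(self, stage: str) -> tuple[float, float]:
        """Diameter support [mean - n*SD, mean + n*SD] for a growing stage."""
        m = self.diameter_mean[stage]
        s = self.diameter_sd[stage]
        return (m - self.n_sd_support * s, m + self.n_sd_support * s)

    def with_means_scaled(self, factor: float) -> "StageRubric":
        """Return a rubric with all diameter means and SDs scaled by ``factor``."""
        return replace(
            self,
            diameter_mean={k: v * factor for k, v in self.diameter_mean.items()},
            diameter_sd={k: v * factor for k, v in self.diameter_sd.items()},
            cl_min_diameter=self.cl_min_diameter * factor,
        )


DEFAULT_RUBRIC = StageRubric()


def class_boundaries(rubric: StageRubric = DEFAULT_RUBRIC) -> tuple[float, ...]:
    """Diameter thresholds between adjacent stages (midpoints of class means).

    Returns the four boundaries (T4/T5, T5/T6, T6/T7, T7/T8) in um.  With the
    default rubric these are (71.1, 113.0, 177.95, 269.95).  The boundaries
    are a derived convenience for diameter-only fallback decisions; the
    primary staging path is morphological.
    """
    means = [rubric.diameter_mean[s] for s in GROWING_STAGES]
    return tuple((a + b) / 2.0 for a, b in zip(means, means[1:]))


def classify_follicle(features, rubric: StageRubric = DEFAULT_RUBRIC) -> tuple[str, str]:
    """Assign a stage label to one measured follicle candidate.

    Parameters
    ----------
    features
        Any object exposing ``major_diameter`` (um), ``n_antra`` (int),
        ``antrum_fraction`` (float in [0, 1), NaN allowed), ``zp_present``
        and ``oocyte_present`` (bool).  Typically a
        :class:`ovamap.segment.FollicleFeatures`.
    rubric
        Decision parameters; defaults to the printed mouse rubric.

    Returns
    -------
    (stage, rationale)
        ``stage`` is one of ``T4``..``T8``, ``CL`` or ``"unclassified"``;
        ``rationale`` is a short human-readable record of the rule that
        fired.  The function is pure: identical features always map to the
        same label, and every candidate receives exactly one label.

    Notes
    -----
    Decision order (morphology first, diameter as support bound only):

    1. no oocyte, no zona, no antrum, diameter >= CL minimum -> ``CL``
    2. two or more antral cavities -> ``T6``
    3. one antrum cavity -> ``T8`` when its volume fraction reaches
       ``large_antrum_fraction``, else ``T7``; when the fraction is not
       available (NaN) the T7/T8 diameter midpoint decides
    4. no antrum, zona pellucida present -> ``T5``
    5. no antrum, no zona, diameter within the T4 support -> ``T4``
    6. otherwise ``"unclassified"`` (never silently dropped)
    """
    d = float(features.major_diameter)
    n_antra = int(features.n_antra)
    frac = float(features.antrum_fraction)
    zp = bool(features.zp_present)
    oocyte = bool(getattr(features, "oocyte_present", zp))

    if n_antra == 0 and not zp and not oocyte and d >= rubric.cl_min_diameter:
        return "CL", (
            f"rule CL: no oocyte/zona/antrum and diameter {d:.1f} um >= "
            f"{rubric.cl_min_diameter:.0f} um (CL size criterion is an assumption)"
        )
    if n_antra >= 2:
        return "T6", f"rule T6: {n_antra} scattered antral cavities"
    if n_antra == 1:
        t78 = class_boundaries(rubric)[3]
        if frac == frac:  # antrum fraction measured
            if frac >= rubric.large_antrum_fraction:
                return "T8", (
                    f"rule T8: single antrum, fraction {frac:.2f} >= "
                    f"{rubric.large_antrum_fraction:.2f}"
                )
            return "T7", (
                f"rule T7: single antrum, fraction {frac:.2f} < "
                f"{rubric.large_antrum_fraction:.2f}"
            )
        if d >= t78:
            return "T8", f"rule T8 (diameter fallback): {d:.1f} um >= {t78:.2f} um"
        return "T7", f"rule T7 (diameter fallback): {d:.1f} um < {t78:.2f} um"
    if zp:
        return "T5", "rule T5: zona pellucida present, no antrum"
    lo, hi = rubric.support("T4")
    if lo <= d <= hi:
        return "T4", (
            f"rule T4: no zona, diameter {d:.1f} um within T4 support "
            f"[{lo:.1f}, {hi:.1f}]"
        )
    return "unclassified", (
        f"no rule matched: no zona/antrum, diameter {d:.1f} um outside T4 "
        f"support and below CL minimum"
    )
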