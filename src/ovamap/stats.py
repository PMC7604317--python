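"""Homogeneity statistics for sector count tables.

The scientific question is whether follicles are spatially homogeneous
across the ovary: equal numbers anterior vs posterior, dorsal vs ventral,
and across the eight virtual sectors.  The tests follow the conventional
design for such data: two-sided pooled-variance Student's t-tests for the
two-group axis comparisons, one-way ANOVA across the eight sectors with
Bonferroni-adjusted pairwise post-hoc t-tests, all at a significance level
``alpha`` (default 0.05).  The observational unit is the ovary (counts per
sector are summaries over one organ), not the follicle.

A small simulation harness (:func:`typeI_error_simulation`) calibrates the
nominal level empirically under a homogeneous Poisson null.
"""

from __future__ import annotations

import itertools
import math
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats as sps

from .spatial import SECTOR_LABELS, half_totals, sector_totals

__all__ = [
    "TTestResult",
    "AnovaResult",
    "ComparisonResult",
    "HomogeneityReport",
    "t_test_pooled",
    "one_way_anova",
    "bonferroni_posthoc",
    "homogeneity_report",
    "typeI_error_simulation",
]


@dataclass(frozen=True)
class TTestResult:
    t: float
    df: int
    p: float


@dataclass(frozen=True)
class AnovaResult:
    F: float
    df_between: int
    df_within: int
    p: float


@dataclass(frozen=True)
class ComparisonResult:
    """One row of a homogeneity report."""

    name: str
    test: str
    statistic: float
    df: tuple[int, ...]
    p: float
    p_adjusted: float | None = None
    significant: bool = False

    def to_dict(self) -> dict:
        return {
            "name": self.name, "test": self.test,
            "statistic": self.statistic, "df": list(self.df), "p": self.p,
            "p_adjusted": self.p_adjusted, "significant": self.significant,
        }


def _summary(x) -> tuple[float, float, int]:
    """(mean, sd, n) from raw samples or a (mean, sd, n) triple."""
    if isinstance(x, tuple) and len(x) == 3 and np.isscalar(x[0]):
        mean, sd, n = x
        return float(mean), float(sd), int(n)
    arr = np.asarray(x, dtype=float)
    if arr.ndim != 1 or arr.size < 2:
        raise ValueError("each group needs n >= 2 observations")
    return float(arr.mean()), float(arr.std(ddof=1)), int(arr.size)


def t_test_pooled(group1, group2, welch: bool = False) -> TTestResult:
    """Two-sided Student's t-test with pooled variance.

    Groups may be raw 1D samples or ``(mean, sd, n)`` summary triples, so
    the test can be recomputed directly from printed summary statistics.
    With ``welch=True`` the unequal-variance form is used instead (the
    pooled form is the named "Student's t-test" and is the default).

    Degenerate input: when the pooled variance is zero and the means are
    equal, ``t = 0, p = 1`` by convention; zero variance with unequal means
    is an error (the statistic is undefined).
    """
    m1, s1, n1 = _summary(group1)
    m2, s2, n2 = _summary(group2)
    if n1 < 2 or n2 < 2:
        raise ValueError("each group needs n >= 2")
    if s1 == 0.0 and s2 == 0.0:
        if m1 == m2:
            return TTestResult(t=0.0, df=n1 + n2 - 2, p=1.0)
        raise ValueError(
            "zero pooled variance with unequal means: t undefined"
        )
    res = sps.ttest_ind_from_stats(
        m1, s1, n1, m2, s2, n2, equal_var=not welch
    )
    df = n1 + n2 - 2 if not welch else int(np.floor(res.df))
    return TTestResult(t=float(res.statistic), df=df, p=float(res.pvalue))


def one_way_anova(groups) -> AnovaResult:
    """One-way fixed-effects ANOVA over k >= 2 groups of raw values.

    Zero within-group variance is handled as in :func:`t_test_pooled`:
    all-equal data gives ``F = 0, p = 1``; separated constant groups raise.
    For k = 2, ``F`` equals the squared pooled t statistic.
    """
    arrs = [np.asarray(g, dtype=float) for g in groups]
    if len(arrs) < 2:
        raise ValueError("ANOVA needs k >= 2 groups")
    if any(a.size < 2 for a in arrs):
        raise ValueError("each group needs n >= 2")
    k = len(arrs)
    n_total = sum(a.size for a in arrs)
    df_b, df_w = k - 1, n_total - k
    ss_within = sum(((a - a.mean()) ** 2).sum() for a in arrs)
    if ss_within == 0.0:
        if len({float(a.mean()) for a in arrs}) == 1:
            return AnovaResult(F=0.0, df_between=df_b, df_within=df_w, p=1.0)
        raise ValueError("zero within-group variance with unequal means")
    F, p = sps.f_oneway(*arrs)
    return AnovaResult(F=float(F), df_between=df_b, df_within=df_w, p=float(p))


def bonferroni_posthoc(groups, alpha: float = 0.05,
                       labels=None) -> pd.DataFrame:
    """All pairwise pooled t-tests with Bonferroni adjustment.

    Returns a DataFrame with one row per unordered pair (k*(k-1)/2 rows;
    28 for the eight sectors): raw and adjusted p (``min(1, p * m)``) and a
    significance flag at ``alpha``.
    """
    arrs = [np.asarray(g, dtype=float) for g in groups]
    k = len(arrs)
    labels = list(labels) if labels is not None else [str(i) for i in range(k)]
    m = k * (k - 1) // 2
    rows = []
    for i, j in itertools.combinations(range(k), 2):
        try:
            res = t_test_pooled(arrs[i], arrs[j])
            t, df, p = res.t, res.df, res.p
        except ValueError:  # separated constant groups: maximally significant
            t, df, p = math.inf, arrs[i].size + arrs[j].size - 2, 0.0
        p_adj = min(1.0, p * m)
        rows.append({
            "group1": labels[i], "group2": labels[j], "t": t, "df": df,
            "p": p, "p_adjusted": p_adj, "significant": p_adj < alpha,
        })
    return pd.DataFrame(rows)


@dataclass
class HomogeneityReport:
    """Axis and sector homogeneity tests for a set of ovaries."""

    alpha: float
    comparisons: list[ComparisonResult] = field(default_factory=list)
    posthoc: dict[str, pd.DataFrame] = field(default_factory=dict)
    notes: list[str] = field(default_factory=list)

    def significant(self) -> list[ComparisonResult]:
        return [c for c in self.comparisons if c.significant]

    def to_dict(self) -> dict:
        return {
            "alpha": self.alpha,
            "comparisons": [c.to_dict() for c in self.comparisons],
            "posthoc": {k: v.to_dict(orient="records")
                        for k, v in self.posthoc.items()},
            "notes": list(self.notes),
        }


def _safe_t(name: str, a, b, alpha: float,
            report: HomogeneityReport) -> None:
    try:
        res = t_test_pooled(a, b)
        report.comparisons.append(ComparisonResult(
            name=name, test="t_pooled", statistic=res.t, df=(res.df,),
            p=res.p, significant=res.p < alpha,
        ))
    except ValueError:
        report.comparisons.append(ComparisonResult(
            name=name, test="t_pooled", statistic=math.inf, df=(0,),
            p=0.0, significant=True,
        ))
        report.notes.append(f"{name}: degenerate zero-variance comparison")


def _safe_anova(name: str, groups, labels, alpha: float,
                report: HomogeneityReport, with_posthoc: bool) -> None:
    try:
        res = one_way_anova(groups)
        report.comparisons.append(ComparisonResult(
            name=name, test="anova", statistic=res.F,
            df=(res.df_between, res.df_within), p=res.p,
            significant=res.p < alpha,
        ))
    except ValueError:
        report.comparisons.append(ComparisonResult(
            name=name, test="anova", statistic=math.inf, df=(0, 0),
            p=0.0, significant=True,
        ))
        report.notes.append(f"{name}: degenerate zero-variance comparison")
    if with_posthoc:
        report.posthoc[name] = bonferroni_posthoc(groups, alpha, labels)


def homogeneity_report(counts: pd.DataFrame, alpha: float = 0.05) -> HomogeneityReport:
    """Run the full homogeneity analysis on an ovary x (sector, stage) table.

    ``counts`` is the output of :func:`ovamap.spatial.tabulate_counts` for
    N >= 2 ovaries.  The report contains:

    * anterior vs posterior and dorsal vs ventral pooled t-tests, for total
      counts and per stage;
    * eight-sector one-way ANOVAs (totals and per stage) with Bonferroni
      post-hoc pairwise tables;
    * a stage-abundance ANOVA (are some stages more numerous than others);
    * significance flags at ``alpha``.

    Stages absent from every ovary are skipped with a notice.  Note the CL
    size criterion used upstream in staging is an assumption, which the
    report records.
    """
    if len(counts) < 2:
        raise ValueError("homogeneity report needs N >= 2 ovaries")
    report = HomogeneityReport(alpha=alpha)
    report.notes.append(
        "CL staging uses an assumed minimum-diameter criterion; CL counts "
        "inherit that assumption"
    )
    stages = list(counts.columns.get_level_values("stage").unique())

    tot = sector_totals(counts)
    for axis, (na, nb) in (("ap", ("anterior", "posterior")),
                           ("dv", ("dorsal", "ventral"))):
        halves = half_totals(counts, axis)
        _safe_t(f"{na}_vs_{nb}_total", halves[na].values, halves[nb].values,
                alpha, report)
        for st in stages:
            sub = counts.xs(st, level="stage", axis=1)
            if sub.values.sum() == 0:
                continue
            ha = sub[[s for s in SECTOR_LABELS
                      if s in _half_members(axis, True)]].sum(axis=1)
            hb = sub[[s for s in SECTOR_LABELS
                      if s in _half_members(axis, False)]].sum(axis=1)
            _safe_t(f"{na}_vs_{nb}_{st}", ha.values, hb.values, alpha, report)

    groups = [tot[s].values for s in SECTOR_LABELS]
    _safe_anova("sectors_total", groups, SECTOR_LABELS, alpha, report,
                with_posthoc=True)
    for st in stages:
        sub = counts.xs(st, level="stage", axis=1)
        if sub.values.sum() == 0:
            report.notes.append(f"stage {st}: absent everywhere, skipped")
            continue
        _safe_anova(f"sectors_{st}", [sub[s].values for s in SECTOR_LABELS],
                    SECTOR_LABELS, alpha, report, with_posthoc=True)

    present = [st for st in stages
               if counts.xs(st, level="stage", axis=1).values.sum() > 0]
    if len(present) >= 2:
        stage_groups = [
            counts.xs(st, level="stage", axis=1).sum(axis=1).values
            for st in present
        ]
        _safe_anova("stage_abundance", stage_groups, present, alpha, report,
                    with_posthoc=True)
    return report


def _half_members(axis: str, first: bool) -> tuple[str, ...]:
    from .spatial import (ANTERIOR_SECTORS, DORSAL_SECTORS,
                          POSTERIOR_SECTORS, VENTRAL_SECTORS)
    if axis == "ap":
        return ANTERIOR_SECTORS if first else POSTERIOR_SECTORS
    return DORSAL_SECTORS if first else VENTRAL_SECTORS


def typeI_error_simulation(
    n_reps: int,
    per_sector_mean: float,
    n_ovaries: int,
    seed: int,
    alpha: float = 0.05,
) -> float:
    """Empirical rejection rate of the 8-sector ANOVA under a Poisson null.

    Each replicate draws ``n_ovaries x 8`` sector counts i.i.d.
    Poisson(``per_sector_mean``) and runs the eight-group one-way ANOVA;
    the returned fraction of ``p < alpha`` estimates the realised type-I
    error at the nominal level.  Vectorised over replicates.
    """
    if n_reps < 100:
        raise ValueError("n_reps must be >= 100 for a stable rate estimate")
    rng = np.random.default_rng(seed)
    if alpha <= 0:
        return 0.0
    counts = rng.poisson(per_sector_mean,
                         size=(n_reps, 8, n_ovaries)).astype(float)
    groups = [counts[:, i, :] for i in range(8)]
    with np.errstate(invalid="ignore", divide="ignore"):
        import warnings
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            _, p = sps.f_oneway(*groups, axis=1)
    p = np.where(np.isnan(p), 1.0, p)  # all-constant replicate: no rejection
    if alpha >= 1:
        return 1.0
    return float(np.mean(p < alpha))
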