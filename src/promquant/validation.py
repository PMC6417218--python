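"""Evaluation statistics: dose linearity, prediction-measurement correlation,
and strength-class ordering.

Three checks establish that an omics-predicted strength ranking agrees with
dual-reporter measurements: (i) the inducible test construct's ratio must be
linear in inducer concentration (ordinary least squares with r^2); (ii) the
measured ratio must correlate with each platform's mean log2 expression
(Pearson and Spearman, on the raw or log2 ratio); (iii) class means must be
ordered strong > medium > weak.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats

from .errors import InsufficientDataError, InvalidArgumentError
from .flow import DualReporterMeasurement
from .omics import CLASSES, CandidateSet, PLATFORMS

__all__ = [
    "DoseFit",
    "CorrelationReport",
    "ClassOrdering",
    "linear_dose_fit",
    "prediction_correlation",
    "class_ordering",
]

TRANSFORMS = ("raw_ratio", "log2_ratio")


@dataclass(frozen=True)
class DoseFit:
    construct_id: str
    slope: float       # ratio per (ug/mL)
    intercept: float
    r_squared: float
    n_points: int
    degenerate: bool = False


@dataclass(frozen=True)
class CorrelationReport:
    platform: str
    n: int
    pearson_r: float
    r_squared: float
    spearman_rho: float
    transform: str


@dataclass(frozen=True)
class ClassOrdering:
    per_class: dict  # label -> {"n", "mean_ratio", "sd"}
    is_monotone: bool


def linear_dose_fit(series: list[DualReporterMeasurement]) -> DoseFit:
    """OLS of strength ratio on inducer concentration.

    Requires measurements at >= 3 distinct concentrations of one construct.
    Zero variance in concentration is an error (nothing to regress on); zero
    variance in the ratios reports slope 0, r^2 = 0 with a degenerate flag
    rather than NaN.
    """
    if not series:
        raise InsufficientDataError("no measurements")
    constructs = {m.construct_id for m in series}
    if len(constructs) != 1:
        raise InvalidArgumentError(f"mixed constructs: {constructs}")
    conc = np.array([m.inducer_conc for m in series], dtype=float)
    ratio = np.array([m.ratio for m in series], dtype=float)
    if len(np.unique(conc)) < 3:
        raise InsufficientDataError(
            "need >= 3 distinct concentrations for a dose fit")
    if np.ptp(conc) == 0:
        raise InvalidArgumentError("zero variance in concentration")
    construct = series[0].construct_id
    if np.ptp(ratio) == 0:
        return DoseFit(construct_id=construct, slope=0.0,
                       intercept=float(ratio[0]), r_squared=0.0,
                       n_points=len(series), degenerate=True)
    fit = stats.linregress(conc, ratio)
    return DoseFit(construct_id=construct, slope=float(fit.slope),
                   intercept=float(fit.intercept),
                   r_squared=float(fit.rvalue ** 2), n_points=len(series))


def prediction_correlation(candidates: pd.DataFrame,
                           transform: str = "log2_ratio",
                           platforms: tuple[str, ...] = PLATFORMS
                           ) -> dict[str, CorrelationReport]:
    """Correlate per-platform mean log2 expression with the measured ratio.

    ``candidates`` must have a ``ratio`` column plus one column per platform
    holding that platform's mean log2 value; rows missing either member of a
    pair are dropped per platform (and reflected in ``n``). The ratio is
    log2-transformed first when ``transform='log2_ratio'`` (requires positive
    ratios); Spearman is unaffected by this monotone choice.
    """
    if transform not in TRANSFORMS:
        raise InvalidArgumentError(f"transform must be one of {TRANSFORMS}")
    if "ratio" not in candidates.columns:
        raise InvalidArgumentError("candidates needs a 'ratio' column")
    reports: dict[str, CorrelationReport] = {}
    for plat in platforms:
        if plat not in candidates.columns:
            raise InvalidArgumentError(f"missing platform column {plat!r}")
        sub = candidates[[plat, "ratio"]].dropna()
        if transform == "log2_ratio":
            sub = sub[sub["ratio"] > 0]
        if len(sub) < 3:
            raise InsufficientDataError(
                f"{plat}: {len(sub)} complete pairs, need >= 3")
        x = sub[plat].to_numpy(float)
        y = sub["ratio"].to_numpy(float)
        if transform == "log2_ratio":
            y = np.log2(y)
        r = float(stats.pearsonr(x, y).statistic)
        rho = float(stats.spearmanr(x, y).statistic)
        reports[plat] = CorrelationReport(
            platform=plat, n=len(sub), pearson_r=r, r_squared=r * r,
            spearman_rho=rho, transform=transform)
    return reports


def class_ordering(candidates: CandidateSet,
                   ratios: pd.Series) -> ClassOrdering:
    """Per-class mean/SD of measured ratios and the strong>medium>weak check.

    ``ratios`` maps gene_id to the measured strength ratio; class statistics
    use only candidates that have a measurement. Every class must retain at
    least one measured member.
    """
    per_class: dict[str, dict[str, float]] = {}
    means = {}
    for label in CLASSES:
        members = [g for g in candidates.members(label) if g in ratios.index]
        vals = ratios.loc[members].dropna()
        if vals.empty:
            raise InsufficientDataError(f"class {label!r} has no measured members")
        per_class[label] = {"n": int(len(vals)),
                            "mean_ratio": float(vals.mean()),
                            "sd": float(vals.std(ddof=1)) if len(vals) > 1 else 0.0}
        means[label] = float(vals.mean())
    monotone = means["strong"] > means["medium"] > means["weak"]
    return ClassOrdering(per_class=per_class, is_monotone=bool(monotone))
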