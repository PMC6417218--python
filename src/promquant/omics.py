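"""Quantile classification of promoter strength from omics expression.

Each platform (microarray, RNA-seq, proteomics) is summarised per gene by
the arithmetic mean of its log2 values across conditions, genes are ranked
within the platform, and strength labels are assigned by percentile rank:

* strong — at or above the 90th percentile,
* weak   — at or below the 10th percentile,
* medium — between the 40th and 60th percentile (inclusive),
* unlabeled otherwise.

Cross-platform consensus is the intersection of labels: a gene is a strong
candidate only if every required platform calls it strong, and likewise for
the other classes. Hand-picked extra weak genes may be appended with
``manual`` provenance, mirroring the practice of padding the weak class for
broader representation. Platforms are never normalised onto a common scale;
ranking is strictly within-platform.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy.stats import rankdata

from .errors import InvalidArgumentError

__all__ = [
    "PLATFORMS",
    "OmicsDataset",
    "GeneSummary",
    "QuantileThresholds",
    "StrengthCall",
    "CandidateSet",
    "summarize_dataset",
    "classify_by_quantile",
    "consensus_select",
    "CLASSES",
]

PLATFORMS = ("microarray", "rnaseq", "proteomics")
CLASSES = ("strong", "medium", "weak")


@dataclass(frozen=True)
class OmicsDataset:
    """A genes × conditions matrix of log2 expression for one platform."""

    platform: str
    matrix: pd.DataFrame  # index gene_id, columns condition ids

    def __post_init__(self) -> None:
        if self.platform not in PLATFORMS:
            raise InvalidArgumentError(f"unknown platform {self.platform!r}")
        if self.matrix.index.has_duplicates:
            raise InvalidArgumentError("duplicate gene_ids in matrix")
        if self.matrix.shape[1] < 1:
            raise InvalidArgumentError("matrix needs >= 1 condition")
        values = self.matrix.to_numpy()
        if values.size and not np.all(np.isfinite(values[~np.isnan(values)])):
            raise InvalidArgumentError("matrix contains non-finite values")

    @property
    def n_conditions(self) -> int:
        return self.matrix.shape[1]

    @property
    def gene_ids(self) -> list[str]:
        return list(self.matrix.index)


@dataclass(frozen=True)
class GeneSummary:
    """Per-gene mean log2 value for one platform."""

    platform: str
    mean_log2: pd.Series  # index gene_id


@dataclass(frozen=True)
class QuantileThresholds:
    """Percentile cut-offs for the strong/medium/weak labels.

    Boundaries are inclusive on the side of the class: percentile rank 0.90
    is strong, 0.10 is weak, 0.40 and 0.60 are both medium.
    """

    strong_min_pr: float = 0.90
    weak_max_pr: float = 0.10
    medium_lo: float = 0.40
    medium_hi: float = 0.60

    def __post_init__(self) -> None:
        ok = (0.0 <= self.weak_max_pr < self.medium_lo <= self.medium_hi
              < self.strong_min_pr <= 1.0)
        if not ok:
            raise InvalidArgumentError(
                "require 0 <= weak_max_pr < medium_lo <= medium_hi "
                "< strong_min_pr <= 1")

    def label(self, pr: float) -> str:
        if pr >= self.strong_min_pr:
            return "strong"
        if pr <= self.weak_max_pr:
            return "weak"
        if self.medium_lo <= pr <= self.medium_hi:
            return "medium"
        return "unlabeled"


@dataclass(frozen=True)
class StrengthCall:
    gene_id: str
    platform: str
    mean_log2: float
    percentile_rank: float
    label: str


@dataclass(frozen=True)
class CandidateSet:
    """Cross-platform consensus candidates plus manual extras.

    ``provenance`` maps each member gene to either the per-platform label dict
    (consensus members) or the string ``"manual"`` (extras).
    """

    strong: frozenset[str]
    medium: frozenset[str]
    weak: frozenset[str]
    provenance: dict[str, object] = field(default_factory=dict)

    def members(self, label: str) -> frozenset[str]:
        return {"strong": self.strong, "medium": self.medium,
                "weak": self.weak}[label]

    def to_frame(self) -> pd.DataFrame:
        rows = []
        for label in CLASSES:
            for gid in sorted(self.members(label)):
                prov = self.provenance.get(gid, {})
                prov_str = prov if isinstance(prov, str) else "consensus"
                rows.append({"gene_id": gid, "class": label,
                             "provenance": prov_str})
        return pd.DataFrame(rows, columns=["gene_id", "class", "provenance"])


def summarize_dataset(dataset: OmicsDataset) -> GeneSummary:
    """Mean log2 value per gene over all of the dataset's conditions.

    Missing (NaN) entries are skipped; a gene with no observed condition is
    dropped from the summary (and hence from the platform's ranking).
    """
    if dataset.matrix.empty:
        raise InvalidArgumentError("empty omics matrix")
    means = dataset.matrix.mean(axis=1, skipna=True).dropna()
    means.name = "mean_log2"
    return GeneSummary(platform=dataset.platform, mean_log2=means)


def classify_by_quantile(
    summary: GeneSummary,
    thresholds: QuantileThresholds | None = None,
) -> list[StrengthCall]:
    """Assign strong/medium/weak labels by within-platform percentile rank.

    Percentile rank is ascending rank divided by n, with ties receiving the
    mean rank of the tied block — so an all-tied vector (e.g. a proteomics
    floor) classifies every member identically. With all values identical no
    ordering information exists and every gene is unlabeled (with a warning).
    """
    thresholds = thresholds or QuantileThresholds()
    values = summary.mean_log2
    n = len(values)
    if n == 0:
        raise InvalidArgumentError("empty summary")
    if n < 10:
        warnings.warn(
            f"only {n} genes on {summary.platform}: quantile classes are "
            "degenerate below 10 genes", stacklevel=2)
    pr = rankdata(values.to_numpy(), method="average") / n
    if values.nunique() == 1:
        warnings.warn(
            f"all {summary.platform} values identical: no ordering "
            "information, labeling everything 'unlabeled'", stacklevel=2)
        labels = ["unlabeled"] * n
    else:
        labels = [thresholds.label(p) for p in pr]
    return [
        StrengthCall(gene_id=g, platform=summary.platform,
                     mean_log2=float(v), percentile_rank=float(p), label=lab)
        for g, v, p, lab in zip(values.index, values.to_numpy(), pr, labels)
    ]


def calls_to_frame(calls: list[StrengthCall]) -> pd.DataFrame:
    return pd.DataFrame(
        [{"gene_id": c.gene_id, "platform": c.platform,
          "mean_log2": c.mean_log2, "percentile_rank": c.percentile_rank,
          "label": c.label} for c in calls],
        columns=["gene_id", "platform", "mean_log2", "percentile_rank",
                 "label"])


def consensus_select(
    calls: dict[str, list[StrengthCall]],
    required_platforms: tuple[str, ...] | None = None,
    extra_weak: list[str] | None = None,
) -> CandidateSet:
    """Intersect per-platform labels into a consensus candidate set.

    A gene enters class ``c`` iff it is labeled ``c`` on EVERY required
    platform. Genes missing from a platform's ranking are excluded from the
    consensus (not an error). ``extra_weak`` genes are appended to the weak
    class with ``manual`` provenance regardless of their labels.
    """
    required = tuple(required_platforms or PLATFORMS)
    missing = [p for p in required if p not in calls]
    if missing:
        raise InvalidArgumentError(f"missing platform calls: {missing}")

    label_maps = {
        plat: {c.gene_id: c.label for c in calls[plat]} for plat in required
    }
    common = set.intersection(*(set(m) for m in label_maps.values()))

    sets: dict[str, set[str]] = {c: set() for c in CLASSES}
    provenance: dict[str, object] = {}
    for gid in common:
        labels = {plat: label_maps[plat][gid] for plat in required}
        distinct = set(labels.values())
        if len(distinct) == 1 and (lab := distinct.pop()) in sets:
            sets[lab].add(gid)
            provenance[gid] = labels
    for gid in extra_weak or []:
        if gid not in sets["weak"]:
            sets["weak"].add(gid)
            provenance[gid] = "manual"
    return CandidateSet(strong=frozenset(sets["strong"]),
                        medium=frozenset(sets["medium"]),
                        weak=frozenset(sets["weak"]),
                        provenance=provenance)
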