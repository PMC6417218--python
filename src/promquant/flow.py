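"""Dual-reporter flow-cytometry quantification.

The strength readout of the dual reporter-gene system is the ratio of the
mean green-channel (EGFP, test promoter) fluorescence to the mean
red-channel (opmCherry, constitutive calibration) fluorescence. Because the
per-cell plasmid copy number and other shared noise multiply both channels,
they cancel in the ratio — the system's core calibration claim.

The processing chain mirrors standard cytometry practice: optional spillover
compensation by inverting a 2x2 spillover matrix, an event-count QC gate
(at least 20,000 events per sample), per-replicate channel means, the
across-replicate ratio with its replicate STDEV, and for inducible RBS
constructs the induced-minus-uninduced relative strength.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field, replace
from statistics import stdev

import numpy as np
import pandas as pd
from scipy.stats import gmean

from .errors import (DegenerateMeasurementError, InvalidArgumentError)

__all__ = [
    "FlowSample",
    "SpilloverMatrix",
    "DualReporterMeasurement",
    "RBSDesign",
    "compensate",
    "qc_events",
    "sample_means",
    "dual_ratio",
    "rbs_relative_strength",
    "DEFAULT_MIN_EVENTS",
]

DEFAULT_MIN_EVENTS = 20_000


@dataclass(frozen=True)
class FlowSample:
    """One acquisition: per-event green/red intensities plus metadata."""

    sample_id: str
    construct_id: str
    replicate: int
    inducer_conc: float
    green: np.ndarray
    red: np.ndarray
    qc_pass: bool | None = None
    n_clamped: int = 0

    def __post_init__(self) -> None:
        green = np.asarray(self.green, dtype=float)
        red = np.asarray(self.red, dtype=float)
        if green.shape != red.shape or green.ndim != 1:
            raise InvalidArgumentError("green/red must be equal-length 1-D arrays")
        if not (np.all(np.isfinite(green)) and np.all(np.isfinite(red))):
            raise InvalidArgumentError("channel values must be finite")
        if (green < 0).any() or (red < 0).any():
            raise InvalidArgumentError("channel values must be non-negative")
        if self.inducer_conc < 0:
            raise InvalidArgumentError("inducer_conc must be >= 0")
        object.__setattr__(self, "green", green)
        object.__setattr__(self, "red", red)

    @property
    def n_events(self) -> int:
        return self.green.shape[0]

    def events_frame(self) -> pd.DataFrame:
        return pd.DataFrame({"event_index": np.arange(self.n_events),
                             "green": self.green, "red": self.red})

    @classmethod
    def from_events_frame(cls, events: pd.DataFrame, *, sample_id: str,
                          construct_id: str, replicate: int,
                          inducer_conc: float) -> "FlowSample":
        return cls(sample_id=sample_id, construct_id=construct_id,
                   replicate=replicate, inducer_conc=inducer_conc,
                   green=events["green"].to_numpy(float),
                   red=events["red"].to_numpy(float))


@dataclass(frozen=True)
class SpilloverMatrix:
    """2x2 spillover: entry (i, j) = fraction of fluorophore j read in channel i.

    Channel/fluorophore order is (green, red); the diagonal is 1 by
    construction. Compensation applies the inverse to each event's observed
    channel vector.
    """

    green_to_red: float = 0.0
    red_to_green: float = 0.0

    def __post_init__(self) -> None:
        for v in (self.green_to_red, self.red_to_green):
            if not (0.0 <= v < 1.0):
                raise InvalidArgumentError("off-diagonal spillover must be in [0, 1)")
        if abs(np.linalg.det(self.as_matrix())) < 1e-12:
            raise InvalidArgumentError("spillover matrix is singular")

    def as_matrix(self) -> np.ndarray:
        return np.array([[1.0, self.red_to_green],
                         [self.green_to_red, 1.0]])

    @property
    def is_identity(self) -> bool:
        return self.green_to_red == 0.0 and self.red_to_green == 0.0

    @classmethod
    def identity(cls) -> "SpilloverMatrix":
        return cls()


@dataclass(frozen=True)
class DualReporterMeasurement:
    """Aggregated strength readout for one construct at one inducer level."""

    construct_id: str
    inducer_conc: float
    mean_green: float
    mean_red: float
    ratio: float
    sd: float
    n_replicates: int
    n_events_total: int

    def __post_init__(self) -> None:
        if self.mean_red <= 0:
            raise DegenerateMeasurementError("mean_red must be > 0 for a ratio")
        if self.sd < 0 or self.n_replicates < 1:
            raise InvalidArgumentError("sd >= 0 and n_replicates >= 1 required")


@dataclass(frozen=True)
class RBSDesign:
    """A synthetic ribosome binding site with its predicted TIR."""

    name: str
    sequence: str
    predicted_tir: float

    def __post_init__(self) -> None:
        if set(self.sequence) - set("ACGT"):
            raise InvalidArgumentError("RBS sequence must be uppercase A/C/G/T")
        if self.predicted_tir <= 0:
            raise InvalidArgumentError("predicted_tir must be > 0")


def compensate(sample: FlowSample, spillover: SpilloverMatrix) -> FlowSample:
    """Undo spectral spillover by solving the 2x2 mixing system per event.

    Small negative corrected values are clamped to 0 and counted in the
    returned sample's ``n_clamped``. The identity matrix returns the input
    sample unchanged.
    """
    if spillover.is_identity:
        return sample
    inv = np.linalg.inv(spillover.as_matrix())
    obs = np.vstack([sample.green, sample.red])
    true = inv @ obs
    n_clamped = int((true < 0).sum())
    true = np.maximum(true, 0.0)
    return replace(sample, green=true[0], red=true[1], n_clamped=n_clamped)


def qc_events(sample: FlowSample,
              min_events: int = DEFAULT_MIN_EVENTS) -> FlowSample:
    """Flag a sample by the event-count rule (pass iff n_events >= min_events)."""
    return replace(sample, qc_pass=sample.n_events >= min_events)


def sample_means(sample: FlowSample,
                 geometric: bool = False) -> tuple[float, float]:
    """Per-channel mean fluorescence intensity over all retained events.

    Arithmetic by default; ``geometric=True`` switches to the geometric mean
    for sensitivity analysis (zeros are excluded there, as on instruments).
    """
    if sample.n_events == 0:
        raise InvalidArgumentError("sample has no events")
    if geometric:
        g = sample.green[sample.green > 0]
        r = sample.red[sample.red > 0]
        if g.size == 0 or r.size == 0:
            raise InvalidArgumentError("no positive events for geometric mean")
        return float(gmean(g)), float(gmean(r))
    return float(sample.green.mean()), float(sample.red.mean())


def dual_ratio(samples: list[FlowSample], geometric: bool = False,
               enforce_qc: bool = True) -> DualReporterMeasurement:
    """Aggregate replicate samples into the headline strength readout.

    Per-replicate channel means are averaged across replicates and the ratio
    of those averages (mean EGFP / mean opmCherry) is the strength; the SD is
    the sample STDEV of the per-replicate ratios (0 with a warning for a
    single replicate). All samples must share construct and inducer level and
    pass QC (run :func:`qc_events` first, or set ``enforce_qc=False``).
    """
    if not samples:
        raise InvalidArgumentError("no samples given")
    constructs = {s.construct_id for s in samples}
    concs = {s.inducer_conc for s in samples}
    if len(constructs) != 1 or len(concs) != 1:
        raise InvalidArgumentError(
            f"mixed constructs {constructs} or inducer levels {concs}")
    if enforce_qc:
        flagged = [s.sample_id for s in samples if s.qc_pass is False]
        if flagged:
            raise InvalidArgumentError(f"samples failed QC: {flagged}")

    per_rep = [sample_means(s, geometric=geometric) for s in samples]
    greens = np.array([m[0] for m in per_rep])
    reds = np.array([m[1] for m in per_rep])
    if np.any(reds <= 0):
        raise DegenerateMeasurementError("a replicate has zero red signal")
    mean_green = float(greens.mean())
    mean_red = float(reds.mean())
    if mean_red <= 0:
        raise DegenerateMeasurementError("average red signal is zero")
    rep_ratios = greens / reds
    if len(samples) == 1:
        warnings.warn("single replicate: SD reported as 0", stacklevel=2)
        sd = 0.0
    else:
        sd = float(stdev(rep_ratios))
    return DualReporterMeasurement(
        construct_id=samples[0].construct_id,
        inducer_conc=samples[0].inducer_conc,
        mean_green=mean_green, mean_red=mean_red,
        ratio=mean_green / mean_red, sd=sd,
        n_replicates=len(samples),
        n_events_total=int(sum(s.n_events for s in samples)))


def rbs_relative_strength(induced: DualReporterMeasurement,
                          uninduced: DualReporterMeasurement) -> float:
    """Induced minus uninduced ratio for the same construct.

    The uninduced measurement must be at inducer concentration 0. Negative
    results (weak RBS within noise) are preserved, not clamped.
    """
    if induced.construct_id != uninduced.construct_id:
        raise InvalidArgumentError("construct mismatch")
    if uninduced.inducer_conc != 0:
        raise InvalidArgumentError("uninduced measurement must be at conc 0")
    return induced.ratio - uninduced.ratio
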