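"""Synthetic inputs with the statistical structure the analysis assumes.

This module generates every input the pipeline consumes — genome annotation
with operons, per-platform expression matrices, and event-level two-channel
flow-cytometry samples — from a known ground truth, so each downstream stage
can be tested by parameter recovery rather than against downloads.

The generative model mirrors the experimental design it emulates:

* Each gene carries a latent promoter strength on the log2 expression scale.
  Every omics platform observes ``latent + platform offset + condition effect
  + noise``; proteomics is additionally left-censored at a detection floor
  (weak promoters all collapse onto the floor value, as in real peptide-count
  data).
* A flow event is one cell. A single lognormal plasmid copy-number factor
  multiplies BOTH channels — this shared nuisance is exactly what the dual
  reporter ratio is built to cancel. On top of that sit independent
  multiplicative channel noise, additive autofluorescence, and optional
  linear spectral spillover of green signal into the red detector.
* An inducible test promoter responds linearly to inducer concentration over
  the 0–1.0 µg/mL window.

All generators take an integer seed and are byte-deterministic for a fixed
seed; there is no hidden global RNG state.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd

from .errors import GenerationError, InvalidArgumentError
from .flow import FlowSample
from .omics import OmicsDataset, PLATFORMS
from .promoters import Annotation, OperonTable

__all__ = [
    "LatentStrengthMap",
    "FlowNoiseParams",
    "DoseResponseParams",
    "gen_latent_strength_map",
    "gen_annotation",
    "gen_omics_suite",
    "gen_flow_sample",
    "gen_dose_series",
    "DEFAULT_CONDITIONS",
    "DEFAULT_NOISE_SD",
    "DEFAULT_PLATFORM_OFFSET",
    "DEFAULT_PROTEOMICS_FLOOR",
]

#: Condition counts per platform: 109 microarrays, 8 RNA-seq, 4 proteomics runs.
DEFAULT_CONDITIONS = {"microarray": 109, "rnaseq": 8, "proteomics": 4}

#: Per-observation Gaussian noise SD (log2 units) per platform.
DEFAULT_NOISE_SD = {"microarray": 0.5, "rnaseq": 0.5, "proteomics": 0.7}

#: Additive platform offsets calibrated so strong genes sit near 15 (array),
#: 11 (RNA-seq) and 8 (proteomics) log2 units, the scales seen in practice.
DEFAULT_PLATFORM_OFFSET = {"microarray": 0.0, "rnaseq": -4.5, "proteomics": -7.5}

#: Proteomics left-censoring floor (log2 units).
DEFAULT_PROTEOMICS_FLOOR = 0.07


@dataclass(frozen=True)
class LatentStrengthMap:
    """Ground-truth promoter strengths for parameter-recovery tests.

    ``latent_log2`` is the true strength on the log2 expression scale;
    ``class_truth`` holds the planted label (``strong``/``medium``/``weak``/
    ``none``) used to score classifier recovery.
    """

    gene_ids: tuple[str, ...]
    latent_log2: np.ndarray
    class_truth: tuple[str, ...]

    def __post_init__(self) -> None:
        arr = np.asarray(self.latent_log2, dtype=float)
        if arr.shape != (len(self.gene_ids),):
            raise InvalidArgumentError("latent_log2 length must match gene_ids")
        if not np.all(np.isfinite(arr)):
            raise InvalidArgumentError("latent_log2 must be finite")
        object.__setattr__(self, "latent_log2", arr)

    def __len__(self) -> int:
        return len(self.gene_ids)

    def genes_in_class(self, label: str) -> list[str]:
        return [g for g, c in zip(self.gene_ids, self.class_truth) if c == label]

    def to_series(self) -> pd.Series:
        return pd.Series(self.latent_log2, index=list(self.gene_ids), name="latent_log2")


@dataclass(frozen=True)
class FlowNoiseParams:
    """Noise model for one simulated flow-cytometry acquisition.

    copy_number_cv
        Coefficient of variation of the per-cell plasmid copy-number factor
        (lognormal, mean 1). Shared between channels.
    autofluor_mean
        Mean per-event additive autofluorescence (AU), drawn Exponential per
        channel; 0 disables it.
    spillover_green_to_red
        Fraction of each event's green signal added to the red detector.
    channel_noise_cv
        CV of independent multiplicative Gaussian noise per channel.
    n_events
        Events per sample; default matches the 20,000-event QC floor.
    """

    copy_number_cv: float = 0.25
    autofluor_mean: float = 5.0
    spillover_green_to_red: float = 0.0
    channel_noise_cv: float = 0.05
    n_events: int = 20_000

    def __post_init__(self) -> None:
        if self.copy_number_cv < 0 or self.autofluor_mean < 0 or self.channel_noise_cv < 0:
            raise InvalidArgumentError("noise parameters must be non-negative")
        if not (0.0 <= self.spillover_green_to_red < 1.0):
            raise InvalidArgumentError("spillover_green_to_red must be in [0, 1)")
        if self.n_events <= 0:
            raise InvalidArgumentError("n_events must be positive")

    @classmethod
    def noiseless(cls, n_events: int = 20_000) -> "FlowNoiseParams":
        return cls(copy_number_cv=0.0, autofluor_mean=0.0,
                   spillover_green_to_red=0.0, channel_noise_cv=0.0,
                   n_events=n_events)


@dataclass(frozen=True)
class DoseResponseParams:
    """Linear inducer dose response ``g(conc) = baseline + slope * conc``.

    The grid default is the tetracycline series 0–1.0 µg/mL in 0.2 steps;
    linearity is only asserted inside this window.
    """

    conc_grid: tuple[float, ...] = (0.0, 0.2, 0.4, 0.6, 0.8, 1.0)
    slope: float = 2.0
    baseline: float = 0.2

    def __post_init__(self) -> None:
        grid = tuple(float(c) for c in self.conc_grid)
        if len(grid) == 0:
            raise InvalidArgumentError("conc_grid must be non-empty")
        if any(c < 0 for c in grid):
            raise InvalidArgumentError("concentrations must be non-negative")
        if any(b <= a for a, b in zip(grid, grid[1:])):
            raise InvalidArgumentError("conc_grid must be strictly increasing")
        if self.baseline < 0:
            raise InvalidArgumentError("baseline must be non-negative")
        object.__setattr__(self, "conc_grid", grid)

    def response(self, conc: float) -> float:
        return self.baseline + self.slope * float(conc)


def gen_latent_strength_map(
    n_genes: int,
    frac_strong: float = 0.10,
    frac_weak: float = 0.10,
    frac_medium: float = 0.0,
    seed: int = 0,
) -> LatentStrengthMap:
    """Plant gene classes with well-separated latent strengths.

    Strong genes draw from Uniform(13, 16), weak from Uniform(3, 5) and the
    background from Uniform(6.5, 12.5); with the default 10 % strong / 10 %
    weak fractions the planted sets occupy exactly the top and bottom deciles.
    ``frac_medium`` optionally pins genes to a narrow central band
    (Uniform(9.2, 9.8)) so a medium consensus class also exists.
    """
    if n_genes < 2:
        raise InvalidArgumentError("n_genes must be >= 2")
    if frac_strong + frac_weak + frac_medium > 1.0:
        raise InvalidArgumentError("class fractions must sum to <= 1")
    rng = np.random.default_rng(seed)
    n_strong = int(round(frac_strong * n_genes))
    n_weak = int(round(frac_weak * n_genes))
    n_medium = int(round(frac_medium * n_genes))
    n_none = n_genes - n_strong - n_weak - n_medium

    latents = np.concatenate([
        rng.uniform(13.0, 16.0, size=n_strong),
        rng.uniform(9.2, 9.8, size=n_medium),
        rng.uniform(6.5, 12.5, size=n_none),
        rng.uniform(3.0, 5.0, size=n_weak),
    ])
    classes = (["strong"] * n_strong + ["medium"] * n_medium
               + ["none"] * n_none + ["weak"] * n_weak)
    order = rng.permutation(n_genes)
    gene_ids = tuple(f"G{i:05d}" for i in range(n_genes))
    return LatentStrengthMap(
        gene_ids=gene_ids,
        latent_log2=latents[order],
        class_truth=tuple(classes[i] for i in order),
    )


def gen_annotation(
    n_genes: int,
    n_contigs: int = 1,
    operon_fraction: float = 0.3,
    min_gap: int = 100,
    seed: int = 0,
    gene_ids: tuple[str, ...] | None = None,
    mean_gene_len: int = 900,
) -> tuple[Annotation, OperonTable, dict[str, str]]:
    """Generate a gene annotation, operon table, and genome sequence.

    Genes are packed left to right on each contig with intergenic gaps of at
    least ``min_gap`` bp, random strands, and gene lengths ~ Uniform(300,
    2*mean_gene_len-300). Operon members are consecutive, same-strand genes
    separated by short gaps (the lead gene owns the shared promoter).
    Returns ``(annotation, operons, genome)`` with genome a contig→sequence
    dict of uppercase A/C/G/T.
    """
    if n_genes < 2:
        raise InvalidArgumentError("n_genes must be >= 2")
    if n_contigs < 1:
        raise InvalidArgumentError("n_contigs must be >= 1")
    if min_gap < 0:
        raise InvalidArgumentError("min_gap must be >= 0")
    if not (0.0 <= operon_fraction <= 1.0):
        raise InvalidArgumentError("operon_fraction must be in [0, 1]")

    rng = np.random.default_rng(seed)
    if gene_ids is None:
        gene_ids = tuple(f"G{i:05d}" for i in range(n_genes))
    elif len(gene_ids) != n_genes:
        raise InvalidArgumentError("gene_ids length must equal n_genes")

    # split genes across contigs as evenly as possible
    per_contig = [n_genes // n_contigs] * n_contigs
    for i in range(n_genes % n_contigs):
        per_contig[i] += 1
    if min(per_contig) < 1:
        raise GenerationError("more contigs than genes")

    lo_len, hi_len = 300, max(301, 2 * mean_gene_len - 300)
    rows = []
    operon_rows = []
    genome: dict[str, str] = {}
    gi = 0
    operon_idx = 0
    bases = np.frombuffer(b"ACGT", dtype=np.uint8)
    for ci, n_here in enumerate(per_contig):
        contig = f"contig{ci + 1}"
        # partition this contig's genes into blocks: operon blocks of 2-4
        # consecutive genes, the rest singletons
        blocks: list[int] = []
        remaining = n_here
        target_operon_genes = int(round(operon_fraction * n_here))
        operon_genes = 0
        while remaining > 0:
            if operon_genes < target_operon_genes and remaining >= 2:
                size = int(rng.integers(2, min(4, remaining) + 1))
                blocks.append(size)
                operon_genes += size
            else:
                blocks.append(1)
                remaining -= 1
                continue
            remaining -= size
        order = rng.permutation(len(blocks))
        blocks = [blocks[i] for i in order]

        pos = 1
        for size in blocks:
            strand = "+" if rng.random() < 0.5 else "-"
            gap = min_gap + int(rng.integers(0, 401))
            pos += gap
            members = []
            for k in range(size):
                length = int(rng.integers(lo_len, hi_len + 1))
                start, end = pos, pos + length - 1
                gid = gene_ids[gi]
                rows.append({"gene_id": gid, "contig": contig,
                             "strand": strand, "start": start, "end": end})
                members.append(gid)
                gi += 1
                # short intra-operon gap, keeps members consecutive
                pos = end + 1 + (int(rng.integers(5, 40)) if k < size - 1 else 0)
            if size >= 2:
                operon_idx += 1
                oid = f"OP{operon_idx:04d}"
                ordered = members if strand == "+" else members[::-1]
                for pos_in_op, gid in enumerate(ordered, start=1):
                    operon_rows.append({"operon_id": oid, "gene_id": gid,
                                        "position_in_operon": pos_in_op,
                                        "strand": strand})
        contig_len = pos + min_gap + 500
        seq_idx = rng.integers(0, 4, size=contig_len)
        genome[contig] = bases[seq_idx].tobytes().decode("ascii")

    annotation = Annotation(pd.DataFrame(rows))
    operons = OperonTable(pd.DataFrame(
        operon_rows,
        columns=["operon_id", "gene_id", "position_in_operon", "strand"]))
    return annotation, operons, genome


def gen_omics_suite(
    truth: LatentStrengthMap,
    n_conditions: dict[str, int] | None = None,
    noise_sd: dict[str, float] | None = None,
    platform_offset: dict[str, float] | None = None,
    condition_sd: float = 0.3,
    proteomics_floor: float = DEFAULT_PROTEOMICS_FLOOR,
    seed: int = 0,
) -> dict[str, OmicsDataset]:
    """Simulate one expression matrix per platform from the latent truth.

    Each observed value is ``latent + offset[platform] + condition_effect +
    N(0, noise_sd[platform])``; condition effects are shared across genes
    within a column (a batch/growth-condition shift). Proteomics values are
    then left-censored at ``proteomics_floor``: everything below the floor is
    reported AT the floor, so all sufficiently weak genes share one value.
    """
    if len(truth) == 0:
        raise InvalidArgumentError("truth must contain at least one gene")
    if not np.isfinite(proteomics_floor):
        raise InvalidArgumentError("proteomics_floor must be finite")
    n_conditions = dict(DEFAULT_CONDITIONS if n_conditions is None else n_conditions)
    noise_sd = dict(DEFAULT_NOISE_SD if noise_sd is None else noise_sd)
    platform_offset = dict(DEFAULT_PLATFORM_OFFSET if platform_offset is None
                           else platform_offset)
    for plat in PLATFORMS:
        if noise_sd.get(plat, 0.0) < 0:
            raise InvalidArgumentError(f"noise_sd[{plat}] must be >= 0")

    rng = np.random.default_rng(seed)
    latent = truth.latent_log2[:, None]
    out: dict[str, OmicsDataset] = {}
    for plat in PLATFORMS:
        n_cond = n_conditions[plat]
        cond_effect = (rng.normal(0.0, condition_sd, size=n_cond)
                       if condition_sd > 0 else np.zeros(n_cond))
        noise = (rng.normal(0.0, noise_sd[plat], size=(len(truth), n_cond))
                 if noise_sd[plat] > 0 else 0.0)
        mat = latent + platform_offset.get(plat, 0.0) + cond_effect[None, :] + noise
        if plat == "proteomics":
            mat = np.maximum(mat, proteomics_floor)
        frame = pd.DataFrame(
            mat, index=list(truth.gene_ids),
            columns=[f"{plat}_c{j + 1}" for j in range(n_cond)])
        frame.index.name = "gene_id"
        out[plat] = OmicsDataset(platform=plat, matrix=frame)
    return out


def _lognormal_factor(rng: np.random.Generator, cv: float, n: int) -> np.ndarray:
    """Mean-1 lognormal draws with the requested coefficient of variation."""
    if cv == 0:
        return np.ones(n)
    sigma2 = np.log1p(cv * cv)
    return rng.lognormal(mean=-sigma2 / 2.0, sigma=np.sqrt(sigma2), size=n)


def gen_flow_sample(
    green_strength: float,
    red_strength: float,
    noise: FlowNoiseParams | None = None,
    inducer_conc: float = 0.0,
    dose: DoseResponseParams | None = None,
    seed: int = 0,
    sample_id: str = "sample",
    construct_id: str = "construct",
    replicate: int = 1,
) -> FlowSample:
    """Simulate one two-channel flow acquisition.

    Per event ``i``::

        C_i     ~ lognormal, mean 1, CV copy_number_cv      (shared nuisance)
        green_i = C_i * g(conc) * green_strength * (1 + eps_g) + af_g
        red_i   = C_i * red_strength * (1 + eps_r) + af_r
                  + spillover_green_to_red * green_i

    where ``g(conc) = baseline + slope*conc`` when ``dose`` is given, else 1,
    ``eps`` are independent N(0, channel_noise_cv) draws and ``af`` are
    exponential autofluorescence draws. Negative values (possible at large
    channel CV) are clamped to 0.
    """
    if red_strength <= 0:
        raise InvalidArgumentError("red_strength must be > 0")
    if green_strength < 0:
        raise InvalidArgumentError("green_strength must be >= 0")
    noise = noise or FlowNoiseParams()
    rng = np.random.default_rng(seed)
    n = noise.n_events

    copies = _lognormal_factor(rng, noise.copy_number_cv, n)
    g = dose.response(inducer_conc) if dose is not None else 1.0
    eps_g = (rng.normal(0.0, noise.channel_noise_cv, n)
             if noise.channel_noise_cv > 0 else 0.0)
    eps_r = (rng.normal(0.0, noise.channel_noise_cv, n)
             if noise.channel_noise_cv > 0 else 0.0)
    af_g = (rng.exponential(noise.autofluor_mean, n)
            if noise.autofluor_mean > 0 else 0.0)
    af_r = (rng.exponential(noise.autofluor_mean, n)
            if noise.autofluor_mean > 0 else 0.0)

    green = copies * g * green_strength * (1.0 + eps_g) + af_g
    red = (copies * red_strength * (1.0 + eps_r) + af_r
           + noise.spillover_green_to_red * green)
    green = np.maximum(np.asarray(green, dtype=float), 0.0)
    red = np.maximum(np.asarray(red, dtype=float), 0.0)
    return FlowSample(sample_id=sample_id, construct_id=construct_id,
                      replicate=replicate, inducer_conc=float(inducer_conc),
                      green=green, red=red)


def gen_dose_series(
    strength_scale: float,
    dose: DoseResponseParams | None = None,
    noise: FlowNoiseParams | None = None,
    red_strength: float = 1000.0,
    replicates: int = 3,
    seed: int = 0,
    construct_id: str = "Ptet",
) -> list[FlowSample]:
    """Simulate an inducer titration: one sample per (concentration, replicate).

    The green channel scales with ``strength_scale * g(conc)``; the red
    calibration channel is statistically identical across concentrations.
    """
    if replicates < 1:
        raise InvalidArgumentError("replicates must be >= 1")
    dose = dose or DoseResponseParams()
    noise = noise or FlowNoiseParams()
    root = np.random.default_rng(seed)
    samples = []
    for conc in dose.conc_grid:
        for rep in range(1, replicates + 1):
            sub_seed = int(root.integers(0, 2**31 - 1))
            samples.append(gen_flow_sample(
                green_strength=strength_scale,
                red_strength=red_strength,
                noise=noise, inducer_conc=conc, dose=dose, seed=sub_seed,
                sample_id=f"{construct_id}_c{conc:g}_r{rep}",
                construct_id=construct_id, replicate=rep))
    return samples
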