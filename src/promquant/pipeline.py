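"""Pipeline orchestration and stable file contracts.

Runs the full chain — summarise omics, classify by quantile, intersect into
consensus candidates, extract promoter regions, quantify flow samples, and
validate — from a :class:`PipelineConfig` pointing at files on disk, writing
a run directory with::

    calls.tsv               per-gene per-platform rank and label
    candidates.tsv          consensus classes with provenance
    promoters.tsv/.fasta    extracted intergenic regions
    measurements.tsv        dual-reporter ratios per construct/inducer level
    validation_report.json  dose fits, correlations, class ordering
    manifest.json           version, config hash, seed, stage log

Every table carries a comment header with the tool version, config hash and
seed; identical config + seed reproduces byte-identical outputs.
"""

from __future__ import annotations

import hashlib
import json
from dataclasses import asdict, dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from . import __version__
from .errors import InvalidArgumentError, PromquantError
from .flow import (DEFAULT_MIN_EVENTS, FlowSample, SpilloverMatrix,
                   compensate, dual_ratio, qc_events)
from .omics import (CLASSES, OmicsDataset, PLATFORMS, QuantileThresholds,
                    calls_to_frame, classify_by_quantile, consensus_select,
                    summarize_dataset)
from .promoters import (extract_promoter, fetch_sequence, read_genome_fasta,
                        read_gff3, regions_to_frame, resolve_anchor,
                        write_promoters_fasta, OperonTable)
from .validation import class_ordering, linear_dose_fit, prediction_correlation

__all__ = ["PipelineConfig", "run_pipeline", "demo_run",
           "read_flow_samples", "write_flow_samples"]


class PipelineStageError(PromquantError):
    """A pipeline stage failed; the message names the stage and record."""


@dataclass
class PipelineConfig:
    annotation_path: str
    genome_path: str
    operons_path: str
    omics_paths: dict[str, str]          # platform -> TSV matrix
    flow_metadata_path: str              # samples.tsv with per-sample CSV paths
    out_dir: str
    thresholds: QuantileThresholds = field(default_factory=QuantileThresholds)
    min_events: int = DEFAULT_MIN_EVENTS
    spillover_green_to_red: float = 0.0
    spillover_red_to_green: float = 0.0
    transform: str = "log2_ratio"
    extra_weak: tuple[str, ...] = ()
    seed: int = 0

    def validate(self) -> None:
        for label, path in [("annotation", self.annotation_path),
                            ("genome", self.genome_path),
                            ("operons", self.operons_path),
                            ("flow metadata", self.flow_metadata_path),
                            *[(f"omics[{p}]", v)
                              for p, v in self.omics_paths.items()]]:
            if not Path(path).exists():
                raise InvalidArgumentError(f"{label} path does not exist: {path}")
        missing = set(PLATFORMS) - set(self.omics_paths)
        if missing:
            raise InvalidArgumentError(f"omics_paths missing platforms {missing}")

    def config_hash(self) -> str:
        """Hash of the analysis settings (paths excluded, so relocated but
        otherwise identical runs compare equal)."""
        payload = {k: v for k, v in asdict(self).items()
                   if not (k.endswith("_path") or k.endswith("_paths")
                           or k == "out_dir")}
        blob = json.dumps(payload, sort_keys=True, default=str)
        return hashlib.sha256(blob.encode()).hexdigest()[:12]


def _header(config: PipelineConfig) -> str:
    return (f"# promquant v{__version__}\n"
            f"# config_hash={config.config_hash()}\n"
            f"# seed={config.seed}\n")


def _write_tsv(frame: pd.DataFrame, path: Path, config: PipelineConfig) -> None:
    with open(path, "w") as fh:
        fh.write(_header(config))
        frame.to_csv(fh, sep="\t", index=False, lineterminator="\n",
                     float_format="%.10g")


def write_flow_samples(samples: list[FlowSample], out_dir: str | Path) -> Path:
    """Write event CSVs plus a samples.tsv metadata sheet; returns its path."""
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    rows = []
    for s in samples:
        csv_path = out / f"{s.sample_id}.csv"
        s.events_frame().to_csv(csv_path, index=False, lineterminator="\n",
                                float_format="%.10g")
        rows.append({"sample_id": s.sample_id, "construct": s.construct_id,
                     "replicate": s.replicate, "inducer_conc": s.inducer_conc,
                     "path": csv_path.name})
    meta_path = out / "samples.tsv"
    pd.DataFrame(rows).to_csv(meta_path, sep="\t", index=False,
                              lineterminator="\n")
    return meta_path


def read_flow_samples(metadata_path: str | Path) -> list[FlowSample]:
    """Read event CSVs referenced by a samples.tsv metadata sheet."""
    meta_path = Path(metadata_path)
    meta = pd.read_csv(meta_path, sep="\t")
    samples = []
    for _, row in meta.iterrows():
        events = pd.read_csv(meta_path.parent / row["path"])
        samples.append(FlowSample.from_events_frame(
            events, sample_id=str(row["sample_id"]),
            construct_id=str(row["construct"]),
            replicate=int(row["replicate"]),
            inducer_conc=float(row["inducer_conc"])))
    return samples


def _stage(name: str):
    def deco(fn):
        def wrapped(*args, **kwargs):
            try:
                return fn(*args, **kwargs)
            except PromquantError as exc:
                raise PipelineStageError(f"stage {name!r}: {exc}") from exc
        return wrapped
    return deco


def run_pipeline(config: PipelineConfig) -> dict:
    """Execute all stages and write the run directory; returns the manifest."""
    config.validate()
    out = Path(config.out_dir)
    out.mkdir(parents=True, exist_ok=True)
    stages_done: list[str] = []

    # --- omics: summarize -> classify ---
    calls = {}
    for plat in PLATFORMS:
        matrix = pd.read_csv(config.omics_paths[plat], sep="\t", comment="#",
                             index_col="gene_id")
        dataset = OmicsDataset(platform=plat, matrix=matrix)
        summary = _stage("summarize")(summarize_dataset)(dataset)
        calls[plat] = _stage("classify")(classify_by_quantile)(
            summary, config.thresholds)
    calls_frame = pd.concat([calls_to_frame(c) for c in calls.values()],
                            ignore_index=True)
    _write_tsv(calls_frame, out / "calls.tsv", config)
    stages_done += ["summarize", "classify"]

    # --- consensus ---
    candidates = _stage("consensus")(consensus_select)(
        calls, extra_weak=list(config.extra_weak))
    _write_tsv(candidates.to_frame(), out / "candidates.tsv", config)
    stages_done.append("consensus")

    # --- promoter extraction ---
    annotation = read_gff3(config.annotation_path)
    genome = read_genome_fasta(config.genome_path)
    operons = OperonTable(pd.read_csv(config.operons_path, sep="\t"))
    contig_lengths = {c: len(s) for c, s in genome.items()}
    regions = []
    candidate_genes = sorted(
        set().union(*(candidates.members(c) for c in CLASSES)))
    for gid in candidate_genes:
        if gid not in annotation:
            continue
        anchor = _stage("extract")(resolve_anchor)(gid, operons, annotation)
        region = _stage("extract")(extract_promoter)(
            anchor, annotation, contig_lengths)
        regions.append(_stage("extract")(fetch_sequence)(region, genome))
    # one region per distinct anchor (operon members share a promoter)
    regions = list({r.anchor_gene_id: r for r in regions}.values())
    regions.sort(key=lambda r: r.anchor_gene_id)
    _write_tsv(regions_to_frame(regions), out / "promoters.tsv", config)
    write_promoters_fasta(regions, out / "promoters.fasta")
    stages_done.append("extract")

    # --- flow quantification ---
    spill = SpilloverMatrix(green_to_red=config.spillover_green_to_red,
                            red_to_green=config.spillover_red_to_green)
    samples = read_flow_samples(config.flow_metadata_path)
    groups: dict[tuple[str, float], list[FlowSample]] = {}
    for s in samples:
        s = _stage("flowquant")(compensate)(s, spill)
        s = qc_events(s, config.min_events)
        if s.qc_pass:
            groups.setdefault((s.construct_id, s.inducer_conc), []).append(s)
    measurements = [
        _stage("flowquant")(dual_ratio)(group)
        for key, group in sorted(groups.items())
    ]
    meas_frame = pd.DataFrame(
        [{"construct_id": m.construct_id, "inducer_conc": m.inducer_conc,
          "mean_green": m.mean_green, "mean_red": m.mean_red,
          "ratio": m.ratio, "sd": m.sd, "n_replicates": m.n_replicates,
          "n_events_total": m.n_events_total} for m in measurements])
    _write_tsv(meas_frame, out / "measurements.tsv", config)
    stages_done.append("flowquant")

    # --- validation ---
    report: dict = {"dose_fits": [], "correlations": {}, "class_ordering": None}
    by_construct: dict[str, list] = {}
    for m in measurements:
        by_construct.setdefault(m.construct_id, []).append(m)
    for cid, series in sorted(by_construct.items()):
        if len({m.inducer_conc for m in series}) >= 3:
            fit = _stage("validate")(linear_dose_fit)(series)
            report["dose_fits"].append(asdict(fit))

    ratios = (meas_frame.sort_values("inducer_conc")
              .groupby("construct_id")["ratio"].first())
    joined = (calls_frame.pivot_table(index="gene_id", columns="platform",
                                      values="mean_log2", aggfunc="first")
              .join(ratios.rename("ratio"), how="inner"))
    if len(joined) >= 3:
        reports = _stage("validate")(prediction_correlation)(
            joined.reset_index(), transform=config.transform)
        report["correlations"] = {p: asdict(r) for p, r in reports.items()}
        try:
            ordering = class_ordering(candidates, ratios)
            report["class_ordering"] = {"per_class": ordering.per_class,
                                        "is_monotone": ordering.is_monotone}
        except PromquantError:
            report["class_ordering"] = None
    (out / "validation_report.json").write_text(
        json.dumps(report, indent=2, sort_keys=True) + "\n")
    stages_done.append("validate")

    manifest = {
        "tool": "promquant",
        "version": __version__,
        "config_hash": config.config_hash(),
        "seed": config.seed,
        "stages": stages_done,
        "outputs": sorted(p.name for p in out.iterdir()
                          if p.name != "manifest.json"),
        "n_candidates": int(len(candidate_genes)),
        "n_measurements": int(len(measurements)),
    }
    (out / "manifest.json").write_text(
        json.dumps(manifest, indent=2, sort_keys=True) + "\n")
    return manifest


def demo_run(work_dir: str | Path, seed: int = 0, n_genes: int = 120,
             n_events: int = 2_000) -> dict:
    """Generate a small synthetic study on disk and run the full pipeline.

    Scaled down (120 genes, 2,000 events/sample) so the whole round trip —
    generation, file I/O and analysis — completes in seconds.
    """
    from . import synthetic
    from .promoters import write_genome_fasta, write_gff3
    from .study import candidate_flow_samples

    work = Path(work_dir)
    inputs = work / "inputs"
    inputs.mkdir(parents=True, exist_ok=True)

    truth = synthetic.gen_latent_strength_map(n_genes, seed=seed)
    annotation, operons, genome = synthetic.gen_annotation(
        n_genes, n_contigs=2, operon_fraction=0.3, min_gap=60,
        seed=seed + 1, gene_ids=truth.gene_ids)
    write_gff3(annotation, inputs / "genes.gff3")
    write_genome_fasta(genome, inputs / "genome.fasta")
    operons.table.to_csv(inputs / "operons.tsv", sep="\t", index=False,
                         lineterminator="\n")

    omics = synthetic.gen_omics_suite(truth, seed=seed + 2)
    omics_paths = {}
    for plat, ds in omics.items():
        p = inputs / f"omics_{plat}.tsv"
        ds.matrix.to_csv(p, sep="\t", lineterminator="\n",
                         float_format="%.6g")
        omics_paths[plat] = str(p)

    noise = synthetic.FlowNoiseParams(n_events=n_events)
    samples = candidate_flow_samples(truth, truth.gene_ids, noise=noise,
                                     seed=seed + 3)
    meta_path = write_flow_samples(samples, inputs / "flow")

    config = PipelineConfig(
        annotation_path=str(inputs / "genes.gff3"),
        genome_path=str(inputs / "genome.fasta"),
        operons_path=str(inputs / "operons.tsv"),
        omics_paths=omics_paths,
        flow_metadata_path=str(meta_path),
        out_dir=str(work / "run"),
        min_events=n_events,
        seed=seed)
    return run_pipeline(config)
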