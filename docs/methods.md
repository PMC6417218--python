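# Methods

## Quantile classification of promoter strength

Each omics platform is treated as an independent witness of promoter
strength. A platform's dataset is a genes × conditions matrix of log₂
expression (microarray), log₂ read abundance (RNA-seq) or log₂ peptide
abundance (proteomics). Per gene we take the arithmetic mean over all the
platform's conditions; genes missing from a platform are dropped from that
platform's ranking rather than imputed. Percentile rank is ascending rank
divided by *n*, with tied values receiving the mean rank of their block, so
that (for example) all proteomics values sitting at the detection floor fall
in one rank block and classify identically. Labels are assigned with
inclusive boundaries: rank ≥ 0.90 → strong, ≤ 0.10 → weak, 0.40–0.60 →
medium, otherwise unlabeled. Below 10 genes the classes are degenerate and a
warning is emitted; an all-tied vector carries no ordering information and
yields no labels.

Consensus is a strict three-way intersection: a gene is a candidate of class
*c* only if every required platform labels it *c*. Platforms are never
rescaled onto a common axis — the intersection operates on labels, so
between-platform scale differences are irrelevant. Manually chosen extra
weak genes can be appended with `manual` provenance; they bypass the
intersection by design, mirroring the practice of padding the weak class for
broader representation. We deliberately replace exploratory hierarchical
clustering with this quantile + intersection rule: it is the operational
content of a three-platform Venn selection, and it is testable.

A note on the boundary convention: with the inclusive ≥ 90th-percentile
rule, a platform with *n* divisible by 10 selects ⌊0.1·n⌋ + 1 genes (rank
0.90 itself is strong). Class-size assertions in the tests therefore allow
±1 around ⌈0.1·n⌉.

## Promoter extraction

A promoter is operationally the whole intergenic region between a gene and
the nearest preceding ORF **on either strand** (the definition speaks of
the preceding open reading frame, not the preceding same-strand gene).
Operon members resolve to the operon's first gene in transcription order
before extraction, so all members share one region. Coordinates are 1-based
inclusive GFF3 throughout; minus-strand sequences are returned
reverse-complemented. Degenerate (zero-length) gaps raise an explicit error
instead of emitting an empty record; contig-edge anchors are truncated at
position 1 or the contig end and flagged `truncated`, since no circular
topology is assumed. No maximum length cap is applied.

## Dual-reporter quantification

The strength statistic is the ratio of averaged means: per replicate the
arithmetic mean of each channel over all retained events, means averaged
across replicates, then green/red. The reported SD is the sample STDEV of
the per-replicate ratios (0, with a warning, for a single replicate);
geometric means are available behind a flag for sensitivity analysis but
the headline statistic is arithmetic. Samples must carry ≥ 20,000 events to
pass QC — the boundary is inclusive — and failing samples are flagged and
excluded rather than raising. Spillover compensation inverts the 2×2
mixing matrix per event; small negative corrected values are clamped to
zero and counted. Compensation defaults to the identity matrix: whether
published ratios were computed on compensated or raw red signal is not
stated, so uncompensated is the default and a matrix is supplied
explicitly when known. Background (empty-vector autofluorescence)
subtraction is not applied by default for the same reason.

RBS strength is the induced ratio minus the uninduced (0 µg/mL) ratio of
the same construct; negative values are preserved, since a weak RBS can
fall within noise of its baseline.

## Synthetic data: what it emulates

The generators produce inputs with the statistical structure the analysis
assumes, from a known ground truth, so every stage can be scored by
parameter recovery.

**Latent truth.** Each gene has a latent strength on the log₂ expression
scale. Planted classes are well separated: strong ~ U(13, 16), weak ~
U(3, 5), background ~ U(6.5, 12.5), with an optional pinned medium band
U(9.2, 9.8). With 10% strong / 10% weak the planted sets occupy the outer
deciles exactly.

**Omics.** Observed value = latent + platform offset + condition effect +
Gaussian noise. Defaults: 109 / 8 / 4 conditions for microarray / RNA-seq /
proteomics; offsets 0 / −4.5 / −7.5 so strong genes sit near 15 / 11 / 8
log₂ units, the scales seen in the packaged reference table; noise SD
0.5 / 0.5 / 0.7 (proteomics is the noisiest, smallest-n platform);
condition effects N(0, 0.3) shared across genes within a column. Proteomics
is left-censored at 0.07: values below the floor are reported at the floor,
reproducing the uniform floor value carried by every weak promoter in the
reference table. The generator does not emulate platform-specific
mean–variance relationships, batch structure beyond a per-condition shift,
or cross-platform sample correlation, so passing recovery tests demonstrate
the pipeline's logic under its stated assumptions, not robustness to those
real-data complications.

**Flow events.** One event is one cell:

    C_i     ~ lognormal, mean 1, CV = copy_number_cv
    green_i = C_i · g(conc) · green_strength · (1 + ε_g) + af_g
    red_i   = C_i · red_strength · (1 + ε_r) + af_r + s · green_i

with ε ~ N(0, channel_noise_cv) independent per channel, af ~
Exponential(autofluor_mean), and s the green→red spillover fraction. The
lognormal-multiplicative form is a modeling choice (no noise model is
published for these measurements) motivated by the log-displayed single-mode
fluorescence distributions typical of such data; the copy-number factor is
deliberately common to both channels because that shared nuisance is what
the ratio is meant to cancel. Defaults: copy_number_cv 0.25,
channel_noise_cv 0.05, autofluor_mean 5 AU, spillover 0, n_events 20,000
(the QC floor). The dose response is strictly linear, g(conc) = baseline +
slope·conc with defaults 0.2 + 2.0·conc over the 0–1.0 µg/mL grid in 0.2
steps — linearity is only claimed inside this window, so no saturating
(Hill) term is modeled. Forward/side scatter, doublets and instrument FCS
binary output are out of scope.

All generators take an explicit integer seed, use one `numpy` Generator per
call, and are byte-deterministic; there is no global RNG state.

## End-to-end study conditions

The recovery study (`promquant.study.run_synthetic_study`) uses 1,000 genes
with 10% planted strong and weak and a 10% pinned medium band, default
omics noise, and triplicate flow samples of 20,000 events for every
consensus candidate. The flow coupling is exact in log space: green
strength = 6.25 · 2^latent AU against a fixed red strength of 102,400 AU,
placing the weakest construct (~50 AU) well above the autofluorescence
floor and true ratios in the 10⁻⁴–0.6 range. Scored quantities: precision
and recall of consensus strong/weak against the planted sets, per-platform
Spearman ρ between predicted mean log₂ and measured ratio, and the
strong > medium > weak ordering of measured class means. Ten seeds of this
study, plus the fixture statistics, classifier-oracle comparison,
copy-number-cancellation sweep, compensation round trip, dose fit and
extraction invariants, are what `scripts/acceptance.py` recomputes;
together they run in well under a minute on one CPU.

The copy-number cancellation sweep fixes channel noise at CV 0.05 and turns
autofluorescence off, isolating the cancellation claim from the unrelated
additive-background bias; the compensation round trip compares compensated
spillover data against an independently seeded spillover-free run, within
three Monte-Carlo standard errors of the difference of means.

## Numerical and design choices

- Degenerate OLS (zero ratio variance) reports slope 0, r² 0 with a
  `degenerate` flag instead of NaN; zero concentration variance is an error.
- Correlations are reported as Pearson r, r² = r², and Spearman ρ, on
  either the raw ratio or (default) the log₂ ratio; Spearman is invariant
  to this monotone choice, which the tests assert. No p-values are
  attached.
- The published reference tables are packaged as TSV with SHA-256
  integrity checks and schema invariants (row count 38, class counts
  19/9/10, exactly one row without omics values) enforced at load time.
- Pipeline outputs carry a header with the tool version, a hash of the
  analysis settings (paths excluded) and the seed; identical settings +
  seed reproduce byte-identical files.
- The package is organised as a library with narrative example scripts
  rather than a subcommand CLI; `pipeline.run_pipeline` /
  `pipeline.demo_run` provide the orchestrated file-based entry points.

## Known limitations

- Consensus requires exact label agreement on all three platforms; there is
  no two-of-three relaxation (configurable via `required_platforms`).
- The synthetic omics model is additive-Gaussian in log space with a single
  censoring mechanism; count-based noise for RNA-seq and peptide sampling
  for proteomics are not modeled.
- Flow simulation has no scatter channels, so no scatter gating is
  reproduced; the only QC is the event-count rule.
- Measured-vs-predicted correlation magnitudes on the packaged table are
  rank-based checks only; the exact transform and sample set behind the
  published figure-level R² values are not recoverable from the printed
  data, so they are not asserted.
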