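# promquant

Omics-driven prediction and dual-reporter flow-cytometry quantification of
bacterial promoter and ribosome-binding-site (RBS) strength.

## The problem

Metabolic engineering of bacteria such as *Zymomonas mobilis* needs promoters
and RBSs of graded, known strengths, but most native regulatory elements have
never been quantified. Two ideas make systematic characterization tractable:

1. **Predict from accumulated omics data.** The strength of a promoter is
   approximated by the expression of its downstream gene. Within each
   platform (microarray, RNA-seq, proteomics) genes are summarised by their
   mean log₂ expression across conditions and ranked; genes at or above the
   90th percentile are called *strong*, at or below the 10th *weak*, and in
   the 40–60% band *medium*. Candidates are the genes whose label agrees on
   **all** platforms (a Venn-style intersection). Because operon-internal
   genes have no promoter of their own, each candidate is resolved to its
   operon lead, and the promoter is taken as the entire intergenic region
   between that anchor and the preceding open reading frame.

2. **Measure with a ratiometric dual reporter.** A plasmid carries *EGFP*
   under the element being tested and *opmCherry* under a constitutive
   promoter as an internal calibration. For a flow-cytometry sample of
   ≥ 20,000 events, the strength readout is

   ratio = mean(EGFP) / mean(opmCherry),

   averaged over triplicates with the across-replicate STDEV as the error.
   Per-cell plasmid copy number and other shared noise multiply both
   channels and cancel in the ratio. Spillover of green signal into the red
   detector is corrected by inverting a 2×2 spillover matrix. For inducible
   elements, strength is linear in inducer concentration over 0–1.0 µg/mL
   tetracycline, and an RBS's relative strength is the induced ratio minus
   the uninduced ratio.

The package implements both halves plus the synthetic-data generators needed
to test them by parameter recovery, and ships the published reference tables:
38 characterized candidate promoters (19 strong / 9 medium / 10 weak, with
measured ratios in exponential and stationary phase) and 4 synthetic RBSs
with predicted translation initiation rates 10 / 1,000 / 10,000 / 15,000.

## Worked example

```bash
python examples/04_dual_reporter_ratio.py
```

```
true strength ratio: 0.380
copy-number CV 0.00: mean green   379.8 AU, ratio 0.3797 +/- 0.0002  (bias -0.09%)
copy-number CV 0.25: mean green   378.8 AU, ratio 0.3800 +/- 0.0001  (bias -0.00%)
copy-number CV 0.50: mean green   377.3 AU, ratio 0.3800 +/- 0.0001  (bias -0.01%)
```

Even when the per-cell plasmid copy number varies with a CV of 0.5 — enough
to shift any single-channel mean — the triplicate EGFP/opmCherry ratio stays
within 0.1% of the true strength 0.38: the shared copy-number factor cancels
in the ratio of channel means.

The other examples each exercise one capability: `01` class ordering and
rank correlation on the packaged promoter table, `02` quantile
classification + consensus, `03` operon-aware promoter extraction, `05`
dose-response fitting and RBS relative strength, `06` the full
1,000-gene end-to-end recovery run. For a file-based pipeline run with
stable output contracts (`calls.tsv`, `candidates.tsv`, `promoters.tsv`,
`measurements.tsv`, `validation_report.json`, `manifest.json`):

```python
from promquant.pipeline import demo_run
demo_run("runs/demo", seed=0)
```

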