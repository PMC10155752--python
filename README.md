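# spgkit

Analysis toolkit for **dual-analyte spatial profiling**: experiments that
read out whole-transcriptome RNA and a high-plex antibody (protein) panel
simultaneously from the same areas of interest (AOIs) on a single tissue
section, as barcode-count matrices. It is written for computational
biologists who need to QC such data, normalize it against its built-in
controls, benchmark a dual-analyte run against single-analyte controls, and
test for differential expression between tissue segments.

## What it computes

Every AOI carries its own background estimate from control probes —
negative ISH probes for RNA, IgG isotype antibodies for protein. With
geometric mean and geometric SD over those controls in AOI *i*:

* **Limit of quantification**: LoQ_i = geomean_i · geosd_i², floored at 2;
  a gene is detected when its count exceeds LoQ_i.
* **Signal-to-noise ratio**: SNR_gi = count_gi / geomean_i(controls), the
  normalized expression used everywhere downstream (detection thresholds:
  protein SNR ≥ 3, RNA SNR ≥ 4).
* **Detection filters**: AOIs with < 5% of genes above LoQ are dropped,
  then genes detected in ≤ 15% of AOIs (or, in the stricter profile, below
  LoQ in ≥ 10% of AOIs) are dropped.
* **Assay benchmarking**: Pearson concordance of log2 SNR profiles,
  max-correlation identity matching of cell lines, detection TPR/FPR
  against an expressed-gene truth set (reference expression > 1), and
  sensitivity loss measured as the average change in the regression slope
  of log2 SNR between a test assay and its control.
* **Differential expression**: per-target Welch t-tests, or a linear mixed
  model log2 SNR ~ segment + (1 | tissue) with REML and Satterthwaite
  degrees of freedom for repeated sampling of segments per tissue;
  Benjamini–Hochberg adjustment within analyte; significance tiers
  (P < 0.05 / FDR < 0.05 / FDR < 0.001) and a combined RNA+protein volcano
  table.

Because public data for this assay family is unavailable, the package ships
a first-class synthetic-data generator (`spgkit.simulate`) producing
cell-pellet-array and segmented-tissue designs with a complete
planted-truth manifest, so every stage is testable against known ground
truth. See `docs/methods.md` for the models and their assumptions.

## Worked example

Simulate a 12-cell-line paired experiment (single-analyte controls plus the
dual-analyte condition) and run the full pipeline:

```bash
cat > run.yaml <<EOF
seed: 7
simulate:
  kind: cpa
  cpa: {n_cell_lines: 12, n_genes: 100, n_proteins: 40, n_negprobes: 20}
EOF
spgkit run --config run.yaml --out out/
```

The run logs each stage (`simulate → qc → shift → loq → snr → detect →
filter → concordance`) with its dimensions and writes `out/metrics.json`:

```json
{
  "max_r_match_accuracy_protein": 1.0,
  "max_r_ties": 0,
  "mean_fpr_rna": 0.0,
  "mean_matched_r_protein": 0.9114759008980471,
  "mean_tpr_rna": 0.5914684400267924,
  "sensitivity_percent_change_protein": 11.43190155650725,
  "sensitivity_percent_change_rna": 11.44886957869259
}
```

Reading the numbers: every cell line in the dual-analyte run is matched to
itself in the protein control by maximum correlation (accuracy 1.0, mean
matched r ≈ 0.91); no gene that the truth set calls unexpressed is detected
(FPR 0), while ~59% of expressed genes clear the SNR ≥ 4 threshold at this
sequencing scale; and the dual-analyte condition shows an ~11% sensitivity
loss per analyte relative to its single-analyte control — the generator
planted attenuations of 0.89 (protein) and 0.85 (RNA), and the slope metric
also carries its intrinsic regression-dilution offset (see
`docs/methods.md`).

`out/` also contains the simulated counts/annotations per condition, the
truth manifest, LoQ and SNR tables, QC and filter reports, the correlation
matrix and `manifest.json` echoing every defaulted parameter. Rerunning the
same config and seed reproduces every file byte for byte.

For a segmented-tissue study with mixed-model differential expression:

```bash
spgkit run --config tissue.yaml --out out_tissue/   # simulate: {kind: tissue}
```

which writes `de.tsv` (target, analyte, log2FC, p, FDR, tier, variance
components) and a combined volcano table. The same steps are available as
library functions (`spgkit.simulate_cpa`, `compute_loq`, `snr_normalize`,
`filter_segments`, `mixed_model_de`, ...) and as standalone subcommands
(`spgkit simulate|normalize|filter|de`).

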