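# peakqc

Automated quality control of chromatographic peaks in targeted
mass-spectrometry (MRM/PRM/SRM) experiments.

## The problem

Targeted proteomics quantifies peptides by monitoring transitions —
(peptide precursor, fragment ion) pairs — over chromatographic time, with a
spiked stable-isotope-labelled (SIL, "heavy") standard co-eluting with each
endogenous ("light") peptide. Before any number is reported, an analyst
inspects every chromatographic peak for interference, co-elution
violations, bimodality, tailing, noise, background and weak standard
signal. On studies with tens of peptides and dozens of runs this manual
review takes days, requires trained analysts, and drifts between operators.

`peakqc` replaces most of that inspection with a supervised pipeline:

1. **Features** — 32 engineered QC metrics in 9 groups (jaggedness,
   similarity, symmetry, FWHM, modality, shift, intensity, area ratio,
   retention time) computed at four levels (single transition, isotope,
   endogenous/standard pair, whole peak group). Label-specific metrics are
   evaluated for both isotopes, giving a 52-entry descriptor per transition
   pair.
2. **Training set** — chromatograms, peak boundaries and a small set of
   analyst `ok`/`flag` annotations are merged; pairs without an isotope
   partner and groups without boundaries are filtered out with full
   accounting.
3. **Model** — five classifier families (regularized logistic regression,
   regularized random forest, KNN, linear and polynomial SVM) are tuned by
   stratified run-grouped 10-fold cross-validation repeated 3 times; the
   family with the best cross-validated accuracy (or ROC AUC) is selected
   and applied to the whole dataset. A pair is flagged when its `flag`
   class probability reaches the cutoff (default 0.5).
4. **Report** — per-peptide fragment × run status heatmaps, flag rates,
   systematically flagged transitions and marginal cases near the decision
   boundary.

A built-in simulator generates multi-run datasets of exponentially-modified
Gaussian peak groups with a menu of controllable defects and ground-truth
labels, so the whole pipeline is testable without instrument data.

## Key definitions

For a boundary-clipped intensity vector \(I_1..I_n\):

* **jaggedness** = (# interior points where the first difference changes
  sign, excluding the apex) / (n − 2); flat steps inherit the previous
  direction. 0 for a smooth peak.
* **similarity** = Pearson correlation between two co-eluting traces.
* **symmetry** = correlation of the first half against the reversed second
  half (odd midpoint excluded); 1 for a mirror-symmetric peak.
* **modality** = max interior dip, `min(runmax_left, runmax_right) − I_i`,
  normalized by peak height; 0 when strictly unimodal.
* **FWHM** — full width at half max (zero baseline, linear interpolation),
  plus its ratio to the base width.
* **shift** = |apex − median(co-eluting apexes)| / base width.
* **pair ratio consistency** = |transition area fraction (endo) −
  transition area fraction (std)|; interference indicator.

## Worked example

Simulate a 6-run, 12-peptide panel (both isotope labels, 4 transitions per
peptide), train on its annotations, and QC the whole dataset:

```bash
peakqc simulate --out data --seed 42 --runs 6 --peptides 12
# wrote 576 traces, 288 pairs (90 flagged) to data

peakqc train --chromatograms data/chromatograms.tsv \
             --boundaries data/boundaries.csv \
             --annotations data/annotations.csv \
             --out trained --seed 42
# selected svm_linear: validation accuracy 0.983, sensitivity 0.944,
# specificity 1.000, AUC 1.000 (n=58)

peakqc predict --model trained/model \
               --chromatograms data/chromatograms.tsv \
               --boundaries data/boundaries.csv --out qc
# 288 pairs scored, 89 flagged (threshold 0.5)
```

`trained/model_comparison.csv` ranks all five families by cross-validated
accuracy (here linear SVM at 0.996 edges out logistic regression and the
regularized random forest at 0.992); the winner is archived in
`trained/model/`. `qc/predictions.csv` holds one row per transition pair
with its flag probability and verdict; `qc/qc_summary.csv` gives per-
fragment flag rates and marks transitions flagged in at least half the
runs as systematic; `qc/report.html` renders the per-peptide heatmaps. The
sensitivity figure (0.944) is the fraction of genuinely poor pairs caught
— `flag` is the positive class throughout.

The same steps are available as library calls (`peakqc.simulate_dataset`,
`peakqc.merge_and_filter`, `peakqc.compare_models`, `peakqc.predict`,
`peakqc.summarize`); the CLI is a thin wrapper.

## Layout

```
src/peakqc/
  datamodel.py   core types: traces, peak groups, transition pairs
  io_skyline.py  chromatogram/boundary/annotation table IO (dialect-configurable)
  features.py    the 32-metric registry and 52-entry vector assembly
  trainset.py    merge + filters + annotation join
  model.py       training, tuning, selection, prediction, diagnostics
  simulate.py    EMG peak-group simulator with defect menu + ground truth
  report.py      summaries, heatmap report (HTML/PDF)
  cli.py         peakqc simulate|features|train|predict|report
docs/methods.md  models, parameters, assumptions, limitations
```
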