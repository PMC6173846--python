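# Methods

This note documents the models, numerical choices and assumptions behind
`peakqc`, in the spirit of a package vignette: what is computed, why the
defaults are what they are, and what passing the test suite does and does
not demonstrate.

## Coordinate conventions

Retention times are minutes; intensities are non-negative detector counts
on an arbitrary scale. A trace is identified by the 6-tuple (run, modified
peptide sequence, precursor charge, fragment ion, product charge, isotope
label). The modified sequence is kept verbatim — keys must round-trip
through the input files, so no normalization of modification notation is
attempted. Peak boundaries are closed intervals set per peptide per run
and shared by every trace of the peak group; samples exactly on a boundary
are included. All shape features are computed on the boundary-clipped
region on the sampled grid as-is: no resampling, no smoothing, no
background subtraction, zero baseline. This matches how exported
chromatogram points are integrated in practice and keeps every feature a
pure function of the exported data.

## The feature registry

The registry is a declarative table of 32 metrics in 9 groups at 4 levels:

| level | entries | label-specific |
|---|---|---|
| transition (one trace) | 12 | yes |
| isotope (all fragments of one label) | 8 | yes |
| transition pair (endo vs std of one fragment) | 7 | no |
| peak group (all traces) | 5 | no |

Because the classification unit is the endogenous/standard pair, the 20
label-specific metrics are evaluated twice (`.endo`, `.std`), giving
32 + 20 = 52 model inputs in a fixed documented order. The registry is
data-driven so individual definitions can be revised without touching the
assembly code; the exact composition of the four levels is this package's
design choice, reconstructed from the in-text definitions of each metric
group.

Numerical details worth recording:

* **jaggedness** — zero first-differences inherit the previous non-zero
  sign (leading zeros take the first real direction), so integer plateaus
  do not inflate the score. The apex is the *first* global maximum and is
  excluded only when interior. Consequence: a peak with a flat apex
  plateau registers its single down-turn on the plateau's trailing point
  (score 1/(n−2), not 0); genuine smooth peaks score exactly 0.
* **modality** — dip at point *i* is
  `min(runmax_left_i, runmax_right_i) − I_i` with inclusive running
  maxima; the score is the largest interior dip over peak height. This is
  the only construction that is exactly 0 for every strictly unimodal
  vector. For `[0,3,1,2,0]` the deepest valley sits 1 below the smaller
  flanking maximum, so the score is 1/3.
* **FWHM** — half-max is max/2 against a zero baseline; leftmost/rightmost
  crossings are linearly interpolated. A side that never drops below
  half-max falls back to its boundary; if the signal never crosses at all
  (plateau), FWHM = base width and the ratio is 1, with a warning. The
  ratio is clipped to [0, 1].
* **symmetry** — correlation of mirrored halves rather than area skew:
  consistent with the correlation-based similarity family and exactly 1.0
  on mirror-symmetric peaks. Odd-length midpoints are excluded.
* **apex** — index of the global maximum, earliest index on ties.

"Consistency" metrics need a cross-run reference. A `PeakContext`
accumulates, per (peptide, fragment, charge, label), the median apex RT,
median FWHM, median transition area fraction (area of a fragment over the
summed fragment areas of its label) and its cross-run CV, and per fragment
the median endo/std area ratio and the per-run areas (for the cross-run
endo-vs-std area correlation, which requires ≥ 3 shared runs). Medians are
taken over **all** runs, flagged or not, because quality status is unknown
at feature time.

A metric that cannot be computed (too few points, constant trace, zero
peak, singleton group, zero denominator) is carried as missing (NaN with a
mask bit), never silently zero: zero is a meaningful score for most
features. Missing entries are imputed at model time only.

## Training-set assembly

Boundaries are joined per (run, peptide); groups with no (or blank)
boundary rows are dropped, as are fragments lacking either isotope label —
each with per-filter counts surfaced in the output. Valid but unannotated
pairs are kept in a separate pool so the same merge serves training and
whole-dataset prediction. Statuses are case-insensitive `ok`/`flag`;
anything else is a hard error (the model is strictly binary). Output rows
are sorted by key, making the merge deterministic.

## The classifier

Flag is the positive class everywhere: sensitivity is the rate at which
genuinely poor peaks are caught, the quantity that matters most, since
wrongly flagging a good peak costs a minute of review while passing a bad
peak corrupts a reported concentration.

Pipeline per family: median imputation → mean-centering/unit-variance
scaling → classifier, all statistics fit on training data only (a
construction test asserts the stored statistics change when validation
rows are added). Zero-variance and all-missing features are dropped and
recorded on the model. Hyper-parameters are tuned by 10-fold
cross-validation repeated 3 times over fixed grids (logistic C ∈
{0.01, 0.1, 1, 10}; forest importance-floor ∈ {0.01, 0.05} ×
max-features ∈ {√p, 0.3p}; KNN k ∈ {3, 5, 7, 11, 15}; SVM C ∈
{0.1, 1, 10}, polynomial degree ∈ {2, 3}). Folds are stratified by class
and, by default, grouped by run — all pairs of one run share
chromatography and must not straddle a fold; with fewer runs than folds
the fold count drops to the run count. Ungrouped folds are a config
toggle.

The **regularized random forest** is implemented as an importance-floor
selection pass: a first forest is fit, features below `floor × max
importance` are dropped, and the forest is refit on the survivors. This
preserves the intent of regularization-by-simplification with a mechanism
that is explicit and testable.

`compare_models` trains every family on identical folds, ranks by the
cross-validated metric (accuracy by default; ROC AUC recommended for
imbalanced sets) and breaks exact ties by the fixed order forest > KNN >
polynomial SVM > linear SVM > logistic. The threshold on the flag
probability defaults to 0.5, flagging at exactly the cutoff; ROC analysis
emits a per-cutoff sensitivity/specificity table for users who want to
trade false positives for false negatives. Marginal cases are predictions
with probability in [0.35, 0.65], sorted by distance from 0.5.
`feature_importance` is permutation importance (algorithm-agnostic, hence
defined for every family), normalized to max = 100; it takes the rows to
permute as an argument since permutation importance is undefined without
data. The learning curve resamples run subsets without replacement,
trains on the sampled runs and scores the held-out runs, reporting a
normal-approximation 95% CI over resamples (undefined at one repeat).

Everything downstream of one integer seed — splits, folds, tuning, fits,
predictions — is bit-reproducible.

## The simulator

Each peptide elutes as an exponentially-modified Gaussian: σ = 0.06 min
(FWHM ≈ 0.14 min, typical of 60-min nano-LC gradients), intrinsic tail
τ = 0.3 σ, apex drawn uniformly over a 10–50 min window. The default
design mirrors a scheduled-MRM biomarker panel: 36 peptides × 4 fragments
(144 transitions) × 2 isotope labels × 8 runs, sampled every 0.015 min
(~1 s cycle), endogenous peak heights lognormal around 1e5 counts with
heavy standards spiked 3× higher, per-run intensity factor lognormal
(CV ≈ 10%), per-run RT jitter 0.005 min SD. Boundaries sit at apex ± 4 σ.
Baseline detector noise is 0.5% multiplicative plus a 2-count additive
floor, keeping clean-peak jaggedness near zero (mean < 0.05).

Defects are drawn per (run, peptide, fragment) and applied in the fixed
order tailing → rt_shift → bimodal → interference → background → jagged →
low_standard, so composed defects are reproducible. Chromatographic
defects (tailing, bimodal, jagged, background, rt_shift) hit both labels
of a fragment — light and heavy co-elute through the same column;
interference hits the endogenous trace only (the standard is spiked pure),
and low_standard divides the heavy intensities of a whole peptide group.
Default magnitudes are set at visibly-flaggable levels (e.g. 15% noise CV,
second mode at 40% of the base width with height 0.5× apex, tail constant
4× σ, interferent at 0.6× apex, background 15% of apex, 0.08-min apex
displacement, 30× standard attenuation) with per-instance ×U(0.8, 1.25)
jitter; default probabilities put roughly a third of pairs in the flag
class, the prevalence seen in annotated MRM training sets. Ground truth
labels a pair `flag` iff any applied defect reaches its explicit
`visible_threshold`, so the gray zone between visible and invisible
defects is a controllable experimental variable, not a hidden rule.

The `simulate_feature_table` generator produces the tabular counterpart
used to validate the *learner* in isolation: flag status is a noisy
threshold on two informative standard-normal features (sum plus N(0, 0.1)
annotation noise against 0), plus uninformative columns. The noise level
puts the Bayes-optimal rule near 98% accuracy — the regime reconciled
analyst annotations operate in (pre-reconciliation inter-analyst agreement
is typically 80–95%, and models trained on reconciled labels reach the
mid-90s). At 400 training pairs every competent family recovers the rule
to well above 90% validation accuracy, sensitivity and specificity.

**What the simulator does not emulate:** detector saturation, scheduling-
window truncation, correlated defects across peptides within a run (real
matrix effects hit many peptides at once), drifting retention time over a
study, heteroscedastic noise at the limit of quantitation, and annotator
bias that correlates with peak intensity. Passing tests on simulated data
therefore demonstrates that the features respond to the defect physics
they were designed for and that the pipeline is correct and reproducible —
not that a model trained here transfers to any particular instrument or
matrix. On real data the model must be retrained per panel and matrix;
models trained in a simple matrix are known not to transfer to complex
ones.

## Problem sizes in the test suite

Tests run on scaled-down designs chosen to keep the statistical checks
meaningful at desk scale: 4-run × 8–13-peptide datasets (~130–210 pairs)
for feature/defect properties, 200 forced-defect pairs for the
defect-alignment checks, 500-pair tables (400 training) across 5 seeds
for model recovery, and a 4-run × 36-peptide panel (576 pairs) for the
training-set size contract. The full-pipeline determinism check runs the
simulate → features → train → predict chain twice end to end.

## Known limitations

* The 32-entry registry is a reconstruction from the in-text metric
  definitions; individual formulas (e.g. shift normalized by base width
  rather than FWHM, untransformed intensity features) are registry entries
  that can be swapped without code changes.
* Peak-group aggregates span both labels jointly; per-label aggregates
  live at the isotope level.
* Boundaries are forced equal across the light/heavy traces of a peptide;
  exports with label-specific boundaries are not representable.
* No boundary re-optimization: flagged peaks are returned to the analyst,
  not re-integrated.
* Probabilities are used as ranked scores; no calibration (Platt/
  isotonic) is applied, so thresholds other than 0.5 should be chosen from
  the ROC table, not interpreted as calibrated risks.
* `SVC(probability=True)` Platt scaling is scheduled for removal in a
  future scikit-learn; the pinned-version behaviour is exercised in tests.
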