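# Methods

This document describes the model implemented by `sersdx`, its parameters and
numerical choices, what the synthetic cohort generator does and does not
capture, and the known limitations of the workflow.

## Overview

`sersdx` implements a label-free serum SERS (surface-enhanced Raman
spectroscopy) diagnostic workflow for parotid gland tumors. Serum spectra from
four groups — pleomorphic adenoma (PA), Warthin tumor (WT), mucoepidermoid
carcinoma (MEC), and healthy controls (Normal) — are preprocessed, compared
band-by-band via difference spectra, and classified with a two-step RBF-SVM
protocol evaluated under two cross-validation schemes.

The workflow has five stages:

1. **Acquisition / simulation** — read real two-column spectra via a cohort
   manifest, or simulate a cohort with a generative model (below).
2. **Preprocessing** — quality control, baseline removal, smoothing,
   normalization.
3. **Difference analysis** — group mean spectra, tumor-minus-Normal difference
   spectra, signed peak detection, band assignment.
4. **Classification** — six binary RBF-SVM tasks in two steps, jackknife
   hyperparameter tuning, LOSO and LOPO cross-validation.
5. **Reporting** — metric tables (SP/SE/ACC/MCC) and plain-text artifacts.

## Spectral representation

Spectra live on a uniform wavenumber grid, by default 200–1800 cm⁻¹ with a
2 cm⁻¹ step (801 points). Each spectrum carries metadata: spectrum id, patient
id, group label, an ordered list of preprocessing states, and QC flags. A
cohort additionally maintains a patient→group map; a patient may never appear
in two groups.

## Band catalogue

A catalogue of 16 Raman bands (each a wavenumber interval with a molecular
assignment: hypoxanthine at 723–727 cm⁻¹, thymine at 744–747 cm⁻¹, protein,
lipid and nucleic-acid modes, …) underpins both the synthetic generator and
peak assignment. Per tumor group, *effect lists* record which band positions
are increased or decreased relative to Normal serum. One WT effect position
(450 cm⁻¹) has no catalogue entry and is reported as `unassigned`.

## Synthetic cohort generator

Because the original cohort data are not public, the package ships a
generative model used for all end-to-end validation:

- **Design.** Default: 20/21/19/31 patients (PA/WT/MEC/Normal) contributing
  101/105/95/153 spectra; each patient contributes 4–6 replicate spectra, with
  a seeded adjustment step matching the exact per-group totals.
- **Peaks.** Each catalogue band is a pseudo-Voigt profile (FWHM 12 cm⁻¹,
  Lorentzian fraction 0.5) at the entry's center wavenumber, with a fixed base
  amplitude per band (hypoxanthine dominant). Group effects act purely on
  amplitude: an *increased* band's amplitude is multiplied by `effect_size`
  (default 1.5), a *decreased* band's divided by it. `effect_size = 1` yields
  a null cohort with no group differences.
- **Patient effect.** A log-normal amplitude multiplier
  `exp(patient_sd · N(0,1))` shared by all of a patient's spectra
  (default `patient_sd = 0.2`) — this is what makes LOPO harder than LOSO.
- **Baseline and noise.** A per-spectrum random positive degree-4 polynomial
  baseline (Chebyshev coefficients, rescaled; amplitude 300) plus white
  Gaussian noise (`noise_sd = 2`). Intensities are clipped at zero.
- **Artifacts.** `inject_saturation` clamps a random contiguous region of a
  random subset of spectra to a ceiling, flagging them, to exercise QC.

**Scope.** The generator reproduces the *structure* of the problem — band
positions, signed group effects, patient-level amplitude correlation,
baselines, noise, replicate design — not the absolute photophysics of a SERS
substrate. Band shapes, amplitudes and the baseline family are stylized;
quantitative accuracies obtained on synthetic cohorts characterize the
pipeline, not real serum.

## Preprocessing

Applied in a fixed order, each stage recorded in the spectrum's state list
(re-running a stage raises an error):

1. **Quality control.** Reject spectra with non-finite samples, and spectra
   with a saturation plateau: a run of ≥ 12 consecutive points at ≥ 0.99 × the
   cohort-wide intensity maximum.
2. **Baseline removal.** Iterative modified polynomial fitting: fit a
   degree-4 polynomial (least squares on x rescaled to [−1, 1]), clip the
   spectrum to the fit, refit until convergence (max-change tolerance 1e-6,
   ≤ 100 iterations). The corrected spectrum is clipped at zero. Pure
   polynomial backgrounds of degree ≤ 4 are removed to numerical precision
   (asserted by tests).
3. **Smoothing.** Savitzky–Golay filter, window 11, polynomial order 3,
   `mode='interp'`. Polynomials of degree ≤ 3 pass through unchanged
   (asserted); white-noise variance is reduced by > 20 % on average.
4. **Normalization.** Default: unit area (trapezoidal integral over the full
   axis). Alternatives: unit Euclidean norm (`vector`), min–max. All modes are
   invariant to overall intensity scale (asserted).

## Difference analysis

- **Group mean** with per-point standard deviation (ddof = 1; ≥ 2 spectra
  required).
- **Difference spectrum**: tumor mean minus Normal mean.
- **Signed peak detection**: local maxima of the difference (increases) and
  of its negation (decreases) via `scipy.signal.find_peaks`, with minimum
  separation 8 cm⁻¹ and prominence threshold 8 × a robust noise scale
  (1.4826 × median absolute deviation of the difference around its median).
  The 8σ multiplier was calibrated once on the generator *before* the
  acceptance tests were written: null cohorts (effect 1) produce essentially
  no hits while all generator effect bands are recovered at default settings.
- **Assignment**: each hit is matched to the nearest catalogue band within a
  3 cm⁻¹ tolerance, else `unassigned`.

Note on area normalization: multiplying some bands changes the total area, so
normalization rescales *all* bands; non-effect bands can therefore appear as
genuine (usually opposite-signed) difference peaks. This is a property of the
normalization convention, not a detector false positive.

## Classification

- **Tasks.** Step 1: Normal vs PA, Normal vs WT, Normal vs MEC. Step 2:
  PA vs WT, PA vs MEC, WT vs MEC. Features are the preprocessed intensity
  vectors (801 dimensions).
- **Model.** Support vector machine with RBF kernel (precomputed kernels via
  scikit-learn `SVC`).
- **Tuning.** Jackknife (leave-one-spectrum-out) grid search over
  C ∈ 2⁻⁵…2¹⁵ and γ ∈ 2⁻¹⁵…2³ (stride 2² each). γ values are *scale-relative*
  by default: multiplied by 1/(n_features · Var(X)) so the same grid works
  across normalization conventions. Ties break toward the smallest C, then γ.
  Leave-one-out is computed exactly but cheaply: removing a non-support
  vector cannot change the solution, so only support vectors are refit.
- **Class weights.** Prior-correction weights computed **once from the full
  task's class sizes** and held fixed across CV folds. Fold-wise re-balancing
  (sklearn's `class_weight='balanced'` evaluated per training fold) is
  deliberately avoided: removing the held-out spectrum or patient makes its
  class the training minority, and re-weighting then systematically favors
  exactly the held-out class — with equal class sizes this turns LOO into an
  oracle that scores perfectly even on pure noise.
- **Evaluation.** Two schemes: LOSO (leave-one-spectrum-out) and LOPO
  (leave-one-patient-out, all spectra of one patient held out together). A
  runtime guard asserts train and test patient sets never intersect. LOPO
  folds whose training portion lacks a class are skipped with a warning and
  reported. Confusion counts are pooled over folds.
- **Tuning protocol.** Default is optimize-once per task (tune on the full
  task, then cross-validate with the chosen pair). Nested per-fold re-tuning
  is available via `ModelConfig(reoptimize_per_fold=True)`.
- **Metrics.** Specificity tn/(tn+fp), sensitivity tp/(tp+fn), accuracy, and
  Matthews correlation (0 when a marginal is zero). For reconstructing
  metrics from published SE/SP percentages, counts are recovered as
  rate × class size rounded half away from zero.

## Numerical choices

- Baseline fitting uses `numpy.polynomial` least squares on x ∈ [−1, 1] for
  conditioning; convergence by maximum absolute change of the fit.
- Display rounding is half-away-from-zero (percentages to 1 decimal, MCC to
  3 decimals); stored CSVs keep 6 decimals; cohort round-trips use `%.17g`
  (exact for doubles).
- All stochastic components flow from a single integer seed through
  `numpy.random.default_rng`; identical seeds give bit-identical cohorts and
  identical metric tables.

## Limitations

- **Synthetic validation only.** No real serum data are included; every
  accuracy reported by the tests and the acceptance script is a property of
  the generator + pipeline combination.
- **Optimize-once selection bias.** Under optimize-once tuning, the outer
  LOSO accuracy equals the inner jackknife maximum over the grid, so LOSO
  estimates carry an upward selection bias visible even on null cohorts
  (the maximum of many chance-level grid cells exceeds 0.5). Nested tuning
  removes this at substantially higher cost.
- **LOO on exactly balanced classes is pathological.** With artificially
  equalized class counts, the held-out sample's class is always the training
  minority; class-sensitive learners are then biased away from chance in
  either direction (oracle behaviour with fold-wise re-balancing,
  anti-learning without). The null-cohort acceptance test therefore uses the
  reference design's unequal group sizes, where class counts are generically
  unequal.
- **LOSO optimism under patient structure.** With a patient-level amplitude
  effect, LOSO lets the model recognize the held-out spectrum's patient from
  their other spectra; LOPO is the honest generalization estimate. The
  acceptance suite demonstrates LOSO ≥ LOPO across seeds rather than treating
  LOSO as ground truth.
- The peak detector reports any robust local extremum of the difference
  spectrum; with area normalization, compensatory rescaling produces genuine
  off-effect-band peaks (see above), so hit lists should be read together
  with the catalogue assignments.
- The metric "R" printed alongside SP/SE/ACC/MCC in some published reports of
  this protocol has no published definition and is not implemented.
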