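# sersdx

Label-free serum SERS diagnostics for parotid gland tumors: preprocessing,
difference-spectrum analysis, and two-step SVM classification.

## The scientific problem

Parotid gland tumors — pleomorphic adenoma (PA), Warthin tumor (WT), and
mucoepidermoid carcinoma (MEC) — are difficult to diagnose preoperatively.
Surface-enhanced Raman spectroscopy (SERS) of blood serum offers a label-free
alternative: tumor metabolism changes the serum's molecular composition
(cell-free nucleic acids, free amino acids, proteins), which shifts the
intensities of specific Raman bands such as hypoxanthine (~725 cm⁻¹) and
thymine (~745 cm⁻¹).

`sersdx` implements the full diagnostic workflow:

1. **Spectra I/O** — two-column text spectra + a CSV cohort manifest, with
   grid harmonization and strict validation.
2. **Synthetic cohorts** — a seeded generative model of the four-group design
   (4–6 replicate spectra per patient, band effects, patient-level amplitude
   correlation, baselines, noise, saturation artifacts), since the original
   cohort data are not public.
3. **Preprocessing** — QC (saturation/non-finite rejection), iterative
   polynomial baseline removal, Savitzky–Golay smoothing, area normalization.
4. **Difference analysis** — tumor-minus-Normal difference spectra, robust
   signed peak detection, assignment against a 16-band molecular catalogue.
5. **Classification** — two-step RBF-SVM (step 1: Normal vs each tumor;
   step 2: tumors pairwise) with jackknife hyperparameter tuning, evaluated
   by leave-one-spectrum-out (LOSO) and leave-one-patient-out (LOPO)
   cross-validation, reported as SP/SE/ACC/MCC tables.

See [docs/methods.md](docs/methods.md) for the model, parameters, and
limitations.

## Worked example

Simulate a small cohort with injected detector saturation, preprocess it, and
classify it (full scripts in [examples/](examples/)):

```python
import numpy as np
import sersdx

config = sersdx.SyntheticConfig(
    patients_per_group={"PA": 4, "Normal": 4},
    seed=7,
)
cohort = sersdx.generate_cohort(config)
dirty = sersdx.inject_saturation(cohort, fraction=0.15, rng=np.random.default_rng(7))

processed, rejected = sersdx.preprocess_cohort(dirty, return_rejected=True)
print(f"input spectra:     {len(dirty)}")
print(f"rejected by QC:    {len(rejected)}")
print(f"processed spectra: {len(processed)}")
print("preprocessing states:", processed.spectra[0].meta.preprocessing_state)
```

Output (`python examples/02_preprocess.py`):

```text
input spectra:     42
rejected by QC:    5
  PA-P02-S1: saturated
  PA-P04-S6: saturated
  Normal-P01-S1: saturated
processed spectra: 37
preprocessing states: ['raw', 'qc_passed', 'baseline_corrected', 'smoothed', 'normalized']
area under first processed spectrum: 1.000000  (area-normalized)
```

Running the two-step classifier on a four-group cohort with a weak effect and
strong patient-level variability (`python examples/04_classify.py`) renders
publication-style tables and shows why the two CV schemes disagree — LOSO can
recognize the held-out spectrum's patient from their other spectra, LOPO
cannot:

```text
Step 1 - LOSO
Parameter	Normal vs PA	Normal vs WT	Normal vs MEC
SP	100.0 %	100.0 %	100.0 %
SE	100.0 %	100.0 %	100.0 %
ACC	100.0 %	100.0 %	100.0 %
MCC	1.000	1.000	1.000

Step 1 - LOPO
Parameter	PA vs Normal	WT vs Normal	MEC vs Normal
SP	100.0 %	82.1 %	100.0 %
SE	77.8 %	90.9 %	100.0 %
ACC	91.3 %	86.0 %	100.0 %
MCC	0.825	0.725	1.000

Step 2 - LOSO
Parameter	PA vs WT	PA vs MEC	WT vs MEC
SP	100.0 %	100.0 %	100.0 %
SE	100.0 %	100.0 %	100.0 %
ACC	100.0 %	100.0 %	100.0 %
MCC	1.000	1.000	1.000

Step 2 - LOPO
Parameter	PA vs WT	PA vs MEC	WT vs MEC
SP	77.3 %	100.0 %	100.0 %
SE	66.7 %	50.0 %	100.0 %
ACC	72.5 %	77.5 %	100.0 %
MCC	0.442	0.596	1.000
```

A single call runs the whole pipeline and writes all artifacts (cohort,
rejection log, peak tables, metric CSV/text, run log) to a directory:

```python
from sersdx.pipeline import RunConfig, run_full_pipeline
run_full_pipeline(RunConfig(seed=1), "out/run1")
```

## Repository layout

- `src/sersdx/` — the library (`io`, `synthetic`, `preprocess`, `difference`,
  `classify`, `pipeline`, `catalogue`, `core`).
- `examples/` — four short narrative scripts, one per capability: simulate,
  preprocess, difference peaks, classify.
- `tests/` — unit and property tests plus `tests/test_acceptance.py`, one
  test per acceptance criterion.
- `scripts/acceptance.py` — standalone acceptance metrics (JSON output).
- `docs/methods.md` — model description, numerical choices, limitations.

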