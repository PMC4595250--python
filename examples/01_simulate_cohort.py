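"""Simulate a serum-SERS cohort and write it to disk.

The generator reproduces the reference study design: four groups (PA, WT,
MEC tumors and Normal controls), 4-6 replicate spectra per patient, and
group-specific intensity effects at the catalogued Raman bands.
"""

from pathlib import Path

import sersdx

# The default configuration is the full reference design (91 patients,
# 454 spectra); here we simulate a smaller cohort to keep the run quick.
config = sersdx.SyntheticConfig(
    patients_per_group={"PA": 4, "WT": 4, "MEC": 4, "Normal": 6},
    seed=42,
)
cohort = sersdx.generate_cohort(config)

print("patients per group:", cohort.patient_counts())
print("spectra per group: ", cohort.spectra_counts())

first = cohort.spectra[0]
print(f"first spectrum: {first.meta.spectrum_id} "
      f"(patient {first.meta.patient_id}, group {first.meta.group})")
print(f"axis: {first.grid.start}-{first.grid.stop} cm^-1, "
      f"{first.grid.n_points} points, step {first.grid.step}")

out = Path("scratch/example_cohort")
manifest = sersdx.write_cohort(cohort, out)
print("manifest written to", manifest)

# Round-trip: reading the manifest reproduces the cohort exactly.
again = sersdx.read_cohort(manifest)
print("round-trip spectra:", len(again))
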