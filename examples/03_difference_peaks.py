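"""Difference-spectrum analysis: which Raman bands separate tumor from normal serum?

Group mean spectra are subtracted (tumor minus Normal), signed peaks are
detected against a robust noise threshold, and each peak is assigned to
the nearest catalogued band (hypoxanthine, thymine, protein and nucleic
acid modes, ...).
"""

import sersdx
from sersdx.difference import assign_peaks, detect_signed_peaks, difference_spectrum, group_mean

cohort = sersdx.generate_cohort(sersdx.SyntheticConfig(seed=1))
processed = sersdx.preprocess_cohort(cohort)
catalogue = sersdx.default_catalogue()

for tumor in ("PA", "WT", "MEC"):
    diff = difference_spectrum(
        group_mean(processed, tumor), group_mean(processed, "Normal")
    )
    hits = assign_peaks(detect_signed_peaks(diff), catalogue)
    print(f"\n{tumor} minus Normal: {len(hits)} signed peaks")
    for h in hits:
        print(f"  {h.position:7.1f} cm^-1  {h.sign:8s}  {h.assignment}")
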