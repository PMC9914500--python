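"""Simulate a labeled honey cohort and look at its marker bands.

Builds the default 147-sample cohort (21 sucrose-adulterated), then
locates the absorbance maximum inside the 950-1050 cm^-1 sugar window for
each class: pure honey peaks at 1020 cm^-1, syrup-adulterated samples
shift toward 1010 cm^-1.
"""

import numpy as np

import honeyspec as hs

cohort = hs.generate_cohort(hs.CohortConfig())
ds = cohort.dataset

print(f"cohort: {ds.n_samples} samples x {ds.n_wavenumbers} wavenumbers")
print(ds.class_labels.value_counts().to_string())

window = (ds.wavenumbers >= 950) & (ds.wavenumbers <= 1050)
for label in ("pure", "suspicious"):
    rows = (ds.class_labels == label).to_numpy()
    peaks = ds.wavenumbers[window][np.argmax(ds.matrix[rows][:, window], axis=1)]
    counts = dict(zip(*np.unique(peaks, return_counts=True)))
    print(f"{label:>10}: fingerprint peak positions {counts}")

print(
    "\nThe pure-honey sugar band sits at 1020 cm^-1; added sucrose syrup\n"
    "moves the peak to the grid points nearest 1010 cm^-1 - the spectral\n"
    "signature the authentication model exploits."
)
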