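"""Calibrate one PLS1 trait model and validate it externally.

Moisture is predicted from the spectra: select the informative wavenumber
regions, split 80/20, pick the latent-variable count by leave-one-out
cross-validation, then report SECV/R2cv (internal) and SEP/R2pre/RPD/RER
(external) with their application bands.
"""

import numpy as np

import honeyspec as hs

cohort = hs.generate_cohort(hs.CohortConfig())
region = hs.DEFAULT_PLSR_REGION
sub = hs.select_region(cohort.dataset, region)
train, val = hs.split_dataset(sub, 0.2, seed=20230124, stratify=False)

X, y = train.matrix, train.traits["moisture"].to_numpy(float)
cv = hs.loocv(X, y, max_lv=10)
n_lv = hs.select_lv(cv)
model = hs.fit_pls1(X, y, n_lv, wavenumbers=train.wavenumbers, region=region,
                    trait_name="moisture")
report = hs.external_validate(
    model, val.matrix, val.traits["moisture"].to_numpy(float)
)

print(f"moisture model: {n_lv} latent variables (LOO-selected)")
print(f"  SECV {cv.secv[n_lv - 1]:.3f} %   R2cv {cv.r2_cv[n_lv - 1]:.4f}")
print(f"  SEP  {report.sep:.3f} %   R2pre {report.r2_pre:.4f}   "
      f"bias {report.bias:+.4f} %")
print(f"  RPD {report.rpd:.1f} ({report.rpd_band})   "
      f"RER {report.rer:.1f} ({report.rer_band})")
print(
    "\nSECV/SEP are the cross-validated and external prediction errors in\n"
    "moisture percentage points; RPD (calibration SD / SEP) and RER\n"
    "(calibration range / SEP) grade what applications the model supports."
)
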