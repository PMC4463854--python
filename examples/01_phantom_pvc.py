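"""Partial-volume correction on a digital phantom.

Builds a spherical-shell cortex with a thin (2 mm) ribbon and true GM
uptake 1.2, blurs it with a 6 mm scanner PSF, then maps uptake onto the
surface with and without partial-volume correction.  The raw surface
uptake (sFDG) badly underestimates the truth because the thin ribbon mixes
with WM and CSF inside the PSF; dividing by the identically sampled tissue
response (swPVE) restores it.
"""

import numpy as np

import cortexfuse as cf
from cortexfuse.geometry import regional_mean

spec = cf.PhantomSpec(thickness=2.0, uptake=1.2, psf_fwhm=6.0, seed=1)
subject = cf.generate_phantom(spec)

thickness, csfdg, maps = cf.build_surface_features(
    subject.pair, subject.labels, subject.pet, subject.tissues,
    cerebellum=subject.cerebellum, return_maps=True,
)
raw = regional_mean(maps["sFDG"], subject.labels)

truth = 1.2
raw_vals = np.array(list(raw.values()))
pvc_vals = np.array(list(csfdg.values()))
print(f"true GM uptake (DVR units):     {truth:.3f}")
print(f"raw surface uptake, mean:       {raw_vals.mean():.3f} "
      f"({100 * (raw_vals.mean() - truth) / truth:+.1f}% vs truth)")
print(f"corrected csFDG, mean:          {pvc_vals.mean():.3f} "
      f"({100 * (pvc_vals.mean() - truth) / truth:+.1f}% vs truth)")
print(f"thickness regional means (mm):  "
      f"{np.mean(list(thickness.values())):.3f} (truth 2.000)")
# The raw deficit is the partial-volume effect; the corrected value shows
# the surface-based PVC removing it to within a few percent.
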