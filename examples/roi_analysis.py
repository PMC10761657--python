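"""Semiquantitative reading of a simulated scan pair.

Draws a 2 cm circular liver ROI and measures SUVmax / SUVmean / SD on the
reference and on a short scan, computes the lesion-to-background ratio from
an SUV >= 5 lesion mask, and summarises agreement with Bland-Altman limits.
"""

import numpy as np

from petrestore import (AcquisitionModel, CircularROI, bland_altman,
                        build_duration_series, default_phantom_spec, delta_suv,
                        generate_phantom, lbr, roi_stats, threshold_mask)

acq = AcquisitionModel(durations_s=(15.0, 600.0))
liver_means_short, liver_means_ref = [], []
for p in range(6):
    truth, ct = generate_phantom(default_phantom_spec(seed=p))
    series, _ = build_duration_series(truth, ct, acq, seed=100 + p)
    short, ref = series[15.0], series[600.0]

    ny, nx, nz = ref.data.shape
    # the default phantom's liver sits right-anterior of the grid center
    liver_roi = CircularROI(slice_index=nz // 2,
                            center=(ny / 2 + 0.16 * ny, nx / 2 - 0.17 * nx),
                            diameter_mm=20.0)
    s_ref = roi_stats(ref, liver_roi)
    s_short = roi_stats(short, liver_roi)
    liver_means_ref.append(s_ref.suv_mean)
    liver_means_short.append(s_short.suv_mean)

    if p == 0:
        mask = threshold_mask(ref, 5.0)           # lesion mask from reference
        lesion_max = ref.data[mask].max()
        print(f"liver ROI on reference: SUVmax {s_ref.suv_max:.2f}, "
              f"SUVmean {s_ref.suv_mean:.2f}, SD {s_ref.suv_sd:.2f}")
        print(f"lesion mask (SUV>=5): {mask.sum()} voxels, "
              f"lesion SUVmax {lesion_max:.2f}, "
              f"LBR {lbr(lesion_max, s_ref.suv_mean):.2f}")
        d = delta_suv(short, ref, mask)
        print(f"deltaSUV in lesion (15 s - 600 s): "
              f"mean {d.mean():+.3f}, SD {d.std():.3f} SUV\n")

bias, lo, hi = bland_altman(liver_means_short, liver_means_ref)
print(f"Bland-Altman of liver SUVmean (15 s vs 600 s, n={len(liver_means_ref)}):")
print(f"  bias {bias:+.4f} SUV, limits of agreement [{lo:+.4f}, {hi:+.4f}]")
print("\nA small bias with tight limits means the short scan, despite its"
      "\nnoise, preserves the mean liver uptake that clinical reading uses.")
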