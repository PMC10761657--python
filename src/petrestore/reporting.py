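"""Group-level evaluation tables and agreement plots.

:func:`group_report` materializes the full quantitative/semiquantitative
assessment as one pandas row per (duration, method) group: PSNR, SSIM and
mean 2D correlation against the reference scan, liver-ROI statistics, lesion
SUVmax, the lesion-to-background ratio, and Bland-Altman agreement of the
liver SUVmean across phantoms.  Image metrics are computed on the [0, 1]
scale (divided by the reference-set maximum); ROI quantities stay in SUV.
Descriptive paired-difference summaries (mean +/- SD of per-phantom
differences against the reference) are included; inferential tests are not.
"""

from __future__ import annotations

import math
from typing import Mapping, Sequence

import numpy as np
import pandas as pd

from .metrics import (CircularROI, bland_altman, corr2d_mean, lbr, psnr,
                      roi_stats, ssim)
from .phantom import PETVolume

__all__ = ["group_report", "plot_bland_altman"]


def _as_list(v) -> list:
    return list(v) if isinstance(v, (list, tuple)) else [v]


def group_report(volumes_by_group: Mapping[tuple, PETVolume | Sequence[PETVolume]],
                 references: PETVolume | Sequence[PETVolume],
                 liver_rois: Sequence[CircularROI],
                 lesion_roi: CircularROI | None = None,
                 expected_groups: Sequence[tuple] | None = None) -> pd.DataFrame:
    """One row of metrics per (duration, method) group.

    ``volumes_by_group`` maps ``(duration, method)`` to a volume or to one
    volume per phantom; ``references`` matches phantom-wise.  ROIs are drawn
    once (on the reference) and transferred unchanged to every group.
    Groups listed in ``expected_groups`` but missing from the mapping appear
    with status ``"absent"`` rather than being silently skipped.
    """
    refs = _as_list(references)
    scale = max(float(np.max(r.data)) for r in refs)
    keys = list(volumes_by_group.keys())
    if expected_groups is not None:
        keys = list(expected_groups)
    ref_liver = [np.mean([roi_stats(r, roi).suv_mean for roi in liver_rois])
                 for r in refs]
    rows = []
    for key in keys:
        duration, method = key
        if key not in volumes_by_group:
            rows.append({"duration_s": duration, "method": method,
                         "status": "absent"})
            continue
        vols = _as_list(volumes_by_group[key])
        if len(vols) != len(refs):
            raise ValueError(f"group {key}: {len(vols)} volumes for "
                             f"{len(refs)} references")
        psnrs, ssims, corrs = [], [], []
        liver_max, liver_mean, liver_sd = [], [], []
        lesion_max, lbrs = [], []
        for v, r in zip(vols, refs):
            vn = v.data / scale
            rn = r.data / scale
            psnrs.append(psnr(vn, rn))
            ssims.append(ssim(vn, rn))
            corrs.append(corr2d_mean(vn, rn))
            lstats = [roi_stats(v, roi) for roi in liver_rois]
            liver_max.append(np.mean([s.suv_max for s in lstats]))
            liver_mean.append(np.mean([s.suv_mean for s in lstats]))
            liver_sd.append(np.mean([s.suv_sd for s in lstats]))
            if lesion_roi is not None:
                les = roi_stats(v, lesion_roi)
                lesion_max.append(les.suv_max)
                lbrs.append(lbr(les.suv_max, liver_mean[-1]))
        row = {
            "duration_s": duration, "method": method, "status": "ok",
            "n_phantoms": len(vols),
            "psnr": float(np.mean(psnrs)) if all(map(math.isfinite, psnrs))
            else math.inf,
            "ssim": float(np.mean(ssims)),
            "corr2d_mean": float(np.mean(corrs)),
            "liver_suv_max": float(np.mean(liver_max)),
            "liver_suv_mean": float(np.mean(liver_mean)),
            "liver_suv_sd": float(np.mean(liver_sd)),
        }
        if lesion_roi is not None:
            row["lesion_suv_max"] = float(np.mean(lesion_max))
            row["lbr"] = float(np.mean(lbrs))
        # paired differences against the reference (per phantom)
        d = np.asarray(liver_mean) - np.asarray(ref_liver)
        row["d_liver_suv_mean"] = float(d.mean())
        row["d_liver_suv_mean_sd"] = float(d.std(ddof=1)) if d.size > 1 else 0.0
        if len(vols) >= 2:
            bias, lo, hi = bland_altman(liver_mean, ref_liver)
            row.update(ba_bias=bias, ba_loa_low=lo, ba_loa_high=hi)
        rows.append(row)
    return pd.DataFrame(rows)


def plot_bland_altman(series_a, series_b, path, title="Bland-Altman") -> None:
    """Scatter of pairwise differences vs means with bias and LoA lines."""
    import matplotlib
    matplotlib.use("Agg")
    import matplotlib.pyplot as plt

    a = np.asarray(series_a, dtype=float)
    b = np.asarray(series_b, dtype=float)
    bias, lo, hi = bland_altman(a, b)
    fig, ax = plt.subplots(figsize=(5, 4))
    ax.scatter((a + b) / 2, a - b, s=12)
    for y, style in [(bias, "-"), (lo, "--"), (hi, "--")]:
        ax.axhline(y, linestyle=style, color="k", linewidth=1)
    ax.set_xlabel("mean of pair")
    ax.set_ylabel("difference")
    ax.set_title(title)
    fig.tight_layout()
    fig.savefig(path, dpi=120)
    plt.close(fig)
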