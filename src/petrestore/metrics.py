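"""Quantitative and semiquantitative image-quality measures.

Volume-level metrics
    * :func:`psnr` -- ``10 * log10(V^2 / MSE)`` with ``V`` the maximum of the
      *evaluated* image (note: not of the reference).
    * :func:`ssim` -- the global-moment structural similarity
      ``(2 mu_x mu_r + a1)(2 cov + a2) / ((mu_x^2 + mu_r^2 + a1)(var_x + var_r + a2))``
      with stabilizers ``a1 = 1e-6``, ``a2 = 3e-6``; intended for images on
      the normalized [0, 1] scale.
    * :func:`corr2d_mean` -- Pearson correlation per axial slice, averaged.

Semiquantitative measures mirror clinical reading: 2-cm circular liver ROIs
(SUVmax / SUVmean / SD), lesion SUVmax, the lesion-to-background ratio
(lesion SUVmax over liver SUVmean), SUV >= 5 lesion masks with voxel-wise
SUV-difference samples, and Bland-Altman agreement (bias +/- 1.96 SD).

ROI objects are plain geometric descriptors, so the ROI drawn once on the
reference image transfers unchanged to every other group.
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass

import numpy as np

__all__ = [
    "psnr",
    "ssim",
    "ssim_windowed",
    "corr2d_mean",
    "CircularROI",
    "RoiStats",
    "roi_stats",
    "lbr",
    "threshold_mask",
    "delta_suv",
    "bland_altman",
]

SSIM_A1 = 1e-6
SSIM_A2 = 3e-6


def _payload(x) -> np.ndarray:
    if hasattr(x, "voxel_size_mm"):          # one of the volume containers
        x = x.data
    return np.asarray(x, dtype=np.float64)


def psnr(x, x_r, peak: str = "evaluated") -> float:
    """Peak signal-to-noise ratio in dB of ``x`` against reference ``x_r``.

    ``peak='evaluated'`` takes V from the evaluated image x (the convention
    used throughout this package); ``peak='reference'`` is offered for
    comparison with tools that normalize by the reference maximum.
    Identical inputs have zero MSE; the result is ``math.inf`` as an
    "infinite PSNR" flag rather than an exception.
    """
    xd, rd = _payload(x), _payload(x_r)
    if xd.shape != rd.shape:
        raise ValueError("shape mismatch")
    mse = float(np.mean((rd - xd) ** 2))
    if mse == 0.0:
        return math.inf
    V = float(np.max(xd if peak == "evaluated" else rd))
    return 10.0 * math.log10(V * V / mse)


def ssim(x, x_r, a1: float = SSIM_A1, a2: float = SSIM_A2,
         per_slice: bool = False) -> float:
    """Global-statistics SSIM (no sliding window), the default comparison.

    With ``per_slice=True`` the global form is evaluated per axial slice and
    averaged.  For the conventional sliding-window variant see
    :func:`ssim_windowed`.
    """
    xd, rd = _payload(x), _payload(x_r)
    if xd.shape != rd.shape:
        raise ValueError("shape mismatch")
    if per_slice:
        return float(np.mean([ssim(xd[:, :, d], rd[:, :, d], a1, a2)
                              for d in range(xd.shape[2])]))
    mu_x, mu_r = float(xd.mean()), float(rd.mean())
    var_x, var_r = float(xd.var()), float(rd.var())
    cov = float(((xd - mu_x) * (rd - mu_r)).mean())
    return ((2 * mu_x * mu_r + a1) * (2 * cov + a2)
            / ((mu_x ** 2 + mu_r ** 2 + a1) * (var_x + var_r + a2)))


def ssim_windowed(x, x_r, data_range: float = 1.0, win_size: int = 7) -> float:
    """Sliding-window SSIM (mean local SSIM), for cross-tool comparison.

    Delegates to scikit-image's implementation; offered as an option, not
    the package's default global-moment form.
    """
    from skimage.metrics import structural_similarity

    xd, rd = _payload(x), _payload(x_r)
    if xd.shape != rd.shape:
        raise ValueError("shape mismatch")
    return float(structural_similarity(rd, xd, data_range=data_range,
                                       win_size=win_size))


def corr2d_mean(x, x_r, return_skipped: bool = False):
    """Mean Pearson correlation over axial (depth-axis) slices.

    Slices where either member is constant have an undefined correlation and
    are skipped (their count is available via ``return_skipped``); if every
    slice is degenerate the input pair carries no structure to correlate and
    an error is raised.
    """
    xd, rd = _payload(x), _payload(x_r)
    if xd.shape != rd.shape:
        raise ValueError("shape mismatch")
    vals = []
    skipped = 0
    for d in range(xd.shape[2]):
        a = xd[:, :, d].ravel()
        b = rd[:, :, d].ravel()
        sa, sb = a.std(), b.std()
        if sa == 0.0 or sb == 0.0:
            skipped += 1
            continue
        vals.append(float(np.mean((a - a.mean()) * (b - b.mean())) / (sa * sb)))
    if not vals:
        raise ValueError("all slices are degenerate (constant)")
    mean = float(np.mean(vals))
    return (mean, skipped) if return_skipped else mean


# ---------------------------------------------------------------------------
# ROI analysis
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class CircularROI:
    """A 2D circular ROI on one axial slice; diameter in millimetres."""
    slice_index: int
    center: tuple[float, float]     # in-plane voxel coordinates (row, col)
    diameter_mm: float = 20.0

    def __post_init__(self):
        if self.diameter_mm <= 0:
            raise ValueError("diameter_mm must be positive")

    def member_indices(self, shape, voxel_size_mm) -> tuple[np.ndarray, np.ndarray]:
        """Indices of voxels whose in-plane centers fall within the disc."""
        if not 0 <= self.slice_index < shape[2]:
            raise ValueError("ROI slice outside the volume")
        rr, cc = np.indices(shape[:2], dtype=np.float64)
        d2 = (((rr - self.center[0]) * voxel_size_mm[0]) ** 2
              + ((cc - self.center[1]) * voxel_size_mm[1]) ** 2)
        radius = self.diameter_mm / 2.0
        inside = d2 <= radius ** 2
        # the disc must lie entirely inside the slice
        r_ext = radius / voxel_size_mm[0]
        c_ext = radius / voxel_size_mm[1]
        if (self.center[0] - r_ext < -0.5 or self.center[0] + r_ext > shape[0] - 0.5
                or self.center[1] - c_ext < -0.5 or self.center[1] + c_ext > shape[1] - 0.5):
            raise ValueError("ROI disc extends outside the slice")
        if not inside.any():
            raise ValueError("ROI disc contains no voxel centers")
        return np.nonzero(inside)


@dataclass(frozen=True)
class RoiStats:
    suv_max: float
    suv_mean: float
    suv_sd: float           # population SD over the member voxels


def roi_stats(vol, roi: CircularROI) -> RoiStats:
    """SUVmax / SUVmean / SD over the ROI's member voxels."""
    data = _payload(vol)
    voxel = getattr(vol, "voxel_size_mm", (1.0, 1.0, 1.0))
    rows, cols = roi.member_indices(data.shape, voxel)
    vals = data[rows, cols, roi.slice_index]
    return RoiStats(suv_max=float(vals.max()), suv_mean=float(vals.mean()),
                    suv_sd=float(vals.std()))


def lbr(lesion_suv_max: float, liver_suv_mean: float) -> float:
    """Lesion-to-background ratio: lesion SUVmax over liver SUVmean."""
    if liver_suv_mean <= 0:
        raise ZeroDivisionError("liver SUVmean must be positive")
    return lesion_suv_max / liver_suv_mean


# ---------------------------------------------------------------------------
# threshold lesion masks and voxel-difference samples
# ---------------------------------------------------------------------------

def threshold_mask(vol, suv_threshold: float = 5.0) -> np.ndarray:
    """Boolean lesion mask: voxels with value >= threshold (inclusive)."""
    if suv_threshold <= 0:
        raise ValueError("threshold must be positive")
    return _payload(vol) >= suv_threshold


def delta_suv(vol_a, vol_ref, mask: np.ndarray) -> np.ndarray:
    """Voxel-wise SUV differences ``vol_a - vol_ref`` inside the mask.

    The mask is meant to come from the reference volume only (drawn once,
    applied to every condition).  An empty mask yields an empty sample with
    a warning.
    """
    a, r = _payload(vol_a), _payload(vol_ref)
    if a.shape != r.shape or a.shape != mask.shape:
        raise ValueError("shape mismatch")
    if not mask.any():
        warnings.warn("empty lesion mask: no voxels above threshold",
                      stacklevel=2)
        return np.empty(0)
    return (a - r)[mask]


def bland_altman(series_a, series_b) -> tuple[float, float, float]:
    """Bland-Altman agreement: (bias, lower LoA, upper LoA).

    Bias is the mean paired difference; the limits of agreement are
    ``bias -/+ 1.96 * SD`` with the sample (n-1) standard deviation.
    """
    a = np.asarray(series_a, dtype=np.float64)
    b = np.asarray(series_b, dtype=np.float64)
    if a.shape != b.shape:
        raise ValueError("paired series must have equal length")
    if a.size < 2:
        raise ValueError("need at least two pairs")
    d = a - b
    bias = float(d.mean())
    sd = float(d.std(ddof=1))
    return bias, bias - 1.96 * sd, bias + 1.96 * sd
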