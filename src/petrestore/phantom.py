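"""Synthetic co-registered PET/CT phantoms and count-limited scan simulation.

The generator paints ellipsoidal "organs" and spherical "lesions" into a
background volume, producing a ground-truth activity map (SUV) and a
perfectly co-registered CT (HU) on the same grid.  Short-scan acquisitions
are emulated statistically: a scan of duration ``t`` seconds sees per-voxel
expected counts ``lambda = activity * counts_per_suv_second * t``; a Poisson
draw, conversion back to SUV and a 3 mm Gaussian postfilter yield the
reconstructed image.  This preserves the first two moments of count-limited
imaging -- the mean equals the truth and the pre-filter variance scales as
``1/t`` -- which is the structure a restoration method has to contend with,
while the physics of iterative reconstruction is absorbed into the
postfilter.

Default acquisition values follow a pediatric total-body FDG protocol:
3.7 MBq/kg injected dose, 17 kg reference body weight, a 600 s reference
scan and reconstructions truncated to {6, 15, 30, 60, 150, 600} s on a
2.34 x 2.34 x 2.89 mm voxel grid.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

import numpy as np
from scipy.ndimage import gaussian_filter

__all__ = [
    "Ellipsoid",
    "Sphere",
    "PhantomSpec",
    "AcquisitionModel",
    "PETVolume",
    "CTVolume",
    "GeometryError",
    "generate_phantom",
    "simulate_scan",
    "build_duration_series",
    "default_phantom_spec",
    "random_phantom_spec",
    "FWHM_TO_SIGMA",
]

#: FWHM of a Gaussian = 2*sqrt(2*ln 2) * sigma
FWHM_TO_SIGMA = 2.3548200450309493


class GeometryError(ValueError):
    """A phantom descriptor does not fit inside the voxel grid."""


@dataclass(frozen=True)
class Ellipsoid:
    """Axis-aligned ellipsoid: center in voxel coordinates, semi-axes in mm."""
    center: tuple[float, float, float]
    semi_axes_mm: tuple[float, float, float]
    activity: float          # SUV painted into the PET truth
    ct_level: float          # HU painted into the CT


@dataclass(frozen=True)
class Sphere:
    """Sphere: center in voxel coordinates, radius in mm."""
    center: tuple[float, float, float]
    radius_mm: float
    activity: float
    ct_level: float


@dataclass(frozen=True)
class PhantomSpec:
    """Parametric description of a paired activity/CT phantom."""
    grid_shape: tuple[int, int, int] = (96, 96, 24)
    voxel_size_mm: tuple[float, float, float] = (2.34, 2.34, 2.89)
    organs: tuple[Ellipsoid, ...] = ()
    lesions: tuple[Sphere, ...] = ()
    background_activity: float = 0.2
    ct_background_hu: float = -1000.0
    seed: int = 0

    def validate(self) -> None:
        if self.background_activity < 0:
            raise ValueError("background_activity must be >= 0")
        if any(v <= 0 for v in self.voxel_size_mm):
            raise ValueError("voxel sizes must be positive")
        for org in self.organs:
            if any(a <= 0 for a in org.semi_axes_mm):
                raise GeometryError(f"non-positive semi-axis in {org}")
            self._check_extent(org.center, [a / v for a, v in
                                            zip(org.semi_axes_mm,
                                                self.voxel_size_mm)], org)
        for les in self.lesions:
            if les.radius_mm <= 0:
                raise GeometryError(f"non-positive radius in {les}")
            self._check_extent(les.center, [les.radius_mm / v
                                            for v in self.voxel_size_mm], les)

    def _check_extent(self, center, half_extents_vox, desc) -> None:
        for c, h, n in zip(center, half_extents_vox, self.grid_shape):
            if c - h < -0.5 or c + h > n - 0.5:
                raise GeometryError(f"descriptor extends outside the grid: {desc}")


@dataclass(frozen=True)
class AcquisitionModel:
    """Acquisition parameters of the emulated count-limited scan.

    ``counts_per_suv_second`` calibrates expected counts per voxel per second
    per unit SUV and therefore sets the absolute noise level; the dose and
    weight fields document the protocol the calibration emulates.
    """
    dose_per_kg_MBq: float = 3.7
    weight_kg: float = 17.0
    reference_duration_s: float = 600.0
    durations_s: tuple[float, ...] = (6.0, 15.0, 30.0, 60.0, 150.0, 600.0)
    counts_per_suv_second: float = 2.0
    postfilter_fwhm_mm: float = 3.0

    def validate(self) -> None:
        if self.counts_per_suv_second <= 0:
            raise ValueError("counts_per_suv_second must be positive")
        if not self.durations_s:
            raise ValueError("durations_s must be nonempty")
        for t in self.durations_s:
            if t <= 0 or t > self.reference_duration_s:
                raise ValueError(
                    f"durations must lie in (0, {self.reference_duration_s}]: {t}")


@dataclass
class PETVolume:
    """A 3D activity image in SUV on a fixed voxel grid."""
    data: np.ndarray
    voxel_size_mm: tuple[float, float, float] = (2.34, 2.34, 2.89)
    duration_s: float | None = None
    meta: dict = field(default_factory=dict)

    def __post_init__(self):
        self.data = np.asarray(self.data)
        if self.data.ndim != 3:
            raise ValueError("PETVolume payload must be 3D")


@dataclass
class CTVolume:
    """A 3D attenuation image in HU, co-registered with its PET partner."""
    data: np.ndarray
    voxel_size_mm: tuple[float, float, float] = (2.34, 2.34, 2.89)
    meta: dict = field(default_factory=dict)

    def __post_init__(self):
        self.data = np.asarray(self.data)
        if self.data.ndim != 3:
            raise ValueError("CTVolume payload must be 3D")


# ---------------------------------------------------------------------------
# phantom painting
# ---------------------------------------------------------------------------

def _membership(spec: PhantomSpec, desc) -> np.ndarray:
    """Boolean mask of voxels whose centers fall inside a descriptor."""
    idx = np.indices(spec.grid_shape, dtype=np.float64)
    if isinstance(desc, Ellipsoid):
        semi = desc.semi_axes_mm
    else:
        semi = (desc.radius_mm,) * 3
    q = np.zeros(spec.grid_shape)
    for ax in range(3):
        d_mm = (idx[ax] - desc.center[ax]) * spec.voxel_size_mm[ax]
        q += (d_mm / semi[ax]) ** 2
    return q <= 1.0


def generate_phantom(spec: PhantomSpec) -> tuple[PETVolume, CTVolume]:
    """Paint the phantom: background, then organs, then lesions (last wins)."""
    spec.validate()
    activity = np.full(spec.grid_shape, spec.background_activity, dtype=np.float64)
    ct = np.full(spec.grid_shape, spec.ct_background_hu, dtype=np.float64)
    for desc in list(spec.organs) + list(spec.lesions):
        mask = _membership(spec, desc)
        activity[mask] = desc.activity
        ct[mask] = desc.ct_level
    meta = {"kind": "truth", "seed": spec.seed}
    return (PETVolume(activity, spec.voxel_size_mm, duration_s=None, meta=meta),
            CTVolume(ct, spec.voxel_size_mm, meta=dict(meta)))


# ---------------------------------------------------------------------------
# count-limited scan emulation
# ---------------------------------------------------------------------------

def simulate_scan(truth: PETVolume, acq: AcquisitionModel, duration_s: float,
                  seed: int, apply_postfilter: bool = True) -> PETVolume:
    """Emulate a ``duration_s``-second scan of the ground-truth activity.

    Per-voxel expected counts are ``truth * counts_per_suv_second * t``; a
    Poisson draw divided back by the count factor gives an unbiased SUV image
    with variance ``truth / (counts_per_suv_second * t)``, which the 3 mm
    Gaussian postfilter then smooths (set ``apply_postfilter=False`` for the
    raw count image, e.g. to validate the noise moments).
    """
    acq.validate()
    if duration_s <= 0:
        raise ValueError("duration_s must be positive")
    if np.any(truth.data < 0):
        raise ValueError("truth activity must be nonnegative")
    rng = np.random.default_rng(seed)
    factor = acq.counts_per_suv_second * duration_s
    lam = truth.data * factor
    counts = rng.poisson(lam).astype(np.float64)
    img = counts / factor
    if apply_postfilter and acq.postfilter_fwhm_mm > 0:
        sigma_vox = [acq.postfilter_fwhm_mm / FWHM_TO_SIGMA / v
                     for v in truth.voxel_size_mm]
        img = gaussian_filter(img, sigma=sigma_vox, mode="nearest")
    meta = {"kind": "simulated", "seed": seed,
            "counts_per_suv_second": acq.counts_per_suv_second,
            "postfiltered": bool(apply_postfilter)}
    return PETVolume(img, truth.voxel_size_mm, duration_s=duration_s, meta=meta)


def build_duration_series(truth: PETVolume, ct: CTVolume, acq: AcquisitionModel,
                          seed: int) -> tuple[dict[float, PETVolume], CTVolume]:
    """One simulated volume per configured duration, with distinct sub-seeds.

    The longest (reference) duration goes through the same noise pathway as
    the short scans: the reference image is itself a simulated scan, not the
    noiseless truth.
    """
    acq.validate()
    ss = np.random.SeedSequence(entropy=seed)
    children = ss.spawn(len(acq.durations_s))
    series = {}
    for t, child in zip(acq.durations_s, children):
        sub_seed = int(child.generate_state(1)[0] % (2 ** 31))
        series[t] = simulate_scan(truth, acq, t, seed=sub_seed)
    return series, ct


# ---------------------------------------------------------------------------
# stock phantoms
# ---------------------------------------------------------------------------

def default_phantom_spec(grid_shape=(96, 96, 24),
                         voxel_size_mm=(2.34, 2.34, 2.89),
                         seed: int = 0) -> PhantomSpec:
    """A torso-like phantom: body, liver, lung, spine, two avid lesions.

    Geometry scales with the grid so the same anatomy works at desk sizes.
    Lesion uptake sits above SUV 5 so threshold-based lesion masking is
    exercised; organ CT levels give the anatomical contrast the CT-prior
    branch is meant to exploit.
    """
    ny, nx, nz = grid_shape
    vy, vx, vz = voxel_size_mm
    cy, cx, cz = (ny - 1) / 2, (nx - 1) / 2, (nz - 1) / 2
    # half field-of-view in mm, with a small margin
    hy, hx, hz = (ny / 2 - 1) * vy, (nx / 2 - 1) * vx, (nz / 2 - 1) * vz
    body = Ellipsoid((cy, cx, cz), (0.95 * hy, 0.85 * hx, 0.98 * hz), 0.5, 20.0)
    liver = Ellipsoid((cy + 0.22 * ny, cx - 0.12 * nx, cz),
                      (0.30 * hy, 0.38 * hx, 0.80 * hz), 2.0, 60.0)
    lung = Ellipsoid((cy - 0.22 * ny, cx + 0.10 * nx, cz),
                     (0.28 * hy, 0.30 * hx, 0.80 * hz), 0.25, -750.0)
    spine = Ellipsoid((cy, cx + 0.30 * nx, cz),
                      (0.10 * hy, 0.10 * hx, 0.90 * hz), 1.2, 600.0)
    r_les = max(1.6 * max(vy, vx), 0.06 * hy)
    lesion1 = Sphere((cy + 0.22 * ny + 0.16 * hy / vy, cx - 0.12 * nx + 0.2 * hx / vx, cz),
                     r_les, 9.0, 45.0)
    lesion2 = Sphere((cy - 0.22 * ny, cx + 0.10 * nx, cz), 0.8 * r_les, 6.5, 30.0)
    return PhantomSpec(grid_shape=grid_shape, voxel_size_mm=voxel_size_mm,
                       organs=(body, liver, lung, spine),
                       lesions=(lesion1, lesion2),
                       background_activity=0.2, seed=seed)


def random_phantom_spec(seed: int, grid_shape=(32, 32, 5),
                        voxel_size_mm=(2.34, 2.34, 2.89)) -> PhantomSpec:
    """A randomized phantom for training-set generation.

    Draws 2-4 ellipsoidal organs and 1-3 spherical lesions with random
    placement, size, uptake (lesions 5-10 SUV) and CT level, so a network
    trained across seeds sees genuinely varied anatomy rather than one
    memorized layout.
    """
    rng = np.random.default_rng(seed)
    ny, nx, nz = grid_shape
    vy, vx, vz = voxel_size_mm
    cy, cx, cz = (ny - 1) / 2, (nx - 1) / 2, (nz - 1) / 2
    hy, hx, hz = (ny / 2 - 1) * vy, (nx / 2 - 1) * vx, (nz / 2 - 1) * vz
    organs = [Ellipsoid((cy, cx, cz), (0.95 * hy, 0.9 * hx, 0.98 * hz),
                        float(rng.uniform(0.3, 0.7)),
                        float(rng.uniform(-50, 60)))]
    for _ in range(int(rng.integers(1, 4))):
        c = (float(rng.uniform(0.3, 0.7) * (ny - 1)),
             float(rng.uniform(0.3, 0.7) * (nx - 1)), cz)
        semi = (float(rng.uniform(0.15, 0.4) * hy),
                float(rng.uniform(0.15, 0.4) * hx),
                float(rng.uniform(0.6, 0.95) * hz))
        organs.append(Ellipsoid(c, semi, float(rng.uniform(0.2, 3.0)),
                                float(rng.uniform(-800, 700))))
    lesions = []
    for _ in range(int(rng.integers(1, 4))):
        c = (float(rng.uniform(0.3, 0.7) * (ny - 1)),
             float(rng.uniform(0.3, 0.7) * (nx - 1)),
             float(rng.uniform(0.35, 0.65) * (nz - 1)))
        r = float(rng.uniform(1.2, 2.5) * max(vy, vx))
        r = min(r, 0.3 * min(hy, hx), 0.9 * min((c[2] + 0.49) * vz,
                                                (nz - 1 - c[2] + 0.49) * vz))
        if r <= 0:
            continue
        lesions.append(Sphere(c, r, float(rng.uniform(5.0, 10.0)),
                              float(rng.uniform(-20, 80))))
    return PhantomSpec(grid_shape=grid_shape, voxel_size_mm=voxel_size_mm,
                       organs=tuple(organs), lesions=tuple(lesions),
                       background_activity=float(rng.uniform(0.05, 0.3)),
                       seed=seed)
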