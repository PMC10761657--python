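"""Volume I/O, intensity normalization, CT resampling and slab handling.

Volumes travel on disk as 3D NIfTI with the voxel size in the header.  PET
intensities are normalized to [0, 1] by a dataset-wide maximum SUV and CT by
a dataset-wide maximum HU; the two constants are persisted alongside any
trained model and reused verbatim at inference (values of unseen volumes may
exceed 1 -- nothing is clipped).  Networks consume overlapping H x W x S
multislice slabs with S = 5; :func:`extract_slabs` / :func:`reassemble` cut a
volume into slabs and average them back together exactly.
"""

from __future__ import annotations

import json
from dataclasses import dataclass
from pathlib import Path

import nibabel as nib
import numpy as np
import yaml
from scipy.ndimage import map_coordinates

from .phantom import CTVolume, PETVolume

__all__ = [
    "FormatError",
    "read_volume",
    "write_volume",
    "NormalizationConstants",
    "fit_normalization",
    "normalize",
    "denormalize",
    "save_normalization",
    "load_normalization",
    "resample_to_pet_grid",
    "SlabStack",
    "extract_slabs",
    "reassemble",
]

S_DEFAULT = 5


class FormatError(ValueError):
    """An on-disk volume violates the expected 3D NIfTI layout."""


def write_volume(vol: PETVolume | CTVolume, path) -> None:
    """Write a volume as 3D NIfTI with spacing in the header."""
    affine = np.diag(list(vol.voxel_size_mm) + [1.0])
    img = nib.Nifti1Image(np.asarray(vol.data, dtype=np.float32), affine)
    img.header.set_zooms(vol.voxel_size_mm)
    nib.save(img, str(path))


def write_mask(mask: np.ndarray, voxel_size_mm, path) -> None:
    """Write a boolean lesion mask as NIfTI with an integer payload."""
    affine = np.diag(list(voxel_size_mm) + [1.0])
    img = nib.Nifti1Image(np.asarray(mask, dtype=np.uint8), affine)
    img.header.set_zooms(voxel_size_mm)
    nib.save(img, str(path))


def read_volume(path, kind: str = "pet",
                duration_s: float | None = None) -> PETVolume | CTVolume:
    """Read a 3D NIfTI volume; ``kind`` selects the returned container."""
    img = nib.load(str(path))
    data = np.asanyarray(img.dataobj)
    if data.ndim != 3:
        raise FormatError(f"expected a 3D payload, got {data.ndim}D in {path}")
    zooms = img.header.get_zooms()[:3]
    if any(z <= 0 for z in zooms):
        raise FormatError(f"missing or non-positive spacing in {path}")
    spacing = tuple(float(z) for z in zooms)
    if kind == "pet":
        return PETVolume(np.asarray(data, dtype=np.float64), spacing,
                         duration_s=duration_s)
    if kind == "ct":
        return CTVolume(np.asarray(data, dtype=np.float64), spacing)
    raise ValueError("kind must be 'pet' or 'ct'")


# ---------------------------------------------------------------------------
# normalization
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class NormalizationConstants:
    """Dataset-wide maxima used to map intensities to the [0, 1] scale."""
    pet_max_suv: float
    ct_max_hu: float

    def __post_init__(self):
        if self.pet_max_suv <= 0 or self.ct_max_hu <= 0:
            raise ValueError("normalization constants must be positive")


def fit_normalization(pet_volumes, ct_volumes=()) -> NormalizationConstants:
    """Maximum SUV / HU over the training collections.

    An all-zero PET collection (or a CT collection with no positive HU) has
    no usable scale and is rejected.
    """
    pet_volumes = list(pet_volumes)
    ct_volumes = list(ct_volumes)
    if not pet_volumes:
        raise ValueError("need at least one PET volume")
    pet_max = max(float(np.max(v.data)) for v in pet_volumes)
    if pet_max <= 0:
        raise ValueError("degenerate normalization: all-zero PET collection")
    if ct_volumes:
        ct_max = max(float(np.max(v.data)) for v in ct_volumes)
        if ct_max <= 0:
            raise ValueError("degenerate normalization: no positive HU in CT")
    else:
        ct_max = 1.0
    return NormalizationConstants(pet_max_suv=pet_max, ct_max_hu=ct_max)


def _scale_for(vol, constants: NormalizationConstants) -> float:
    return (constants.pet_max_suv if isinstance(vol, PETVolume)
            else constants.ct_max_hu)


def normalize(vol, constants: NormalizationConstants):
    """Divide by the stored dataset maximum; nothing is clipped."""
    scale = _scale_for(vol, constants)
    out = type(vol)(vol.data / scale, vol.voxel_size_mm)
    if isinstance(vol, PETVolume):
        out.duration_s = vol.duration_s
    out.meta = dict(getattr(vol, "meta", {}), normalized=True)
    return out


def denormalize(vol, constants: NormalizationConstants):
    """Inverse of :func:`normalize` (exact elementwise)."""
    scale = _scale_for(vol, constants)
    out = type(vol)(vol.data * scale, vol.voxel_size_mm)
    if isinstance(vol, PETVolume):
        out.duration_s = vol.duration_s
    out.meta = dict(getattr(vol, "meta", {}), normalized=False)
    return out


def save_normalization(constants: NormalizationConstants, path) -> None:
    path = Path(path)
    payload = {"pet_max_suv": constants.pet_max_suv,
               "ct_max_hu": constants.ct_max_hu}
    if path.suffix in {".yaml", ".yml"}:
        path.write_text(yaml.safe_dump(payload))
    else:
        path.write_text(json.dumps(payload))


def load_normalization(path) -> NormalizationConstants:
    path = Path(path)
    text = path.read_text()
    payload = yaml.safe_load(text) if path.suffix in {".yaml", ".yml"} \
        else json.loads(text)
    return NormalizationConstants(**payload)


# ---------------------------------------------------------------------------
# CT -> PET grid resampling
# ---------------------------------------------------------------------------

def resample_to_pet_grid(ct: CTVolume, pet: PETVolume) -> CTVolume:
    """Trilinear resampling of the CT onto the PET voxel grid.

    The two grids are assumed to share the same physical extent origin
    (corner-aligned voxel grids, as produced by the phantom generator);
    positions outside the CT extent are filled with the CT minimum.
    """
    if any(v <= 0 for v in ct.voxel_size_mm) or any(v <= 0 for v in pet.voxel_size_mm):
        raise ValueError("voxel sizes must be positive")
    coords = []
    for ax in range(3):
        idx = np.arange(pet.data.shape[ax], dtype=np.float64)
        coords.append((idx + 0.5) * pet.voxel_size_mm[ax]
                      / ct.voxel_size_mm[ax] - 0.5)
    grid = np.meshgrid(*coords, indexing="ij")
    fill = float(np.min(ct.data))
    out = map_coordinates(ct.data.astype(np.float64), np.stack(grid),
                          order=1, mode="constant", cval=fill)
    return CTVolume(out, pet.voxel_size_mm,
                    meta=dict(getattr(ct, "meta", {}), resampled=True))


# ---------------------------------------------------------------------------
# slab extraction / reassembly
# ---------------------------------------------------------------------------

@dataclass
class SlabStack:
    """Overlapping H x W x S slabs tiling a volume along the depth axis."""
    slabs: list[np.ndarray]
    origin_indices: list[int]
    source_shape: tuple[int, int, int]
    pad_front: int = 0

    def __post_init__(self):
        depths = {s.shape[2] for s in self.slabs}
        if len(depths) > 1:
            raise ValueError("all slabs must share the same depth")
        if any(b <= a for a, b in zip(self.origin_indices, self.origin_indices[1:])):
            raise ValueError("origin_indices must be strictly increasing")


def extract_slabs(vol, S: int = S_DEFAULT, stride: int | None = None) -> SlabStack:
    """Cut a volume (or bare 3D array) into depth-S slabs.

    Origins advance by ``stride`` (default S, seamless tiling; training uses
    a denser stride); if the depth is not reached exactly, a final slab flush
    with the last slice is appended.  Volumes shallower than S are
    front-padded by edge replication and the padding is cropped again by
    :func:`reassemble`.
    """
    if S < 1:
        raise ValueError("S must be >= 1")
    stride = S if stride is None else stride
    if stride < 1:
        raise ValueError("stride must be >= 1")
    data = vol.data if hasattr(vol, "voxel_size_mm") else np.asarray(vol)
    src_shape = data.shape
    pad_front = 0
    if data.shape[2] < S:
        pad_front = S - data.shape[2]
        data = np.concatenate([np.repeat(data[:, :, :1], pad_front, axis=2),
                               data], axis=2)
    depth = data.shape[2]
    origins = list(range(0, depth - S + 1, stride))
    if origins[-1] != depth - S:
        origins.append(depth - S)
    slabs = [data[:, :, o:o + S].copy() for o in origins]
    return SlabStack(slabs=slabs, origin_indices=origins,
                     source_shape=src_shape, pad_front=pad_front)


def reassemble(stack: SlabStack) -> np.ndarray:
    """Voxel-wise average of the overlapping slabs; inverts extract_slabs."""
    H, W, D = stack.source_shape
    depth = D + stack.pad_front
    acc = np.zeros((H, W, depth), dtype=np.float64)
    cnt = np.zeros(depth, dtype=np.float64)
    for slab, o in zip(stack.slabs, stack.origin_indices):
        S = slab.shape[2]
        acc[:, :, o:o + S] += slab
        cnt[o:o + S] += 1.0
    if np.any(cnt == 0):
        raise ValueError("slabs do not cover the depth axis")
    out = acc / cnt[None, None, :]
    return out[:, :, stack.pad_front:]
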