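"""Volumetric CT containers and file I/O.

Volumes are stored as rank-3 float32 arrays in ``(z, y, x)`` index order,
with ``z`` the axial (through-plane) axis whose resolution the model
enhances.  Intensities are Hounsfield units (HU) on disk and in
:class:`Volume`; the model operates on ``[0, 1]`` intensities obtained by
clamping HU to ``[-1024, 2048]`` and rescaling (:func:`normalize_hu`).
"""

from __future__ import annotations

import os
from dataclasses import dataclass, field

import numpy as np
import SimpleITK as sitk

HU_MIN = -1024.0
HU_MAX = 2048.0
HU_RANGE = HU_MAX - HU_MIN  # 3072

_EXTENSIONS = (".nii", ".nii.gz", ".mha", ".mhd")


@dataclass
class Volume:
    """A rank-3 HU image with physical spacing.

    Parameters
    ----------
    values : ndarray, shape (D, H, W)
        HU intensities, indexed ``(z, y, x)``.
    spacing : tuple of float
        ``(dz, dy, dx)`` voxel spacing in mm; all positive.
    origin : tuple of float
        ``(oz, oy, ox)`` position of voxel (0, 0, 0) in mm.
    """

    values: np.ndarray
    spacing: tuple[float, float, float] = (1.0, 1.0, 1.0)
    origin: tuple[float, float, float] = (0.0, 0.0, 0.0)

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=np.float32)
        if self.values.ndim != 3:
            raise ValueError(f"Volume requires a rank-3 array, got rank {self.values.ndim}")
        if self.values.shape[0] < 1:
            raise ValueError("Volume requires at least one slice")
        if not np.all(np.isfinite(self.values)):
            raise ValueError("Volume values must be finite")
        self.spacing = tuple(float(s) for s in self.spacing)
        self.origin = tuple(float(o) for o in self.origin)
        if len(self.spacing) != 3 or any(s <= 0 for s in self.spacing):
            raise ValueError(f"spacing must be 3 positive floats, got {self.spacing}")

    @property
    def shape(self) -> tuple[int, int, int]:
        return self.values.shape

    @property
    def n_slices(self) -> int:
        return self.values.shape[0]


@dataclass
class NormalizedVolume:
    """A rank-3 image with intensities in [0, 1] (model space)."""

    values: np.ndarray
    spacing: tuple[float, float, float] = (1.0, 1.0, 1.0)
    origin: tuple[float, float, float] = (0.0, 0.0, 0.0)

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=np.float32)
        if self.values.ndim != 3:
            raise ValueError(f"NormalizedVolume requires rank 3, got rank {self.values.ndim}")
        lo, hi = float(self.values.min()), float(self.values.max())
        if lo < 0.0 or hi > 1.0:
            raise ValueError(f"normalized values outside [0, 1]: min={lo}, max={hi}")
        self.spacing = tuple(float(s) for s in self.spacing)
        self.origin = tuple(float(o) for o in self.origin)

    @property
    def shape(self) -> tuple[int, int, int]:
        return self.values.shape


def read_volume(path: str | os.PathLike) -> Volume:
    """Read a NIfTI (.nii/.nii.gz) or MetaImage (.mha/.mhd) volume.

    Spacing and origin come from the header; the header's slice axis
    becomes axis 0 of :attr:`Volume.values` (SimpleITK's array order is
    already ``(z, y, x)``).
    """
    path = os.fspath(path)
    if not os.path.exists(path):
        raise IOError(f"cannot read volume: no such file {path!r}")
    try:
        img = sitk.ReadImage(path)
    except Exception as exc:  # sitk raises RuntimeError on malformed files
        raise IOError(f"cannot read volume {path!r}: {exc}") from exc
    if img.GetDimension() != 3:
        raise IOError(f"{path!r}: expected a 3-D image, got {img.GetDimension()}-D")
    arr = sitk.GetArrayFromImage(img).astype(np.float32)
    sx, sy, sz = img.GetSpacing()  # sitk orders (x, y, z)
    ox, oy, oz = img.GetOrigin()
    return Volume(arr, spacing=(sz, sy, sx), origin=(oz, oy, ox))


def write_volume(v: Volume, path: str | os.PathLike) -> str:
    """Write a volume to NIfTI or MetaImage, inferred from the extension."""
    path = os.fspath(path)
    if not path.endswith(_EXTENSIONS):
        raise IOError(f"unsupported extension for {path!r}; use one of {_EXTENSIONS}")
    parent = os.path.dirname(path) or "."
    if not os.path.isdir(parent):
        raise IOError(f"cannot write volume: no such directory {parent!r}")
    img = sitk.GetImageFromArray(v.values.astype(np.float32))
    dz, dy, dx = v.spacing
    oz, oy, ox = v.origin
    img.SetSpacing((dx, dy, dz))
    img.SetOrigin((ox, oy, oz))
    try:
        sitk.WriteImage(img, path)
    except Exception as exc:
        raise IOError(f"cannot write volume {path!r}: {exc}") from exc
    return path


def normalize_hu(v: Volume) -> NormalizedVolume:
    """Map HU to model space: clamp to [-1024, 2048], rescale to [0, 1]."""
    out = (np.clip(v.values, HU_MIN, HU_MAX) - HU_MIN) / HU_RANGE
    return NormalizedVolume(out.astype(np.float32), spacing=v.spacing, origin=v.origin)


def denormalize(nv: NormalizedVolume) -> Volume:
    """Inverse of :func:`normalize_hu` on its range: [0, 1] -> HU."""
    vals = np.asarray(nv.values, dtype=np.float32)
    if vals.min() < 0.0 or vals.max() > 1.0:
        raise ValueError("denormalize requires values in [0, 1]")
    return Volume(vals * HU_RANGE + HU_MIN, spacing=nv.spacing, origin=nv.origin)
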