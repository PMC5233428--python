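"""NIfTI / FSL-gradient I/O for diffusion-weighted volumes and derived maps.

Conventions: voxel indices are 0-based; gradient vectors are interpreted in
the image frame (FSL bvecs convention, no rotation by the affine); all
volumes are written as single-precision NIfTI-1.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Optional

import nibabel as nib
import numpy as np

__all__ = [
    "GradientTable",
    "DwiVolume",
    "DwiFormatError",
    "CalibrationError",
    "read_dwi",
    "write_dwi",
    "write_scalar_map",
    "write_coefficients",
    "write_peaks",
    "read_peaks",
]

DEFAULT_B0_THRESHOLD = 50.0  # s/mm^2


class DwiFormatError(ValueError):
    """Inconsistent image / gradient-file geometry."""


class CalibrationError(ValueError):
    """Data insufficient to calibrate (no b=0 volume, too few voxels, ...)."""


@dataclass(frozen=True)
class GradientTable:
    """Acquisition geometry: one b-value (s/mm^2) and unit direction per volume."""

    bvals: np.ndarray
    bvecs: np.ndarray
    b0_threshold: float = DEFAULT_B0_THRESHOLD

    def __post_init__(self):
        bvals = np.atleast_1d(np.asarray(self.bvals, dtype=float))
        bvecs = np.asarray(self.bvecs, dtype=float)
        if bvecs.ndim != 2 or bvecs.shape[1] != 3:
            raise DwiFormatError(f"bvecs must be (N, 3), got {bvecs.shape}")
        if len(bvals) != len(bvecs):
            raise DwiFormatError(
                f"{len(bvals)} bvals but {len(bvecs)} bvecs"
            )
        if np.any(bvals < 0):
            raise DwiFormatError("negative b-values")
        dw = bvals > self.b0_threshold
        norms = np.linalg.norm(bvecs[dw], axis=1)
        if np.any(np.abs(norms - 1.0) > 1e-4):
            raise DwiFormatError("diffusion-weighted bvecs must have unit norm")
        object.__setattr__(self, "bvals", bvals)
        object.__setattr__(self, "bvecs", bvecs)

    def __len__(self) -> int:
        return len(self.bvals)

    @property
    def b0_mask(self) -> np.ndarray:
        return self.bvals <= self.b0_threshold

    @property
    def dwi_mask(self) -> np.ndarray:
        return ~self.b0_mask

    @classmethod
    def from_files(cls, bvals_path, bvecs_path,
                   b0_threshold: float = DEFAULT_B0_THRESHOLD) -> "GradientTable":
        bvals = np.atleast_1d(np.loadtxt(bvals_path))
        bvecs = np.atleast_2d(np.loadtxt(bvecs_path))
        if bvecs.shape[0] == 3 and bvecs.shape[1] != 3:
            bvecs = bvecs.T  # FSL dialect: 3 rows of N entries
        elif bvecs.shape == (3, 3):
            pass  # ambiguous; FSL files are row-major 3xN, keep as-is
        return cls(bvals, bvecs, b0_threshold)

    def to_files(self, bvals_path, bvecs_path) -> None:
        np.savetxt(bvals_path, self.bvals[None, :], fmt="%.6g")
        np.savetxt(bvecs_path, self.bvecs.T, fmt="%+.17e")


@dataclass
class DwiVolume:
    """A 4D diffusion-weighted image with optional brain mask."""

    data: np.ndarray
    affine: np.ndarray
    mask: Optional[np.ndarray] = None

    def __post_init__(self):
        self.data = np.asarray(self.data)
        if self.data.ndim != 4:
            raise DwiFormatError(f"DWI data must be 4D, got shape {self.data.shape}")
        if self.mask is not None:
            self.mask = np.asarray(self.mask).astype(bool)
            if self.mask.shape != self.data.shape[:3]:
                raise DwiFormatError("mask shape does not match spatial shape")

    @property
    def spatial_shape(self):
        return self.data.shape[:3]

    def s0(self, gtab: GradientTable) -> np.ndarray:
        """Per-voxel b=0 reference: mean over the b0 volumes."""
        b0 = gtab.b0_mask
        if not b0.any():
            raise CalibrationError("no b=0 volume below the b0 threshold")
        return self.data[..., b0].mean(axis=-1)

    def attenuations(self, gtab: GradientTable, include_b0: bool = True):
        """Per-voxel attenuations S/S0.

        By default the b=0 columns are kept (attenuation ~ 1 there): the
        deconvolution model fits them too, since they pin the total
        compartment volume.  ``include_b0=False`` restricts to the
        diffusion-weighted volumes (tensor fitting).  Voxels with
        nonpositive S0 are removed from the returned mask.
        """
        s0 = self.s0(gtab)
        valid = s0 > 0
        mask = valid if self.mask is None else (self.mask & valid)
        cols = slice(None) if include_b0 else gtab.dwi_mask
        n_cols = len(gtab) if include_b0 else int(gtab.dwi_mask.sum())
        att = np.zeros(self.spatial_shape + (n_cols,))
        att[valid] = self.data[valid][:, cols] / s0[valid, None]
        return att, mask


# ---------------------------------------------------------------------------
# readers / writers
# ---------------------------------------------------------------------------

def read_dwi(image_path, bvals_path, bvecs_path, mask_path=None,
             b0_threshold: float = DEFAULT_B0_THRESHOLD):
    """Load a DWI volume plus FSL gradient files (and optional mask)."""
    img = nib.load(str(image_path))
    data = np.asarray(img.dataobj, dtype=np.float32)
    gtab = GradientTable.from_files(bvals_path, bvecs_path, b0_threshold)
    if data.ndim != 4 or data.shape[3] != len(gtab):
        raise DwiFormatError(
            f"image has {data.shape[3] if data.ndim == 4 else 'non-4D'} volumes "
            f"but gradient table has {len(gtab)} entries"
        )
    if not gtab.b0_mask.any():
        raise CalibrationError("gradient table contains no b=0 volume")
    mask = None
    if mask_path is not None:
        mask = np.asarray(nib.load(str(mask_path)).dataobj) > 0
    return DwiVolume(data, np.asarray(img.affine), mask), gtab


def _check_finite(arr, what):
    if not np.all(np.isfinite(arr)):
        idx = tuple(int(i) for i in
                    np.unravel_index(int(np.argmax(~np.isfinite(arr))), arr.shape))
        raise ValueError(f"non-finite value in {what} at voxel index {idx}")


def _save(arr, affine, path):
    nib.save(nib.Nifti1Image(np.asarray(arr, dtype=np.float32), affine), str(path))


def write_dwi(volume: DwiVolume, gtab: GradientTable, image_path,
              bvals_path, bvecs_path, mask_path=None) -> None:
    _check_finite(volume.data, "DWI data")
    _save(volume.data, volume.affine, image_path)
    gtab.to_files(bvals_path, bvecs_path)
    if mask_path is not None and volume.mask is not None:
        _save(volume.mask.astype(np.float32), volume.affine, mask_path)


def write_scalar_map(volume3d, affine, path) -> None:
    arr = np.asarray(volume3d)
    if arr.ndim != 3:
        raise DwiFormatError("scalar map must be 3D")
    _check_finite(arr, "scalar map")
    _save(arr, affine, path)


def write_coefficients(field4d, affine, path) -> None:
    arr = np.asarray(field4d)
    if arr.ndim != 4:
        raise DwiFormatError("coefficient field must be 4D (spatial x channels)")
    _check_finite(arr, "coefficient field")
    _save(arr, affine, path)


def write_peaks(peaks5d, affine, path, max_peaks: int = 3) -> None:
    """Write peak directions as spatial dims x (max_peaks*3), zero-padded."""
    arr = np.asarray(peaks5d, dtype=float)
    if arr.ndim != 5 or arr.shape[4] != 3:
        raise DwiFormatError("peaks array must be (x, y, z, n_peaks, 3)")
    _check_finite(arr, "peaks volume")
    n = arr.shape[3]
    if n > max_peaks:
        arr = arr[:, :, :, :max_peaks, :]
        n = max_peaks
    out = np.zeros(arr.shape[:3] + (max_peaks, 3), dtype=np.float32)
    out[:, :, :, :n, :] = arr
    _save(out.reshape(arr.shape[:3] + (max_peaks * 3,)), affine, path)


def read_peaks(path, max_peaks: int = 3) -> np.ndarray:
    img = nib.load(str(path))
    arr = np.asarray(img.dataobj, dtype=np.float32)
    return arr.reshape(arr.shape[:3] + (max_peaks, 3))
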