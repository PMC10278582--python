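"""Acquisition description and NIfTI / gradient-table I/O.

The whole pipeline shares two pieces of plumbing: the multi-shell
acquisition scheme (b-values plus unit gradient directions, FSL
``.bval``/``.bvec`` dialect) and a thin image container that keeps the
voxel grid tied to world coordinates through the NIfTI affine.
Gradient vectors are interpreted in the image frame; no re-orientation
by the affine is applied, because the analysis is carried out in-plane
on acquired coronal slices.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path

import nibabel as nib
import numpy as np

__all__ = [
    "AcquisitionScheme",
    "ImageVolume",
    "FormatError",
    "read_scheme",
    "write_scheme",
    "read_volume",
    "write_volume",
]

#: b-values below this (s/mm^2) count as non-diffusion-weighted.
DEFAULT_B0_THRESHOLD = 10.0


class FormatError(ValueError):
    """Raised when an on-disk file does not match the expected dialect."""


@dataclass(frozen=True)
class AcquisitionScheme:
    """Multi-shell diffusion sampling scheme.

    Parameters
    ----------
    bvals : (V,) array
        Diffusion weighting per volume in s/mm^2, non-negative.
    bvecs : (V, 3) array
        Unit gradient directions; the zero vector is allowed (and
        expected) for b=0 volumes.
    b0_threshold : float
        b-values at or below this are classified as b=0.
    """

    bvals: np.ndarray
    bvecs: np.ndarray
    b0_threshold: float = DEFAULT_B0_THRESHOLD

    def __post_init__(self) -> None:
        bvals = np.atleast_1d(np.asarray(self.bvals, dtype=float))
        bvecs = np.asarray(self.bvecs, dtype=float)
        if bvecs.ndim != 2 or bvecs.shape[1] != 3:
            raise FormatError(f"bvecs must be (n, 3), got {bvecs.shape}")
        if len(bvals) != len(bvecs):
            raise FormatError(
                f"{len(bvals)} b-values but {len(bvecs)} directions"
            )
        if np.any(bvals < 0):
            raise ValueError("b-values must be non-negative")
        norms = np.linalg.norm(bvecs, axis=1)
        weighted = bvals > self.b0_threshold
        if np.any(np.abs(norms[weighted] - 1.0) > 1e-6):
            bad = np.argmax(np.abs(norms[weighted] - 1.0) > 1e-6)
            raise ValueError(
                f"non-unit gradient direction on weighted volume (norm={norms[weighted][bad]:g})"
            )
        object.__setattr__(self, "bvals", bvals)
        object.__setattr__(self, "bvecs", bvecs)

    @property
    def is_b0(self) -> np.ndarray:
        return self.bvals <= self.b0_threshold

    @property
    def n_b0(self) -> int:
        return int(np.count_nonzero(self.is_b0))

    @property
    def n_volumes(self) -> int:
        return len(self.bvals)

    @property
    def shells(self) -> np.ndarray:
        """Unique nonzero b-values, ascending."""
        return np.unique(self.bvals[~self.is_b0])

    def __len__(self) -> int:
        return self.n_volumes


@dataclass
class ImageVolume:
    """A scalar image (2D slice, 3D volume, or 4D series) with geometry."""

    data: np.ndarray
    voxel_size: tuple
    affine: np.ndarray = field(default=None)  # type: ignore[assignment]

    def __post_init__(self) -> None:
        self.data = np.asarray(self.data)
        self.voxel_size = tuple(float(v) for v in self.voxel_size)
        if any(v <= 0 for v in self.voxel_size):
            raise ValueError(f"voxel size must be positive, got {self.voxel_size}")
        if self.affine is None:
            aff = np.eye(4)
            for i, v in enumerate(self.voxel_size[:3]):
                aff[i, i] = v
            self.affine = aff
        self.affine = np.asarray(self.affine, dtype=float)
        if self.affine.shape != (4, 4) or abs(np.linalg.det(self.affine)) < 1e-12:
            raise ValueError("affine must be an invertible 4x4 matrix")

    @property
    def shape(self) -> tuple:
        return self.data.shape


def _parse_rows(path: Path) -> np.ndarray:
    rows = []
    for line in Path(path).read_text().splitlines():
        line = line.strip()
        if line:
            try:
                rows.append([float(tok) for tok in line.split()])
            except ValueError as exc:
                raise FormatError(f"{path}: non-numeric entry ({exc})") from None
    if not rows:
        raise FormatError(f"{path}: empty gradient file")
    return np.array(rows, dtype=float)


def read_scheme(
    bval_path, bvec_path, b0_threshold: float = DEFAULT_B0_THRESHOLD
) -> AcquisitionScheme:
    """Read an FSL-dialect .bval/.bvec pair.

    The FSL dialect stores b-values as a single whitespace-separated row
    and directions as three rows (x, y, z components).  A one-line-per-
    volume table is rejected with an explicit message.
    """
    bval_rows = _parse_rows(Path(bval_path))
    if bval_rows.shape[0] != 1:
        raise FormatError(
            f"{bval_path}: expected one row of b-values (FSL dialect), "
            f"got {bval_rows.shape[0]} rows — transposed table?"
        )
    bvals = bval_rows[0]
    bvec_rows = _parse_rows(Path(bvec_path))
    if bvec_rows.shape[0] != 3:
        raise FormatError(
            f"{bvec_path}: expected three rows (x/y/z, FSL dialect), "
            f"got {bvec_rows.shape[0]} rows — transposed table?"
        )
    if bvec_rows.shape[1] != len(bvals):
        raise FormatError(
            f"count mismatch: {len(bvals)} b-values vs "
            f"{bvec_rows.shape[1]} gradient columns"
        )
    return AcquisitionScheme(bvals, bvec_rows.T, b0_threshold=b0_threshold)


def write_scheme(scheme: AcquisitionScheme, bval_path, bvec_path) -> None:
    """Write a scheme back out in the FSL dialect."""
    Path(bval_path).write_text(
        " ".join(f"{b:.6g}" for b in scheme.bvals) + "\n"
    )
    lines = [
        " ".join(f"{v:.8f}" for v in scheme.bvecs[:, ax])
        for ax in range(3)
    ]
    Path(bvec_path).write_text("\n".join(lines) + "\n")


def read_volume(path) -> ImageVolume:
    """Read a NIfTI-1 image into an :class:`ImageVolume`."""
    try:
        img = nib.load(str(path))
    except Exception as exc:  # nibabel raises several unrelated types
        raise FormatError(f"{path}: not a readable NIfTI file ({exc})") from None
    if not isinstance(img, nib.Nifti1Image):
        raise FormatError(f"{path}: not NIfTI-1 (got {type(img).__name__})")
    zooms = tuple(img.header.get_zooms()[:3])
    zooms = zooms + (1.0,) * (3 - len(zooms))
    return ImageVolume(
        np.asarray(img.dataobj), zooms, np.asarray(img.affine)
    )


def write_volume(vol: ImageVolume, path) -> None:
    data = vol.data
    if data.dtype == bool:
        data = data.astype(np.uint8)
    elif data.dtype in (np.int64, np.uint64):
        data = data.astype(np.int32)  # NIfTI-1 has no 64-bit int type
    img = nib.Nifti1Image(data, vol.affine)
    img.header.set_zooms(vol.voxel_size[: min(3, data.ndim)])
    nib.save(img, str(path))
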