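"""Volumetric I/O and the voxel-geometry contract.

A :class:`CTVolume` is a 3-D grid of Hounsfield-unit (HU) values indexed
``(slice, row, col)`` with the slice axis along the axial (z) direction.
Spacings are in millimetres; the physical volume of one voxel is the
product of the three spacings.  HU values are stored as floating point
after rescale — no windowing is ever applied at I/O time, because every
downstream threshold (e.g. the −825 HU air-density cut) is defined in HU.

Volumes and masks travel as NIfTI (``.nii`` / ``.nii.gz``) via nibabel.
Masks carry a ``role`` tag (lung / injured_candidate / vessel /
injured_final) stored in a JSON sidecar next to the NIfTI file.

A plain-text "slice series" layout (a directory of per-slice ``.txt``
arrays plus a ``series.json`` sidecar with slice positions and the
rescale slope/intercept) stands in for a scanner series: slices are
re-ordered by physical position, stored values are converted to HU via
``HU = slope * stored + intercept``, and non-uniform slice spacing is
rejected.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field, replace
from enum import Enum
from pathlib import Path

import nibabel as nib
import numpy as np

__all__ = [
    "CTVolume",
    "BinaryMask",
    "MaskRole",
    "read_ct_series",
    "read_volume",
    "write_volume",
    "read_mask",
    "write_mask",
]

#: Relative tolerance on slice-spacing uniformity within one series.
SLICE_SPACING_RTOL = 0.01


class MaskRole(str, Enum):
    lung = "lung"
    injured_candidate = "injured_candidate"
    vessel = "vessel"
    injured_final = "injured_final"


@dataclass
class CTVolume:
    """A CT scan as HU values on a regular grid.

    Parameters
    ----------
    voxels : ndarray, shape (n_slices, n_rows, n_cols)
        Hounsfield-unit values, float.
    spacing_mm : tuple of float
        (slice_increment, row, col) spacing in mm; all positive.
    origin_mm : tuple of float
        Physical position of voxel (0, 0, 0).
    scan_id : str
        Identifier used to tie masks and results back to the scan.
    acquisition_time : str or None
        Optional ISO timestamp; admission/follow-up ordering is the
        caller's responsibility (scans are analysed independently).
    """

    voxels: np.ndarray
    spacing_mm: tuple[float, float, float]
    origin_mm: tuple[float, float, float] = (0.0, 0.0, 0.0)
    scan_id: str = "scan"
    acquisition_time: str | None = None

    def __post_init__(self) -> None:
        self.voxels = np.asarray(self.voxels, dtype=np.float64)
        if self.voxels.ndim != 3:
            raise ValueError(f"voxels must be 3-D, got ndim={self.voxels.ndim}")
        if self.voxels.shape[0] < 3:
            raise ValueError(
                "need at least 3 slices (the 3-D mean-CT correlation uses "
                f"slices n-1, n, n+1); got {self.voxels.shape[0]}"
            )
        if not np.all(np.isfinite(self.voxels)):
            raise ValueError("voxels contain non-finite HU values")
        self.spacing_mm = tuple(float(s) for s in self.spacing_mm)
        if len(self.spacing_mm) != 3 or any(s <= 0 for s in self.spacing_mm):
            raise ValueError(f"spacings must be 3 positive mm values, got {self.spacing_mm}")

    @property
    def shape(self) -> tuple[int, int, int]:
        return self.voxels.shape

    @property
    def voxel_volume_mm3(self) -> float:
        """Physical volume of one voxel: product of the three spacings."""
        s = self.spacing_mm
        return s[0] * s[1] * s[2]

    def with_voxels(self, voxels: np.ndarray) -> "CTVolume":
        """Same geometry/metadata, new voxel values."""
        return replace(self, voxels=np.asarray(voxels, dtype=np.float64))


@dataclass
class BinaryMask:
    """Boolean grid aligned to a :class:`CTVolume`."""

    bits: np.ndarray
    role: MaskRole
    source_scan_id: str = "scan"
    spacing_mm: tuple[float, float, float] | None = None

    def __post_init__(self) -> None:
        self.bits = np.asarray(self.bits, dtype=bool)
        if self.bits.ndim != 3:
            raise ValueError("mask bits must be 3-D")
        self.role = MaskRole(self.role)

    @property
    def shape(self) -> tuple[int, int, int]:
        return self.bits.shape

    def count(self) -> int:
        return int(self.bits.sum())

    def check_aligned(self, volume: CTVolume) -> None:
        if self.bits.shape != volume.shape:
            raise ValueError(
                f"mask shape {self.bits.shape} does not match volume {volume.shape}"
            )


# ---------------------------------------------------------------------------
# NIfTI round-trip
# ---------------------------------------------------------------------------

def _affine(spacing_mm, origin_mm) -> np.ndarray:
    # nibabel stores (x, y, z) = our (col, row, slice); keep a diagonal affine.
    aff = np.diag([spacing_mm[2], spacing_mm[1], spacing_mm[0], 1.0])
    aff[:3, 3] = [origin_mm[2], origin_mm[1], origin_mm[0]]
    return aff


def _spacing_from_affine(aff: np.ndarray) -> tuple[float, float, float]:
    zooms = np.sqrt((aff[:3, :3] ** 2).sum(axis=0))
    return (float(zooms[2]), float(zooms[1]), float(zooms[0]))


def write_volume(volume: CTVolume, path: str | Path) -> Path:
    """Write a CTVolume as NIfTI (float32 HU, no scaling)."""
    path = Path(path)
    data = np.transpose(volume.voxels, (2, 1, 0)).astype(np.float32)
    img = nib.Nifti1Image(data, _affine(volume.spacing_mm, volume.origin_mm))
    img.header.set_data_dtype(np.float32)
    img.header["descrip"] = volume.scan_id.encode()[:79]
    nib.save(img, str(path))
    return path


def read_volume(path: str | Path, scan_id: str | None = None) -> CTVolume:
    """Read a NIfTI volume as a CTVolume (values taken as HU)."""
    img = nib.load(str(path))
    data = np.asarray(img.get_fdata(), dtype=np.float64)
    if data.ndim != 3:
        raise ValueError(f"{path}: expected a 3-D volume, got ndim={data.ndim}")
    voxels = np.transpose(data, (2, 1, 0))
    aff = img.affine
    if scan_id is None:
        scan_id = img.header["descrip"].tobytes().split(b"\x00")[0].decode() or Path(path).stem
    origin = (float(aff[2, 3]), float(aff[1, 3]), float(aff[0, 3]))
    return CTVolume(voxels, _spacing_from_affine(aff), origin, scan_id=scan_id)


def write_mask(mask: BinaryMask, path: str | Path) -> Path:
    """Write a BinaryMask as a 0/1 NIfTI plus a JSON role sidecar."""
    path = Path(path)
    spacing = mask.spacing_mm or (1.0, 1.0, 1.0)
    data = np.transpose(mask.bits.astype(np.uint8), (2, 1, 0))
    img = nib.Nifti1Image(data, _affine(spacing, (0.0, 0.0, 0.0)))
    img.header.set_data_dtype(np.uint8)
    nib.save(img, str(path))
    sidecar = {"role": mask.role.value, "source_scan_id": mask.source_scan_id}
    _sidecar_path(path).write_text(json.dumps(sidecar))
    return path


def read_mask(path: str | Path, reference: CTVolume | None = None) -> BinaryMask:
    """Read a mask written by :func:`write_mask`.

    If `reference` is given the mask shape must match it.
    """
    img = nib.load(str(path))
    bits = np.transpose(np.asarray(img.get_fdata()) > 0.5, (2, 1, 0))
    meta = {"role": "lung", "source_scan_id": Path(path).stem}
    sc = _sidecar_path(Path(path))
    if sc.exists():
        meta.update(json.loads(sc.read_text()))
    mask = BinaryMask(
        bits,
        MaskRole(meta["role"]),
        source_scan_id=meta["source_scan_id"],
        spacing_mm=_spacing_from_affine(img.affine),
    )
    if reference is not None:
        mask.check_aligned(reference)
    return mask


def _sidecar_path(path: Path) -> Path:
    name = path.name
    for suffix in (".nii.gz", ".nii"):
        if name.endswith(suffix):
            return path.with_name(name[: -len(suffix)] + ".json")
    return path.with_suffix(".json")


# ---------------------------------------------------------------------------
# Plain-text slice series (stands in for a scanner series directory)
# ---------------------------------------------------------------------------

def write_ct_series(volume: CTVolume, directory: str | Path,
                    slope: float = 1.0, intercept: float = -1024.0) -> Path:
    """Write a per-slice text series with rescale metadata (testing aid).

    Stored values are ``(HU - intercept) / slope`` so that reading the
    series back through the rescale formula recovers the HU values.
    """
    directory = Path(directory)
    directory.mkdir(parents=True, exist_ok=True)
    positions = [volume.origin_mm[0] + i * volume.spacing_mm[0]
                 for i in range(volume.shape[0])]
    meta = {
        "scan_id": volume.scan_id,
        "rescale_slope": slope,
        "rescale_intercept": intercept,
        "pixel_spacing_mm": [volume.spacing_mm[1], volume.spacing_mm[2]],
        "slices": [],
    }
    for i, pos in enumerate(positions):
        fname = f"slice_{i:04d}.txt"
        stored = (volume.voxels[i] - intercept) / slope
        np.savetxt(directory / fname, stored, fmt="%.6f")
        meta["slices"].append({"file": fname, "position_mm": pos})
    (directory / "series.json").write_text(json.dumps(meta, indent=1))
    return directory


def read_ct_series(path: str | Path) -> CTVolume:
    """Read one axial series (text-series directory or a NIfTI file).

    Slices are ordered by physical position, stored values converted to
    HU via the rescale slope/intercept, and spacing populated from the
    metadata.  A series whose successive slice gaps differ by more than
    1% is rejected as non-uniform; missing rescale tags are an error.
    """
    path = Path(path)
    if path.is_file():
        return read_volume(path)
    meta_path = path / "series.json"
    if not meta_path.exists():
        raise FileNotFoundError(f"{path}: no series.json sidecar found")
    meta = json.loads(meta_path.read_text())
    for tag in ("rescale_slope", "rescale_intercept"):
        if tag not in meta:
            raise ValueError(f"{path}: missing rescale tag '{tag}'")
    slices = sorted(meta["slices"], key=lambda s: s["position_mm"])
    if len(slices) < 3:
        raise ValueError(f"{path}: a series needs at least 3 slices")
    positions = np.array([s["position_mm"] for s in slices], dtype=float)
    gaps = np.diff(positions)
    if np.any(gaps <= 0):
        raise ValueError(f"{path}: duplicate or unordered slice positions")
    if (gaps.max() - gaps.min()) > SLICE_SPACING_RTOL * gaps.mean():
        raise ValueError(
            f"{path}: non-uniform slice spacing {sorted(set(np.round(gaps, 6)))} mm"
        )
    slope = float(meta["rescale_slope"])
    intercept = float(meta["rescale_intercept"])
    stack = np.stack([np.loadtxt(path / s["file"]) for s in slices])
    voxels = slope * stack + intercept
    row_mm, col_mm = (float(v) for v in meta["pixel_spacing_mm"])
    return CTVolume(
        voxels,
        (float(gaps.mean()), row_mm, col_mm),
        origin_mm=(float(positions[0]), 0.0, 0.0),
        scan_id=meta.get("scan_id", path.name),
    )
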