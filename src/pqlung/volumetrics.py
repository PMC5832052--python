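"""Volumes, injured-lung fractions, and the longitudinal prognostic ratio.

The injured lung volume fraction of one scan is the injured lung volume
divided by the whole lung volume (the denominator includes the injured
voxels).  The prognostic quantity is the *ratio of injured lung volume
fractions*: first-scan fraction over second-scan fraction.  A low ratio
means the injury grew quickly between scans — rapid disease evolution
and poor prognosis; values near or above 1 mean stable or resolving
injury.

Volumes are exact voxel counts times the voxel volume (spacing product),
reported in ml.  Mesh export (marching cubes) exists for visualisation
only and never feeds the volumetry.
"""

from __future__ import annotations

import json
from dataclasses import asdict, dataclass

import numpy as np
from scipy import ndimage
from skimage import measure

from .volume_io import BinaryMask, MaskRole

__all__ = [
    "VolumetricsResult",
    "RatioResult",
    "remove_small_regions",
    "mask_volume",
    "injured_fraction",
    "fraction_ratio",
    "export_mesh",
]

DEFAULT_MIN_VOXELS = 30


@dataclass(frozen=True)
class VolumetricsResult:
    scan_id: str
    whole_lung_ml: float
    injured_ml: float
    injured_fraction: float

    def __post_init__(self) -> None:
        if self.injured_ml > self.whole_lung_ml * (1 + 1e-12):
            raise ValueError("injured volume exceeds whole-lung volume")
        if not (0.0 <= self.injured_fraction <= 1.0):
            raise ValueError("fraction out of [0, 1]")

    def to_dict(self) -> dict:
        return asdict(self)


@dataclass(frozen=True)
class RatioResult:
    fraction_scan1: float
    fraction_scan2: float
    ratio: float

    @property
    def ratio_2dp(self) -> float:
        """Presentation value, rounded to 2 decimals as reported clinically."""
        return round(self.ratio, 2)

    def to_dict(self) -> dict:
        d = asdict(self)
        d["ratio_2dp"] = self.ratio_2dp
        return d


def remove_small_regions(mask: BinaryMask, min_voxels: int = DEFAULT_MIN_VOXELS,
                         connectivity: int = 26) -> BinaryMask:
    """Delete every connected component smaller than `min_voxels`.

    Isolated specks of a few voxels are classifier noise, not injury;
    26-connectivity matches the region-growing convention.
    """
    if min_voxels < 0:
        raise ValueError("min_voxels must be >= 0")
    if min_voxels == 0:
        bits = mask.bits.copy()
    else:
        structure = (np.ones((3, 3, 3), bool) if connectivity == 26
                     else ndimage.generate_binary_structure(3, 1))
        labels, n = ndimage.label(mask.bits, structure=structure)
        if n == 0:
            bits = mask.bits.copy()
        else:
            sizes = ndimage.sum_labels(np.ones_like(labels), labels,
                                       index=np.arange(1, n + 1))
            keep = np.concatenate([[False], sizes >= min_voxels])
            bits = keep[labels]
    return BinaryMask(bits, MaskRole.injured_final,
                      source_scan_id=mask.source_scan_id, spacing_mm=mask.spacing_mm)


def mask_volume(mask: BinaryMask, spacing_mm=None) -> float:
    """Volume in ml: true-voxel count x voxel volume (mm^3) / 1000."""
    spacing = spacing_mm or mask.spacing_mm
    if spacing is None:
        raise ValueError("spacing required (on the mask or as an argument)")
    voxel_mm3 = float(np.prod(spacing))
    return mask.count() * voxel_mm3 / 1000.0


def injured_fraction(injured: BinaryMask, lung: BinaryMask,
                     spacing_mm=None, scan_id: str | None = None) -> VolumetricsResult:
    """Injured lung volume fraction of one scan.

    The injured mask is intersected with the lung mask first, so the
    subset invariant holds by construction.
    """
    if injured.shape != lung.shape:
        raise ValueError("injured/lung mask shape mismatch")
    if not lung.bits.any():
        raise ValueError("empty lung mask: fraction undefined")
    spacing = spacing_mm or lung.spacing_mm or injured.spacing_mm or (1.0, 1.0, 1.0)
    inj = BinaryMask(injured.bits & lung.bits, MaskRole.injured_final,
                     source_scan_id=injured.source_scan_id, spacing_mm=tuple(spacing))
    lung_ml = mask_volume(lung, spacing)
    inj_ml = mask_volume(inj, spacing)
    return VolumetricsResult(
        scan_id=scan_id or lung.source_scan_id,
        whole_lung_ml=lung_ml, injured_ml=inj_ml,
        injured_fraction=inj.count() / lung.count(),
    )


def fraction_ratio(scan1: VolumetricsResult, scan2: VolumetricsResult) -> RatioResult:
    """Ratio of injured lung volume fractions, scan 1 over scan 2.

    A zero second-scan fraction leaves the ratio undefined (the injury
    resolved entirely or was never detected) and raises rather than
    silently coercing.
    """
    if scan2.injured_fraction <= 0:
        raise ZeroDivisionError(
            "second-scan injured fraction is 0: ratio undefined "
            "(disease resolved or misdetection)"
        )
    return RatioResult(
        fraction_scan1=scan1.injured_fraction,
        fraction_scan2=scan2.injured_fraction,
        ratio=scan1.injured_fraction / scan2.injured_fraction,
    )


# ---------------------------------------------------------------------------
# Mesh export (visualisation only)
# ---------------------------------------------------------------------------

def export_mesh(mask: BinaryMask, spacing_mm=None, path=None):
    """Closed triangulated surface of a mask via marching cubes.

    Returns ``(verts, faces, volume_mm3)`` with the mesh-enclosed volume
    from the divergence theorem; writes ASCII STL when `path` is given.
    The mask is zero-padded first so surfaces close at the grid border.
    """
    if not mask.bits.any():
        raise ValueError("cannot mesh an empty mask")
    spacing = spacing_mm or mask.spacing_mm or (1.0, 1.0, 1.0)
    padded = np.pad(mask.bits.astype(np.float64), 1)
    verts, faces, _, _ = measure.marching_cubes(padded, level=0.5,
                                                spacing=tuple(spacing))
    verts = verts - np.asarray(spacing)  # undo padding offset
    tri = verts[faces]
    vol = float(abs(np.einsum("ij,ij->i", tri[:, 0],
                              np.cross(tri[:, 1], tri[:, 2])).sum()) / 6.0)
    if path is not None:
        _write_stl(verts, faces, path)
    return verts, faces, vol


def mesh_to_mask(verts: np.ndarray, faces: np.ndarray, shape, spacing_mm) -> np.ndarray:
    """Re-voxelise a closed mesh by even-odd ray casting.

    For every (row, col) column a ray is cast along the slice axis; a
    voxel centre is inside when an odd number of triangle crossings lies
    below it.  Columns are nudged by a tiny offset so rays avoid hitting
    triangle edges exactly.
    """
    spacing = np.asarray(spacing_mm, dtype=float)
    tri = (verts / spacing)[faces]               # voxel-index coordinates
    # near-silhouette triangles project edge-on for any single ray axis,
    # leaving cracks; cast along all three axes and take a majority vote
    votes = np.zeros(shape, dtype=np.int8)
    for axis in range(3):
        order = (axis, (axis + 1) % 3, (axis + 2) % 3)
        cast = _parity_cast(tri[:, :, order], tuple(np.asarray(shape)[list(order)]))
        votes += np.moveaxis(cast, (0, 1, 2), order)
    return votes >= 2


def _parity_cast(tri: np.ndarray, shape) -> np.ndarray:
    """Even-odd inside test, rays along axis 0 of `tri` coordinates."""
    a, b, c = tri[:, 0], tri[:, 1], tri[:, 2]
    d = ((b[:, 1] - a[:, 1]) * (c[:, 2] - a[:, 2])
         - (b[:, 2] - a[:, 2]) * (c[:, 1] - a[:, 1]))
    keep = np.abs(d) > 1e-12
    a, b, c, d = a[keep], b[keep], c[keep], d[keep]
    out = np.zeros(shape, dtype=bool)
    # rays must avoid the integer/half-integer grid lines where marching-
    # cubes vertices live AND the +-45-degree triangulation diagonals;
    # two unequal sub-voxel offsets clear all of them
    eps_y, eps_x = 0.2137, 0.3391
    z_centres = np.arange(shape[0])
    for row in range(shape[1]):
        py = row + eps_y
        for col in range(shape[2]):
            px = col + eps_x
            u = ((c[:, 2] - a[:, 2]) * (py - a[:, 1])
                 - (c[:, 1] - a[:, 1]) * (px - a[:, 2])) / d
            v = ((b[:, 1] - a[:, 1]) * (px - a[:, 2])
                 - (b[:, 2] - a[:, 2]) * (py - a[:, 1])) / d
            hit = (u >= 0) & (v >= 0) & (u + v <= 1)
            if not hit.any():
                continue
            z_hits = (a[hit, 0] + u[hit] * (b[hit, 0] - a[hit, 0])
                      + v[hit] * (c[hit, 0] - a[hit, 0]))
            below = (z_hits[None, :] < z_centres[:, None]).sum(axis=1)
            out[:, row, col] = (below % 2) == 1
    return out


def _write_stl(verts: np.ndarray, faces: np.ndarray, path) -> None:
    tri = verts[faces]
    normals = np.cross(tri[:, 1] - tri[:, 0], tri[:, 2] - tri[:, 0])
    norms = np.linalg.norm(normals, axis=1, keepdims=True)
    normals = np.where(norms > 0, normals / np.where(norms == 0, 1, norms), 0.0)
    with open(path, "w") as fh:
        fh.write("solid pqlung\n")
        for n, t in zip(normals, tri):
            fh.write(f" facet normal {n[0]:.6e} {n[1]:.6e} {n[2]:.6e}\n  outer loop\n")
            for v in t:
                fh.write(f"   vertex {v[0]:.6e} {v[1]:.6e} {v[2]:.6e}\n")
            fh.write("  endloop\n endfacet\n")
        fh.write("endsolid pqlung\n")


def results_to_json(results: list[VolumetricsResult], ratio: RatioResult | None,
                    path) -> None:
    payload = {"scans": [r.to_dict() for r in results]}
    if ratio is not None:
        payload["ratio"] = ratio.to_dict()
    with open(path, "w") as fh:
        json.dump(payload, fh, indent=1)
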