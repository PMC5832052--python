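"""Lung segmentation by seeded region growing.

The procedure mirrors manual clinical practice: a reader places a seed
inside the aerated lung close to the pleura; a 40x40 pixel window
centred on the seed (spanning both lung and surrounding soft tissue)
supplies the local dynamic range CTmax - CTmin; a voxel joins the lung
if it is connected to the seed and its HU value differs from the seed's
by strictly less than ``coefficient * (CTmax - CTmin)`` with the
coefficient 0.3 by default.

The criterion window lives on the seed's 2-D slice, but growth itself is
volumetric (26-connected by default) because the analysis target is a
volume.  Injured (ground-glass / consolidated) tissue and intrapulmonary
vessels are denser than the acceptance band around an aerated seed, so
they appear as interior holes of the grown component; ``fill_holes=True``
(the pipeline default) closes them so the whole-lung mask includes the
tissue whose injured fraction is being measured.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy import ndimage

from .volume_io import BinaryMask, CTVolume, MaskRole

__all__ = [
    "SeedPoint",
    "GrowCriterion",
    "derive_criterion",
    "region_grow",
    "segment_both_lungs",
    "RegionGrowLeak",
]

#: A seed must be aerated lung: HU strictly below this.
SEED_MAX_HU = -500.0
#: A mask covering more than this fraction of the volume is a suspected leak.
LEAK_FRACTION = 0.90


class RegionGrowLeak(RuntimeError):
    """Grown region covers most of the volume — criterion probably leaked."""


@dataclass(frozen=True)
class SeedPoint:
    """A seed voxel inside the aerated lung, close to the pleura."""

    slice: int
    row: int
    col: int
    value: float

    @classmethod
    def from_volume(cls, volume: CTVolume, index: tuple[int, int, int]) -> "SeedPoint":
        k, i, j = (int(v) for v in index)
        shape = volume.shape
        if not (0 <= k < shape[0] and 0 <= i < shape[1] and 0 <= j < shape[2]):
            raise ValueError(f"seed {index} outside volume bounds {shape}")
        value = float(volume.voxels[k, i, j])
        if value >= SEED_MAX_HU:
            raise ValueError(
                f"seed HU {value:.0f} >= {SEED_MAX_HU:.0f}: seed must lie in aerated lung"
            )
        return cls(k, i, j, value)


@dataclass(frozen=True)
class GrowCriterion:
    """Acceptance criterion derived from the seed's local window."""

    ct_max: float
    ct_min: float
    coefficient: float = 0.3
    window_edge: int = 40

    def __post_init__(self) -> None:
        if not self.ct_max > self.ct_min:
            raise ValueError("ct_max must exceed ct_min")
        if not (0 < self.coefficient < 1):
            raise ValueError("coefficient must lie in (0, 1)")

    @property
    def threshold(self) -> float:
        """HU acceptance half-width: coefficient * (ct_max - ct_min)."""
        return self.coefficient * (self.ct_max - self.ct_min)


def derive_criterion(volume: CTVolume, seed: SeedPoint, coefficient: float = 0.3,
                     window_edge: int = 40) -> GrowCriterion:
    """CTmax/CTmin over the window centred at the seed, on the seed's slice.

    The window is clipped to the slice bounds; a constant (degenerate)
    window cannot define a dynamic range and raises.
    """
    half = window_edge // 2
    sl = volume.voxels[seed.slice]
    r0, r1 = max(0, seed.row - half), min(sl.shape[0], seed.row + half)
    c0, c1 = max(0, seed.col - half), min(sl.shape[1], seed.col + half)
    window = sl[r0:r1, c0:c1]
    ct_max, ct_min = float(window.max()), float(window.min())
    if ct_max == ct_min:
        raise ValueError(
            f"degenerate constant window (all {ct_max:.0f} HU) at seed "
            f"({seed.slice},{seed.row},{seed.col})"
        )
    return GrowCriterion(ct_max=ct_max, ct_min=ct_min, coefficient=coefficient,
                         window_edge=window_edge)


def _structure(connectivity: int) -> np.ndarray:
    if connectivity == 26:
        return np.ones((3, 3, 3), dtype=bool)
    if connectivity == 6:
        return ndimage.generate_binary_structure(3, 1)
    raise ValueError("connectivity must be 6 or 26")


def region_grow(volume: CTVolume, seed: SeedPoint, criterion: GrowCriterion,
                connectivity: int = 26) -> BinaryMask:
    """Connected component of {|CT(p) - CT(seed)| < threshold} through the seed.

    The inequality is strict.  Raises :class:`RegionGrowLeak` when the
    result exceeds 90% of the volume (acceptance band too wide — e.g. a
    seed window that missed the soft-tissue boundary).
    """
    accept = np.abs(volume.voxels - seed.value) < criterion.threshold
    labels, _ = ndimage.label(accept, structure=_structure(connectivity))
    seed_label = labels[seed.slice, seed.row, seed.col]
    if seed_label == 0:
        # strict "<" with threshold 0 excludes even the seed itself
        bits = np.zeros(volume.shape, dtype=bool)
        bits[seed.slice, seed.row, seed.col] = criterion.threshold > 0
    else:
        bits = labels == seed_label
    if bits.sum() > LEAK_FRACTION * bits.size:
        raise RegionGrowLeak(
            f"grown region covers {bits.sum() / bits.size:.0%} of the volume"
        )
    return BinaryMask(bits, MaskRole.lung, source_scan_id=volume.scan_id,
                      spacing_mm=volume.spacing_mm)


def segment_both_lungs(volume: CTVolume, seeds: list[SeedPoint],
                       coefficient: float = 0.3, window_edge: int = 40,
                       connectivity: int = 26, fill_holes: bool = True) -> BinaryMask:
    """Union of per-seed region growings — one seed per lung suffices.

    With ``fill_holes`` interior holes are closed slice-by-slice (then in
    3-D) so denser interior structures — vessels, injured tissue — count
    as lung volume.  Filling is 2-D first because vessels run
    through-plane and exit the lung at the hilum: in 3-D their lumen is
    open to the outside, while in every axial slice it is a closed hole.
    """
    if not seeds:
        raise ValueError("at least one seed point is required")
    bits = np.zeros(volume.shape, dtype=bool)
    for seed in seeds:
        crit = derive_criterion(volume, seed, coefficient=coefficient,
                                window_edge=window_edge)
        bits |= region_grow(volume, seed, crit, connectivity=connectivity).bits
    if fill_holes:
        for k in range(bits.shape[0]):
            bits[k] = ndimage.binary_fill_holes(bits[k])
        bits = ndimage.binary_fill_holes(bits)
    return BinaryMask(bits, MaskRole.lung, source_scan_id=volume.scan_id,
                      spacing_mm=volume.spacing_mm)


def auto_seeds(volume: CTVolume, n_seeds: int = 2) -> list[SeedPoint]:
    """Automatic fallback seed picker (plumbing; readers normally place seeds).

    Takes the largest air-density connected components that do not touch
    the volume border (i.e. lie inside the body) and returns one interior
    voxel of each.
    """
    air = volume.voxels < -700.0
    labels, n = ndimage.label(air, structure=_structure(26))
    if n == 0:
        raise ValueError("no air-density regions found")
    border = np.zeros(volume.shape, dtype=bool)
    border[:, [0, -1], :] = True
    border[:, :, [0, -1]] = True
    border_labels = set(np.unique(labels[border])) - {0}
    sizes = ndimage.sum_labels(np.ones_like(labels), labels, index=np.arange(1, n + 1))
    order = np.argsort(sizes)[::-1] + 1
    seeds: list[SeedPoint] = []
    for lab in order:
        if lab in border_labels or len(seeds) >= n_seeds:
            continue
        k, i, j = (int(np.round(c.mean())) for c in np.nonzero(labels == lab))
        if labels[k, i, j] != lab:  # centroid fell outside a non-convex region
            k, i, j = (int(c[0]) for c in np.nonzero(labels == lab))
        try:
            seeds.append(SeedPoint.from_volume(volume, (k, i, j)))
        except ValueError:
            continue
    if not seeds:
        raise ValueError("no interior air-density component usable as a seed")
    return seeds
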