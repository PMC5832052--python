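"""Per-pixel texture features for injured-tissue classification.

Nine features are computed for every in-lung pixel from the 7x7 window
centred on it (49 pixels when full):

1. ``center_hu``    — the pixel's own HU value;
2. ``mean``         — window mean HU;
3. ``sd``           — window standard deviation (population);
4. ``max``          — window maximum;
5. ``min``          — window minimum;
6. ``skewness``     — Fisher skewness m3/sd^3 (0 for constant windows);
7. ``kurtosis``     — excess kurtosis m4/sd^4 - 3 (0 for constant windows);
8. ``rco``          — 3-D mean-CT correlation, the product
   (mean_n - mean_{n-1}) * (mean_n - mean_{n+1}) of co-located window
   means on adjacent slices.  A structure present on a single slice only
   (the partial-volume signature) makes both factors large with the same
   sign, hence a large positive rco; tissue continuing across slices
   gives rco near zero or negative;
9. ``air_fraction`` — fraction of window pixels with HU < -825 (air
   density), counting only valid pixels.

Window pixels outside the lung mask are ignored: every statistic is
taken over the valid pixels only, with the divisor equal to their count
(49 for interior windows).  On the first/last slice rco reuses the only
available neighbour for both factors; a neighbour window with no valid
pixels contributes a zero factor.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import ndimage

from .volume_io import BinaryMask, CTVolume

__all__ = [
    "FEATURE_NAMES",
    "RoiWindow",
    "FeatureVector",
    "FeatureDataset",
    "roi_window",
    "roi_mean",
    "slice_correlation",
    "air_fraction",
    "extract_features",
    "feature_map",
    "build_dataset",
]

FEATURE_NAMES = (
    "center_hu", "mean", "sd", "max", "min",
    "skewness", "kurtosis", "rco", "air_fraction",
)

WINDOW_EDGE = 7          # 7x7 ROI, 49 pixels when full
AIR_THRESHOLD_HU = -825.0


@dataclass(frozen=True)
class RoiWindow:
    """Valid (in-lung) HU values of one 7x7 window."""

    values: np.ndarray
    n_valid: int
    center: tuple[int, int, int]

    def __post_init__(self) -> None:
        if self.n_valid < 1:
            raise ValueError(f"empty ROI window at {self.center}")
        if self.n_valid > WINDOW_EDGE ** 2:
            raise ValueError("window cannot hold more than 49 pixels")


@dataclass(frozen=True)
class FeatureVector:
    center_hu: float
    mean: float
    sd: float
    max: float
    min: float
    skewness: float
    kurtosis: float
    rco: float
    air_fraction: float

    def to_array(self) -> np.ndarray:
        return np.array([getattr(self, n) for n in FEATURE_NAMES], dtype=np.float64)


@dataclass
class FeatureDataset:
    """Labelled feature vectors for classifier training.

    ``labels`` are 1 = injured, 0 = noninjured; ``coords`` keeps the
    (slice, row, col) of each pixel for traceability.
    """

    features: np.ndarray          # (n, 9)
    labels: np.ndarray            # (n,) in {0, 1}
    coords: np.ndarray | None = None
    provenance: str = ""

    def __post_init__(self) -> None:
        self.features = np.asarray(self.features, dtype=np.float64)
        self.labels = np.asarray(self.labels, dtype=int)
        if self.features.ndim != 2 or self.features.shape[1] != len(FEATURE_NAMES):
            raise ValueError(f"features must be (n, {len(FEATURE_NAMES)})")
        if len(self.labels) != len(self.features):
            raise ValueError("features and labels length mismatch")

    def __len__(self) -> int:
        return len(self.features)

    @property
    def class_counts(self) -> dict[str, int]:
        return {"noninjured": int((self.labels == 0).sum()),
                "injured": int((self.labels == 1).sum())}

    def to_frame(self) -> pd.DataFrame:
        df = pd.DataFrame(self.features, columns=list(FEATURE_NAMES))
        if self.coords is not None:
            df.insert(0, "slice", self.coords[:, 0])
            df.insert(1, "row", self.coords[:, 1])
            df.insert(2, "col", self.coords[:, 2])
        df["label"] = np.where(self.labels == 1, "injured", "noninjured")
        return df

    def to_csv(self, path) -> None:
        self.to_frame().to_csv(path, index=False)

    @classmethod
    def from_csv(cls, path) -> "FeatureDataset":
        df = pd.read_csv(path)
        coords = None
        if {"slice", "row", "col"} <= set(df.columns):
            coords = df[["slice", "row", "col"]].to_numpy(dtype=int)
        return cls(df[list(FEATURE_NAMES)].to_numpy(),
                   (df["label"] == "injured").to_numpy().astype(int),
                   coords=coords, provenance=str(path))


# ---------------------------------------------------------------------------
# Single-window (direct) path
# ---------------------------------------------------------------------------

def roi_window(volume: CTVolume, lung: BinaryMask, center: tuple[int, int, int],
               slice_offset: int = 0) -> RoiWindow | None:
    """7x7 window at `center` shifted by `slice_offset` slices.

    Returns None when the shifted slice exists but holds no in-lung
    pixels in the window (the caller decides the fallback).
    """
    k, i, j = center
    k = int(np.clip(k + slice_offset, 0, volume.shape[0] - 1))
    half = WINDOW_EDGE // 2
    r0, r1 = max(0, i - half), min(volume.shape[1], i + half + 1)
    c0, c1 = max(0, j - half), min(volume.shape[2], j + half + 1)
    valid = lung.bits[k, r0:r1, c0:c1]
    if not valid.any():
        return None
    values = volume.voxels[k, r0:r1, c0:c1][valid]
    return RoiWindow(values=values, n_valid=int(valid.sum()), center=(k, i, j))


def roi_mean(window: RoiWindow) -> float:
    """Arithmetic mean over the window's valid pixels (divisor = n_valid)."""
    return float(window.values.sum() / window.n_valid)


def slice_correlation(mean_prev: float, mean_cur: float, mean_next: float) -> float:
    """rco = (mean_cur - mean_prev) * (mean_cur - mean_next)."""
    return float((mean_cur - mean_prev) * (mean_cur - mean_next))


def slice_correlation_quotient(mean_prev: float, mean_cur: float,
                               mean_next: float) -> float:
    """Quotient reading of the 3-D correlation (config alternative).

    Undefined (NaN) when the current and next slice means coincide.
    """
    denom = mean_cur - mean_next
    if denom == 0:
        return float("nan")
    return float((mean_cur - mean_prev) / denom)


def air_fraction(window: RoiWindow, threshold: float = AIR_THRESHOLD_HU) -> float:
    """Fraction of valid pixels with HU strictly below the air threshold."""
    return float((window.values < threshold).sum() / window.n_valid)


def _moments(values: np.ndarray) -> tuple[float, float, float, float]:
    """mean, sd (population), skewness, excess kurtosis; 0 when sd == 0."""
    mean = float(values.mean())
    centred = values - mean
    var = float(np.mean(centred ** 2))
    if var <= 0 or values.max() == values.min():
        return mean, 0.0, 0.0, 0.0
    sd = var ** 0.5
    skew = float(np.mean(centred ** 3)) / sd ** 3
    kurt = float(np.mean(centred ** 4)) / var ** 2 - 3.0
    return mean, sd, skew, kurt


def extract_features(volume: CTVolume, lung: BinaryMask,
                     center: tuple[int, int, int]) -> FeatureVector:
    """All nine features for the in-lung pixel at `center`."""
    lung.check_aligned(volume)
    k, i, j = (int(v) for v in center)
    if not lung.bits[k, i, j]:
        raise ValueError(f"center {center} lies outside the lung mask")
    win = roi_window(volume, lung, (k, i, j))
    assert win is not None  # centre itself is valid
    mean, sd, skew, kurt = _moments(win.values)

    # rco with one-sided reuse at the first/last slice and a zero factor
    # when a neighbour window holds no lung pixels
    off_prev = -1 if k > 0 else +1
    off_next = +1 if k < volume.shape[0] - 1 else -1
    wp = roi_window(volume, lung, (k, i, j), slice_offset=off_prev)
    wn = roi_window(volume, lung, (k, i, j), slice_offset=off_next)
    mean_prev = roi_mean(wp) if wp is not None else mean
    mean_next = roi_mean(wn) if wn is not None else mean
    rco = slice_correlation(mean_prev, mean, mean_next)

    return FeatureVector(
        center_hu=float(volume.voxels[k, i, j]),
        mean=mean, sd=sd,
        max=float(win.values.max()), min=float(win.values.min()),
        skewness=skew, kurtosis=kurt, rco=rco,
        air_fraction=air_fraction(win),
    )


# ---------------------------------------------------------------------------
# Whole-volume (vectorised) path
# ---------------------------------------------------------------------------

def feature_map(volume: CTVolume, lung: BinaryMask) -> tuple[np.ndarray, np.ndarray]:
    """Features for every in-lung pixel at once.

    Returns ``(coords, features)`` with coords of shape (n, 3) in
    (slice, row, col) order (C enumeration of the mask) and features of
    shape (n, 9) in :data:`FEATURE_NAMES` order.  Numerically matches
    :func:`extract_features` pixel-by-pixel; windows are realised by
    masked 2-D convolutions so lung-boundary exclusion and image-edge
    clipping fall out of the zero padding.
    """
    lung.check_aligned(volume)
    hu = volume.voxels
    m = lung.bits.astype(np.float64)
    # shift HU towards zero before forming power sums (cancellation guard)
    offset = float(hu[lung.bits].mean()) if lung.bits.any() else 0.0
    x = (hu - offset) * m

    kernel = np.ones((1, WINDOW_EDGE, WINDOW_EDGE))
    conv = lambda a: ndimage.convolve(a, kernel, mode="constant", cval=0.0)
    cnt = conv(m)
    s1, s2, s3, s4 = conv(x), conv(x * m * x), conv(x ** 3 * m), conv(x ** 4 * m)

    with np.errstate(invalid="ignore", divide="ignore"):
        mean_s = np.where(cnt > 0, s1 / np.maximum(cnt, 1), 0.0)
        var = s2 / np.maximum(cnt, 1) - mean_s ** 2
        m3 = s3 / np.maximum(cnt, 1) - 3 * mean_s * s2 / np.maximum(cnt, 1) + 2 * mean_s ** 3
        m4 = (s4 / np.maximum(cnt, 1) - 4 * mean_s * s3 / np.maximum(cnt, 1)
              + 6 * mean_s ** 2 * s2 / np.maximum(cnt, 1) - 3 * mean_s ** 4)

    neg_inf = np.where(lung.bits, hu, -np.inf)
    pos_inf = np.where(lung.bits, hu, np.inf)
    foot = np.ones((1, WINDOW_EDGE, WINDOW_EDGE), dtype=bool)
    wmax = ndimage.maximum_filter(neg_inf, footprint=foot, mode="constant", cval=-np.inf)
    wmin = ndimage.minimum_filter(pos_inf, footprint=foot, mode="constant", cval=np.inf)

    var = np.maximum(var, 0.0)
    constant = wmax == wmin
    sd = np.sqrt(var)
    with np.errstate(invalid="ignore", divide="ignore"):
        skew = np.where(constant | (sd == 0), 0.0, m3 / np.where(sd == 0, 1, sd) ** 3)
        kurt = np.where(constant | (var == 0), 0.0,
                        m4 / np.where(var == 0, 1, var) ** 2 - 3.0)
    sd = np.where(constant, 0.0, sd)

    air = conv((hu < AIR_THRESHOLD_HU) * m)
    airfrac = np.where(cnt > 0, air / np.maximum(cnt, 1), 0.0)

    # rco from co-located slice means, one-sided at the ends, zero factor
    # when the neighbour window has no lung pixels
    means = mean_s + offset
    K = hu.shape[0]
    idx_prev = np.clip(np.arange(K) - 1, 0, K - 1)
    idx_next = np.clip(np.arange(K) + 1, 0, K - 1)
    idx_prev[0], idx_next[-1] = 1, K - 2
    mp = np.where(cnt[idx_prev] > 0, means[idx_prev], means)
    mn = np.where(cnt[idx_next] > 0, means[idx_next], means)
    rco = (means - mp) * (means - mn)

    coords = np.argwhere(lung.bits)
    k, i, j = coords.T
    feats = np.column_stack([
        hu[k, i, j], means[k, i, j], sd[k, i, j], wmax[k, i, j], wmin[k, i, j],
        skew[k, i, j], kurt[k, i, j], rco[k, i, j], airfrac[k, i, j],
    ])
    return coords, feats


def build_dataset(volume: CTVolume, lung: BinaryMask,
                  labeled_regions: dict[str, np.ndarray],
                  provenance: str = "") -> FeatureDataset:
    """One labelled FeatureVector per pixel of the given regions.

    `labeled_regions` maps 'injured'/'noninjured' to boolean arrays;
    every labelled pixel must lie inside the lung mask.  A single-class
    dataset is allowed (for evaluation) but flagged with a warning.
    """
    unknown = set(labeled_regions) - {"injured", "noninjured"}
    if unknown:
        raise ValueError(f"unknown labels {sorted(unknown)}")
    masks = {name: np.asarray(bits, dtype=bool) for name, bits in labeled_regions.items()}
    total = sum(int(b.sum()) for b in masks.values())
    if total == 0:
        raise ValueError("empty label set")
    for name, bits in masks.items():
        if bits.shape != lung.shape:
            raise ValueError(f"label mask '{name}' shape mismatch")
        if np.any(bits & ~lung.bits):
            raise ValueError(f"label '{name}' marks pixels outside the lung mask")

    coords_all, feats_all = feature_map(volume, lung)
    index = np.full(lung.shape, -1, dtype=np.int64)
    index[tuple(coords_all.T)] = np.arange(len(coords_all))

    rows, labels, coords = [], [], []
    for name, bits in masks.items():
        sel = index[bits]
        rows.append(feats_all[sel])
        coords.append(np.argwhere(bits))
        labels.append(np.full(int(bits.sum()), 1 if name == "injured" else 0))
    ds = FeatureDataset(np.concatenate(rows), np.concatenate(labels),
                        coords=np.concatenate(coords), provenance=provenance)
    counts = ds.class_counts
    if min(counts.values()) == 0:
        warnings.warn(f"single-class dataset: {counts}", stacklevel=2)
    return ds
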