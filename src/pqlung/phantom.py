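"""Synthetic chest-CT phantoms with exact ground truth.

The phantom emulates the HU phenomenology the pipeline relies on: air
(-1000), aerated parenchyma (-850 plus acquisition noise), injured
tissue — the ground-glass / consolidation pattern — as a correlated
Gaussian random field around -450 HU (a pure offset would leave the
sd/skewness/kurtosis features uninformative), tubular vessels (+50),
and a soft-tissue body (0) enclosing two ellipsoidal lungs.  Optional
partial-volume mixing blurs the through-plane transition at lung
boundaries, producing the single-slice signature the 3-D mean-CT
correlation feature exists to flag.

Truth masks are exact by construction, so ground-truth injured-volume
fractions are exact voxel-count ratios.  All randomness flows from the
spec's seed; the same seed reproduces the volume bit for bit.

Scan pairs share geometry and differ in the injured extent: the
second-scan injury is the first-scan region grown outward (by distance
ordering, voxel-exact) to a target fraction, emulating disease
progression between admission and follow-up.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd
from scipy import ndimage, stats

from .volume_io import BinaryMask, CTVolume, MaskRole

__all__ = ["PhantomSpec", "render_phantom", "render_scan_pair", "sample_cohort"]

HU_AIR = -1000.0
HU_PARENCHYMA = -850.0
HU_INJURED = -450.0
HU_VESSEL = 50.0
HU_BODY = 0.0


@dataclass(frozen=True)
class PhantomSpec:
    """Geometry and intensity model of one synthetic thorax.

    Defaults give a 24x64x64 grid at (1.25, 0.7, 0.7) mm spacing — a
    down-scaled axial acquisition — with two lungs, one injured blob in
    the left lung, and one vessel per lung running through-plane.
    """

    shape: tuple[int, int, int] = (24, 64, 64)
    spacing_mm: tuple[float, float, float] = (1.25, 0.7, 0.7)
    body_radii: tuple[float, float] = (29.0, 31.0)           # (row, col)
    lung_centers: tuple = ((11.5, 32.0, 18.0), (11.5, 32.0, 46.0))
    lung_radii: tuple[float, float, float] = (11.0, 22.0, 12.0)
    injured_blobs: tuple = (((11.5, 32.0, 18.0), (5.0, 9.0, 6.0)),)
    vessel_offsets: tuple = ((8.0, -5.0), (-8.0, 5.0))        # (drow, dcol) per lung
    vessel_radius: float = 1.4                                # voxels, in-plane
    injured_mean_hu: float = HU_INJURED
    injured_texture_sd: float = 60.0
    texture_corr_len: float = 2.0                             # voxels
    noise_sd: float = 30.0                                    # acquisition noise, HU
    partial_volume: bool = False
    seed: int = 0
    scan_id: str = "phantom"

    def validate(self) -> None:
        k, r, c = self.shape
        if min(self.shape) < 3:
            raise ValueError("phantom grid too small")
        for ctr in self.lung_centers:
            for x, rad, n in zip(ctr, self.lung_radii, self.shape):
                if x - rad < -1 or x + rad > n:
                    raise ValueError("lung geometry outside grid")
        # injured-in-lung containment is enforced voxel-wise at render time


def _ellipsoid(shape, center, radii) -> np.ndarray:
    grids = np.ogrid[tuple(slice(0, n) for n in shape)]
    acc = sum(((g - c) / r) ** 2 for g, c, r in zip(grids, center, radii))
    return acc <= 1.0


def _correlated_field(shape, corr_len, rng) -> np.ndarray:
    """Zero-mean, unit-sd Gaussian random field with given correlation length."""
    white = rng.standard_normal(shape)
    if corr_len > 0:
        fieldv = ndimage.gaussian_filter(white, sigma=corr_len, mode="wrap")
    else:
        fieldv = white
    sd = fieldv.std()
    return fieldv / sd if sd > 0 else fieldv


def render_phantom(spec: PhantomSpec,
                   injured_override: np.ndarray | None = None
                   ) -> tuple[CTVolume, dict[str, BinaryMask]]:
    """Render a phantom and its exact truth masks.

    Returns ``(volume, {"lung", "injured", "vessel"})``.  The lung truth
    includes vessel and injured voxels (they are lung volume); the
    injured truth excludes vessels.  `injured_override` substitutes a
    precomputed injured-region boolean array (used by scan pairs).
    """
    spec.validate()
    shape = spec.shape
    rng = np.random.default_rng(spec.seed)

    k_axis = np.arange(shape[0])
    body2d = _ellipsoid(shape[1:], (shape[1] / 2, shape[2] / 2), spec.body_radii)
    body = np.broadcast_to(body2d, shape).copy()

    lung = np.zeros(shape, dtype=bool)
    for ctr in spec.lung_centers:
        lung |= _ellipsoid(shape, ctr, spec.lung_radii)
    if np.any(lung & ~body):
        raise ValueError("lung geometry not enclosed by the body")

    if injured_override is not None:
        injured = np.asarray(injured_override, dtype=bool)
        if injured.shape != shape:
            raise ValueError("injured override shape mismatch")
    else:
        injured = np.zeros(shape, dtype=bool)
        for ctr, radii in spec.injured_blobs:
            injured |= _ellipsoid(shape, ctr, radii)
    if np.any(injured & ~lung):
        raise ValueError("injured region extends outside the lung")

    vessel = np.zeros(shape, dtype=bool)
    rows = np.arange(shape[1])[:, None]
    cols = np.arange(shape[2])[None, :]
    for ctr, (drow, dcol) in zip(spec.lung_centers, spec.vessel_offsets):
        disk = ((rows - (ctr[1] + drow)) ** 2 + (cols - (ctr[2] + dcol)) ** 2
                <= spec.vessel_radius ** 2)
        vessel |= np.broadcast_to(disk, shape)
    vessel &= lung
    injured_clean = injured & ~vessel

    hu = np.full(shape, HU_AIR)
    hu[body] = HU_BODY
    hu[lung] = HU_PARENCHYMA
    texture = _correlated_field(shape, spec.texture_corr_len, rng)
    hu[injured_clean] = (spec.injured_mean_hu
                         + spec.injured_texture_sd * texture[injured_clean])
    hu[vessel] = HU_VESSEL

    if spec.partial_volume:
        # linear through-plane mixing at lung boundary slices
        hu = ndimage.gaussian_filter1d(hu, sigma=0.7, axis=0, mode="nearest")

    if spec.noise_sd > 0:
        hu = hu + spec.noise_sd * rng.standard_normal(shape)

    volume = CTVolume(hu, spec.spacing_mm, scan_id=spec.scan_id)
    masks = {
        "lung": BinaryMask(lung, MaskRole.lung, spec.scan_id, spec.spacing_mm),
        "injured": BinaryMask(injured_clean, MaskRole.injured_final,
                              spec.scan_id, spec.spacing_mm),
        "vessel": BinaryMask(vessel, MaskRole.vessel, spec.scan_id, spec.spacing_mm),
    }
    return volume, masks


def _grow_to_fraction(base: np.ndarray, lung: np.ndarray, target_fraction: float,
                      margin: int = 1, exclude: np.ndarray | None = None) -> np.ndarray:
    """Grow `base` outward (distance ordering) to an exact voxel count.

    The grown region stays inside the lung eroded by `margin` voxels so
    it remains strictly interior (an aerated shell always surrounds it),
    and avoids `exclude` voxels (vessels), so the resulting truth count
    is exactly ``round(target_fraction * |lung|)``.  Deterministic:
    candidate voxels are ranked by Euclidean distance to the base region
    with index order breaking ties.
    """
    lung_count = int(lung.sum())
    n_target = int(round(target_fraction * lung_count))
    allowed = ndimage.binary_erosion(lung, iterations=margin) if margin else lung.copy()
    if exclude is not None:
        allowed &= ~exclude
    base = base & allowed
    n_base = int(base.sum())
    if n_target > int(allowed.sum()):
        raise ValueError(
            f"target fraction {target_fraction:.2f} exceeds the interior lung "
            f"capacity {allowed.sum() / lung_count:.2f}"
        )
    if n_target <= n_base:
        # shrink: keep the n_target voxels deepest inside the base
        depth = ndimage.distance_transform_edt(base)
        flat = np.argsort(-depth[base], kind="stable")[:n_target]
        idx = np.argwhere(base)[flat]
        out = np.zeros_like(base)
        out[tuple(idx.T)] = True
        return out
    dist = ndimage.distance_transform_edt(~base)
    cand = allowed & ~base
    order = np.argsort(dist[cand], kind="stable")[: n_target - n_base]
    idx = np.argwhere(cand)[order]
    out = base.copy()
    out[tuple(idx.T)] = True
    return out


def render_scan_pair(spec: PhantomSpec, growth_factor: float | None = None,
                     target_fractions: tuple[float, float] | None = None,
                     ) -> tuple[tuple[CTVolume, dict], tuple[CTVolume, dict]]:
    """Two scans of one phantom patient with the injury grown in between.

    Either give `growth_factor` g > 0 (scan-2 fraction = g x scan-1
    fraction) or explicit `target_fractions` (f1, f2) of the whole-lung
    volume.  Noise differs between scans (independent sub-seeds);
    geometry and truth construction are shared.
    """
    if (growth_factor is None) == (target_fractions is None):
        raise ValueError("give exactly one of growth_factor / target_fractions")
    _, base_masks = render_phantom(replace(spec, noise_sd=0.0, seed=spec.seed))
    lung = base_masks["lung"].bits
    base_injured = base_masks["injured"].bits
    lung_count = int(lung.sum())

    if target_fractions is not None:
        f1, f2 = (float(f) for f in target_fractions)
    else:
        if growth_factor <= 0:
            raise ValueError("growth_factor must be > 0")
        f1 = base_injured.sum() / lung_count
        f2 = growth_factor * f1
    vessel = base_masks["vessel"].bits
    inj1 = _grow_to_fraction(base_injured, lung, f1, exclude=vessel)
    inj2 = _grow_to_fraction(inj1 if f2 >= f1 else base_injured, lung, f2,
                             exclude=vessel)

    spec1 = replace(spec, seed=spec.seed, scan_id=f"{spec.scan_id}-scan1")
    spec2 = replace(spec, seed=spec.seed + 1, scan_id=f"{spec.scan_id}-scan2")
    scan1 = render_phantom(spec1, injured_override=inj1)
    scan2 = render_phantom(spec2, injured_override=inj2)
    return scan1, scan2


# ---------------------------------------------------------------------------
# Synthetic cohorts
# ---------------------------------------------------------------------------

#: Generating distributions per outcome group: (mean, sd, low, high).
#: The ratio row reflects the separation reported clinically between
#: survivors and nonsurvivors; covariates are plausible adult ranges.
DEFAULT_PARAM_SPECS = {
    "ratio": {"survivor": (0.73, 0.17), "nonsurvivor": (0.40, 0.14),
              "range": (0.0, 2.0)},
    "age": {"survivor": (38.5, 17.0), "nonsurvivor": (39.9, 16.6),
            "range": (14.0, 90.0)},
    "wbc": {"survivor": (12.74, 5.50), "nonsurvivor": (20.41, 10.61),
            "range": (1.0, 60.0)},
}

#: Male proportion per group, matching a 13:8 vs 19:18 gender split.
DEFAULT_MALE_P = {"survivor": 13 / 21, "nonsurvivor": 19 / 37}


def sample_cohort(n_surv: int, n_nonsurv: int, param_specs: dict | None = None,
                  seed: int = 0, male_p: dict | None = None) -> pd.DataFrame:
    """Draw a synthetic cohort of survivor/nonsurvivor records.

    Each parameter is an independent truncated-Gaussian draw per group;
    deterministic given the seed.
    """
    if n_surv <= 0 or n_nonsurv <= 0:
        raise ValueError("both groups need n > 0")
    specs = param_specs or DEFAULT_PARAM_SPECS
    male_p = male_p or DEFAULT_MALE_P
    rng = np.random.default_rng(seed)
    rows = {"outcome": (["survivor"] * n_surv + ["nonsurvivor"] * n_nonsurv)}
    rows["patient_id"] = [f"P{i:04d}" for i in range(n_surv + n_nonsurv)]
    for name, ps in specs.items():
        lo, hi = ps.get("range", (-np.inf, np.inf))
        col = []
        for group, n in (("survivor", n_surv), ("nonsurvivor", n_nonsurv)):
            mean, sd = ps[group]
            if sd <= 0:
                raise ValueError(f"sd must be positive for '{name}'/{group}")
            a, b = (lo - mean) / sd, (hi - mean) / sd
            col.append(stats.truncnorm.rvs(a, b, loc=mean, scale=sd, size=n,
                                           random_state=rng))
        rows[name] = np.concatenate(col)
    gender = []
    for group, n in (("survivor", n_surv), ("nonsurvivor", n_nonsurv)):
        gender.append(np.where(rng.random(n) < male_p[group], "M", "F"))
    rows["gender"] = np.concatenate(gender)
    return pd.DataFrame(rows)
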