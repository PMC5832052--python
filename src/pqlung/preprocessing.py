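"""Edge-preserving smoothing before segmentation.

Perona–Malik anisotropic diffusion, run slice-wise in 2-D (segmentation
is seeded per slice and the slice increment is coarse relative to the
in-plane pixel size).  The conduction function is the exponential form
``g(d) = exp(-(d/kappa)**2)``, so diffusion is suppressed across strong
edges (|d| >> kappa) while flat-region noise is averaged away.  Reflective
boundaries avoid darkening at the image edge.

Defaults: 10 iterations, kappa = 50 HU, step = 0.15 (stable for the
4-neighbour scheme, which requires step <= 0.25).
"""

from __future__ import annotations

import numpy as np

from .volume_io import CTVolume

__all__ = ["anisotropic_diffusion", "diffuse_slice"]

#: 4-neighbour explicit scheme is stable for step <= 1/4.
MAX_STABLE_STEP = 0.25


def diffuse_slice(image: np.ndarray, n_iter: int = 10, kappa: float = 50.0,
                  step: float = 0.15) -> np.ndarray:
    """Perona–Malik diffusion of a single 2-D image (HU)."""
    img = np.array(image, dtype=np.float64)
    zrow = np.zeros((1, img.shape[1]))
    zcol = np.zeros((img.shape[0], 1))
    for _ in range(n_iter):
        # neighbour-minus-centre differences; zero at the border (reflective)
        dd = np.diff(img, axis=0)
        dn = np.vstack([zrow, -dd])      # north neighbour: img[i-1] - img[i]
        ds = np.vstack([dd, zrow])       # south neighbour: img[i+1] - img[i]
        dd = np.diff(img, axis=1)
        dw = np.hstack([zcol, -dd])
        de = np.hstack([dd, zcol])
        flux = sum(np.exp(-(d / kappa) ** 2) * d for d in (dn, ds, dw, de))
        img += step * flux
    return img


def anisotropic_diffusion(volume: CTVolume, n_iter: int = 10,
                          kappa: float = 50.0, step: float = 0.15) -> CTVolume:
    """Smooth a CT volume slice-by-slice with Perona–Malik diffusion.

    Parameters
    ----------
    volume : CTVolume
        Input scan; must be finite (enforced by CTVolume).
    n_iter : int
        Number of explicit iterations; 0 returns the input unchanged.
    kappa : float
        Conduction threshold in HU; gradients well above kappa are
        treated as edges and preserved.
    step : float
        Integration step; must lie in (0, 0.25] for stability.

    Returns
    -------
    CTVolume with the same shape, spacing and metadata.
    """
    if n_iter < 0:
        raise ValueError("n_iter must be >= 0")
    if not (0 < step <= MAX_STABLE_STEP):
        raise ValueError(f"step must be in (0, {MAX_STABLE_STEP}] for stability")
    if kappa <= 0:
        raise ValueError("kappa must be positive (HU)")
    if n_iter == 0:
        return volume.with_voxels(volume.voxels.copy())
    out = np.empty_like(volume.voxels)
    for k in range(volume.shape[0]):
        out[k] = diffuse_slice(volume.voxels[k], n_iter=n_iter, kappa=kappa, step=step)
    return volume.with_voxels(out)
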