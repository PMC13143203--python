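"""Per-channel intensity normalization and 3D denoising.

The quantification pipeline operates on one channel at a time: the channel is
rescaled to the unit interval against its own extrema, then smoothed with a
3D median filter (salt-and-pepper / shot noise) followed by a small truncated
Gaussian (residual high-frequency noise). All filtering is performed in voxel
units on the raw grid; no physical-unit (anisotropy-aware) filtering is done.

Boundary handling for both filters is mirror (symmetric) padding, which avoids
the dark rims that zero padding would introduce and that would bias the
downstream histogram threshold.
"""

from __future__ import annotations

import numpy as np
from scipy import ndimage as ndi

__all__ = ["normalize_stack", "median_filter_3d", "gaussian_filter_3d"]


def _as_volume(volume: np.ndarray) -> np.ndarray:
    vol = np.asarray(volume)
    if vol.size == 0:
        raise ValueError("volume is empty")
    if vol.ndim != 3:
        raise ValueError(f"expected a 3D volume, got ndim={vol.ndim}")
    return vol


def normalize_stack(volume: np.ndarray) -> np.ndarray:
    """Rescale a channel volume linearly onto [0, 1].

    The minimum intensity maps to 0 and the maximum to 1 (min-max rescaling
    against the extrema found in the channel). A constant volume maps to all
    zeros rather than raising: blank channels (e.g. an EdU-negative control)
    must flow through the pipeline and come out as an empty mask.

    Parameters
    ----------
    volume : ndarray, 3D
        Non-negative intensities, any numeric dtype.

    Returns
    -------
    ndarray of float64 in [0, 1], same shape.
    """
    vol = _as_volume(volume).astype(np.float64)
    if not np.all(np.isfinite(vol)):
        raise ValueError("volume contains non-finite values")
    vmin = vol.min()
    vmax = vol.max()
    if vmax == vmin:
        return np.zeros_like(vol)
    return (vol - vmin) / (vmax - vmin)


def median_filter_3d(volume: np.ndarray, window: int = 3) -> np.ndarray:
    """Median filter with a cubic ``window**3`` neighborhood.

    ``window`` must be odd so the neighborhood is centered. The default of 3
    is the conventional default neighborhood for 3D median filtering.
    Boundaries use mirror (symmetric) padding.
    """
    vol = _as_volume(volume)
    if window < 1 or window % 2 == 0:
        raise ValueError(f"window must be odd and >= 1, got {window}")
    return ndi.median_filter(vol, size=window, mode="reflect")


def gaussian_filter_3d(
    volume: np.ndarray, kernel_size: int = 5, sigma: float = 0.5
) -> np.ndarray:
    """Separable Gaussian smoothing truncated to ``kernel_size`` per axis.

    The 1D kernel is evaluated on ``kernel_size`` taps centered at the origin
    and renormalized to sum to 1, so constant volumes are preserved exactly
    (up to floating point). Boundaries use mirror (symmetric) padding.

    Parameters
    ----------
    kernel_size : odd int
        Full extent of the truncated kernel along each axis (default 5, i.e.
        a 5x5x5 filter).
    sigma : float > 0
        Standard deviation of the Gaussian in voxels.
    """
    vol = _as_volume(volume).astype(np.float64)
    if kernel_size < 1 or kernel_size % 2 == 0:
        raise ValueError(f"kernel_size must be odd and >= 1, got {kernel_size}")
    if sigma <= 0:
        raise ValueError(f"sigma must be positive, got {sigma}")
    radius = kernel_size // 2
    return ndi.gaussian_filter(vol, sigma=sigma, radius=radius, mode="reflect")
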