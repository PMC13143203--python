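"""Independent brute-force oracles for the image operations.

Everything here is written as direct loops / exhaustive enumeration from the
operation definitions, deliberately avoiding the code paths (scipy.ndimage,
skimage, the package's own vectorized Otsu) used by the implementation.
"""

from __future__ import annotations

import numpy as np


def ball_offsets_bruteforce(radius: int) -> set[tuple[int, int, int]]:
    """All integer (dz, dy, dx) with dz²+dy²+dx² <= radius², by enumeration."""
    offs = set()
    for dz in range(-radius, radius + 1):
        for dy in range(-radius, radius + 1):
            for dx in range(-radius, radius + 1):
                if dz * dz + dy * dy + dx * dx <= radius * radius:
                    offs.add((dz, dy, dx))
    return offs


def median_bruteforce(vol: np.ndarray, window: int) -> np.ndarray:
    """Median over each window³ neighborhood with symmetric (mirror) padding."""
    r = window // 2
    padded = np.pad(vol, r, mode="symmetric")
    out = np.empty_like(np.asarray(vol, dtype=float))
    nz, ny, nx = vol.shape
    for z in range(nz):
        for y in range(ny):
            for x in range(nx):
                block = padded[z : z + window, y : y + window, x : x + window]
                out[z, y, x] = np.median(block)
    return out


def gaussian_bruteforce(vol: np.ndarray, kernel_size: int, sigma: float) -> np.ndarray:
    """Dense convolution with a truncated, renormalized separable Gaussian."""
    r = kernel_size // 2
    x = np.arange(-r, r + 1, dtype=float)
    k1 = np.exp(-0.5 * (x / sigma) ** 2)
    k1 /= k1.sum()
    kernel = k1[:, None, None] * k1[None, :, None] * k1[None, None, :]
    padded = np.pad(np.asarray(vol, dtype=float), r, mode="symmetric")
    out = np.empty(vol.shape, dtype=float)
    nz, ny, nx = vol.shape
    for z in range(nz):
        for y in range(ny):
            for x_ in range(nx):
                block = padded[z : z + kernel_size, y : y + kernel_size,
                               x_ : x_ + kernel_size]
                out[z, y, x_] = float((block * kernel).sum())
    return out


def erosion_bruteforce(
    vol: np.ndarray, offsets: set[tuple[int, int, int]]
) -> np.ndarray:
    """Min over in-bounds offset positions (out-of-bounds ignored)."""
    vol = np.asarray(vol, dtype=float)
    out = np.empty_like(vol)
    nz, ny, nx = vol.shape
    for z in range(nz):
        for y in range(ny):
            for x in range(nx):
                best = np.inf
                for dz, dy, dx in offsets:
                    zz, yy, xx = z + dz, y + dy, x + dx
                    if 0 <= zz < nz and 0 <= yy < ny and 0 <= xx < nx:
                        best = min(best, vol[zz, yy, xx])
                out[z, y, x] = best
    return out


def _neighborhood_offsets(connectivity: int) -> list[tuple[int, int, int]]:
    rank = {6: 1, 18: 2, 26: 3}[connectivity]
    offs = []
    for dz in (-1, 0, 1):
        for dy in (-1, 0, 1):
            for dx in (-1, 0, 1):
                if abs(dz) + abs(dy) + abs(dx) <= rank:
                    offs.append((dz, dy, dx))
    return offs


def reconstruction_bruteforce(
    marker: np.ndarray, mask: np.ndarray, connectivity: int = 26
) -> np.ndarray:
    """Iterate (dilate by neighborhood, clip to mask) to the fixed point."""
    offs = _neighborhood_offsets(connectivity)
    cur = np.minimum(np.asarray(marker, dtype=float), mask)
    nz, ny, nx = cur.shape
    while True:
        nxt = cur.copy()
        for z in range(nz):
            for y in range(ny):
                for x in range(nx):
                    best = cur[z, y, x]
                    for dz, dy, dx in offs:
                        zz, yy, xx = z + dz, y + dy, x + dx
                        if 0 <= zz < nz and 0 <= yy < ny and 0 <= xx < nx:
                            if cur[zz, yy, xx] > best:
                                best = cur[zz, yy, xx]
                    nxt[z, y, x] = min(best, mask[z, y, x])
        if np.array_equal(nxt, cur):
            return nxt
        cur = nxt


def otsu_bruteforce(vol: np.ndarray, bins: int = 256) -> float:
    """Exhaustive search over all cut points of the fixed [0,1] histogram."""
    values = np.asarray(vol, dtype=float).ravel()
    hist = [0] * bins
    for v in values:
        idx = min(int(v * bins), bins - 1)
        hist[idx] += 1
    total = len(values)
    best_sigma = -1.0
    best_cuts: list[int] = []
    for t in range(1, bins):  # class 0 = bins [0, t), class 1 = bins [t, bins)
        w0 = sum(hist[:t])
        w1 = total - w0
        if w0 == 0 or w1 == 0:
            continue
        mu0 = sum(hist[i] * (i + 0.5) / bins for i in range(t)) / w0
        mu1 = sum(hist[i] * (i + 0.5) / bins for i in range(t, bins)) / w1
        sigma = w0 * w1 * (mu0 - mu1) ** 2
        if sigma > best_sigma:
            best_sigma = sigma
            best_cuts = [t]
        elif sigma == best_sigma:
            best_cuts.append(t)
    if best_sigma <= 0 or not best_cuts:
        return 0.0
    return sum(best_cuts) / len(best_cuts) / bins


def max_projection_bruteforce(channel: np.ndarray) -> np.ndarray:
    nz, ny, nx = channel.shape
    out = np.empty((ny, nx), dtype=channel.dtype)
    for y in range(ny):
        for x in range(nx):
            best = channel[0, y, x]
            for z in range(1, nz):
                if channel[z, y, x] > best:
                    best = channel[z, y, x]
            out[y, x] = best
    return out


def polygon_area_raster(
    vertices: tuple[tuple[float, float], ...], oversample: int = 8
) -> float:
    """Pixel-count area estimate on a fine grid (matplotlib point-in-polygon)."""
    from matplotlib.path import Path as MplPath

    verts = np.asarray(vertices, dtype=float)
    xmin, ymin = verts.min(axis=0) - 1
    xmax, ymax = verts.max(axis=0) + 1
    step = 1.0 / oversample
    xs = np.arange(xmin, xmax, step) + step / 2
    ys = np.arange(ymin, ymax, step) + step / 2
    gx, gy = np.meshgrid(xs, ys)
    pts = np.column_stack([gx.ravel(), gy.ravel()])
    inside = MplPath(verts).contains_points(pts)
    return inside.sum() * step * step
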