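"""Naive per-voxel reference implementations used only as test oracles.

Everything here is deliberately written with explicit Python loops over
voxels so it shares no code path with the vectorized package internals.
"""

from __future__ import annotations

import math

import numpy as np


def naive_mean(values: np.ndarray, mask: np.ndarray) -> float:
    total, n = 0.0, 0
    for idx in np.ndindex(values.shape):
        if mask[idx]:
            total += values[idx]
            n += 1
    return total / n


def naive_tidal_volume_ml(values: np.ndarray, mask: np.ndarray, spacing) -> float:
    vox_mm3 = spacing[0] * spacing[1] * spacing[2]
    total = 0.0
    for idx in np.ndindex(values.shape):
        if mask[idx]:
            total += values[idx] * vox_mm3
    return total * 1e-3


def naive_vdp(values: np.ndarray, mask: np.ndarray, threshold_fraction: float,
              reference_msv: float | None = None) -> float:
    if reference_msv is None:
        reference_msv = naive_mean(values, mask)
    thresh = threshold_fraction * reference_msv
    n_defect, n = 0, 0
    for idx in np.ndindex(values.shape):
        if mask[idx]:
            n += 1
            if values[idx] < thresh:
                n_defect += 1
    return 100.0 * n_defect / n


def naive_quantile(sorted_vals: list[float], q: float) -> float:
    """Linear-interpolation quantile on an already sorted list."""
    n = len(sorted_vals)
    if n == 1:
        return sorted_vals[0]
    pos = q * (n - 1)
    lo = int(math.floor(pos))
    hi = min(lo + 1, n - 1)
    frac = pos - lo
    return sorted_vals[lo] * (1 - frac) + sorted_vals[hi] * frac


def naive_iqr(values: np.ndarray, mask: np.ndarray) -> float:
    vals = sorted(values[idx] for idx in np.ndindex(values.shape) if mask[idx])
    return naive_quantile(vals, 0.75) - naive_quantile(vals, 0.25)


def naive_vh(values: np.ndarray, mask: np.ndarray) -> float:
    return naive_iqr(values, mask) / naive_mean(values, mask)


def gaussian_kernel_1d(sigma: float) -> np.ndarray:
    """Discrete Gaussian kernel with the standard truncation (4 sigma)."""
    radius = int(4.0 * sigma + 0.5)
    x = np.arange(-radius, radius + 1)
    w = np.exp(-0.5 * (x / sigma) ** 2)
    return w / w.sum()


def naive_masked_lowpass(values: np.ndarray, mask: np.ndarray, sigma_vox) -> np.ndarray:
    """Renormalized masked Gaussian smoothing by explicit per-voxel sums.

    Uses the separable product kernel with zero padding outside the grid,
    normalized per voxel by the in-mask kernel weight.
    """
    kx = gaussian_kernel_1d(sigma_vox[0])
    ky = gaussian_kernel_1d(sigma_vox[1])
    kz = gaussian_kernel_1d(sigma_vox[2])
    rx, ry, rz = len(kx) // 2, len(ky) // 2, len(kz) // 2
    out = np.zeros_like(values, dtype=float)
    nx, ny, nz = values.shape
    for i, j, k in np.ndindex(values.shape):
        if not mask[i, j, k]:
            continue
        num = den = 0.0
        for di in range(-rx, rx + 1):
            ii = i + di
            if not 0 <= ii < nx:
                continue
            for dj in range(-ry, ry + 1):
                jj = j + dj
                if not 0 <= jj < ny:
                    continue
                wij = kx[di + rx] * ky[dj + ry]
                for dk in range(-rz, rz + 1):
                    kk = k + dk
                    if not 0 <= kk < nz:
                        continue
                    if mask[ii, jj, kk]:
                        w = wij * kz[dk + rz]
                        num += w * values[ii, jj, kk]
                        den += w
        out[i, j, k] = num / den
    return out


def windowed_masked_lowpass(values: np.ndarray, mask: np.ndarray, sigma_vox) -> np.ndarray:
    """Per-voxel masked smoothing with an explicit 3D product kernel.

    Same computation as :func:`naive_masked_lowpass` but each voxel's
    window sum is a direct weighted sum over a zero-padded neighborhood
    array instead of three nested scalar loops, so large case counts stay
    affordable while the per-voxel structure remains independent of the
    package's separable-filter implementation.
    """
    kx = gaussian_kernel_1d(sigma_vox[0])
    ky = gaussian_kernel_1d(sigma_vox[1])
    kz = gaussian_kernel_1d(sigma_vox[2])
    kernel = kx[:, None, None] * ky[None, :, None] * kz[None, None, :]
    rx, ry, rz = len(kx) // 2, len(ky) // 2, len(kz) // 2
    pad_vals = np.pad(values * mask, ((rx, rx), (ry, ry), (rz, rz)))
    pad_mask = np.pad(mask.astype(float), ((rx, rx), (ry, ry), (rz, rz)))
    out = np.zeros_like(values, dtype=float)
    for i, j, k in np.ndindex(values.shape):
        if not mask[i, j, k]:
            continue
        win_v = pad_vals[i : i + 2 * rx + 1, j : j + 2 * ry + 1, k : k + 2 * rz + 1]
        win_m = pad_mask[i : i + 2 * rx + 1, j : j + 2 * ry + 1, k : k + 2 * rz + 1]
        out[i, j, k] = float(np.sum(kernel * win_v)) / float(np.sum(kernel * win_m))
    return out


def naive_vh_scales(values: np.ndarray, mask: np.ndarray, spacing, cutoff_mm: float):
    sigma_vox = [cutoff_mm / s for s in spacing]
    low = naive_masked_lowpass(values, mask, sigma_vox)
    high = np.zeros_like(values)
    for idx in np.ndindex(values.shape):
        if mask[idx]:
            high[idx] = values[idx] - low[idx]
    mean = naive_mean(values, mask)
    vh_ls = naive_iqr(low, mask) / naive_mean(low, mask)
    vh_ss = naive_iqr(high, mask) / mean
    return vh_ss, vh_ls


def welch_ttest(x, y):
    """Textbook Welch t statistic, Welch–Satterthwaite df, two-sided p."""
    from scipy.stats import t as tdist

    x, y = list(map(float, x)), list(map(float, y))
    nx, ny = len(x), len(y)
    mx, my = sum(x) / nx, sum(y) / ny
    vx = sum((v - mx) ** 2 for v in x) / (nx - 1)
    vy = sum((v - my) ** 2 for v in y) / (ny - 1)
    se2 = vx / nx + vy / ny
    t = (mx - my) / math.sqrt(se2)
    df = se2**2 / ((vx / nx) ** 2 / (nx - 1) + (vy / ny) ** 2 / (ny - 1))
    p = 2 * tdist.sf(abs(t), df)
    return t, df, p


def pearson_r_p(x, y):
    """Textbook Pearson r and its two-sided t-distribution p-value."""
    from scipy.stats import t as tdist

    x, y = list(map(float, x)), list(map(float, y))
    n = len(x)
    mx, my = sum(x) / n, sum(y) / n
    sxy = sum((a - mx) * (b - my) for a, b in zip(x, y))
    sxx = sum((a - mx) ** 2 for a in x)
    syy = sum((b - my) ** 2 for b in y)
    r = sxy / math.sqrt(sxx * syy)
    t = r * math.sqrt((n - 2) / (1 - r**2))
    p = 2 * tdist.sf(abs(t), n - 2)
    return r, p
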