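"""Temporal and spatial conditioning before GLM/ICA.

Three geometry-preserving, deterministic stages in fixed order:
high-pass filtering (Gaussian-weighted running-line detrend, the FSL
convention sigma = 1/(2 * cutoff * TR) volumes), 3D Gaussian smoothing with
border renormalization, and global intensity normalization to a target
median.  A DCT-basis regression filter is available as an alternative
high-pass implementation.
"""

from __future__ import annotations

import numpy as np
from scipy import ndimage

from fceq.core import VolumeSeries

FWHM_TO_SIGMA = 1.0 / (2.0 * np.sqrt(2.0 * np.log(2.0)))


def _gaussian_kernel_1d(sigma: float, truncate: float = 4.0) -> np.ndarray:
    radius = max(int(np.ceil(truncate * sigma)), 1)
    x = np.arange(-radius, radius + 1, dtype=float)
    w = np.exp(-0.5 * (x / sigma) ** 2)
    return w / w.sum()


def highpass_filter(series: VolumeSeries, cutoff: float = 0.01, method: str = "gaussian") -> VolumeSeries:
    """Remove slow trends below ``cutoff`` (Hz), preserving each voxel's mean.

    ``method="gaussian"`` subtracts a Gaussian-weighted running-line trend
    (local weighted linear regression); the kernel width is calibrated so
    the filter passes half the amplitude exactly at the cutoff frequency,
    sigma = sqrt(2 ln 2) / (2 pi * cutoff * TR) volumes.  ``method="dct"``
    instead regresses out discrete-cosine basis functions with frequencies
    below the cutoff.  Both restore the voxel's original temporal mean
    exactly, so a constant series passes through unchanged.
    """
    tr = series.tr
    nyquist = 0.5 / tr
    if cutoff <= 0:
        raise ValueError("cutoff must be positive")
    if cutoff >= nyquist:
        raise ValueError(f"cutoff {cutoff} Hz is at or above Nyquist ({nyquist} Hz)")
    y = series.flat()  # (V, T)
    mean = y.mean(axis=1, keepdims=True)
    if method == "gaussian":
        sigma_vols = np.sqrt(2.0 * np.log(2.0)) / (2.0 * np.pi * cutoff * tr)
        detrended = y - _running_line_trend(y, sigma_vols=sigma_vols)
        out = detrended - detrended.mean(axis=1, keepdims=True) + mean
    elif method == "dct":
        out = _dct_highpass(y, tr, cutoff) + mean
    else:
        raise ValueError("method must be 'gaussian' or 'dct'")
    return series.with_data(out.reshape(series.data.shape))


def _running_line_trend(y: np.ndarray, sigma_vols: float) -> np.ndarray:
    """Gaussian-weighted local linear trend of each row of y, evaluated at
    every time point, with truncated (border-renormalized) windows."""
    T = y.shape[1]
    w = _gaussian_kernel_1d(sigma_vols)
    radius = (w.size - 1) // 2
    u = np.arange(-radius, radius + 1, dtype=float)
    ones = np.ones(T)
    # windowed moments; 'constant' padding + explicit sums handle the borders
    s0 = ndimage.correlate1d(ones, w, mode="constant")
    s1 = ndimage.correlate1d(ones, w * u, mode="constant")
    s2 = ndimage.correlate1d(ones, w * u**2, mode="constant")
    sy = ndimage.correlate1d(y, w, axis=1, mode="constant")
    suy = ndimage.correlate1d(y, w * u, axis=1, mode="constant")
    denom = s0 * s2 - s1**2
    return (s2 * sy - s1 * suy) / denom


def _dct_highpass(y: np.ndarray, tr: float, cutoff: float) -> np.ndarray:
    """Residual of y against low-frequency DCT-II basis columns (demeaned)."""
    T = y.shape[1]
    n_basis = int(np.floor(2.0 * T * tr * cutoff))
    t = np.arange(T)
    cols = [np.ones(T)]
    for k in range(1, n_basis + 1):
        cols.append(np.cos(np.pi * k * (2 * t + 1) / (2 * T)))
    X = np.column_stack(cols)
    beta, *_ = np.linalg.lstsq(X, y.T, rcond=None)
    return (y.T - X @ beta).T


def smooth_spatial(series: VolumeSeries, fwhm: float = 5.0) -> VolumeSeries:
    """Convolve each volume with a 3D Gaussian of the given FWHM (mm).

    Sigma per axis is ``fwhm / (2 sqrt(2 ln 2))`` divided by the voxel size.
    The kernel is renormalized at the borders (smoothing a constant volume
    returns it exactly); ``fwhm = 0`` is the identity.
    """
    if fwhm < 0:
        raise ValueError("fwhm must be nonnegative")
    if fwhm == 0:
        return series.copy()
    sigma_vox = tuple(fwhm * FWHM_TO_SIGMA / v for v in series.voxel_size)
    sigma4 = sigma_vox + (0.0,)
    blurred = ndimage.gaussian_filter(series.data, sigma=sigma4, mode="constant")
    norm = ndimage.gaussian_filter(np.ones(series.grid), sigma=sigma_vox, mode="constant")
    return series.with_data(blurred / norm[..., None])


def intensity_normalize(
    series: VolumeSeries, target_median: float = 1e4, mask: np.ndarray | None = None
) -> VolumeSeries:
    """Global scaling so the median over all voxels and volumes equals the target.

    An optional boolean mask restricts the median to in-mask voxels (synthetic
    volumes have no anatomical background to exclude by default).
    """
    if mask is not None:
        values = series.data[np.asarray(mask, dtype=bool)]
    else:
        values = series.data
    med = float(np.median(values))
    if med <= 0:
        raise ValueError(f"global median must be positive (got {med})")
    return series.with_data(series.data * (target_median / med))


def run_preprocess(
    series: VolumeSeries,
    highpass_hz: float | None = 0.01,
    fwhm_mm: float | None = 5.0,
    target_median: float | None = 1e4,
    highpass_method: str = "gaussian",
    mask: np.ndarray | None = None,
) -> VolumeSeries:
    """The fixed pipeline highpass -> smooth -> normalize; pass None to skip a stage."""
    out = series
    if highpass_hz is not None:
        out = highpass_filter(out, highpass_hz, method=highpass_method)
    if fwhm_mm is not None:
        out = smooth_spatial(out, fwhm_mm)
    if target_median is not None:
        out = intensity_normalize(out, target_median, mask=mask)
    return out
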