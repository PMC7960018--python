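"""Volume quality metrics: RMSE and mean structural similarity (MSSIM).

SSIM is computed on cubic windows with uniform weights sliding voxel by
voxel; MSSIM averages the per-window values over all fully contained
windows.  The stabilizing constants are the standard c1 = (k1 L)^2 and
c2 = (k2 L)^2 with k1 = 0.01, k2 = 0.03 and L the dynamic range of the
reference volume.  Window statistics use population (1/N) normalization.
SSIM of a window can be negative for anticorrelated content; no clamping is
applied.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy import ndimage

__all__ = [
    "MetricReport",
    "rmse",
    "ssim_window",
    "mssim",
    "relative_improvement",
    "evaluate_volumes",
]

K1 = 0.01
K2 = 0.03
DEFAULT_WINDOW = 7


@dataclass
class MetricReport:
    rmse: float
    mssim: float
    n_windows: int
    window_size: int
    dynamic_range: float

    def as_dict(self) -> dict:
        return {
            "rmse": self.rmse,
            "mssim": self.mssim,
            "n_windows": self.n_windows,
            "window_size": self.window_size,
            "dynamic_range": self.dynamic_range,
        }


def rmse(z: np.ndarray, g: np.ndarray) -> float:
    """Root mean squared voxel difference."""
    z = np.asarray(z, dtype=float)
    g = np.asarray(g, dtype=float)
    if z.shape != g.shape:
        raise ValueError(f"shape mismatch: {z.shape} vs {g.shape}")
    if z.size == 0:
        raise ValueError("empty volumes")
    return float(np.sqrt(np.mean((z - g) ** 2)))


def ssim_window(z_win: np.ndarray, g_win: np.ndarray, dynamic_range: float) -> float:
    """SSIM of a single pair of windows."""
    z = np.asarray(z_win, dtype=float)
    g = np.asarray(g_win, dtype=float)
    if z.shape != g.shape:
        raise ValueError("windows must share a shape")
    c1 = (K1 * dynamic_range) ** 2
    c2 = (K2 * dynamic_range) ** 2
    mz, mg = z.mean(), g.mean()
    vz, vg = z.var(), g.var()
    cov = ((z - mz) * (g - mg)).mean()
    return float(
        (2 * mz * mg + c1)
        * (2 * cov + c2)
        / ((mz**2 + mg**2 + c1) * (vz + vg + c2))
    )


def mssim(
    z: np.ndarray,
    g: np.ndarray,
    window: int = DEFAULT_WINDOW,
    dynamic_range: float | None = None,
) -> tuple[float, int]:
    """Mean SSIM over all fully contained cubic windows at stride 1.

    Returns ``(mssim, n_windows)``.  ``dynamic_range`` defaults to
    max(g) - min(g) of the reference.
    """
    z = np.asarray(z, dtype=float)
    g = np.asarray(g, dtype=float)
    if z.shape != g.shape:
        raise ValueError(f"shape mismatch: {z.shape} vs {g.shape}")
    if any(n < window for n in z.shape):
        raise ValueError(f"window {window} larger than volume {z.shape}")
    if dynamic_range is None:
        dynamic_range = float(g.max() - g.min())
    c1 = (K1 * dynamic_range) ** 2
    c2 = (K2 * dynamic_range) ** 2

    def wmean(a):
        return ndimage.uniform_filter(a, size=window, mode="constant")

    mz, mg = wmean(z), wmean(g)
    vz = wmean(z * z) - mz**2
    vg = wmean(g * g) - mg**2
    cov = wmean(z * g) - mz * mg
    with np.errstate(invalid="ignore", divide="ignore"):  # border region, cropped below
        smap = (
            (2 * mz * mg + c1)
            * (2 * cov + c2)
            / ((mz**2 + mg**2 + c1) * (vz + vg + c2))
        )
    r = window // 2
    core = smap[tuple(slice(r, n - r) for n in z.shape)]
    return float(core.mean()), int(core.size)


def relative_improvement(before: float, after: float) -> float:
    """Relative reduction in percent: 100 (before - after) / before."""
    if before == 0:
        raise ValueError("undefined for a zero baseline")
    return 100.0 * (before - after) / before


def evaluate_volumes(
    z: np.ndarray,
    g: np.ndarray,
    window: int = DEFAULT_WINDOW,
    dynamic_range: float | None = None,
) -> MetricReport:
    """RMSE + MSSIM report of a reconstruction against a reference."""
    g = np.asarray(g, dtype=float)
    if dynamic_range is None:
        dynamic_range = float(g.max() - g.min())
    ms, m = mssim(z, g, window=window, dynamic_range=dynamic_range)
    return MetricReport(
        rmse=rmse(z, g),
        mssim=ms,
        n_windows=m,
        window_size=window,
        dynamic_range=dynamic_range,
    )
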