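"""EM robust statistics: Gaussian-inlier / uniform-outlier residual mixture.

Residuals between acquired and simulated slices are modeled as a two-class
mixture: inliers follow a zero-mean normal N(0, sigma^2), outliers a uniform
density U = 1/(b - a) over the residual range.  EM alternates the posterior
inlier probability per pixel,

    p_ij = c N_sigma(e_ij) / (c N_sigma(e_ij) + (1 - c) U),

with the weighted moment updates sigma^2 = sum p e^2 / sum p and
c = mean(p).  A slice's inlier probability is the mean *squared* pixel
posterior, p_slice = sum_i p_ij^2 / N_j; slices below a threshold are
excluded from the volume update.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np

__all__ = [
    "EMState",
    "e_step",
    "m_step",
    "fit_em",
    "slice_probability",
    "exclude_outlier_slices",
]

log = logging.getLogger(__name__)

DEFAULT_SLICE_THRESHOLD = 0.5


@dataclass
class EMState:
    """Fitted mixture parameters and derived probabilities."""

    sigma: float  # inlier residual std, intensity units
    c: float  # mixing proportion of inliers
    uniform_density: float  # U = 1/(max e - min e)
    posteriors: np.ndarray = field(default_factory=lambda: np.empty(0))
    n_iter: int = 0
    converged: bool = True
    log_likelihood: float = np.nan


def _normal_pdf(e: np.ndarray, sigma: float) -> np.ndarray:
    return np.exp(-0.5 * (e / sigma) ** 2) / (sigma * np.sqrt(2 * np.pi))


def e_step(residuals: np.ndarray, sigma: float, c: float, u: float) -> np.ndarray:
    """Posterior inlier probability per residual."""
    if sigma <= 0 or u <= 0 or not 0 <= c <= 1:
        raise ValueError("require sigma > 0, U > 0 and c in [0, 1]")
    e = np.asarray(residuals, dtype=float)
    if e.size == 0:
        return np.empty(0)
    num = c * _normal_pdf(e, sigma)
    den = num + (1 - c) * u
    # den == 0 only when c == 0 exactly at density-0 points; treat as outlier
    with np.errstate(invalid="ignore"):
        p = np.where(den > 0, num / np.maximum(den, np.finfo(float).tiny), 0.0)
    return p


def m_step(residuals: np.ndarray, posteriors: np.ndarray) -> tuple[float, float]:
    """Weighted residual std and mean posterior (Eq-style moment update)."""
    e = np.asarray(residuals, dtype=float)
    p = np.asarray(posteriors, dtype=float)
    total = float(p.sum())
    if total <= 0:
        raise ValueError("degenerate EM fit: all posteriors zero")
    sigma = float(np.sqrt(np.sum(p * e**2) / total))
    c = total / e.size
    return sigma, c


def _log_likelihood(e: np.ndarray, sigma: float, c: float, u: float) -> float:
    dens = c * _normal_pdf(e, sigma) + (1 - c) * u
    return float(np.sum(np.log(np.maximum(dens, np.finfo(float).tiny))))


def fit_em(
    residuals: np.ndarray,
    *,
    init_sigma: float | None = None,
    init_c: float = 0.9,
    tol: float = 1e-4,
    max_iter: int = 50,
) -> EMState:
    """Fit the inlier/outlier mixture by EM.

    U is held fixed at 1/(max - min) of the residuals.  Initialization
    defaults to the sample std and c = 0.9; passing ``init_sigma``/``init_c``
    warm-starts from a previous fit.
    """
    e = np.asarray(residuals, dtype=float).ravel()
    e = e[np.isfinite(e)]
    if e.size < 16:
        raise ValueError(f"need >= 16 valid residuals, got {e.size}")
    rng = float(e.max() - e.min())
    if rng == 0:
        return EMState(
            sigma=max(abs(float(e[0])), np.finfo(float).eps),
            c=1.0,
            uniform_density=np.inf,
            posteriors=np.ones_like(e),
        )
    u = 1.0 / rng
    sigma = float(init_sigma) if init_sigma else float(np.std(e))
    sigma = max(sigma, 1e-12 * rng)
    c = float(np.clip(init_c, 1e-6, 1.0))
    p = np.ones_like(e)
    converged = False
    it = 0
    for it in range(1, max_iter + 1):
        p = e_step(e, sigma, c, u)
        new_sigma, new_c = m_step(e, p)
        new_sigma = max(new_sigma, 1e-12 * rng)
        if abs(new_sigma - sigma) / sigma < tol and abs(new_c - c) < tol:
            sigma, c = new_sigma, new_c
            converged = True
            break
        sigma, c = new_sigma, new_c
    return EMState(
        sigma=sigma,
        c=c,
        uniform_density=u,
        posteriors=e_step(e, sigma, c, u),
        n_iter=it,
        converged=converged,
        log_likelihood=_log_likelihood(e, sigma, c, u),
    )


def slice_probability(posteriors: np.ndarray, n_valid: int | None = None) -> float:
    """Mean squared posterior over a slice's valid pixels."""
    p = np.asarray(posteriors, dtype=float).ravel()
    n = int(n_valid) if n_valid is not None else p.size
    if n <= 0:
        raise ValueError("slice has no valid pixels")
    return float(np.sum(p**2) / n)


def exclude_outlier_slices(
    slice_probs: np.ndarray, threshold: float = DEFAULT_SLICE_THRESHOLD
) -> np.ndarray:
    """Inclusion flags: slice kept iff its probability >= threshold."""
    if not 0 <= threshold < 1:
        raise ValueError("threshold must lie in [0, 1)")
    probs = np.asarray(slice_probs, dtype=float)
    include = probs >= threshold
    if probs.size and not include.any():
        raise RuntimeError(
            "all slices classified as outliers; threshold too aggressive"
        )
    return include
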