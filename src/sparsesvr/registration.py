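"""Rigid 3D registration: stack-to-template volumes and slice-to-volume.

Dissimilarity is 1 - NCC (normalized cross-correlation), which is invariant
to the per-slice global intensity scale of the acquisition model, minimized
over the 6 rigid parameters with Powell's derivative-free method.
Volume-to-volume registration runs coarse-to-fine over a 3-level Gaussian
pyramid; slice-to-volume registration compares the observed slice (valid
pixels only) against the slice simulated from the volume at the candidate
pose.  Resampling uses linear interpolation, and out-of-field samples are
excluded from the metric rather than zero-filled.

The fitted transform maps moving-world points into fixed-world points, i.e.
it composes into the reconstruction chain as T_global (stacks) or T_local
(slices).
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
from scipy import ndimage, optimize

from .geometry import RigidTransform
from .model import ReconVolume, Slice
from .psf import PsfSpec, _simulate_slice

__all__ = [
    "RegistrationResult",
    "register_volume_to_volume",
    "register_slice_to_volume",
]

log = logging.getLogger(__name__)

MIN_OVERLAP = 0.10
MIN_SLICE_PIXELS = 32


@dataclass
class RegistrationResult:
    transform: RigidTransform
    final_metric: float
    converged: bool
    n_evals: int


def _ncc_dissimilarity(a: np.ndarray, b: np.ndarray) -> float:
    """1 - NCC over paired samples; 1.0 when degenerate (flat signal)."""
    if a.size < 2:
        return 1.0
    a = a - a.mean()
    b = b - b.mean()
    denom = np.sqrt(np.sum(a * a) * np.sum(b * b))
    if denom == 0:
        return 1.0
    return float(1.0 - np.sum(a * b) / denom)


def _params_to_transform(p: np.ndarray) -> RigidTransform:
    """Optimizer vector [rx, ry, rz (deg), tx, ty, tz (mm)] -> transform."""
    return RigidTransform(
        rotation=tuple(np.deg2rad(p[:3])), translation=tuple(p[3:])
    )


def _transform_to_params(t: RigidTransform) -> np.ndarray:
    return np.concatenate([np.rad2deg(t.rotation), t.translation])


def register_volume_to_volume(
    moving: ReconVolume,
    fixed: ReconVolume,
    init: RigidTransform | None = None,
    levels: tuple[int, ...] = (4, 2, 1),
    xtol: float = 1e-3,
    maxfev: int = 2000,
) -> RegistrationResult:
    """Rigid registration of ``moving`` onto ``fixed`` (coarse-to-fine Powell).

    Returns the transform mapping moving-world coordinates into fixed-world
    coordinates.  ``converged`` is False when fewer than 10% of the fixed
    samples land inside the moving volume at the solution.
    """
    init = init or RigidTransform.identity()
    n_evals = 0
    w_f = fixed.world
    w_m_inv = np.linalg.inv(moving.world)

    def metric_at(level: int, mov_img: np.ndarray, fix_img: np.ndarray, p):
        nonlocal n_evals
        n_evals += 1
        t = _params_to_transform(np.asarray(p))
        chain = w_m_inv @ np.linalg.inv(t.matrix) @ w_f
        grids = [np.arange(0, n, level) for n in fixed.shape]
        gx, gy, gz = np.meshgrid(*grids, indexing="ij")
        pts = np.stack([gx, gy, gz, np.ones_like(gx)], axis=-1).reshape(-1, 4)
        mv = pts @ chain.T
        mv = mv[:, :3]
        inside = np.all((mv >= 0) & (mv <= np.asarray(moving.shape) - 1), axis=1)
        if inside.sum() < 2:
            return 1.0, 0.0
        samp = ndimage.map_coordinates(
            mov_img, mv[inside].T, order=1, mode="constant", cval=0.0
        )
        fvals = fix_img[gx.ravel()[inside], gy.ravel()[inside], gz.ravel()[inside]]
        return _ncc_dissimilarity(samp, fvals), inside.mean()

    p = _transform_to_params(init)
    for level in levels:
        sigma = level / 2.0 if level > 1 else 0.0
        mov_img = ndimage.gaussian_filter(moving.voxels, sigma) if sigma else moving.voxels
        fix_img = ndimage.gaussian_filter(fixed.voxels, sigma) if sigma else fixed.voxels

        res = optimize.minimize(
            lambda q: metric_at(level, mov_img, fix_img, q)[0],
            p,
            method="Powell",
            options={"xtol": xtol, "ftol": 1e-8, "maxfev": maxfev},
        )
        p = np.asarray(res.x)

    final_metric, overlap = metric_at(1, moving.voxels, fixed.voxels, p)
    init_metric, _ = metric_at(1, moving.voxels, fixed.voxels, _transform_to_params(init))
    if init_metric < final_metric:  # Powell should never regress; belt and braces
        p = _transform_to_params(init)
        final_metric = init_metric
    converged = overlap >= MIN_OVERLAP
    if not converged:
        log.warning("registration overlap %.1f%% below threshold", 100 * overlap)
    return RegistrationResult(
        transform=_params_to_transform(p),
        final_metric=final_metric,
        converged=converged,
        n_evals=n_evals,
    )


def register_slice_to_volume(
    sl: Slice,
    volume: ReconVolume,
    init: RigidTransform | None = None,
    t_global: RigidTransform | None = None,
    spec: PsfSpec | None = None,
    xtol: float = 1e-2,
    maxfev: int = 600,
) -> RegistrationResult:
    """Refine one slice's local motion transform against the current volume.

    Minimizes 1 - NCC between the observed corrected slice (valid pixels
    only) and the slice simulated from ``volume`` at the candidate pose.
    Slices with fewer than 32 valid pixels are skipped (``converged=False``,
    transform = init).
    """
    init = init or RigidTransform.identity()
    t_global = t_global or RigidTransform.identity()
    # floor the footprint reach so the metric responds to sub-voxel motion
    spec = spec or PsfSpec.for_slice(sl, min_reach=1.1)
    corrected = sl.scale * np.exp(-np.asarray(sl.bias, dtype=float)) * sl.pixels
    corrected = np.broadcast_to(corrected, sl.pixels.shape)
    if sl.valid_mask.sum() < MIN_SLICE_PIXELS:
        return RegistrationResult(init, np.nan, False, 0)
    n_evals = 0

    def metric(p):
        nonlocal n_evals
        n_evals += 1
        t_local = _params_to_transform(np.asarray(p))
        sim, ok = _simulate_slice(sl, t_global, t_local, volume, spec)
        use = ok & sl.valid_mask
        if use.sum() < MIN_SLICE_PIXELS:
            return 1.0
        return _ncc_dissimilarity(corrected[use], sim[use])

    p0 = _transform_to_params(init)
    res = optimize.minimize(
        metric,
        p0,
        method="Powell",
        options={"xtol": xtol, "ftol": 1e-6, "maxfev": maxfev},
    )
    final = float(res.fun)
    init_metric = metric(p0)
    if init_metric < final:
        res.x = p0
        final = init_metric
    return RegistrationResult(
        transform=_params_to_transform(np.asarray(res.x)),
        final_metric=final,
        converged=bool(res.success) or final <= init_metric,
        n_evals=n_evals,
    )
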