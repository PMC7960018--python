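"""Gaussian point-spread-function volume update and slice simulation.

Each acquired pixel samples a 3D neighborhood of the anatomy.  The slice
profile is modeled as a separable anisotropic Gaussian whose FWHM equals the
in-plane spacing in-plane and the slice thickness through-plane.  Scattering
adds each pixel's (corrected) intensity into every reconstruction voxel whose
center falls within the truncated PSF support, weighted by the PSF value at
the voxel's offset from the mapped pixel position; the accumulated PSF
weights are kept alongside so a gather step can divide them out (a weighted
mean — the raw additive update alone would grow without bound over
iterations).  Simulating slices from the volume is the adjoint: a PSF-weighted
average of voxels over the same footprint.

PSF offsets are measured in mm in the *slice* frame (in-plane x/y,
through-plane z), so oblique stacks blur along their own slice-select axis.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np

from .geometry import RigidTransform
from .model import ReconVolume, Slice, Stack, nearest_voxel

__all__ = [
    "PsfSpec",
    "SimulatedSlices",
    "psf_weight",
    "sigma_from_fwhm",
    "scatter_slice_to_volume",
    "gather",
    "simulate_slices",
]

log = logging.getLogger(__name__)

#: FWHM of a Gaussian = 2 sqrt(2 ln 2) sigma
_FWHM_FACTOR = 2.0 * np.sqrt(2.0 * np.log(2.0))


@dataclass(frozen=True)
class PsfSpec:
    """Separable Gaussian PSF widths (mm) and truncation radius (in sigmas).

    ``min_reach`` (reconstruction voxels) optionally floors the per-axis
    truncation so every pixel's footprint spans at least that many voxels.
    The default 0 keeps the pure ``support_radius * sigma`` truncation used
    for scatter/gather; the slice-registration metric uses a floor of ~1.1
    voxels because a sub-voxel in-plane footprint makes the simulated slice —
    and hence the metric — piecewise constant under sub-voxel pose changes.
    """

    sigma_x: float
    sigma_y: float
    sigma_z: float
    support_radius: float = 2.0
    min_reach: float = 0.0

    def __post_init__(self) -> None:
        if min(self.sigma_x, self.sigma_y, self.sigma_z) <= 0:
            raise ValueError("PSF sigmas must be positive")
        if self.support_radius < 1:
            raise ValueError("support_radius must be >= 1 sigma")

    @classmethod
    def for_slice(
        cls, sl: Slice, support_radius: float = 2.0, min_reach: float = 0.0
    ) -> "PsfSpec":
        """Slice-profile PSF: FWHM = spacing in-plane, = thickness through-plane."""
        s_in = sigma_from_fwhm(sl.spacing)
        return cls(
            s_in, s_in, sigma_from_fwhm(sl.thickness), support_radius, min_reach
        )

    @property
    def sigmas(self) -> np.ndarray:
        return np.array([self.sigma_x, self.sigma_y, self.sigma_z])


@dataclass
class SimulatedSlices:
    """Slices simulated from the volume plus per-pixel residuals.

    ``residuals`` holds ``I'(p_s) - I_ss(p_s)`` where simulated; entries whose
    footprint was empty (or invalid pixels) are NaN and carry
    ``simulated_mask`` False.
    """

    slices: list[np.ndarray]
    residuals: list[np.ndarray]
    simulated_masks: list[np.ndarray]


def sigma_from_fwhm(fwhm: float) -> float:
    """Gaussian sigma whose full width at half maximum is ``fwhm`` (mm)."""
    if fwhm <= 0:
        raise ValueError("fwhm must be positive")
    return fwhm / _FWHM_FACTOR


def psf_weight(dx, dy, dz, spec: PsfSpec):
    """Unnormalized separable Gaussian PSF value at offsets (mm).

    The global scale is irrelevant: weights are normalized at gather.
    """
    dx = np.asarray(dx, dtype=float)
    dy = np.asarray(dy, dtype=float)
    dz = np.asarray(dz, dtype=float)
    q = (
        dx**2 / (2 * spec.sigma_x**2)
        + dy**2 / (2 * spec.sigma_y**2)
        + dz**2 / (2 * spec.sigma_z**2)
    )
    return np.exp(-q)


def _slice_frame(chain_world: np.ndarray) -> np.ndarray:
    """Orthonormal slice axes (columns) from a pixel->world affine."""
    a = chain_world[:3, :3]
    q = a / np.linalg.norm(a, axis=0, keepdims=True)
    # re-orthogonalize softly (world affines are rigid*diag in practice)
    u, _, vt = np.linalg.svd(q)
    return u @ vt


def _footprint(
    sl: Slice,
    t_global: RigidTransform,
    t_local: RigidTransform,
    volume: ReconVolume,
    spec: PsfSpec,
):
    """Shared scatter/gather machinery.

    Returns (pix_idx flat valid indices, voxel index triples (m, S, 3),
    weights (m, S), in-bounds mask (m, S)) over the truncated stencil S.
    """
    pixel_to_world = t_global.matrix @ t_local.matrix @ sl.world
    chain = np.linalg.inv(volume.world) @ pixel_to_world
    valid = sl.valid_mask.ravel()
    grid = sl.pixel_grid()[valid]
    if grid.shape[0] == 0:
        return None
    cont = grid @ chain.T
    cont = cont[:, :3] / cont[:, 3:4]

    # truncated support per axis, optionally floored at min_reach voxels
    cutoff = np.maximum(
        spec.support_radius * spec.sigmas, spec.min_reach * volume.spacing
    )
    r_vox = max(1, int(np.ceil(cutoff.max() / volume.spacing)))
    offs = np.stack(
        np.meshgrid(*([np.arange(-r_vox, r_vox + 1)] * 3), indexing="ij"), axis=-1
    ).reshape(-1, 3)

    base, _ = nearest_voxel(cont, volume.shape)
    cand = base[:, None, :] + offs[None, :, :]  # (m, S, 3)
    inb = np.all((cand >= 0) & (cand < np.asarray(volume.shape)), axis=-1)

    # offsets from voxel centers to the mapped pixel position, in world mm,
    # expressed in the slice frame
    d_vox = cand - cont[:, None, :]
    d_world = d_vox @ volume.world[:3, :3].T
    frame = _slice_frame(pixel_to_world)
    d_slice = d_world @ frame  # == frame.T applied to each offset
    w = psf_weight(d_slice[..., 0], d_slice[..., 1], d_slice[..., 2], spec)
    w = np.where(np.all(np.abs(d_slice) <= cutoff, axis=-1), w, 0.0)
    return np.flatnonzero(valid), cand, w, inb


def scatter_slice_to_volume(
    sl: Slice,
    t_global: RigidTransform,
    t_local: RigidTransform,
    volume: ReconVolume,
    spec: PsfSpec,
    pixel_weight: np.ndarray | None = None,
    pixel_values: np.ndarray | None = None,
) -> ReconVolume:
    """Scatter one slice's corrected intensities into the volume (in place).

    Every valid pixel adds ``psf_weight * pixel_weight * S' exp(-B) I`` into
    the voxels inside its truncated PSF footprint; the matching PSF-times-
    pixel weights accumulate in ``volume.weights``.  ``pixel_values``
    overrides the corrected intensities (used for residual scatter).
    """
    fp = _footprint(sl, t_global, t_local, volume, spec)
    if fp is None:
        log.warning(
            "slice (stack %d, index %d) has no valid pixels; skipped",
            sl.stack_id,
            sl.slice_index,
        )
        return volume
    pix_idx, cand, w, inb = fp
    if not inb.any():
        log.warning(
            "slice (stack %d, index %d) is fully out of field; skipped",
            sl.stack_id,
            sl.slice_index,
        )
        return volume
    if pixel_values is None:
        vals = (sl.scale * np.exp(-np.asarray(sl.bias, dtype=float)) * sl.pixels)
        vals = np.broadcast_to(vals, sl.pixels.shape).ravel()[pix_idx]
    else:
        vals = np.asarray(pixel_values, dtype=float).ravel()[pix_idx]
    if pixel_weight is None:
        pw = np.ones_like(vals)
    else:
        pw = np.asarray(pixel_weight, dtype=float).ravel()[pix_idx]

    wt = w * pw[:, None]
    sel = inb & (wt > 0)
    tgt = cand[sel]
    contrib = wt[sel]
    np.add.at(volume.voxels, (tgt[:, 0], tgt[:, 1], tgt[:, 2]), contrib * np.repeat(vals, sel.sum(axis=1)))
    np.add.at(volume.weights, (tgt[:, 0], tgt[:, 1], tgt[:, 2]), contrib)
    return volume


def gather(volume: ReconVolume) -> ReconVolume:
    """Divide accumulated intensities by accumulated weights (weighted mean).

    Voxels with zero weight stay zero and are 'unknown' to downstream steps.
    """
    out = volume.copy()
    nz = out.weights > 0
    out.voxels[nz] = out.voxels[nz] / out.weights[nz]
    out.voxels[~nz] = 0.0
    return out


def _simulate_slice(
    sl: Slice,
    t_global: RigidTransform,
    t_local: RigidTransform,
    volume: ReconVolume,
    spec: PsfSpec,
) -> tuple[np.ndarray, np.ndarray]:
    """PSF-weighted average of volume voxels over each pixel's footprint."""
    sim = np.full(sl.pixels.shape, np.nan)
    mask = np.zeros(sl.pixels.shape, dtype=bool)
    fp = _footprint(sl, t_global, t_local, volume, spec)
    if fp is None:
        return sim, mask
    pix_idx, cand, w, inb = fp
    w = np.where(inb, w, 0.0)
    ci = np.clip(cand, 0, np.asarray(volume.shape) - 1)
    vals = volume.voxels[ci[..., 0], ci[..., 1], ci[..., 2]]
    # only voxels that actually received data contribute
    known = volume.weights[ci[..., 0], ci[..., 1], ci[..., 2]] > 0
    w = np.where(known, w, 0.0)
    wsum = w.sum(axis=1)
    ok = wsum > 0
    est = np.zeros(pix_idx.shape[0])
    est[ok] = (w * vals).sum(axis=1)[ok] / wsum[ok]
    flat_sim = sim.ravel()
    flat_mask = mask.ravel()
    flat_sim[pix_idx[ok]] = est[ok]
    flat_mask[pix_idx[ok]] = True
    return flat_sim.reshape(sl.pixels.shape), flat_mask.reshape(sl.pixels.shape)


def simulate_slices(
    volume: ReconVolume,
    stacks: list[Stack],
    globals_: list[RigidTransform],
    locals_: list[list[RigidTransform]],
    spec: PsfSpec | None = None,
) -> SimulatedSlices:
    """Simulate every slice from the gathered volume and compute residuals.

    ``globals_[s]`` is the stack-to-template transform of stack ``s`` and
    ``locals_[s][j]`` the slice-level motion transform.  Residuals are
    ``corrected_observed - simulated`` on valid, simulated pixels; elsewhere
    NaN.
    """
    sims: list[np.ndarray] = []
    resids: list[np.ndarray] = []
    masks: list[np.ndarray] = []
    for s, stack in enumerate(stacks):
        for j, sl in enumerate(stack.slices):
            sp = spec if spec is not None else PsfSpec.for_slice(sl)
            sim, ok = _simulate_slice(sl, globals_[s], locals_[s][j], volume, sp)
            corrected = sl.scale * np.exp(-np.asarray(sl.bias, dtype=float)) * sl.pixels
            corrected = np.broadcast_to(corrected, sl.pixels.shape)
            ok = ok & sl.valid_mask
            resid = np.where(ok, corrected - sim, np.nan)
            sims.append(sim)
            resids.append(resid)
            masks.append(ok)
    return SimulatedSlices(slices=sims, residuals=resids, simulated_masks=masks)
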