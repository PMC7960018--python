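"""Synthetic multi-stack acquisition: phantom, motion, corruption, sparsity.

The simulator emulates fast spin-echo style multi-orientation acquisitions of
a rigid object: each stack is a set of thick parallel slices sampled from a
ground-truth volume through the slice-profile PSF, with an independent rigid
motion per slice, a smooth multiplicative bias field and a global scale per
slice, additive Gaussian noise, and uniform random pixel removal (the sparse
sampling protocol: a fixed proportion of pixels is dropped per slice).

It does not model MR physics (T2 decay, k-space, spin history) or
through-plane motion within a single slice.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

import numpy as np

from .geometry import RigidTransform
from .model import ReconVolume, Slice, Stack
from .psf import PsfSpec, _simulate_slice

__all__ = [
    "AcquisitionConfig",
    "GroundTruth",
    "generate_phantom",
    "simulate_stack",
    "sparse_sample",
    "simulate_dataset",
]

_ORIENTATION_AXES = {
    # orientation -> (in-plane axis i, in-plane axis j, slice-select axis)
    "axial": (0, 1, 2),
    "coronal": (0, 2, 1),
    "sagittal": (1, 2, 0),
}


@dataclass(frozen=True)
class AcquisitionConfig:
    """Study conditions for one synthetic acquisition.

    ``motion_amplitude`` is (max rotation in degrees, max translation in mm)
    per slice, drawn uniformly in +-amplitude per parameter.  ``noise_sigma``
    is the additive Gaussian std on the 0-255 intensity scale;
    ``bias_amplitude`` bounds |B| in the multiplicative exp(-B) bias;
    ``scale_range`` bounds the per-slice global scale S'.
    """

    orientations: tuple[str, ...] = ("axial", "coronal", "sagittal")
    slice_thickness: float = 2.0
    in_plane_spacing: float = 1.0
    motion_amplitude: tuple[float, float] = (5.0, 2.0)
    noise_sigma: float = 2.0
    bias_amplitude: float = 0.2
    scale_range: tuple[float, float] = (0.9, 1.1)
    removal_proportion: float = 0.5
    seed: int = 0

    def __post_init__(self) -> None:
        if not 0 <= self.removal_proportion < 1:
            raise ValueError("removal_proportion must lie in [0, 1)")
        if self.slice_thickness <= 0 or self.in_plane_spacing <= 0:
            raise ValueError("thickness and spacing must be positive")
        if self.scale_range[0] <= 0 or self.scale_range[0] > self.scale_range[1]:
            raise ValueError("scale_range must be positive and ordered")
        for o in self.orientations:
            if o not in _ORIENTATION_AXES:
                raise ValueError(f"unknown orientation {o!r}")


@dataclass
class GroundTruth:
    """What the simulator knows and reconstruction must recover."""

    volume: ReconVolume
    per_slice_transforms: list[RigidTransform]
    clean_stacks: list[Stack]


def _centered_affine(shape, spacing: float) -> np.ndarray:
    aff = np.eye(4)
    aff[:3, :3] *= spacing
    aff[:3, 3] = -spacing * (np.asarray(shape) - 1) / 2.0
    return aff


def generate_phantom(
    shape: tuple[int, int, int], spacing: float = 1.0, seed: int = 0
) -> ReconVolume:
    """Deterministic nested-ellipsoid phantom with intensities in [0, 255].

    Outer shell, interior matter with two lobes of distinct intensity, and a
    low-amplitude smooth texture: smooth regions plus sharp boundaries, so
    both the footprint scaling and the edge-following elongation of the
    steering kernels are exercised.
    """
    shape = tuple(int(n) for n in shape)
    if any(n < 16 for n in shape):
        raise ValueError(f"phantom dims must be >= 16, got {shape}")
    rng = np.random.default_rng(seed)
    ax = [np.linspace(-1, 1, n) for n in shape]
    x, y, z = np.meshgrid(*ax, indexing="ij")

    def ellipsoid(cx, cy, cz, rx, ry, rz):
        return ((x - cx) / rx) ** 2 + ((y - cy) / ry) ** 2 + ((z - cz) / rz) ** 2 <= 1

    vol = np.zeros(shape)
    outer = ellipsoid(0, 0, 0, 0.85, 0.8, 0.8)
    inner = ellipsoid(0, 0, 0, 0.68, 0.63, 0.63)
    vol[outer] = 220.0  # shell
    vol[inner] = 120.0  # interior matter
    lobe_hi = ellipsoid(-0.25, 0.2, 0.1, 0.28, 0.22, 0.25) & inner
    lobe_lo = ellipsoid(0.3, -0.15, -0.1, 0.22, 0.26, 0.2) & inner
    vol[lobe_hi] = 185.0
    vol[lobe_lo] = 60.0
    # low-amplitude smooth texture inside the head
    texture = np.zeros(shape)
    for _ in range(3):
        k = rng.uniform(2.0, 5.0, size=3)
        phase = rng.uniform(0, 2 * np.pi, size=3)
        texture += np.cos(np.pi * k[0] * x + phase[0]) * np.cos(
            np.pi * k[1] * y + phase[1]
        ) * np.cos(np.pi * k[2] * z + phase[2])
    vol += np.where(inner, 8.0 * texture / 3.0, 0.0)
    vol = np.clip(vol, 0.0, 255.0)
    return ReconVolume(
        voxels=vol,
        spacing=float(spacing),
        world=_centered_affine(shape, spacing),
        weights=np.ones(shape),
    )


def _slice_geometry(gt: ReconVolume, cfg: AcquisitionConfig, orientation: str):
    """In-plane shape, slice count and per-slice world affines for one stack."""
    ai, aj, ak = _ORIENTATION_AXES[orientation]
    extent = np.asarray(gt.shape) * gt.spacing
    n = max(2, int(np.ceil(extent[ai] / cfg.in_plane_spacing)))
    h = max(2, int(np.ceil(extent[aj] / cfg.in_plane_spacing)))
    k = max(1, int(np.ceil(extent[ak] / cfg.slice_thickness)))
    ui = np.eye(3)[ai]
    uj = np.eye(3)[aj]
    uk = np.eye(3)[ak]
    worlds = []
    for idx in range(k):
        w = np.eye(4)
        w[:3, 0] = cfg.in_plane_spacing * ui
        w[:3, 1] = cfg.in_plane_spacing * uj
        w[:3, 2] = cfg.slice_thickness * uk
        w[:3, 3] = (
            -cfg.in_plane_spacing * (n - 1) / 2.0 * ui
            - cfg.in_plane_spacing * (h - 1) / 2.0 * uj
            + (idx - (k - 1) / 2.0) * cfg.slice_thickness * uk
        )
        worlds.append(w)
    return n, h, k, worlds


def _bias_field(n: int, h: int, amplitude: float, rng: np.random.Generator):
    """Low-order 2D polynomial bias scaled to max |B| = amplitude."""
    if amplitude == 0:
        return np.zeros((n, h))
    u, v = np.meshgrid(np.linspace(-1, 1, n), np.linspace(-1, 1, h), indexing="ij")
    coef = rng.uniform(-1, 1, size=6)
    b = (
        coef[0]
        + coef[1] * u
        + coef[2] * v
        + coef[3] * u * u
        + coef[4] * u * v
        + coef[5] * v * v
    )
    peak = np.abs(b).max()
    return amplitude * b / peak if peak > 0 else b


def simulate_stack(
    gt: ReconVolume,
    cfg: AcquisitionConfig,
    orientation: str,
    stack_id: int = 0,
    rng: np.random.Generator | None = None,
) -> tuple[Stack, list[RigidTransform], Stack]:
    """Simulate one oriented stack from the ground truth.

    Each slice is the PSF-weighted resampling of ``gt`` under a random
    per-slice rigid motion, corrupted by the inverse of the scale/bias
    correction (raw = exp(+B)/S' * clean) plus additive Gaussian noise.
    Returns ``(stack, true_transforms, clean_stack)`` where the clean stack
    holds the uncorrupted, motion-sampled slices.
    """
    if rng is None:
        rng = np.random.default_rng(cfg.seed)
    n, h, k, worlds = _slice_geometry(gt, cfg, orientation)
    spec = PsfSpec(
        sigma_x=_sigma(cfg.in_plane_spacing),
        sigma_y=_sigma(cfg.in_plane_spacing),
        sigma_z=_sigma(cfg.slice_thickness),
    )
    max_rot = np.deg2rad(cfg.motion_amplitude[0])
    max_tr = cfg.motion_amplitude[1]
    slices: list[Slice] = []
    clean_slices: list[Slice] = []
    transforms: list[RigidTransform] = []
    identity = RigidTransform.identity()
    for idx in range(k):
        t_true = RigidTransform(
            rotation=tuple(rng.uniform(-max_rot, max_rot, size=3)),
            translation=tuple(rng.uniform(-max_tr, max_tr, size=3)),
        )
        probe = Slice(
            pixels=np.zeros((n, h)),
            spacing=cfg.in_plane_spacing,
            thickness=cfg.slice_thickness,
            world=worlds[idx],
            stack_id=stack_id,
            slice_index=idx,
        )
        clean, ok = _simulate_slice(probe, identity, t_true, gt, spec)
        if not ok.any():
            raise ValueError(
                f"slice {idx} of stack {stack_id} fell fully outside the volume"
            )
        clean = np.where(ok, clean, 0.0)
        bias = _bias_field(n, h, cfg.bias_amplitude, rng)
        scale = float(rng.uniform(*cfg.scale_range))
        raw = clean * np.exp(bias) / scale
        if cfg.noise_sigma > 0:
            raw = raw + rng.normal(0.0, cfg.noise_sigma, size=raw.shape)
        raw = np.clip(raw, 0.0, None)
        slices.append(
            Slice(
                pixels=raw,
                spacing=cfg.in_plane_spacing,
                thickness=cfg.slice_thickness,
                world=worlds[idx],
                stack_id=stack_id,
                slice_index=idx,
                scale=scale,
                bias=bias,
            )
        )
        clean_slices.append(replace(probe, pixels=clean))
        transforms.append(t_true)
    return (
        Stack(slices=slices, orientation_tag=orientation),
        transforms,
        Stack(slices=clean_slices, orientation_tag=orientation),
    )


def _sigma(fwhm: float) -> float:
    return fwhm / (2.0 * np.sqrt(2.0 * np.log(2.0)))


def sparse_sample(sl: Slice, proportion: float, seed: int) -> Slice:
    """Invalidate exactly round(proportion * n * h) pixels, chosen uniformly.

    Pixel values under the removed mask are untouched but never used
    downstream.
    """
    if not 0 <= proportion < 1:
        raise ValueError("proportion must lie in [0, 1)")
    m = sl.pixels.size
    n_remove = int(round(proportion * m))
    rng = np.random.default_rng(seed)
    removed = rng.choice(m, size=n_remove, replace=False)
    mask = sl.valid_mask.copy().ravel()
    mask[removed] = False
    return replace(sl, valid_mask=mask.reshape(sl.pixels.shape), pixels=sl.pixels.copy())


def simulate_dataset(
    cfg: AcquisitionConfig,
    shape: tuple[int, int, int] = (64, 64, 64),
    gt: ReconVolume | None = None,
) -> tuple[list[Stack], GroundTruth]:
    """Full synthetic acquisition: phantom + one stack per orientation.

    Applies the sparse-sampling protocol at ``cfg.removal_proportion`` to
    every slice independently.  Fully deterministic for a fixed config.
    """
    if gt is None:
        gt = generate_phantom(shape, spacing=1.0, seed=cfg.seed)
    rng = np.random.default_rng(cfg.seed + 1)
    stacks: list[Stack] = []
    clean_stacks: list[Stack] = []
    all_transforms: list[RigidTransform] = []
    mask_seed = np.random.default_rng(cfg.seed + 2)
    for sid, orientation in enumerate(cfg.orientations):
        stack, transforms, clean = simulate_stack(gt, cfg, orientation, sid, rng)
        if cfg.removal_proportion > 0:
            stack = Stack(
                slices=[
                    sparse_sample(
                        s, cfg.removal_proportion, int(mask_seed.integers(2**31))
                    )
                    for s in stack.slices
                ],
                orientation_tag=stack.orientation_tag,
            )
        stacks.append(stack)
        clean_stacks.append(clean)
        all_transforms.extend(transforms)
    return stacks, GroundTruth(
        volume=gt, per_slice_transforms=all_transforms, clean_stacks=clean_stacks
    )
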