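"""Data containers and the slice acquisition model.

A ``Slice`` is one acquired 2D image with its world geometry, a validity mask
for sparse sampling, and the per-slice intensity corruption parameters: a
global scale S' and a smooth bias field B acting multiplicatively as
``corrected = S' * exp(-B) * raw``.  A ``Stack`` is an ordered set of parallel
slices in one orientation; a ``ReconVolume`` is the isotropic reconstruction
grid with per-voxel accumulated PSF weights.

Coordinate convention: pixel/voxel centers sit at integer 0-based indices, and
``world_mm = affine @ [i, j, k, 1]^T``.  The full pixel-to-voxel chain is

    p_r = W_r^-1 @ T_global @ T_local @ W_s @ p_s

mapping a homogeneous pixel index ``p_s = [i, j, 0, 1]`` through the slice
world affine ``W_s``, the motion transforms, and the inverse volume world
affine ``W_r``.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

import numpy as np

from .geometry import RigidTransform

__all__ = [
    "Slice",
    "Stack",
    "ReconVolume",
    "correct_slice",
    "map_pixel_to_voxel",
    "nearest_voxel",
]


@dataclass
class Slice:
    """A single 2D slice with geometry and corruption parameters."""

    pixels: np.ndarray  # (n, h) non-negative intensities
    spacing: float  # in-plane pixel size, mm
    thickness: float  # through-plane size, mm
    world: np.ndarray  # 4x4 affine: [i, j, 0, 1] -> world mm
    valid_mask: np.ndarray | None = None
    stack_id: int = 0
    slice_index: int = 0
    scale: float = 1.0  # S', dimensionless
    bias: np.ndarray | float = 0.0  # B, additive in the exponent

    def __post_init__(self) -> None:
        self.pixels = np.asarray(self.pixels, dtype=float)
        if self.pixels.ndim != 2:
            raise ValueError("slice pixels must be 2D")
        if not np.all(np.isfinite(self.pixels)):
            raise ValueError(
                f"slice (stack {self.stack_id}, index {self.slice_index}) "
                "has non-finite pixels"
            )
        if self.valid_mask is None:
            self.valid_mask = np.ones(self.pixels.shape, dtype=bool)
        else:
            self.valid_mask = np.asarray(self.valid_mask, dtype=bool)
        if self.valid_mask.shape != self.pixels.shape:
            raise ValueError("valid_mask shape must equal pixels shape")
        if self.spacing <= 0 or self.thickness <= 0:
            raise ValueError("spacing and thickness must be positive")
        self.world = np.asarray(self.world, dtype=float)
        if self.world.shape != (4, 4):
            raise ValueError("world affine must be 4x4")

    @property
    def shape(self) -> tuple[int, int]:
        return self.pixels.shape

    def pixel_grid(self) -> np.ndarray:
        """Homogeneous indices (m, 4) of all pixels, m = n*h, C order."""
        n, h = self.pixels.shape
        ii, jj = np.meshgrid(np.arange(n), np.arange(h), indexing="ij")
        m = n * h
        out = np.zeros((m, 4))
        out[:, 0] = ii.ravel()
        out[:, 1] = jj.ravel()
        out[:, 3] = 1.0
        return out


@dataclass
class Stack:
    """Ordered slices sharing orientation, spacing and thickness."""

    slices: list[Slice]
    orientation_tag: str = "other"

    def __post_init__(self) -> None:
        if not self.slices:
            raise ValueError("a stack needs at least one slice")
        sp = {(s.spacing, s.thickness) for s in self.slices}
        if len(sp) != 1:
            raise ValueError("all slices in a stack must share spacing/thickness")

    def __len__(self) -> int:
        return len(self.slices)

    @property
    def spacing(self) -> float:
        return self.slices[0].spacing

    @property
    def thickness(self) -> float:
        return self.slices[0].thickness

    def as_array(self) -> np.ndarray:
        """Slices stacked along the third axis, shape (n, h, k)."""
        return np.stack([s.pixels for s in self.slices], axis=-1)


@dataclass
class ReconVolume:
    """Isotropic 3D reconstruction grid with accumulated PSF weights."""

    voxels: np.ndarray  # (nx, ny, nz)
    spacing: float  # mm, isotropic
    world: np.ndarray  # 4x4 affine: voxel index -> world mm
    weights: np.ndarray | None = None

    def __post_init__(self) -> None:
        self.voxels = np.asarray(self.voxels, dtype=float)
        if self.voxels.ndim != 3:
            raise ValueError("volume must be 3D")
        if self.weights is None:
            self.weights = np.zeros_like(self.voxels)
        else:
            self.weights = np.asarray(self.weights, dtype=float)
        if self.weights.shape != self.voxels.shape:
            raise ValueError("voxels and weights must share a shape")
        if np.any(self.weights < 0):
            raise ValueError("weights must be non-negative")
        if self.spacing <= 0:
            raise ValueError("spacing must be positive")
        self.world = np.asarray(self.world, dtype=float)
        if self.world.shape != (4, 4):
            raise ValueError("world affine must be 4x4")

    @property
    def shape(self) -> tuple[int, int, int]:
        return self.voxels.shape

    def copy(self) -> "ReconVolume":
        return ReconVolume(
            voxels=self.voxels.copy(),
            spacing=self.spacing,
            world=self.world.copy(),
            weights=self.weights.copy(),
        )

    @classmethod
    def empty_like(cls, other: "ReconVolume") -> "ReconVolume":
        return cls(
            voxels=np.zeros(other.shape),
            spacing=other.spacing,
            world=other.world.copy(),
        )


def correct_slice(sl: Slice) -> Slice:
    """Apply scale and bias correction: ``pixels' = S' * exp(-B) * pixels``.

    Returns a new slice with corrected intensities, unit scale and zero bias;
    the validity mask is untouched.
    """
    bias = np.asarray(sl.bias, dtype=float)
    if not np.all(np.isfinite(bias)):
        raise ValueError(
            f"slice (stack {sl.stack_id}, index {sl.slice_index}) has non-finite bias"
        )
    if not np.isfinite(sl.scale) or sl.scale <= 0:
        raise ValueError(
            f"slice (stack {sl.stack_id}, index {sl.slice_index}) has scale "
            f"{sl.scale!r}; expected a positive finite value"
        )
    corrected = sl.scale * np.exp(-bias) * sl.pixels
    return replace(
        sl,
        pixels=np.broadcast_to(corrected, sl.pixels.shape).copy(),
        scale=1.0,
        bias=0.0,
        valid_mask=sl.valid_mask.copy(),
    )


def _chain_matrix(
    sl: Slice,
    t_global: RigidTransform,
    t_local: RigidTransform,
    volume: ReconVolume,
) -> np.ndarray:
    """Full 4x4 map from homogeneous pixel index to continuous voxel index."""
    w_r = volume.world
    det = np.linalg.det(w_r)
    if abs(det) < 1e-12:
        raise np.linalg.LinAlgError("volume world affine is singular")
    return np.linalg.inv(w_r) @ t_global.matrix @ t_local.matrix @ sl.world


def map_pixel_to_voxel(
    p_s: np.ndarray,
    sl: Slice,
    t_global: RigidTransform,
    t_local: RigidTransform,
    volume: ReconVolume,
) -> np.ndarray:
    """Map homogeneous pixel index(es) to continuous voxel coordinates.

    ``p_s`` is a homogeneous 4-vector ``[i, j, 0, 1]`` or an (m, 4) array of
    them; returns shape (3,) or (m, 3) continuous voxel coordinates.
    """
    chain = _chain_matrix(sl, t_global, t_local, volume)
    p = np.asarray(p_s, dtype=float)
    single = p.ndim == 1
    p = np.atleast_2d(p)
    if p.shape[-1] != 4:
        raise ValueError("pixel coordinates must be homogeneous 4-vectors")
    out = p @ chain.T
    out = out[:, :3] / out[:, 3:4]
    return out[0] if single else out


def nearest_voxel(
    coord: np.ndarray, shape: tuple[int, int, int] | None = None
) -> tuple[np.ndarray, np.ndarray]:
    """Round continuous voxel coordinates to nearest integer voxel centers.

    Halves round away from zero (deterministic, direction-symmetric
    tie-break).  Returns ``(indices, in_field)``; where ``shape`` is given,
    ``in_field`` flags coordinates whose rounded index lies inside the grid
    so callers can skip out-of-field contributions.
    """
    c = np.asarray(coord, dtype=float)
    if not np.all(np.isfinite(c)):
        raise ValueError("voxel coordinates must be finite")
    # np.round halves-to-even; away-from-zero = sign * floor(|x| + 0.5)
    idx = (np.sign(c) * np.floor(np.abs(c) + 0.5)).astype(int)
    if shape is None:
        in_field = np.ones(idx.shape[:-1] if idx.ndim > 1 else (), dtype=bool)
    else:
        lims = np.asarray(shape)
        in_field = np.all((idx >= 0) & (idx < lims), axis=-1)
    return idx, in_field
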