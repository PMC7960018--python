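"""NIfTI and plain-text I/O for stacks, volumes and transforms.

Stacks are stored one NIfTI file per stack with slices along the third axis
and the slice-0 world affine (plus the through-plane step in the third
column) in the header; validity masks are parallel 0/1 NIfTI files.
Transforms are 4x4 row-major plain-text matrices.
"""

from __future__ import annotations

from pathlib import Path

import nibabel as nib
import numpy as np
from scipy import ndimage

from .geometry import RigidTransform
from .model import ReconVolume, Slice, Stack

__all__ = [
    "read_stack",
    "write_stack",
    "read_volume",
    "write_volume",
    "read_transform",
    "write_transform",
    "resample_to",
]


def write_stack(stack: Stack, path: str | Path, mask_path: str | Path | None = None) -> None:
    arr = stack.as_array()
    aff = stack.slices[0].world.copy()
    if len(stack.slices) > 1:
        aff[:3, 2] = stack.slices[1].world[:3, 3] - stack.slices[0].world[:3, 3]
    nib.save(nib.Nifti1Image(arr.astype(np.float32), aff), str(path))
    if mask_path is not None:
        masks = np.stack([s.valid_mask for s in stack.slices], axis=-1)
        nib.save(nib.Nifti1Image(masks.astype(np.uint8), aff), str(mask_path))


def read_stack(
    path: str | Path,
    mask_path: str | Path | None = None,
    orientation_tag: str = "other",
    stack_id: int = 0,
) -> Stack:
    img = nib.load(str(path))
    data = np.asarray(img.dataobj, dtype=float)
    if data.ndim != 3:
        raise ValueError(f"{path}: expected a 3D stack, got shape {data.shape}")
    aff = np.asarray(img.affine, dtype=float)
    zooms = img.header.get_zooms()[:3]
    spacing = float(zooms[0])
    thickness = float(zooms[2])
    masks = None
    if mask_path is not None:
        masks = np.asarray(nib.load(str(mask_path)).dataobj) > 0
        if masks.shape != data.shape:
            raise ValueError("mask shape does not match stack shape")
    slices = []
    step = aff[:3, 2]
    for k in range(data.shape[2]):
        w = aff.copy()
        w[:3, 3] = aff[:3, 3] + k * step
        slices.append(
            Slice(
                pixels=data[:, :, k],
                spacing=spacing,
                thickness=thickness,
                world=w,
                valid_mask=None if masks is None else masks[:, :, k],
                stack_id=stack_id,
                slice_index=k,
            )
        )
    return Stack(slices=slices, orientation_tag=orientation_tag)


def write_volume(vol: ReconVolume, path: str | Path, weights_path: str | Path | None = None) -> None:
    nib.save(nib.Nifti1Image(vol.voxels.astype(np.float32), vol.world), str(path))
    if weights_path is not None:
        nib.save(
            nib.Nifti1Image(vol.weights.astype(np.float32), vol.world), str(weights_path)
        )


def read_volume(path: str | Path) -> ReconVolume:
    img = nib.load(str(path))
    data = np.asarray(img.dataobj, dtype=float)
    spacing = float(img.header.get_zooms()[0])
    return ReconVolume(
        voxels=data,
        spacing=spacing,
        world=np.asarray(img.affine, dtype=float),
        weights=np.ones_like(data),
    )


def write_transform(t: RigidTransform, path: str | Path) -> None:
    np.savetxt(str(path), t.matrix, fmt="%.12g")


def read_transform(path: str | Path) -> RigidTransform:
    m = np.loadtxt(str(path))
    return RigidTransform.from_matrix(m.reshape(4, 4))


def resample_to(vol: ReconVolume, like: ReconVolume, order: int = 1) -> np.ndarray:
    """Linearly resample ``vol`` onto the grid of ``like`` (world-aligned)."""
    chain = np.linalg.inv(vol.world) @ like.world
    grids = np.meshgrid(*(np.arange(n) for n in like.shape), indexing="ij")
    pts = np.stack([*grids, np.ones_like(grids[0])], axis=-1).reshape(-1, 4)
    src = (pts @ chain.T)[:, :3]
    out = ndimage.map_coordinates(
        vol.voxels, src.T, order=order, mode="constant", cval=0.0
    )
    return out.reshape(like.shape)
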