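"""Low-rank motion scoring of slice stacks and template selection.

Misaligned slices break the linear correlation between slices of a stack, so
the relative error of the best rank-r approximation of the stack data matrix
is a surrogate for motion: a still stack is nearly low-rank, a moving one is
not.  With singular values s_1 >= s_2 >= ... the relative Frobenius error is

    delta_r = ||D - D_r*|| / ||D|| = sqrt(sum_{i>r} s_i^2) / sqrt(sum_i s_i^2)

and the motion surrogate is ``mu = delta_{r*} * r*`` where r* is the smallest
rank with delta_r below a threshold beta.  The stack with minimal mu becomes
the registration template.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .model import Stack

__all__ = [
    "MotionReport",
    "build_data_matrix",
    "rank_error",
    "motion_surrogate",
    "select_template",
]

DEFAULT_BETA = 0.1


@dataclass
class MotionReport:
    """Rank-error profile and motion surrogate of one stack."""

    delta: np.ndarray  # delta_r for r = 1..k
    r_star: int  # minimal rank with delta_r < beta (k if none)
    mu: float  # delta_{r_star} * r_star
    beta: float


def build_data_matrix(stack: Stack) -> np.ndarray:
    """Stack slices as columns: D[:, j] = vec(slice j), column-major vec.

    Invalid (sparsely removed) pixels enter as 0 so D keeps a fixed shape
    across removal ratios.  Only singular values are consumed downstream, so
    the vec ordering is a pure convention.
    """
    shapes = {s.pixels.shape for s in stack.slices}
    if len(shapes) != 1:
        raise ValueError(f"mixed slice shapes in stack: {sorted(shapes)}")
    cols = []
    for s in stack.slices:
        px = np.where(s.valid_mask, s.pixels, 0.0)
        cols.append(px.ravel(order="F"))
    return np.stack(cols, axis=1)


def rank_error(d: np.ndarray, r: int) -> float:
    """Relative Frobenius error of the best rank-``r`` approximation."""
    d = np.asarray(d, dtype=float)
    k = d.shape[1]
    if not 1 <= r <= k:
        raise ValueError(f"rank r={r} outside [1, {k}]")
    s = np.linalg.svd(d, compute_uv=False)
    total = float(np.sum(s**2))
    if total == 0:
        raise ValueError("rank_error undefined for a zero matrix")
    tail = float(np.sum(s[r:] ** 2))
    return float(np.sqrt(tail / total))


def motion_surrogate(d: np.ndarray, beta: float = DEFAULT_BETA) -> MotionReport:
    """Motion surrogate ``mu = delta_{r*} * r*`` from the data matrix."""
    if not 0 < beta <= 1:
        raise ValueError("beta must lie in (0, 1]")
    d = np.asarray(d, dtype=float)
    k = d.shape[1]
    s = np.linalg.svd(d, compute_uv=False)
    total = float(np.sum(s**2))
    if total == 0:
        raise ValueError("motion surrogate undefined for a zero matrix")
    tail = np.concatenate([np.cumsum((s**2)[::-1])[::-1][1:], [0.0]])
    delta = np.sqrt(np.maximum(tail, 0.0) / total)
    below = np.flatnonzero(delta < beta)
    r_star = int(below[0]) + 1 if below.size else k
    mu = float(delta[r_star - 1] * r_star)
    return MotionReport(delta=delta, r_star=r_star, mu=mu, beta=float(beta))


def select_template(stacks: list[Stack], beta: float = DEFAULT_BETA) -> int:
    """Index of the stack with minimal motion surrogate (ties: lowest index)."""
    if not stacks:
        raise ValueError("need at least one stack")
    mus = [motion_surrogate(build_data_matrix(st), beta).mu for st in stacks]
    return int(np.argmin(mus))
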