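"""Iterative 3D adaptive steering kernel regression volume update.

After PSF scatter/gather a sparsely sampled volume still contains empty and
noisy voxels.  Each voxel value r(X) is re-estimated by local weighted least
squares of an order-2 Taylor model over the known voxels X_i in a window,

    Y_i ~ beta0 + beta1.(X_i - X) + beta2.vech((X_i - X)(X_i - X)^T),

where the weights come from a *steering* kernel

    K_s(X_i - X) = sqrt(det C_i) / (2 pi h^2) * exp(-(X_i-X)^T C_i (X_i-X) / (2 h^2))

whose covariance C_i is built from local image gradients: a sum of gradient
outer products over an analysis window, eigen-decomposed and regularized into
an elongation (edge-following) and a scale (footprint) factor controlled by
the regularization lambda and the structure sensitivity alpha.  The scheme is
iterated: classical (isotropic-kernel) regression provides initial gradients,
then covariance estimation and steering regression alternate.

Offsets X_i - X are measured in voxel units of the isotropic reconstruction
grid.  Any global rescaling of the kernel cancels in the weighted
least-squares solution, so the printed 2*pi*h^2 normalizer is kept verbatim.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
from scipy import ndimage

__all__ = [
    "KRConfig",
    "SteeringField",
    "LocalDesign",
    "vech",
    "design_row",
    "classical_kr",
    "naive_covariance",
    "regularize_covariance",
    "steering_weight",
    "solve_local",
    "steering_update_volume",
]

log = logging.getLogger(__name__)

_COND_LIMIT = 1e10
_N_COEF = 10  # order-2 design: 1 + 3 + 6


@dataclass(frozen=True)
class KRConfig:
    """Kernel regression parameters.

    Defaults follow the reference operating point: classical window
    ``k_c = 5`` with bandwidth ``h_c = 2.0`` for the initial gradients,
    steering window ``k_s = 7`` with bandwidth ``h_s = 0.5``, covariance
    analysis window ``w = 3``, regularization ``lam = 2.0``, structure
    sensitivity ``alpha = 0.4`` and three steering iterations.
    """

    k_c: int = 5
    h_c: float = 2.0
    k_s: int = 7
    h_s: float = 0.5
    w: int = 3
    alpha: float = 0.4
    lam: float = 2.0
    order: int = 2
    iterations: int = 3

    def __post_init__(self) -> None:
        for name in ("k_c", "k_s", "w"):
            v = getattr(self, name)
            if v < 3 or v % 2 == 0:
                raise ValueError(f"{name} must be odd and >= 3, got {v}")
        if self.h_c <= 0 or self.h_s <= 0:
            raise ValueError("bandwidths must be positive")
        if not 0 <= self.alpha <= 0.5:
            raise ValueError("alpha must lie in [0, 0.5]")
        if self.lam <= 0:
            raise ValueError("lam must be positive")
        if self.order not in (0, 2):
            raise ValueError("supported Taylor orders: 0 and 2")


@dataclass
class SteeringField:
    """Per-voxel regression state: estimate, gradient and steering covariance."""

    beta0: np.ndarray  # (nx, ny, nz)
    grad: np.ndarray  # (nx, ny, nz, 3)
    cov: np.ndarray | None = None  # (nx, ny, nz, 3, 3)
    estimated: np.ndarray | None = None  # voxels with a valid estimate
    work: int = 0  # accumulated (voxel, neighbor) weight evaluations


@dataclass
class LocalDesign:
    """One voxel's weighted least-squares system."""

    XF: np.ndarray  # (L, 10)
    Wd: np.ndarray  # (L,)
    Y: np.ndarray  # (L,)

    def __post_init__(self) -> None:
        if self.XF.ndim != 2 or self.XF.shape[1] != _N_COEF:
            raise ValueError("design matrix must be (L, 10)")
        if np.any(self.Wd < 0):
            raise ValueError("kernel weights must be non-negative")


def vech(s: np.ndarray) -> np.ndarray:
    """Half-vectorization of a symmetric 3x3 matrix, row-wise upper triangle.

    ``[[a,b,c],[b,d,e],[c,e,f]] -> [a, b, c, d, e, f]``.
    """
    s = np.asarray(s, dtype=float)
    if s.shape != (3, 3):
        raise ValueError("vech expects a 3x3 matrix")
    if not np.allclose(s, s.T, atol=1e-9):
        raise ValueError("vech expects a symmetric matrix")
    return np.array([s[0, 0], s[0, 1], s[0, 2], s[1, 1], s[1, 2], s[2, 2]])


def design_row(offset: np.ndarray) -> np.ndarray:
    """Order-2 design row ``[1, d, vech(d d^T)]`` for one offset d."""
    dx, dy, dz = offset
    return np.array(
        [1.0, dx, dy, dz, dx * dx, dx * dy, dx * dz, dy * dy, dy * dz, dz * dz]
    )


def _offsets(k: int) -> np.ndarray:
    r = k // 2
    ax = np.arange(-r, r + 1)
    return np.stack(np.meshgrid(ax, ax, ax, indexing="ij"), axis=-1).reshape(-1, 3)


def _design_matrix(offs: np.ndarray) -> np.ndarray:
    d = offs.astype(float)
    return np.column_stack(
        [
            np.ones(len(d)),
            d[:, 0],
            d[:, 1],
            d[:, 2],
            d[:, 0] * d[:, 0],
            d[:, 0] * d[:, 1],
            d[:, 0] * d[:, 2],
            d[:, 1] * d[:, 1],
            d[:, 1] * d[:, 2],
            d[:, 2] * d[:, 2],
        ]
    )


def solve_local(design: LocalDesign) -> tuple[float, np.ndarray, np.ndarray]:
    """Solve the weighted least-squares system B = (XF' W XF)^-1 XF' W Y.

    Returns ``(beta0, beta1, beta2)``.  Ill-conditioned systems (condition
    number above 1e10) fall back to order 0: beta0 = weighted mean, zero
    gradient and curvature.
    """
    xf, w, y = design.XF, design.Wd, design.Y
    wsum = float(w.sum())
    if wsum <= 0:
        raise ValueError("weight sum must be positive")
    a = xf.T @ (w[:, None] * xf)
    b = xf.T @ (w * y)
    ev = np.linalg.eigvalsh(a)
    if xf.shape[0] >= _N_COEF and ev[0] > 0 and ev[-1] / ev[0] < _COND_LIMIT:
        coef = np.linalg.solve(a, b)
        return float(coef[0]), coef[1:4], coef[4:]
    return float(b[0] / a[0, 0]), np.zeros(3), np.zeros(6)


def classical_kr(
    values: np.ndarray,
    known: np.ndarray,
    x: tuple[int, int, int],
    k_c: int = 5,
    h_c: float = 2.0,
    order: int = 2,
) -> tuple[float, np.ndarray]:
    """Classical (isotropic Gaussian) kernel regression at one voxel.

    ``values`` is the volume, ``known`` the mask of usable voxels.  Returns
    ``(beta0, beta1)`` — the value and gradient estimates at ``x``.  Fewer
    than 10 known neighbors (or a rank-deficient design) degrades to the
    weighted mean with zero gradient.
    """
    values = np.asarray(values, dtype=float)
    known = np.asarray(known, dtype=bool)
    offs = _offsets(k_c)
    pos = np.asarray(x) + offs
    inb = np.all((pos >= 0) & (pos < np.asarray(values.shape)), axis=1)
    posc = pos[inb]
    use = known[posc[:, 0], posc[:, 1], posc[:, 2]]
    posk = posc[use]
    d = (posk - np.asarray(x)).astype(float)
    if len(d) == 0:
        return np.nan, np.zeros(3)
    w = np.exp(-0.5 * np.sum((d / h_c) ** 2, axis=1)) / h_c
    y = values[posk[:, 0], posk[:, 1], posk[:, 2]]
    if order == 0:
        return float(np.sum(w * y) / np.sum(w)), np.zeros(3)
    xf = _design_matrix(d)
    b0, b1, _ = solve_local(LocalDesign(XF=xf, Wd=w, Y=y))
    return b0, b1


def naive_covariance(grad: np.ndarray, x: tuple[int, int, int], w: int) -> np.ndarray:
    """Sum of gradient outer products over the w^3 analysis window at ``x``."""
    grad = np.asarray(grad, dtype=float)
    offs = _offsets(w)
    pos = np.asarray(x) + offs
    inb = np.all((pos >= 0) & (pos < np.asarray(grad.shape[:3])), axis=1)
    g = grad[pos[inb, 0], pos[inb, 1], pos[inb, 2]]
    return g.T @ g


def regularize_covariance(
    c_naive: np.ndarray, alpha: float, lam: float, n_window: int
) -> np.ndarray:
    """Elongation/scaling regularization of the gradient covariance.

    With eigenvalues s_1 >= s_2 >= s_3 of the naive covariance, the
    elongation factors are a_k = (s_k + lam) / (sqrt(prod_{j != k} s_j) + lam)
    and the footprint scale is gamma = (sqrt(prod_k (s_k + lam)) / L)^alpha,
    giving C = gamma * U diag(a) U'.  In a flat region (zero gradients) this
    reduces to the isotropic kernel gamma * I; the result is symmetric
    positive definite for any lam > 0.
    """
    c = np.asarray(c_naive, dtype=float)
    if not np.allclose(c, c.T, atol=1e-8):
        raise ValueError("naive covariance must be symmetric")
    if lam <= 0:
        raise ValueError("lam must be positive")
    s, u = np.linalg.eigh(c)  # ascending
    s = np.clip(s[::-1], 0.0, None)  # descending, clip tiny negatives
    u = u[:, ::-1]
    prod_others = np.array([s[1] * s[2], s[0] * s[2], s[0] * s[1]])
    a = (s + lam) / (np.sqrt(prod_others) + lam)
    gamma = (np.sqrt(np.prod(s + lam)) / n_window) ** alpha
    out = gamma * (u * a) @ u.T
    return 0.5 * (out + out.T)


def steering_weight(xi: np.ndarray, x: np.ndarray, c_i: np.ndarray, h_s: float) -> float:
    """Steering kernel value K_s(X_i - X) for covariance C_i and bandwidth h."""
    c = np.asarray(c_i, dtype=float)
    ev = np.linalg.eigvalsh(c)
    if ev[0] <= 0:
        raise ValueError("steering covariance must be positive definite")
    d = np.asarray(xi, dtype=float) - np.asarray(x, dtype=float)
    q = d @ c @ d
    return float(
        np.sqrt(np.linalg.det(c)) / (2 * np.pi * h_s**2) * np.exp(-q / (2 * h_s**2))
    )


# ---------------------------------------------------------------------------
# vectorized field-level machinery


def _solve_fields(
    a: np.ndarray,
    b: np.ndarray,
    n_known: np.ndarray,
    ylo: np.ndarray | None = None,
    yhi: np.ndarray | None = None,
) -> tuple[np.ndarray, np.ndarray]:
    """Batched solve of (V,10,10) normal equations with order-0 fallback.

    ``ylo``/``yhi`` bound the known neighbor values per voxel; order-2
    estimates escaping that range by more than half its width (polynomial
    extrapolation blow-up under near-degenerate weighting) also fall back to
    the weighted mean.
    """
    wsum = a[:, 0, 0]
    beta0 = np.full(len(a), np.nan)
    beta1 = np.zeros((len(a), 3))
    has = wsum > 0
    ev = np.full((len(a), _N_COEF), np.nan)
    full = has & (n_known >= _N_COEF)
    if full.any():
        ev[full] = np.linalg.eigvalsh(a[full])
    good = full & (ev[:, 0] > 0) & (ev[:, -1] < _COND_LIMIT * np.maximum(ev[:, 0], 1e-300))
    if good.any():
        coef = np.linalg.solve(a[good], b[good][..., None])[..., 0]
        beta0[good] = coef[:, 0]
        beta1[good] = coef[:, 1:4]
    fb = has & ~good
    if ylo is not None:
        margin = 0.5 * (yhi - ylo)
        with np.errstate(invalid="ignore"):
            wild = good & ((beta0 < ylo - margin) | (beta0 > yhi + margin))
        fb |= wild
        beta1[wild] = 0.0
    beta0[fb] = b[fb, 0] / wsum[fb]
    return beta0, beta1


# monomial exponents (px, py, pz) of each order-2 design column
_COL_EXPS = [
    (0, 0, 0),
    (1, 0, 0),
    (0, 1, 0),
    (0, 0, 1),
    (2, 0, 0),
    (1, 1, 0),
    (1, 0, 1),
    (0, 2, 0),
    (0, 1, 1),
    (0, 0, 2),
]


def _sep_corr(img: np.ndarray, exps, k: int, h: float | None) -> np.ndarray:
    """Window correlation with the separable kernel prod_axis o^p (gauss(o)).

    Computes out[v] = sum_{|o|<=r} img[v+o] * prod_axis o_a^{p_a} K(o_a),
    with K the per-axis Gaussian exp(-o^2 / 2 h^2) (or 1 when h is None).
    """
    r = k // 2
    o = np.arange(-r, r + 1, dtype=float)
    g = np.exp(-0.5 * (o / h) ** 2) if h is not None else np.ones_like(o)
    out = img
    for axis, p in enumerate(exps):
        out = ndimage.correlate1d(
            out, g * o**p, axis=axis, mode="constant", cval=0.0
        )
    return out


def _classical_field(
    values: np.ndarray, known: np.ndarray, k_c: int, h_c: float
) -> tuple[np.ndarray, np.ndarray]:
    """Classical KR at every voxel via mask/value correlations.

    The isotropic kernel weight of each window offset is fixed, so the normal
    equations A = sum_l m_l w_l x_l x_l' and b = sum_l m_l w_l y_l x_l are
    window sums of fixed per-offset tensors; every tensor entry is a monomial
    times a separable Gaussian, so each reduces to three 1D correlations.
    """
    m = known.astype(float)
    my = np.where(known, values, 0.0)
    shape = values.shape
    a = np.empty(shape + (_N_COEF, _N_COEF))
    for i in range(_N_COEF):
        ei = _COL_EXPS[i]
        for j in range(i, _N_COEF):
            ej = _COL_EXPS[j]
            exps = tuple(p + q for p, q in zip(ei, ej))
            a[..., i, j] = _sep_corr(m, exps, k_c, h_c) / h_c
            if i != j:
                a[..., j, i] = a[..., i, j]
    b = np.empty(shape + (_N_COEF,))
    for i in range(_N_COEF):
        b[..., i] = _sep_corr(my, _COL_EXPS[i], k_c, h_c) / h_c
    n_known = np.rint(_sep_corr(m, (0, 0, 0), k_c, None)).astype(int)
    ylo = ndimage.minimum_filter(
        np.where(known, values, np.inf), size=k_c, mode="constant", cval=np.inf
    )
    yhi = ndimage.maximum_filter(
        np.where(known, values, -np.inf), size=k_c, mode="constant", cval=-np.inf
    )
    beta0, beta1 = _solve_fields(
        a.reshape(-1, _N_COEF, _N_COEF),
        b.reshape(-1, _N_COEF),
        n_known.ravel(),
        ylo.ravel(),
        yhi.ravel(),
    )
    return beta0.reshape(shape), beta1.reshape(shape + (3,))


def _covariance_field(grad: np.ndarray, w: int, alpha: float, lam: float):
    """Regularized steering covariance at every voxel.

    Returns the six unique covariance components as 3D fields plus the
    sqrt(det) field (the steering-kernel amplitude).
    """
    kern = np.ones((w, w, w))
    shape = grad.shape[:3]
    comps = {}
    for a_, b_ in ((0, 0), (0, 1), (0, 2), (1, 1), (1, 2), (2, 2)):
        comps[(a_, b_)] = ndimage.correlate(
            grad[..., a_] * grad[..., b_], kern, mode="constant", cval=0.0
        )
    cmat = np.empty(shape + (3, 3))
    for (a_, b_), v in comps.items():
        cmat[..., a_, b_] = v
        cmat[..., b_, a_] = v
    flat = cmat.reshape(-1, 3, 3)
    s, u = np.linalg.eigh(flat)
    s = np.clip(s[:, ::-1], 0.0, None)
    u = u[:, :, ::-1]
    prod_others = np.stack(
        [s[:, 1] * s[:, 2], s[:, 0] * s[:, 2], s[:, 0] * s[:, 1]], axis=1
    )
    aa = (s + lam) / (np.sqrt(prod_others) + lam)
    n_window = w**3
    gamma = (np.sqrt(np.prod(s + lam, axis=1)) / n_window) ** alpha
    reg = gamma[:, None, None] * np.einsum("vik,vk,vjk->vij", u, aa, u)
    reg = 0.5 * (reg + np.swapaxes(reg, 1, 2))
    sqrt_det = np.sqrt(np.clip(np.linalg.det(reg), 0.0, None))
    return reg.reshape(shape + (3, 3)), sqrt_det.reshape(shape)


def _steering_field(
    values: np.ndarray,
    known: np.ndarray,
    cov: np.ndarray,
    sqrt_det: np.ndarray,
    k_s: int,
    h_s: float,
    chunk: int = 4096,
) -> tuple[np.ndarray, np.ndarray, int]:
    """Steering-weighted order-2 regression at every voxel, chunked.

    The kernel weight of neighbor i uses that neighbor's covariance C_i
    (sample-adaptive steering).  Returns (beta0, beta1, work) where ``work``
    counts (voxel, neighbor) weight evaluations.  The bulk weight arithmetic
    runs in float32 (the normal equations are solved in float64); the
    per-voxel reference path in :func:`solve_local` stays full precision.
    """
    shape = values.shape
    offs = _offsets(k_s)
    xf = _design_matrix(offs).astype(np.float32)
    r = k_s // 2

    def pad(img):
        return np.pad(img, r, mode="constant", constant_values=0.0).astype(
            np.float32
        )

    kn_p = pad(known.astype(float)).ravel()
    # unknown (and padding) voxels carry zero weight; their values are unused
    vals_p = pad(np.where(known, values, 0.0)).ravel()
    sd_p = pad(sqrt_det).ravel()
    c6_p = np.stack(
        [
            pad(cov[..., 0, 0]).ravel(),
            pad(cov[..., 0, 1]).ravel(),
            pad(cov[..., 0, 2]).ravel(),
            pad(cov[..., 1, 1]).ravel(),
            pad(cov[..., 1, 2]).ravel(),
            pad(cov[..., 2, 2]).ravel(),
        ],
        axis=0,
    )
    pshape = tuple(n + 2 * r for n in shape)
    pstr = np.array([pshape[1] * pshape[2], pshape[2], 1])
    off_flat = offs @ pstr
    d = offs.astype(np.float32)
    quad_terms = np.stack(
        [
            d[:, 0] * d[:, 0],
            2 * d[:, 0] * d[:, 1],
            2 * d[:, 0] * d[:, 2],
            d[:, 1] * d[:, 1],
            2 * d[:, 1] * d[:, 2],
            d[:, 2] * d[:, 2],
        ],
        axis=0,
    )  # (6, L)
    coords = np.stack(
        np.meshgrid(*(np.arange(r, n + r) for n in shape), indexing="ij"), axis=-1
    ).reshape(-1, 3)
    base = coords @ pstr
    nv = base.shape[0]
    beta0 = np.full(nv, np.nan)
    beta1 = np.zeros((nv, 3))
    inv_2h2 = np.float32(1.0 / (2 * h_s**2))
    amp = np.float32(1.0 / (2 * np.pi * h_s**2))
    work = 0
    for start in range(0, nv, chunk):
        sl = slice(start, min(start + chunk, nv))
        nidx = base[sl, None] + off_flat[None, :]  # (V, L), always in bounds
        kn = kn_p[nidx]
        q = c6_p[0][nidx] * quad_terms[0]
        for t in range(1, 6):
            q += c6_p[t][nidx] * quad_terms[t]
        # q = d'Cd >= 0 for SPD C; clamp away float32 cancellation residue
        np.maximum(q, 0.0, out=q)
        w = sd_p[nidx] * amp * np.exp(-q * inv_2h2) * kn
        work += w.size
        y = vals_p[nidx]
        # A = XF' W XF and b = XF' W y as batched matmuls
        wxf = w[:, :, None] * xf[None, :, :]  # (V, L, 10)
        a = np.matmul(xf.T[None], wxf).astype(np.float64)  # (V, 10, 10)
        b = np.einsum("vl,li->vi", w * y, xf, optimize=True).astype(np.float64)
        n_known = kn.sum(axis=1).astype(int)
        wk = kn > 0
        ylo = np.where(wk, y, np.inf).min(axis=1).astype(np.float64)
        yhi = np.where(wk, y, -np.inf).max(axis=1).astype(np.float64)
        b0, b1 = _solve_fields(a, b, n_known, ylo, yhi)
        beta0[sl] = b0
        beta1[sl] = b1
    return beta0.reshape(shape), beta1.reshape(shape + (3,)), work


def steering_update_volume(
    values: np.ndarray,
    known: np.ndarray,
    cfg: KRConfig | None = None,
) -> SteeringField:
    """Iterative adaptive kernel regression over a (sparsely) known volume.

    Iteration 0 estimates gradients everywhere with the classical isotropic
    kernel; each steering iteration then rebuilds the per-voxel covariance
    from the current gradient field and re-estimates every voxel (known ones
    are denoised from known neighbors, unknown ones filled).  Voxels with no
    known neighbor in the steering window stay unknown (NaN estimate, counted
    in the log).
    """
    cfg = cfg or KRConfig()
    values = np.asarray(values, dtype=float)
    known = np.asarray(known, dtype=bool)
    if values.shape != known.shape or values.ndim != 3:
        raise ValueError("values and known mask must be matching 3D arrays")
    beta0, grad = _classical_field(values, known, cfg.k_c, cfg.h_c)
    work = 0
    cov = None
    for _ in range(cfg.iterations):
        cov, sqrt_det = _covariance_field(grad, cfg.w, cfg.alpha, cfg.lam)
        new_b0, new_grad, step_work = _steering_field(
            values, known, cov, sqrt_det, cfg.k_s, cfg.h_s
        )
        work += step_work
        # where the steering weights vanished (strongly anisotropic kernel,
        # no reachable known neighbor) keep the previous estimate
        bad = ~np.isfinite(new_b0) & np.isfinite(beta0)
        new_b0[bad] = beta0[bad]
        new_grad[bad] = grad[bad]
        beta0, grad = new_b0, new_grad
    estimated = np.isfinite(beta0)
    n_unknown = int((~estimated).sum())
    if n_unknown:
        log.info("steering update left %d voxels unknown", n_unknown)
    return SteeringField(
        beta0=beta0, grad=grad, cov=cov, estimated=estimated, work=work
    )
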