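import numpy as np
import pytest

import sparsesvr as svr
from sparsesvr import KRConfig, LocalDesign
from sparsesvr.kernel_regression import (
    _classical_field,
    _covariance_field,
    _offsets,
    _steering_field,
    design_row,
)


def wls_oracle(xf, w, y):
    """Explicit pseudo-inverse solve of the weighted LS normal equations."""
    sw = np.sqrt(w)
    return np.linalg.pinv(sw[:, None] * xf) @ (sw * y)


def classical_oracle(values, known, x, k_c, h_c):
    """Loop-built classical kernel regression (independent of the library path)."""
    r = k_c // 2
    rows, ws, ys = [], [], []
    for dx in range(-r, r + 1):
        for dy in range(-r, r + 1):
            for dz in range(-r, r + 1):
                p = (x[0] + dx, x[1] + dy, x[2] + dz)
                if any(c < 0 or c >= n for c, n in zip(p, values.shape)):
                    continue
                if not known[p]:
                    continue
                d = np.array([dx, dy, dz], dtype=float)
                rows.append(
                    [1, d[0], d[1], d[2], d[0] ** 2, d[0] * d[1], d[0] * d[2],
                     d[1] ** 2, d[1] * d[2], d[2] ** 2]
                )
                ws.append(np.exp(-0.5 * (d @ d) / h_c**2) / h_c)
                ys.append(values[p])
    coef = wls_oracle(np.asarray(rows), np.asarray(ws), np.asarray(ys))
    return coef[0], coef[1:4]


class TestVech:
    def test_ordering(self):
        s = np.array([[1.0, 2, 3], [2, 4, 5], [3, 5, 6]])
        assert np.array_equal(svr.vech(s), [1, 2, 3, 4, 5, 6])

    def test_identity(self):
        assert np.array_equal(svr.vech(np.eye(3)), [1, 0, 0, 1, 0, 1])

    def test_duplication_round_trip(self):
        rng = np.random.default_rng(0)
        a = rng.normal(size=(3, 3))
        s = a + a.T
        v = svr.vech(s)
        rebuilt = np.array(
            [[v[0], v[1], v[2]], [v[1], v[3], v[4]], [v[2], v[4], v[5]]]
        )
        assert np.allclose(rebuilt, s)

    def test_asymmetric_rejected(self):
        with pytest.raises(ValueError):
            svr.vech(np.array([[1.0, 2, 3], [0, 4, 5], [3, 5, 6]]))


class TestClassicalKR:
    def test_constant_field(self):
        vals = np.full((7, 7, 7), 3.3)
        b0, b1 = svr.classical_kr(vals, np.ones_like(vals, bool), (3, 3, 3))
        assert b0 == pytest.approx(3.3)
        assert np.allclose(b1, 0, atol=1e-9)

    def test_linear_field_exact_gradient(self):
        x, y, z = np.meshgrid(*(np.arange(7.0),) * 3, indexing="ij")
        vals = 2 * x + 3 * y - z
        b0, b1 = svr.classical_kr(vals, np.ones_like(vals, bool), (3, 3, 3))
        assert b0 == pytest.approx(vals[3, 3, 3], abs=1e-9)
        assert np.allclose(b1, [2, 3, -1], atol=1e-9)

    @pytest.mark.parametrize("trial", range(20))
    def test_matches_loop_oracle_with_removal(self, trial):
        rng = np.random.default_rng(100 + trial)
        vals = rng.uniform(0, 100, size=(5, 5, 5))
        known = rng.random((5, 5, 5)) > 0.3
        known[2, 2, 2] = True  # keep the window solvable most trials
        if known.sum() < 10:
            known |= rng.random((5, 5, 5)) > 0.5
        b0, b1 = svr.classical_kr(vals, known, (2, 2, 2), k_c=5, h_c=2.0)
        ob0, ob1 = classical_oracle(vals, known, (2, 2, 2), 5, 2.0)
        assert b0 == pytest.approx(ob0, abs=1e-8)
        assert np.allclose(b1, ob1, atol=1e-8)

    def test_too_few_neighbors_falls_back_to_mean(self):
        vals = np.zeros((5, 5, 5))
        known = np.zeros((5, 5, 5), bool)
        known[2, 2, 2] = known[2, 2, 3] = True
        vals[2, 2, 2] = 4.0
        vals[2, 2, 3] = 6.0
        b0, b1 = svr.classical_kr(vals, known, (2, 2, 2), k_c=3, h_c=1e6)
        assert 4.0 < b0 < 6.0
        assert np.allclose(b1, 0)


class TestCovariance:
    def test_flat_region_zero(self):
        grad = np.zeros((5, 5, 5, 3))
        assert np.allclose(svr.naive_covariance(grad, (2, 2, 2), 3), 0)

    def test_ramp_diag(self):
        grad = np.zeros((5, 5, 5, 3))
        grad[..., 0] = 1.0
        c = svr.naive_covariance(grad, (2, 2, 2), 3)
        assert np.allclose(c, np.diag([27.0, 0, 0]))

    def test_random_matches_loop(self):
        rng = np.random.default_rng(5)
        grad = rng.normal(size=(6, 6, 6, 3))
        c = svr.naive_covariance(grad, (2, 3, 2), 3)
        want = np.zeros((3, 3))
        for dx in (-1, 0, 1):
            for dy in (-1, 0, 1):
                for dz in (-1, 0, 1):
                    g = grad[2 + dx, 3 + dy, 2 + dz]
                    want += np.outer(g, g)
        assert np.allclose(c, want, atol=1e-12)


class TestRegularizeCovariance:
    def test_flat_region_isotropic_closed_form(self):
        lam, alpha, L = 2.0, 0.4, 27
        c = svr.regularize_covariance(np.zeros((3, 3)), alpha, lam, L)
        expect = (lam**3) ** (alpha / 2) / L**alpha * np.eye(3)
        assert np.allclose(c, expect, atol=1e-12)

    def test_isotropic_input_stays_isotropic(self):
        c = svr.regularize_covariance(5.0 * np.eye(3), 0.3, 2.0, 27)
        assert np.allclose(c, c[0, 0] * np.eye(3), atol=1e-12)

    def test_alpha_zero_scale_insensitive(self):
        rng = np.random.default_rng(1)
        g = rng.normal(size=(10, 3))
        naive = g.T @ g
        c = svr.regularize_covariance(naive, 0.0, 2.0, 27)
        s = np.sort(np.linalg.eigvalsh(naive))[::-1]
        a = (s + 2.0) / (np.sqrt([s[1] * s[2], s[0] * s[2], s[0] * s[1]]) + 2.0)
        # gamma = 1 at alpha = 0: eigenvalues are exactly the elongation factors
        assert np.allclose(np.sort(np.linalg.eigvalsh(c))[::-1], np.sort(a)[::-1])

    def test_result_spd(self):
        rng = np.random.default_rng(2)
        for _ in range(25):
            g = rng.normal(size=(6, 3)) * rng.uniform(0, 100)
            c = svr.regularize_covariance(g.T @ g, 0.5, 2.0, 27)
            assert np.linalg.eigvalsh(c).min() > 0
            assert np.allclose(c, c.T)


class TestSteeringWeight:
    def test_identity_covariance_center(self):
        w = svr.steering_weight(np.zeros(3), np.zeros(3), np.eye(3), 1.0)
        assert w == pytest.approx(1 / (2 * np.pi))

    def test_identity_covariance_offset(self):
        w = svr.steering_weight(np.array([1.0, 1.0, 0.0]), np.zeros(3), np.eye(3), 1.0)
        assert w == pytest.approx(np.exp(-1) / (2 * np.pi), abs=1e-6)

    def test_elongation_direction(self):
        c = np.diag([10.0, 0.1, 0.1])
        wx = svr.steering_weight(np.array([1.0, 0, 0]), np.zeros(3), c, 1.0)
        wy = svr.steering_weight(np.array([0, 1.0, 0]), np.zeros(3), c, 1.0)
        # larger covariance along x decays faster along x
        assert wx < wy

    def test_non_spd_rejected(self):
        with pytest.raises(ValueError):
            svr.steering_weight(np.zeros(3), np.zeros(3), -np.eye(3), 1.0)


class TestSolveLocal:
    def make_design(self, rng, L=25):
        offs = rng.uniform(-2, 2, size=(L, 3))
        xf = np.stack([design_row(o) for o in offs])
        w = rng.uniform(0.1, 1.0, size=L)
        y = rng.uniform(0, 10, size=L)
        return LocalDesign(XF=xf, Wd=w, Y=y)

    def test_exact_quadratic_interpolation(self):
        rng = np.random.default_rng(3)
        coef = rng.normal(size=10)
        offs = _offsets(3).astype(float)
        xf = np.stack([design_row(o) for o in offs])
        y = xf @ coef
        b0, b1, b2 = svr.solve_local(LocalDesign(XF=xf, Wd=np.ones(len(y)), Y=y))
        fit = np.concatenate([[b0], b1, b2])
        assert np.linalg.norm(y - xf @ fit) < 1e-8

    def test_weight_scale_invariance(self):
        rng = np.random.default_rng(4)
        d = self.make_design(rng)
        a = svr.solve_local(d)
        b = svr.solve_local(LocalDesign(XF=d.XF, Wd=7.0 * d.Wd, Y=d.Y))
        for x, y in zip(a, b):
            assert np.allclose(x, y, atol=1e-10)

    @pytest.mark.parametrize("trial", range(20))
    def test_matches_pinv_oracle(self, trial):
        rng = np.random.default_rng(50 + trial)
        d = self.make_design(rng)
        b0, b1, b2 = svr.solve_local(d)
        want = wls_oracle(d.XF, d.Wd, d.Y)
        got = np.concatenate([[b0], b1, b2])
        assert np.allclose(got, want, atol=1e-8)

    def test_zero_weights_rejected(self):
        rng = np.random.default_rng(6)
        d = self.make_design(rng)
        with pytest.raises(ValueError):
            svr.solve_local(LocalDesign(XF=d.XF, Wd=0.0 * d.Wd, Y=d.Y))


class TestSteeringUpdate:
    def test_smooth_known_volume_changes_little(self, smooth_volume):
        known = np.ones(smooth_volume.shape, bool)
        sf = svr.steering_update_volume(smooth_volume, known, KRConfig(iterations=1))
        rng_int = smooth_volume.max() - smooth_volume.min()
        interior = (slice(2, -2),) * 3
        delta = np.abs(sf.beta0 - smooth_volume)[interior]
        assert delta.max() <= 0.01 * rng_int

    def test_sparse_fill_beats_nearest_neighbor(self, smooth_volume):
        from scipy import ndimage

        rng = np.random.default_rng(9)
        known = rng.random(smooth_volume.shape) > 0.8
        vals = np.where(known, smooth_volume, 0.0)
        sf = svr.steering_update_volume(vals, known, KRConfig())
        filled = np.where(sf.estimated, sf.beta0, 0.0)
        ind = ndimage.distance_transform_edt(~known, return_indices=True)[1]
        nn = vals[tuple(ind)]
        assert svr.rmse(filled, smooth_volume) < svr.rmse(nn, smooth_volume)

    def test_field_consistent_with_pointwise_path(self, smooth_volume):
        rng = np.random.default_rng(10)
        known = rng.random(smooth_volume.shape) > 0.4
        vals = np.where(known, smooth_volume, 0.0)
        cfg = KRConfig(iterations=1)
        b0c, grad = _classical_field(vals, known, cfg.k_c, cfg.h_c)
        for x in [(8, 8, 8), (12, 5, 17), (3, 20, 11)]:
            pb0, _ = svr.classical_kr(vals, known, x, cfg.k_c, cfg.h_c)
            assert b0c[x] == pytest.approx(pb0, abs=1e-8)
        cov, sd = _covariance_field(grad, cfg.w, cfg.alpha, cfg.lam)
        b0s, _, _ = _steering_field(vals, known, cov, sd, cfg.k_s, cfg.h_s)
        for x in [(8, 8, 8), (12, 5, 17)]:
            offs = _offsets(cfg.k_s)
            pos = np.asarray(x) + offs
            inb = np.all((pos >= 0) & (pos < np.asarray(vals.shape)), axis=1)
            pos = pos[inb]
            use = known[pos[:, 0], pos[:, 1], pos[:, 2]]
            pos = pos[use]
            d = (pos - np.asarray(x)).astype(float)
            w = np.array(
                [svr.steering_weight(p, np.asarray(x), cov[tuple(p)], cfg.h_s) for p in pos]
            )
            xf = np.stack([design_row(o) for o in d])
            y = vals[pos[:, 0], pos[:, 1], pos[:, 2]]
            pb0, _, _ = svr.solve_local(LocalDesign(XF=xf, Wd=w, Y=y))
            # field path accumulates in float32; agreement is to that precision
            assert b0s[x] == pytest.approx(pb0, rel=1e-3, abs=1e-2)

    def test_edge_preserved_versus_isotropic(self):
        # two constant half-spaces with a sharp edge, sparse sampling
        n = 20
        vol = np.where(np.arange(n)[:, None, None] < n // 2, 40.0, 200.0)
        vol = np.broadcast_to(vol, (n, n, n)).copy()
        rng = np.random.default_rng(11)
        known = rng.random(vol.shape) > 0.5
        vals = np.where(known, vol, 0.0)
        steer = svr.steering_update_volume(vals, known, KRConfig(alpha=0.4, iterations=2))
        iso = svr.steering_update_volume(vals, known, KRConfig(alpha=0.0, iterations=2))

        def edge_blur(field):
            prof = field[:, 5:-5, 5:-5].mean(axis=(1, 2))
            lo, hi = 40.0, 200.0
            t25 = np.argmax(prof > lo + 0.25 * (hi - lo))
            t75 = np.argmax(prof > lo + 0.75 * (hi - lo))
            return t75 - t25

        assert edge_blur(steer.beta0) <= edge_blur(iso.beta0)

    def test_work_counter_grows_with_kernel_size(self, smooth_volume):
        known = np.ones(smooth_volume.shape, bool)
        works = []
        for ks in (3, 5, 7):
            sf = svr.steering_update_volume(
                smooth_volume, known, KRConfig(k_s=ks, iterations=1)
            )
            works.append(sf.work)
        assert works[0] < works[1] < works[2]


def test_kernel_global_scale_invariance():
    """Multiplying every kernel weight by a constant leaves the estimate fixed."""
    rng = np.random.default_rng(12)
    offs = _offsets(5).astype(float)
    xf = np.stack([design_row(o) for o in offs])
    w = rng.uniform(0.01, 1.0, size=len(offs))
    y = rng.uniform(0, 100, size=len(offs))
    a = svr.solve_local(LocalDesign(XF=xf, Wd=w, Y=y))
    b = svr.solve_local(LocalDesign(XF=xf, Wd=1234.5 * w, Y=y))
    assert np.allclose(np.concatenate([[a[0]], a[1], a[2]]),
                       np.concatenate([[b[0]], b[1], b[2]]), atol=1e-9)
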