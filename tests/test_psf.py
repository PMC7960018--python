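import numpy as np
import pytest

import sparsesvr as svr
from sparsesvr import PsfSpec, RigidTransform
from sparsesvr.psf import _simulate_slice

from conftest import identity_slice


def unit_spec(sigma=0.5, support=2.0):
    return PsfSpec(sigma, sigma, sigma, support)


class TestPsfWeight:
    def test_closed_forms(self):
        spec = PsfSpec(1.0, 2.0, 3.0)
        assert svr.psf_weight(0, 0, 0, spec) == pytest.approx(1.0)
        assert svr.psf_weight(1.0, 0, 0, spec) == pytest.approx(np.exp(-0.5))
        assert svr.psf_weight(1.0, 2.0, 3.0, spec) == pytest.approx(np.exp(-1.5))

    def test_symmetric_and_monotone(self):
        spec = PsfSpec(1.0, 1.5, 2.0)
        assert svr.psf_weight(0.7, -0.3, 1.1, spec) == pytest.approx(
            svr.psf_weight(-0.7, 0.3, -1.1, spec)
        )
        d = np.linspace(0, 3, 10)
        w = svr.psf_weight(d, 0, 0, spec)
        assert np.all(np.diff(w) < 0)


class TestSigmaFromFwhm:
    def test_known_values(self):
        assert svr.sigma_from_fwhm(2.3548) == pytest.approx(1.0, abs=1e-4)
        assert svr.sigma_from_fwhm(1.0) == pytest.approx(0.42466, abs=1e-5)

    def test_half_maximum_property(self):
        fwhm = 3.7
        sigma = svr.sigma_from_fwhm(fwhm)
        spec = PsfSpec(1.0, 1.0, sigma)
        assert svr.psf_weight(0, 0, fwhm / 2, spec) == pytest.approx(0.5, abs=1e-6)

    def test_rejects_nonpositive(self):
        with pytest.raises(ValueError):
            svr.sigma_from_fwhm(0.0)


def scatter_oracle(sl, t_global, t_local, volume, spec, pixel_weight=None):
    """Dense double-loop reference for PSF scatter + gather."""
    acc = np.zeros(volume.shape)
    wacc = np.zeros(volume.shape)
    chain_world = t_global.matrix @ t_local.matrix @ sl.world
    a = chain_world[:3, :3]
    frame = a / np.linalg.norm(a, axis=0, keepdims=True)
    n, h = sl.pixels.shape
    corrected = sl.scale * np.exp(-np.asarray(sl.bias, dtype=float)) * sl.pixels
    corrected = np.broadcast_to(corrected, sl.pixels.shape)
    cutoff = np.maximum(
        spec.support_radius * spec.sigmas, spec.min_reach * volume.spacing
    )
    for i in range(n):
        for j in range(h):
            if not sl.valid_mask[i, j]:
                continue
            world = chain_world @ np.array([i, j, 0, 1.0])
            cont = np.linalg.inv(volume.world) @ world
            cont = cont[:3]
            pw = 1.0 if pixel_weight is None else pixel_weight[i, j]
            for x in range(volume.shape[0]):
                for y in range(volume.shape[1]):
                    for z in range(volume.shape[2]):
                        vworld = (volume.world @ np.array([x, y, z, 1.0]))[:3]
                        d_slice = frame.T @ (vworld - world[:3])
                        if np.any(np.abs(d_slice) > cutoff):
                            continue
                        w = svr.psf_weight(*d_slice, spec) * pw
                        acc[x, y, z] += w * corrected[i, j]
                        wacc[x, y, z] += w
    out = np.zeros(volume.shape)
    nz = wacc > 0
    out[nz] = acc[nz] / wacc[nz]
    return out, wacc


class TestScatter:
    def test_delta_limit_hits_nearest_voxel(self):
        vol = svr.ReconVolume(voxels=np.zeros((5, 5, 5)), spacing=1.0, world=np.eye(4))
        sl = identity_slice(np.array([[7.0]]))
        sl.world[:3, 3] = [2, 2, 2]  # pixel lands on voxel (2,2,2)
        spec = unit_spec(sigma=0.05)
        svr.scatter_slice_to_volume(sl, RigidTransform(), RigidTransform(), vol, spec)
        out = svr.gather(vol)
        assert out.voxels[2, 2, 2] == pytest.approx(7.0, abs=1e-6)
        assert np.count_nonzero(out.voxels) == 1

    def test_constant_slice_gathers_to_constant(self):
        vol = svr.ReconVolume(voxels=np.zeros((6, 6, 6)), spacing=1.0, world=np.eye(4))
        sl = identity_slice(np.full((4, 4), 3.5))
        sl.world[:3, 3] = [1, 1, 2]
        svr.scatter_slice_to_volume(sl, RigidTransform(), RigidTransform(), vol, unit_spec())
        out = svr.gather(vol)
        covered = out.weights > 0
        assert covered.any()
        assert np.allclose(out.voxels[covered], 3.5)

    def test_matches_dense_loop_oracle(self):
        rng = np.random.default_rng(42)
        vol = svr.ReconVolume(voxels=np.zeros((4, 4, 4)), spacing=1.0, world=np.eye(4))
        sl = identity_slice(rng.uniform(10, 100, size=(3, 3)), scale=1.3, bias=0.1)
        sl.valid_mask[1, 2] = False
        sl.world = RigidTransform(
            rotation=(0.3, 0.1, -0.2), translation=(0.7, 0.6, 1.4)
        ).matrix
        spec = unit_spec(sigma=0.8)
        tg = RigidTransform(rotation=(0.05, 0, 0), translation=(0.2, 0, 0))
        tl = RigidTransform(translation=(0, -0.3, 0.1))
        svr.scatter_slice_to_volume(sl, tg, tl, vol, spec)
        got = svr.gather(vol)
        want, wacc = scatter_oracle(sl, tg, tl, svr.ReconVolume.empty_like(vol), spec)
        assert np.allclose(got.voxels, want, atol=1e-9)
        assert np.allclose(got.weights, wacc, atol=1e-9)

    def test_scatter_is_linear_in_intensities(self):
        rng = np.random.default_rng(3)
        base = svr.ReconVolume(voxels=np.zeros((5, 5, 5)), spacing=1.0, world=np.eye(4))
        p1 = rng.uniform(0, 50, (3, 3))
        p2 = rng.uniform(0, 50, (3, 3))
        a, b = 2.0, -0.5
        outs = []
        for px in (p1, p2, a * p1 + b * p2):
            vol = svr.ReconVolume.empty_like(base)
            sl = identity_slice(np.abs(px))
            sl.pixels = px  # allow signed combination for the linearity check
            sl.world[:3, 3] = [1, 1, 2]
            svr.scatter_slice_to_volume(
                sl, RigidTransform(), RigidTransform(), vol, unit_spec()
            )
            outs.append(vol.voxels.copy())
        assert np.allclose(a * outs[0] + b * outs[1], outs[2], atol=1e-9)


class TestSimulateSlices:
    def test_constant_volume_simulates_constant(self):
        vol = svr.ReconVolume(
            voxels=np.full((6, 6, 6), 4.2),
            spacing=1.0,
            world=np.eye(4),
            weights=np.ones((6, 6, 6)),
        )
        sl = identity_slice(np.zeros((4, 4)))
        sl.world[:3, 3] = [1, 1, 3]
        sim, ok = _simulate_slice(sl, RigidTransform(), RigidTransform(), vol, unit_spec())
        assert ok.all()
        assert np.allclose(sim, 4.2)

    def test_scatter_then_simulate_consistency(self, still_dataset):
        """Simulating from a volume scattered from still stacks reproduces them."""
        stacks, gt = still_dataset
        stack = stacks[0]
        vol = svr.ReconVolume.empty_like(gt.volume)
        ident = RigidTransform()
        for sl in stack.slices:
            svr.scatter_slice_to_volume(sl, ident, ident, vol, PsfSpec.for_slice(sl))
        vol = svr.gather(vol)
        sim = svr.simulate_slices(
            vol, [stack], [ident], [[ident] * len(stack.slices)]
        )
        resid = np.concatenate(
            [r[m] for r, m in zip(sim.residuals, sim.simulated_masks)]
        )
        rng_int = gt.volume.voxels.max() - gt.volume.voxels.min()
        # interior agreement well below the intensity range (PSF self-consistency)
        assert np.median(np.abs(resid)) < 0.02 * rng_int

    def test_zero_residual_when_volume_matches(self):
        vol = svr.ReconVolume(
            voxels=np.full((6, 6, 6), 9.0),
            spacing=1.0,
            world=np.eye(4),
            weights=np.ones((6, 6, 6)),
        )
        sl = identity_slice(np.full((3, 3), 9.0))
        sl.world[:3, 3] = [1, 1, 3]
        out = svr.simulate_slices(vol, [svr.Stack(slices=[sl])], [RigidTransform()], [[RigidTransform()]])
        m = out.simulated_masks[0]
        assert np.allclose(out.residuals[0][m], 0.0, atol=1e-12)
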