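"""FSC resolution estimation, image metrics, FBP baseline, volume measurement."""

import warnings

import numpy as np
import pytest

from strtomo.data import ProjectionSet, voxel_centers
from strtomo.evaluate import (
    EvaluationError,
    FSCCurve,
    PSNR_CAP_DB,
    fbp_reconstruct,
    fsc,
    halfbit_threshold,
    image_metrics,
    molten_volume,
    resolution_from_fsc,
)
from strtomo.forward import Geometry, project_volume_oracle
from strtomo.phantom import PhantomSpec, make_phantom


def ball(n, center=(0, 0, 0), radius=0.45):
    xs = voxel_centers(n)
    gx, gy, gz = np.meshgrid(xs, xs, xs, indexing="ij")
    return (
        (gx - center[0]) ** 2 + (gy - center[1]) ** 2 + (gz - center[2]) ** 2
        <= radius**2
    ).astype(float)


def project_stack(vol, angles, geom):
    frames = np.stack([project_volume_oracle(vol, a, geom) for a in angles])
    n = len(angles)
    return ProjectionSet(
        frames=frames,
        theta_deg=np.asarray(angles, dtype=float),
        time_index=np.zeros(n, dtype=int),
        t_norm=np.zeros(n),
        pixel_size=geom.pixel_size,
    )


class TestHalfBit:
    def test_large_shell_asymptote(self):
        t = halfbit_threshold(np.array([1e12]))
        np.testing.assert_allclose(t, 0.2071 / 1.2071, rtol=1e-5)

    def test_single_voxel_shell_value(self):
        t = halfbit_threshold(np.array([1.0]))
        np.testing.assert_allclose(
            t, (0.2071 + 1.9102) / (1.2071 + 0.9102), rtol=1e-12
        )

    def test_strictly_decreasing_in_shell_population(self):
        n = np.arange(1, 2000, dtype=float)
        t = halfbit_threshold(n)
        assert np.all(np.diff(t) < 0)


class TestFSC:
    def test_self_correlation_is_one_everywhere(self, rng):
        vol = rng.normal(size=(16, 16, 16))
        curve = fsc(vol, vol)
        np.testing.assert_allclose(curve.correlation, 1.0, atol=1e-10)

    def test_invariant_to_global_scaling(self, rng):
        a = rng.normal(size=(16, 16, 16))
        c1 = fsc(a, 2.0 * a)
        np.testing.assert_allclose(c1.correlation, 1.0, atol=1e-10)
        b = rng.normal(size=(16, 16, 16))
        np.testing.assert_allclose(
            fsc(a, b).correlation, fsc(a, 5.0 * b).correlation, atol=1e-10
        )

    def test_symmetric_in_arguments(self, rng):
        a = rng.normal(size=(12, 12, 12))
        b = rng.normal(size=(12, 12, 12))
        np.testing.assert_allclose(
            fsc(a, b).correlation, fsc(b, a).correlation, atol=1e-12
        )

    def test_independent_noise_decorrelates_within_sampling_bound(self):
        rng = np.random.default_rng(123)
        a = rng.normal(size=(32, 32, 32))
        b = rng.normal(size=(32, 32, 32))
        curve = fsc(a, b)
        big = curve.n_voxels >= 200
        bound = 3.0 / np.sqrt(curve.n_voxels[big])
        assert np.all(np.abs(curve.correlation[big]) <= bound)

    def test_all_zero_volume_rejected(self):
        with pytest.raises(EvaluationError, match="zero"):
            fsc(np.zeros((8, 8, 8)), np.ones((8, 8, 8)))

    def test_noncubic_volumes_are_padded(self, rng):
        a = rng.normal(size=(16, 12, 8))
        curve = fsc(a, a)
        np.testing.assert_allclose(curve.correlation, 1.0, atol=1e-10)


class TestResolution:
    def test_no_crossing_resolves_to_nyquist_floor(self, rng):
        vol = rng.normal(size=(16, 16, 16))
        assert fsc(vol, vol).resolution_voxels == 2.0

    def test_synthetic_crossing_at_quarter_cycle_gives_four_voxels(self):
        freq = np.array([0.1, 0.2, 0.3, 0.4])
        corr = np.array([1.0, 1.0, 0.0, 0.0])
        thr = np.full(4, 0.5)
        curve = FSCCurve(freq=freq, correlation=corr, n_voxels=np.full(4, 100),
                         threshold=thr)
        # linear crossing of corr-thr between 0.2 (+0.5) and 0.3 (-0.5) -> 0.25
        assert resolution_from_fsc(curve) == pytest.approx(4.0)

    def test_matches_brute_force_shell_scan(self):
        """Band-limited pair: resolution from the curve equals a discrete
        scan for the first below-threshold shell."""
        rng = np.random.default_rng(7)
        n = 32
        a = rng.normal(size=(n, n, n))
        f = np.fft.fftfreq(n)
        r = np.sqrt(f[:, None, None]**2 + f[None, :, None]**2
                    + f[None, None, :]**2)
        cutoff = 0.30
        fa = np.fft.fftn(a)
        low = np.fft.ifftn(np.where(r <= cutoff, fa, 0)).real
        # b agrees below the cutoff, independent noise above
        b = low + np.fft.ifftn(
            np.where(r > cutoff, np.fft.fftn(rng.normal(size=(n, n, n))), 0)
        ).real
        curve = fsc(a, b)
        res = resolution_from_fsc(curve)
        below = np.nonzero(curve.correlation < curve.threshold)[0]
        first = below[0]
        assert curve.freq[first - 1] <= 1.0 / res <= curve.freq[first]
        assert res == pytest.approx(1.0 / cutoff, rel=0.15)

    def test_never_below_two_voxels(self, rng):
        for _ in range(5):
            a = rng.normal(size=(12, 12, 12))
            b = rng.normal(size=(12, 12, 12))
            assert fsc(a, b).resolution_voxels >= 2.0


class TestImageMetrics:
    def test_identical_volumes(self):
        t = ball(16)[None]
        m = image_metrics(t, t)
        assert m["nrmse"][0] == 0.0
        assert m["ssim"][0] == pytest.approx(1.0)
        assert m["psnr"][0] == PSNR_CAP_DB

    def test_constant_offset_nrmse_equals_offset_on_unit_range(self):
        t = ball(16)[None]  # range exactly 1
        m = image_metrics(t + 0.125, t)
        assert m["nrmse"][0] == pytest.approx(0.125)

    def test_matches_scalar_loop_oracle(self, rng):
        t = rng.uniform(size=(1, 8, 8, 8))
        r = t + rng.normal(0, 0.05, size=t.shape)
        m = image_metrics(r, t)
        # loop oracles for RMSE-based metrics
        se = 0.0
        for i in range(8):
            for j in range(8):
                for k in range(8):
                    se += (r[0, i, j, k] - t[0, i, j, k]) ** 2
        rmse = np.sqrt(se / 512)
        rng_t = t.max() - t.min()
        assert m["nrmse"][0] == pytest.approx(rmse / rng_t, rel=1e-9)
        assert m["psnr"][0] == pytest.approx(
            10 * np.log10(rng_t**2 / (se / 512)), rel=1e-9
        )

    def test_per_time_curves_have_length_t(self):
        t = np.stack([ball(12), ball(12, radius=0.3)])
        m = image_metrics(t, t)
        assert len(m["psnr"]) == 2 and len(m["ssim"]) == 2

    def test_constant_truth_rejected(self):
        with pytest.raises(EvaluationError, match="constant"):
            image_metrics(np.ones((1, 4, 4, 4)), np.ones((1, 4, 4, 4)))


class TestFBP:
    def test_ball_recovery_from_full_half_turn(self):
        n = 64
        vol = ball(n, radius=0.5)
        geom = Geometry.for_cube(n)
        angles = np.linspace(0, 180, 180, endpoint=False)
        rec = fbp_reconstruct(project_stack(vol, angles, geom))
        nrmse = np.sqrt(np.mean((rec - vol) ** 2)) / (vol.max() - vol.min())
        assert nrmse < 0.05

    def test_zero_projections_give_zero_volume(self):
        ps = ProjectionSet(
            frames=np.zeros((0, 8, 8)), theta_deg=np.zeros(0),
            time_index=np.zeros(0, dtype=int), t_norm=np.zeros(0),
            pixel_size=0.25,
        )
        np.testing.assert_array_equal(fbp_reconstruct(ps, output_size=8), 0.0)

    def test_linearity(self):
        n = 16
        vol = ball(n, (0.2, 0, 0), 0.3)
        geom = Geometry.for_cube(n)
        ps = project_stack(vol, np.linspace(0, 180, 24, endpoint=False), geom)
        rec1 = fbp_reconstruct(ps)
        ps2 = ps.select(slice(None))
        ps2.frames = 2.0 * ps.frames
        rec2 = fbp_reconstruct(ps2)
        np.testing.assert_allclose(rec2, 2.0 * rec1, rtol=1e-9, atol=1e-12)

    def test_error_decreases_with_angle_count(self):
        n = 32
        vol = ball(n, radius=0.45)
        geom = Geometry.for_cube(n)
        errs = []
        for n_ang in (16, 32, 64, 180):
            angles = np.linspace(0, 180, n_ang, endpoint=False)
            rec = fbp_reconstruct(project_stack(vol, angles, geom))
            errs.append(np.sqrt(np.mean((rec - vol) ** 2)))
        assert all(b <= a + 1e-12 for a, b in zip(errs[:-1], errs[1:]))

    def test_limited_angle_span_warns_not_raises(self):
        n = 16
        vol = ball(n)
        geom = Geometry.for_cube(n)
        ps = project_stack(vol, np.linspace(0, 18, 4), geom)
        with pytest.warns(UserWarning, match="limited-angle"):
            fbp_reconstruct(ps)


class TestMoltenVolume:
    def test_threshold_below_minimum_counts_whole_grid(self):
        vol = np.ones((4, 4, 4))
        assert molten_volume(vol, threshold=0.5, voxel_size=2.0) == 64 * 8.0

    def test_half_filled_toy_grid(self):
        vol = np.zeros((4, 4, 4))
        vol[:2] = 1.0
        assert molten_volume(vol, 0.5, 1.0) == 32.0

    def test_ellipsoidal_pool_matches_analytic_volume(self):
        ph = make_phantom(PhantomSpec(kind="melt_pool", grid_n=48, n_timepoints=1))
        spec = ph.meta["spec"]
        ax, ay, az = spec["pool_axes"]
        analytic = 4.0 / 3.0 * np.pi * ax * ay * az
        measured = molten_volume(ph.delta[0], 1.2, ph.voxel_size)
        # one-voxel-shell tolerance on the ellipsoid surface
        shell = 4.0 * np.pi * (ax * ay * az) ** (2 / 3) * ph.voxel_size
        assert abs(measured - analytic) < shell
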