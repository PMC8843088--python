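"""Echo-PIV engine: correlation, subpixel, outliers, ensembles, POD."""

import numpy as np
import pytest
from scipy.ndimage import shift as nd_shift

from pulseuiv.config import UIVConfig
from pulseuiv.piv import (
    VectorField,
    correlate_window,
    ensemble_average,
    gaussian_subpixel,
    iterative_piv,
    pod_regularize,
    universal_outlier_filter,
)


class TestGaussianSubpixel:
    def test_symmetric_neighbours(self):
        assert gaussian_subpixel(0.5, 1.0, 0.5) == 0.0

    def test_exact_for_gaussian(self):
        c = np.exp(-((np.array([-1, 0, 1]) - 0.3) ** 2) / 0.8)
        assert gaussian_subpixel(*c) == pytest.approx(0.3, abs=1e-12)

    def test_parabolic_fallback_on_nonpositive(self):
        cm, c0, cp = -0.1, 1.0, 0.4
        expected = (cm - cp) / (2 * (cm - 2 * c0 + cp))
        assert gaussian_subpixel(cm, c0, cp) == pytest.approx(expected)

    def test_clamped_to_unit_interval(self):
        assert abs(gaussian_subpixel(1e-9, 1e-9, 1.0)) < 1.0


class TestCorrelateWindow:
    def test_self_correlation_is_zero(self, speckle_image):
        win = speckle_image[:32, :32]
        assert correlate_window(win, win) == pytest.approx((0.0, 0.0))

    def test_integer_shift_exact(self, speckle_image):
        win = speckle_image[:32, :32]
        shifted = np.roll(win, (3, 2), axis=(0, 1))
        dz, dx = correlate_window(win, shifted)
        assert (dz, dx) == pytest.approx((3.0, 2.0), abs=1e-12)

    def test_quarter_pixel_shift(self, speckle_image):
        """A band-limited 0.25-px resample is recovered within 0.05 px."""
        win = speckle_image[8:72, 8:72]
        shifted = nd_shift(speckle_image, (0, 0.25), order=3)[8:72, 8:72]
        dz, dx = correlate_window(win, shifted)
        assert dx == pytest.approx(0.25, abs=0.05)
        assert dz == pytest.approx(0.0, abs=0.05)

    def test_zero_variance_flagged(self):
        flat = np.ones((16, 16))
        dz, dx = correlate_window(flat, flat)
        assert np.isnan(dz) and np.isnan(dx)

    def test_odd_window_rejected(self):
        with pytest.raises(ValueError):
            correlate_window(np.zeros((15, 15)), np.zeros((15, 15)))


def _periodic_speckle(shape=(120, 128), period=8, seed=7):
    """Speckle tiled with the window-compatible period: under a circular
    shift every interrogation window sees an exact cyclic permutation, so
    integer displacements must be recovered with zero error."""
    tile = np.random.default_rng(seed).normal(size=(period, period))
    return np.tile(tile, (shape[0] // period, shape[1] // period))


def _interior(field, shape, margin):
    mz = (field.node_z > margin) & (field.node_z < shape[0] - margin)
    mx = (field.node_x > margin) & (field.node_x < shape[1] - margin)
    return field.valid & mz[:, None] & mx[None, :]


class TestIterativePIV:
    def test_rigid_integer_shift_exact_at_all_passes(self):
        img = _periodic_speckle()
        shifted = np.roll(img, (2, 3), axis=(0, 1))
        for n_it in (1, 2, 3):
            cfg = UIVConfig(n_iterations=n_it)
            f = iterative_piv(img, shifted, cfg)
            sel = _interior(f, img.shape, cfg.window_size)
            assert sel.sum() >= 9
            assert np.allclose(f.u[sel], 3.0, atol=1e-12)
            assert np.allclose(f.v[sel], 2.0, atol=1e-12)

    def test_identical_frames_zero_field(self, speckle_image):
        f = iterative_piv(speckle_image, speckle_image, UIVConfig())
        assert np.allclose(f.u[f.valid], 0.0) and np.allclose(f.v[f.valid], 0.0)

    def test_frame_swap_negates(self, speckle_image):
        shifted = nd_shift(speckle_image, (0.0, 1.3), order=3)
        fwd = iterative_piv(speckle_image, shifted, UIVConfig())
        bwd = iterative_piv(shifted, speckle_image, UIVConfig())
        # interior nodes only: spline edge effects corrupt the border
        sel = fwd.valid & bwd.valid & _interior(fwd, speckle_image.shape, 16)
        assert np.allclose(fwd.u[sel], -bwd.u[sel], atol=0.05)

    def test_velocity_units(self):
        img = _periodic_speckle()
        shifted = np.roll(img, (0, 2), axis=(0, 1))
        f = iterative_piv(img, shifted, UIVConfig(), frame_rate=1500.0, dx=75e-6, dz=52e-6)
        sel = _interior(f, img.shape, 32)
        assert np.allclose(f.u[sel], 2 * 75e-6 * 1500.0, atol=1e-9)

    def test_small_image_rejected(self):
        with pytest.raises(ValueError, match="window"):
            iterative_piv(np.zeros((16, 16)), np.zeros((16, 16)), UIVConfig())

    def test_deterministic(self, speckle_image):
        shifted = nd_shift(speckle_image, (0.4, 1.1), order=3)
        f1 = iterative_piv(speckle_image, shifted, UIVConfig())
        f2 = iterative_piv(speckle_image, shifted, UIVConfig())
        assert np.array_equal(f1.u, f2.u) and np.array_equal(f1.v, f2.v)


def _uniform_field(nz=9, nx=11, u=1.0, v=0.5):
    return VectorField(
        u=np.full((nz, nx), u),
        v=np.full((nz, nx), v),
        valid=np.ones((nz, nx), bool),
        node_z=np.arange(nz, dtype=float),
        node_x=np.arange(nx, dtype=float),
    )


class TestUniversalOutlierFilter:
    def test_uniform_field_unchanged(self):
        f = _uniform_field()
        out = universal_outlier_filter(f)
        assert np.array_equal(out.u, f.u)
        assert not out.replaced.any()

    def test_spike_replaced_by_median(self):
        f = _uniform_field(u=1.0)
        f.u[4, 5] = 10.0
        out = universal_outlier_filter(f, threshold=1.5, eps=0.1)
        assert out.replaced[4, 5]
        assert out.u[4, 5] == pytest.approx(1.0)

    def test_matches_brute_force(self, rng):
        """The vectorised normalised-median test equals a literal per-node
        recomputation on a random field."""
        nz, nx = 8, 9
        f = VectorField(
            u=rng.normal(size=(nz, nx)),
            v=rng.normal(size=(nz, nx)),
            valid=np.ones((nz, nx), bool),
            node_z=np.arange(nz, dtype=float),
            node_x=np.arange(nx, dtype=float),
        )
        out = universal_outlier_filter(f, threshold=1.5, eps=0.1)
        expected = np.zeros((nz, nx), bool)
        for i in range(nz):
            for j in range(nx):
                exceeded = False
                for comp in (f.u, f.v):
                    neigh = [
                        comp[a, b]
                        for a in range(max(0, i - 1), min(nz, i + 2))
                        for b in range(max(0, j - 1), min(nx, j + 2))
                        if (a, b) != (i, j)
                    ]
                    med = np.median(neigh)
                    res_med = np.median(np.abs(np.array(neigh) - med))
                    if abs(comp[i, j] - med) / (res_med + 0.1) > 1.5:
                        exceeded = True
                expected[i, j] = exceeded
        assert np.array_equal(out.replaced, expected)


class TestEnsembleAverage:
    def test_identical_fields(self):
        fields = [_uniform_field() for _ in range(11)]
        out = ensemble_average(fields)
        assert np.allclose(out.u, 1.0) and np.allclose(out.v, 0.5)
        assert out.valid.all()

    def test_alternating_fields_cancel(self):
        fields = []
        for k in range(10):
            f = _uniform_field(u=(-1.0) ** k)
            fields.append(f)
        out = ensemble_average(fields)
        assert np.allclose(out.u, 0.0, atol=1e-12)

    def test_noise_variance_reduced(self, rng):
        base = _uniform_field(nz=10, nx=20)
        fields = []
        for _ in range(11):
            f = _uniform_field(nz=10, nx=20)
            f.u = f.u + rng.normal(0, 1.0, f.u.shape)
            fields.append(f)
        out = ensemble_average(fields)
        assert np.var(out.u - base.u) == pytest.approx(1 / 11, rel=0.35)

    def test_validity_majority_rule(self):
        fields = [_uniform_field(nz=3, nx=3) for _ in range(5)]
        for f in fields[:3]:
            f.valid[1, 1] = False
        out = ensemble_average(fields)
        assert not out.valid[1, 1]
        assert out.valid[0, 0]


class TestPODRegularize:
    def _sequence(self, n_t=20, rank=3, noise=0.0, seed=0):
        rng = np.random.default_rng(seed)
        nz, nx = 6, 8
        spatial = rng.normal(size=(rank, nz, nx))
        temporal = rng.normal(size=(rank, n_t))
        fields = []
        for t in range(n_t):
            u = np.tensordot(temporal[:, t], spatial, axes=1)
            v = 0.5 * u
            if noise:
                u = u + rng.normal(0, noise, u.shape)
                v = v + rng.normal(0, noise, v.shape)
            fields.append(
                VectorField(
                    u=u,
                    v=v,
                    valid=np.ones((nz, nx), bool),
                    node_z=np.arange(nz, dtype=float),
                    node_x=np.arange(nx, dtype=float),
                    t=float(t),
                )
            )
        return fields

    def test_low_rank_sequence_unchanged(self):
        fields = self._sequence(rank=3)
        out = pod_regularize(fields, n_modes=10)
        for a, b in zip(out, fields):
            assert np.allclose(a.u, b.u, atol=1e-10)

    def test_full_rank_retention_is_identity(self):
        fields = self._sequence(rank=5, noise=0.3)
        out = pod_regularize(fields, n_modes=20)
        for a, b in zip(out, fields):
            assert np.allclose(a.u, b.u, atol=1e-10)

    def test_short_sequence_warns_and_passes_through(self):
        fields = self._sequence(n_t=5)
        with pytest.warns(UserWarning, match="shorter"):
            out = pod_regularize(fields, n_modes=10)
        assert all(a is b for a, b in zip(out, fields))

    def test_denoises_smooth_sequence(self):
        clean = self._sequence(rank=3, n_t=40, seed=1)
        noisy = self._sequence(rank=3, n_t=40, noise=0.4, seed=1)
        out = pod_regularize(noisy, n_modes=3)
        err_before = sum(np.sum((a.u - b.u) ** 2) for a, b in zip(noisy, clean))
        err_after = sum(np.sum((a.u - b.u) ** 2) for a, b in zip(out, clean))
        assert err_after < err_before
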