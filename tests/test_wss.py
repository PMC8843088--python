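"""Wall shear rate estimation from wall-normal velocity profiles."""

import numpy as np
import pytest

from pulseuiv.config import WSSConfig
from pulseuiv.piv import VectorField
from pulseuiv.wss import (
    WallNormalProfile,
    assemble_waveforms,
    estimate_wsr,
    extract_profile,
    median_filter_wsr,
    wss_from_wsr,
)


def _profile(y, u):
    return WallNormalProfile(y=np.asarray(y, float), u=np.asarray(u, float))


def _field_from_u(u_of_zx, nz=24, nx=8, dz_px=4.0):
    node_z = np.arange(nz) * dz_px
    node_x = np.arange(nx) * dz_px
    zz, xx = np.meshgrid(node_z, node_x, indexing="ij")
    u = u_of_zx(zz, xx)
    return VectorField(
        u=u,
        v=np.zeros_like(u),
        valid=np.ones_like(u, bool),
        node_z=node_z,
        node_x=node_x,
    )


class TestExtractProfile:
    def test_uniform_field(self):
        f = _field_from_u(lambda z, x: np.full_like(z, 0.7, dtype=float))
        cfg = WSSConfig(n_samples=10, profile_depth=40e-6 * 12)
        p = extract_profile(f, wall_z_px=2.0, column_x_px=12.0, inward=+1, config=cfg, dz=40e-6)
        assert p.y[0] == 0 and p.u[0] == 0
        # samples beyond the first vector node carry the field value; the
        # pinned wall zero shapes the segment closer in than any node
        first_node = 2 * 40e-6
        assert np.allclose(p.u[1:][p.y[1:] >= first_node], 0.7)

    def test_sample_count_contract(self):
        f = _field_from_u(lambda z, x: z.astype(float))
        cfg = WSSConfig(n_samples=2, profile_depth=1e-4)
        p = extract_profile(f, 0.0, 8.0, +1, cfg, dz=40e-6)
        assert p.y.size == 3  # wall pin + 2 samples

    def test_linear_field_reproduced(self):
        """A field linear in depth interpolates exactly along the normal."""
        dz = 50e-6
        f = _field_from_u(lambda z, x: 100.0 * z * dz)
        cfg = WSSConfig(n_samples=10, profile_depth=3e-3)
        p = extract_profile(f, 0.0, 8.0, +1, cfg, dz=dz)
        # beyond the first node the interpolation is exact; below it the pin
        # forces a (correct, for linear u through 0) straight segment
        assert np.allclose(p.u[1:], 100.0 * p.y[1:], rtol=1e-10)

    def test_womersley_profile_matches_analytic(self, aorta_model, geometry):
        """Sampling the analytic field on a PIV-like grid reproduces the
        radial profile to interpolation tolerance."""
        dz = 52e-6
        zc_px = 50.0
        t = 0.02
        R = geometry.radius

        node_z = np.arange(8, 95, 2.0)
        node_x = np.arange(0, 40, 4.0)
        zz, xx = np.meshgrid(node_z, node_x, indexing="ij")
        r = np.clip(np.abs(zz - zc_px) * dz, 0, R)
        u = aorta_model.velocity_profile(r.ravel(), t).reshape(r.shape)
        f = VectorField(
            u=u, v=np.zeros_like(u), valid=np.ones_like(u, bool), node_z=node_z, node_x=node_x
        )
        wall_px = zc_px - R / dz
        cfg = WSSConfig(n_samples=20, profile_depth=1e-3)
        p = extract_profile(f, wall_px, 16.0, +1, cfg, dz=dz)
        truth = aorta_model.velocity_profile(np.clip(R - p.y, 0, R), t)
        beyond_first_node = p.y > 2 * dz * 1.5
        assert np.allclose(
            p.u[beyond_first_node],
            truth[beyond_first_node],
            atol=0.02 * np.abs(truth).max(),
        )


class TestEstimateWSR:
    def test_linear_profile_any_slope(self):
        y = np.linspace(0, 1e-3, 21)
        for m in (-500.0, 0.0, 1234.5):
            p = _profile(y, m * y)
            assert estimate_wsr(p) == pytest.approx(m, rel=1e-9, abs=1e-9)

    def test_cubic_profile_preserved_by_sg(self):
        """An order-3 Savitzky-Golay filter reproduces cubics exactly, so the
        gradient equals the two-point secant of the raw cubic."""
        y = np.linspace(0, 1e-3, 21)
        u = 2000 * y - 3e6 * y**2 + 1e9 * y**3
        p = _profile(y, u)
        secant = (u[2] - u[1]) / (y[2] - y[1])
        assert estimate_wsr(p) == pytest.approx(secant, rel=1e-6)

    def test_poiseuille_within_five_percent(self, steady_model, geometry):
        R = geometry.radius
        V = 0.3
        y = np.linspace(0, R / 4, 21)
        u = steady_model.velocity_profile(R - y, 0.0)
        p = _profile(y, u)
        assert estimate_wsr(p) == pytest.approx(4 * V / R, rel=0.05)

    def test_too_few_samples_uses_raw_gradient(self):
        y = np.array([0.0, 1e-4, 2e-4])
        p = _profile(y, [0.0, 0.01, 0.02])
        assert estimate_wsr(p) == pytest.approx(100.0)


class TestWSSFromWSR:
    def test_scaling_and_sign(self):
        assert wss_from_wsr(1000.0, 0.004) == pytest.approx(4.0)
        assert wss_from_wsr(0.0, 0.004) == 0.0
        assert wss_from_wsr(-250.0, 0.004) == pytest.approx(-1.0)

    def test_invalid_viscosity(self):
        with pytest.raises(ValueError):
            wss_from_wsr(1.0, 0.0)


class TestMedianFilter:
    def test_spike_removed_edges_passed(self):
        s = np.array([1.0, 1.0, 9.0, 1.0, 1.0])
        out = median_filter_wsr(s)
        assert out[2] == 1.0
        assert out[0] == 1.0 and out[-1] == 1.0

    def test_matches_brute_force(self, rng):
        s = rng.normal(size=50)
        out = median_filter_wsr(s)
        for i in range(1, 49):
            assert out[i] == np.median(s[i - 1 : i + 2])
        assert out[0] == s[0] and out[-1] == s[-1]


class TestAssembleWaveforms:
    def _cycles(self, n_cycles=4, n=100, lags=None):
        phase = np.linspace(0, 2 * np.pi, n, endpoint=False)
        # sharp negative peak (as in an arterial waveform's retrograde dip)
        # so the minimum is a well-defined alignment anchor
        cycle = np.sin(phase) + 0.2 - 1.5 * np.exp(-((phase - 4.5) ** 2) / 0.05)
        series = []
        for k in range(n_cycles):
            lag = 0 if lags is None else lags[k]
            series.append(np.roll(cycle, lag))
        return np.concatenate(series), cycle

    def test_identical_cycles_zero_se(self):
        series, cycle = self._cycles(4)
        mean, se = assemble_waveforms(series)
        assert np.allclose(se, 0.0, atol=1e-12)
        assert np.min(mean) == pytest.approx(np.min(cycle), abs=1e-6)

    def test_alignment_recovers_known_dip_offsets(self):
        """Cycles whose negative peak sits at different phases are shifted
        back by exactly those offsets."""
        n = 100
        phase = np.linspace(0, 2 * np.pi, n, endpoint=False)
        offsets = [0, 3, -2, 5, 1]
        series = np.concatenate(
            [
                np.sin(phase) + 0.2
                - 1.5 * np.exp(-((phase - 4.5 - o * 2 * np.pi / n) ** 2) / 0.05)
                for o in offsets
            ]
        )
        out = assemble_waveforms(series)
        # segmentation keeps the four complete cycles (dips of offsets[1:]);
        # every cycle is shifted back to the first kept cycle's dip position
        assert out.n_cycles == 4
        expected = offsets[1] - np.array(offsets[1:])
        assert np.array_equal(out.shifts, expected)

    def test_minimum_at_alignment_phase(self):
        series, _ = self._cycles(4, lags=[0, 2, 4, 6])
        mean, se = assemble_waveforms(series)
        aligned_min = np.argmin(mean)
        # the first cycle's minimum position is the anchor
        first = np.argmin(self._cycles(1)[1])
        assert abs(int(aligned_min) - int(first)) <= 1

    def test_fewer_than_three_cycles_warns(self):
        t = np.linspace(0, 2 * np.pi, 50)
        series = np.sin(t) + 0.2
        with pytest.warns(UserWarning, match="cycles"):
            mean, se = assemble_waveforms(series)
        assert np.array_equal(mean, series)


class TestBatchedSequencePath:
    def test_batched_frame_equals_pointwise(self, rng):
        """The vectorised per-frame shear-rate path used by
        compute_wss_sequence reproduces extract_profile + estimate_wsr."""
        from pulseuiv.wss import _wall_wsr_frame

        nz, nx = 25, 12
        f = VectorField(
            u=rng.normal(size=(nz, nx)),
            v=np.zeros((nz, nx)),
            valid=rng.random((nz, nx)) > 0.15,
            node_z=3.5 + 4 * np.arange(nz, dtype=float),
            node_x=3.5 + 4 * np.arange(nx, dtype=float),
        )
        cfg = WSSConfig()
        for inward, wall in ((+1, 10.0 + 3 * rng.random(nx)), (-1, 90.0 - 3 * rng.random(nx))):
            batched = _wall_wsr_frame(f, wall, inward, cfg, dz=52e-6)
            point = np.array(
                [
                    estimate_wsr(
                        extract_profile(f, wall[j], f.node_x[j], inward, cfg, dz=52e-6),
                        cfg.sg_order,
                        cfg.sg_rel_length,
                    )
                    for j in range(nx)
                ]
            )
            assert np.allclose(batched, point, atol=1e-9)
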