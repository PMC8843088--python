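"""Analytic pulsatile (Womersley) flow in a rigid cylindrical tube.

The cross-sectional mean velocity waveform V(t) is represented as a truncated
complex Fourier series

    V(t) = Re{ sum_j  Vhat_j exp(i j w t) },   w = 2 pi / T,

and the corresponding axial velocity profile u(r, t) follows from the inverse
Womersley solution: the j = 0 term is the steady Poiseuille profile
2 Vhat_0 (1 - r^2/R^2); each harmonic j >= 1 contributes a Bessel-function
radial shape governed by its Womersley number alpha_j = R sqrt(j w / nu),
normalised so that its cross-sectional mean is exactly Vhat_j exp(i j w t).

This module is the ground-truth oracle of the pipeline: both the scatterer
advection of the digital phantom and the accuracy metrics of the evaluation
stage are referenced to `velocity_profile` and `wall_shear_rate`.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np
from scipy.special import jv

from .config import VesselGeometry

__all__ = [
    "FlowWaveform",
    "WomersleyModel",
    "preprocess_waveform",
    "fourier_decompose",
    "womersley_number",
]


def _check_uniform(times: np.ndarray) -> float:
    times = np.asarray(times, dtype=float)
    if times.ndim != 1 or times.size < 2:
        raise ValueError("need a 1-D time axis with at least two samples")
    dt = np.diff(times)
    if not np.allclose(dt, dt[0], rtol=1e-6, atol=1e-12):
        worst = int(np.argmax(np.abs(dt - dt[0])))
        raise ValueError(
            f"non-uniform time spacing: step {worst} is {dt[worst]:.3e} s "
            f"but step 0 is {dt[0]:.3e} s"
        )
    return float(dt[0])


def preprocess_waveform(times, velocities, offset: float = 0.1, scale: float = 0.7):
    """Scale a measured mean-velocity waveform, then subtract a uniform offset.

    The scale converts the parabolic-mean of the measured waveform to a
    paraboloid mean; the offset introduces retrograde flow. Applied as
    ``scale * V(t) - offset``.
    """
    _check_uniform(times)
    v = np.asarray(velocities, dtype=float)
    return scale * v - offset


def fourier_decompose(times, velocities, n: int) -> "FlowWaveform":
    """Complex Fourier coefficients of one period of a uniformly sampled waveform.

    Coefficients satisfy V(t) = Re{ sum_{j=0}^{n} Vhat_j exp(i j w t) } with
    Vhat_0 equal to the time average. Requires at least 2n + 1 samples.
    """
    dt = _check_uniform(times)
    v = np.asarray(velocities, dtype=float)
    m = v.size
    if m < 2 * n + 1:
        raise ValueError(f"{m} samples cannot resolve {n} harmonics (need >= {2 * n + 1})")
    period = m * dt
    t = np.asarray(times, dtype=float) - times[0]
    coeffs = np.empty(n + 1, dtype=complex)
    coeffs[0] = v.mean()
    w = 2.0 * math.pi / period
    for j in range(1, n + 1):
        coeffs[j] = 2.0 * np.mean(v * np.exp(-1j * j * w * t))
    # undo the start-time shift so coefficients refer to absolute time
    coeffs[1:] *= np.exp(-1j * w * np.arange(1, n + 1) * times[0])
    return FlowWaveform(period=period, coeffs=coeffs)


@dataclass(frozen=True)
class FlowWaveform:
    """Periodic cross-sectional mean velocity as a complex Fourier series."""

    period: float
    coeffs: np.ndarray  # complex, j = 0..n

    def __post_init__(self):
        object.__setattr__(self, "coeffs", np.atleast_1d(np.asarray(self.coeffs, dtype=complex)))
        if self.period <= 0:
            raise ValueError("period must be positive")
        if abs(self.coeffs[0].imag) > 1e-12 * max(1.0, abs(self.coeffs[0])):
            raise ValueError("the steady coefficient must be real")

    @property
    def n_harmonics(self) -> int:
        return self.coeffs.size - 1

    @property
    def f1(self) -> float:
        return 1.0 / self.period

    @property
    def omega(self) -> float:
        return 2.0 * math.pi / self.period

    def __call__(self, t):
        """Mean velocity V(t) (m/s)."""
        t = np.asarray(t, dtype=float)
        j = np.arange(self.coeffs.size)
        phases = np.exp(1j * self.omega * np.multiply.outer(t, j))
        return np.real(phases @ self.coeffs)

    @classmethod
    def from_magnitudes(cls, period: float, magnitudes, phases=None) -> "FlowWaveform":
        mags = np.asarray(magnitudes, dtype=float)
        if phases is None:
            coeffs = mags.astype(complex)
        else:
            coeffs = mags * np.exp(1j * np.asarray(phases, dtype=float))
            coeffs[0] = mags[0]
        return cls(period=period, coeffs=coeffs)


def womersley_number(geometry: VesselGeometry, j: int, f1: float) -> float:
    """Womersley number alpha_j = R sqrt(2 pi j f1 / nu) of the j-th harmonic."""
    if j < 1:
        raise ValueError("the steady component has no Womersley number (j >= 1)")
    return geometry.radius * math.sqrt(2.0 * math.pi * j * f1 / geometry.nu)


class WomersleyModel:
    """Inverse-Womersley velocity field for a waveform in a rigid tube.

    Parameters
    ----------
    waveform : FlowWaveform
        Mean-velocity Fourier series.
    geometry : VesselGeometry
        Vessel radius and fluid properties.
    """

    def __init__(self, waveform: FlowWaveform, geometry: VesselGeometry):
        self.waveform = waveform
        self.geometry = geometry
        n = waveform.n_harmonics
        self._j = np.arange(n + 1)
        # i^(3/2) alpha_j for j >= 1
        alphas = np.array([womersley_number(geometry, j, waveform.f1) for j in range(1, n + 1)])
        self._alphas = alphas
        k = (1j) ** 1.5 * alphas
        self._k = k
        j0k = jv(0, k)
        j1k = jv(1, k)
        self._j0k = j0k
        # normalisation so the cross-sectional mean of each harmonic shape is 1
        self._denom = 1.0 - 2.0 * j1k / (k * j0k)
        # wall shear factor g_j such that WSR(t) = Re{sum Vhat_j g_j e^{ijwt}},
        # with the convention WSR = -du/dr at r = R (positive for forward flow)
        g = np.empty(n + 1, dtype=complex)
        g[0] = 4.0 / geometry.radius
        g[1:] = -(k / geometry.radius) * j1k / (j0k * self._denom)
        self._wall_gain = g

    def alpha(self, j: int) -> float:
        if j < 1 or j > self.waveform.n_harmonics:
            raise ValueError("harmonic index out of range")
        return float(self._alphas[j - 1])

    def radial_basis(self, r) -> np.ndarray:
        """Complex harmonic shape matrix Phi[j, i] at radial positions r.

        u(r_i, t) = Re{ sum_j Vhat_j Phi[j, i] exp(i j w t) }.
        """
        r = np.atleast_1d(np.asarray(r, dtype=float))
        R = self.geometry.radius
        if np.any(r < 0) or np.any(r > R * (1 + 1e-12)):
            raise ValueError("radial position outside the lumen (0 <= r <= R)")
        n = self.waveform.n_harmonics
        basis = np.empty((n + 1, r.size), dtype=complex)
        basis[0] = 2.0 * (1.0 - (r / R) ** 2)
        if n:
            kr = np.multiply.outer(self._k, r / R)
            basis[1:] = (1.0 - jv(0, kr) / self._j0k[:, None]) / self._denom[:, None]
        return basis

    def _phases(self, t) -> np.ndarray:
        t = np.atleast_1d(np.asarray(t, dtype=float))
        return np.exp(1j * self.waveform.omega * np.multiply.outer(t, self._j))

    def velocity_profile(self, r, t):
        """Axial velocity u(r, t) (m/s).

        Returns shape (Nt, Nr) for array inputs; scalar axes are squeezed.
        """
        basis = self.radial_basis(r)  # (n+1, Nr)
        coeffs = self.waveform.coeffs[:, None] * basis
        out = np.real(self._phases(t) @ coeffs)  # (Nt, Nr)
        if np.ndim(t) == 0:
            out = out[0]
        if np.ndim(r) == 0:
            out = out[..., 0]
        return out

    def mean_velocity(self, t):
        """Cross-sectional mean velocity (m/s)."""
        return self.waveform(t)

    def wall_shear_rate(self, t):
        """Exact wall shear rate -du/dr at r = R (1/s).

        Positive when the centreline velocity is positive.
        """
        out = np.real(self._phases(t) @ (self.waveform.coeffs * self._wall_gain))
        if np.ndim(t) == 0:
            return float(out[0])
        return out

    def wall_shear_stress(self, t):
        """Exact wall shear stress mu * WSR (Pa)."""
        return self.geometry.mu * self.wall_shear_rate(t)
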