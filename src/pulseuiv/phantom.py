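"""Digital phantom: wall and blood scatterer populations and their advection.

The phantom is a 2-D slab through the vessel axis, one elevational resolution
cell thick: blood scatterers fill the lumen (|z - z_c| < R), wall scatterers
form two static 200-um bands just outside it. Blood amplitudes are zero-mean
normal draws scaled by the flow amplitude factor and modulated by a radial
intensity profile (a static proxy for shear-dependent red-cell aggregation);
wall amplitudes are constant. Scatterers are advected by the analytic
Womersley field with axial-only motion, so each scatterer's radial position
is invariant; scatterers leaving the lateral domain wrap around with a fresh
amplitude draw to avoid periodic speckle.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, replace

import numpy as np
import pandas as pd

from .config import PhantomConfig, VesselGeometry
from .womersley import WomersleyModel

__all__ = ["ScattererField", "init_scatterers", "radial_weight", "advect"]

WALL, BLOOD = 0, 1


@dataclass(frozen=True)
class ScattererField:
    """Point scatterers: positions (m), base amplitudes and a wall/blood label."""

    x: np.ndarray
    z: np.ndarray
    amplitude: np.ndarray
    label: np.ndarray  # 0 = wall, 1 = blood
    domain: tuple  # lateral (x_min, x_max) used for wrap-around

    @property
    def n(self) -> int:
        return self.x.size

    @property
    def blood(self) -> np.ndarray:
        return self.label == BLOOD

    @property
    def wall(self) -> np.ndarray:
        return self.label == WALL

    def to_table(self) -> pd.DataFrame:
        return pd.DataFrame(
            {
                "x_m": self.x,
                "z_m": self.z,
                "amplitude": self.amplitude,
                "label": np.where(self.label == WALL, "wall", "blood"),
            }
        )

    @classmethod
    def from_table(cls, table: pd.DataFrame, domain) -> "ScattererField":
        return cls(
            x=table["x_m"].to_numpy(float),
            z=table["z_m"].to_numpy(float),
            amplitude=table["amplitude"].to_numpy(float),
            label=np.where(table["label"].to_numpy() == "wall", WALL, BLOOD).astype(np.uint8),
            domain=tuple(domain),
        )


def radial_weight(profile: str, r, R: float):
    """Radial intensity modulation in [0, 1].

    constant -> 1; linear -> 1 - r/R; r2 -> 1 - (r/R)^2; r4 -> 1 - (r/R)^4.
    """
    r = np.asarray(r, dtype=float)
    if np.any(r < 0) or np.any(r > R * (1 + 1e-12)):
        raise ValueError("radial position outside [0, R]")
    s = np.clip(r / R, 0.0, 1.0)
    if profile == "constant":
        return np.ones_like(s)
    if profile == "linear":
        return 1.0 - s
    if profile == "r2":
        return 1.0 - s**2
    if profile == "r4":
        return 1.0 - s**4
    raise ValueError(f"unknown radial profile {profile!r}")


def _blood_amplitudes(config: PhantomConfig, r, R: float, rng) -> np.ndarray:
    base = rng.normal(0.0, 1.0, size=np.size(r)) * config.flow_amplitude
    return base * radial_weight(config.radial_profile, r, R)


def init_scatterers(
    config: PhantomConfig, geometry: VesselGeometry, seed=None
) -> ScattererField:
    """Draw the initial scatterer populations at the configured densities.

    Counts are round(region area / cell area * density) per region; the wall
    count is split evenly between the two bands.
    """
    rng = np.random.default_rng(seed)
    L = geometry.lateral_extent
    R = geometry.radius
    zc = geometry.centre_depth
    w = geometry.wall_thickness
    domain = (0.0, L)

    n_blood = int(round(L * 2 * R / config.cell_area * config.flow_density))
    n_wall = int(round(2 * L * w / config.cell_area * config.wall_density))
    for name, count in (("blood", n_blood), ("wall", n_wall)):
        if count == 0:
            warnings.warn(f"{name} region received zero scatterers at the configured density")

    xb = rng.uniform(0.0, L, n_blood)
    zb = rng.uniform(zc - R, zc + R, n_blood)
    ab = _blood_amplitudes(config, np.abs(zb - zc), R, rng)

    n_top = n_wall // 2
    xw = rng.uniform(0.0, L, n_wall)
    zw = np.empty(n_wall)
    zw[:n_top] = rng.uniform(zc - R - w, zc - R, n_top)
    zw[n_top:] = rng.uniform(zc + R, zc + R + w, n_wall - n_top)
    aw = np.full(n_wall, config.wall_amplitude)

    return ScattererField(
        x=np.concatenate([xw, xb]),
        z=np.concatenate([zw, zb]),
        amplitude=np.concatenate([aw, ab]),
        label=np.concatenate(
            [np.zeros(n_wall, np.uint8), np.ones(n_blood, np.uint8)]
        ),
        domain=domain,
    )


def advect(
    field: ScattererField,
    model: WomersleyModel,
    t: float,
    dt: float,
    config: PhantomConfig | None = None,
    rng=None,
    basis: np.ndarray | None = None,
) -> ScattererField:
    """Advance blood scatterers by u(r, t) * dt; wall scatterers stay put.

    Scatterers exiting the lateral domain re-enter on the opposite side; when
    a phantom config and generator are supplied the wrapped scatterers get a
    fresh amplitude draw.

    ``basis`` may carry a precomputed ``model.radial_basis`` for the blood
    scatterers (their radial positions never change), which avoids repeated
    Bessel evaluation in frame loops.
    """
    zc = model.geometry.centre_depth
    blood = field.blood
    r = np.abs(field.z[blood] - zc)
    if basis is None:
        basis = model.radial_basis(r)
    phases = np.exp(1j * model.waveform.omega * t * np.arange(basis.shape[0]))
    u = np.real((model.waveform.coeffs * phases) @ basis)

    x = field.x.copy()
    x[blood] = x[blood] + u * dt
    x0, x1 = field.domain
    span = x1 - x0
    wrapped = (x < x0) | (x >= x1)
    amplitude = field.amplitude
    if np.any(wrapped):
        x[wrapped] = x0 + np.mod(x[wrapped] - x0, span)
        if config is not None and rng is not None:
            amplitude = amplitude.copy()
            idx = np.flatnonzero(wrapped & blood)
            if idx.size:
                amplitude[idx] = _blood_amplitudes(
                    config, np.abs(field.z[idx] - zc), model.geometry.radius, rng
                )
    return replace(field, x=x, amplitude=amplitude)
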