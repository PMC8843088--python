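"""Wall shear rate and stress from wall-normal velocity profiles.

For every wall point the tangential velocity is sampled along the inward
wall normal (with a zero-velocity sample pinned at the wall), smoothed with a
third-order Savitzky-Golay filter, and differentiated with a two-point
gradient over the two filtered samples closest to the wall. The shear rate is
median filtered along the wall, scaled by the dynamic viscosity to give the
wall shear stress, and assembled into cycle-aligned mean waveforms.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy.signal import savgol_filter

try:
    from numba import njit as _njit
except ImportError:  # pragma: no cover
    def _njit(*a, **k):
        def deco(f):
            return f
        return deco if not a else a[0]

from .config import WSSConfig
from .lumen import LumenContour
from .piv import VectorField

__all__ = [
    "WallNormalProfile",
    "WSSRecord",
    "extract_profile",
    "estimate_wsr",
    "wss_from_wsr",
    "median_filter_wsr",
    "assemble_waveforms",
    "compute_wss_sequence",
]


@dataclass
class WallNormalProfile:
    """Tangential velocity sampled along the inward wall normal.

    ``y`` runs from 0 at the wall (where a zero sample is pinned) strictly
    increasing into the lumen.
    """

    y: np.ndarray  # distances from the wall (m), y[0] = 0
    u: np.ndarray  # tangential velocity (m/s), u[0] = 0
    wall_x: float = 0.0
    t: float = 0.0
    truncated: bool = False

    def __post_init__(self):
        if self.y[0] != 0 or np.any(np.diff(self.y) <= 0):
            raise ValueError("profile distances must start at 0 and strictly increase")


def extract_profile(
    field: VectorField,
    wall_z_px: float,
    column_x_px: float,
    inward: int,
    config: WSSConfig = WSSConfig(),
    dz: float = 1.0,
    dx: float = 1.0,
) -> WallNormalProfile:
    """Velocity profile along the (axial) inward normal of a horizontal wall.

    The tangential projection for a horizontal wall is the lateral component
    ``u``. Samples are evenly spaced over the profile depth; velocities are
    linearly interpolated along the column from the valid vector nodes, with
    the pinned wall zero anchoring positions shallower than the first valid
    node. ``inward`` is +1 for the top wall and -1 for the bottom wall.
    Profiles reaching past the last valid node are truncated and flagged.
    """
    y = np.linspace(0.0, config.profile_depth, config.n_samples + 1)
    col = np.interp(column_x_px, field.node_x, np.arange(field.node_x.size))
    c0 = int(np.clip(np.floor(col), 0, field.node_x.size - 2))
    wl = 1.0 - (col - c0)
    if wl == 1.0:  # exactly on a node column
        u_col = field.u[:, c0]
        valid_col = field.valid[:, c0]
    else:
        u_col = wl * field.u[:, c0] + (1 - wl) * field.u[:, c0 + 1]
        valid_col = field.valid[:, c0] & field.valid[:, c0 + 1]

    node_y = inward * (field.node_z - wall_z_px) * dz  # distance from wall, m
    use = valid_col & (node_y > 0)
    truncated = False
    if not use.any():
        return WallNormalProfile(y=y, u=np.zeros_like(y), wall_x=column_x_px, truncated=True)
    knots_y = np.concatenate([[0.0], node_y[use]])
    knots_u = np.concatenate([[0.0], u_col[use]])
    order = np.argsort(knots_y)
    knots_y, knots_u = knots_y[order], knots_u[order]
    if y[-1] > knots_y[-1]:
        truncated = True
    u = np.interp(y, knots_y, knots_u)
    u[0] = 0.0
    return WallNormalProfile(y=y, u=u, wall_x=column_x_px, truncated=truncated)


def estimate_wsr(
    profile: WallNormalProfile, sg_order: int = 3, sg_rel_length: float = 0.4
) -> float:
    """Wall shear rate from the two filtered samples closest to the wall.

    The Savitzky-Golay window is ``round(sg_rel_length * n_samples)`` forced
    odd and larger than the polynomial order; when too few samples are
    available the raw two-point gradient is used. The pinned wall zero is
    excluded from the gradient so the no-slip condition is not hard-coded
    into the estimate.
    """
    samples = profile.u[1:]
    y = profile.y[1:]
    n = samples.size
    win = int(round(sg_rel_length * n))
    if win % 2 == 0:
        win += 1
    if win <= sg_order or win > n:
        filtered = samples
    else:
        filtered = savgol_filter(samples, win, sg_order)
    return float((filtered[1] - filtered[0]) / (y[1] - y[0]))


def wss_from_wsr(wsr, mu: float):
    """Wall shear stress tau = mu * WSR (Pa)."""
    if mu <= 0:
        raise ValueError("viscosity must be positive")
    return mu * np.asarray(wsr, float)


def median_filter_wsr(series) -> np.ndarray:
    """Three-point running median along the wall; edges passed through."""
    series = np.asarray(series, float)
    if series.size < 3:
        return series.copy()
    out = series.copy()
    stacked = np.stack([series[:-2], series[1:-1], series[2:]])
    out[1:-1] = np.median(stacked, axis=0)
    return out


@_njit(cache=True)
def _interp_profiles(u_cols, valid_cols, node_y, y):
    """Per-column linear interpolation with a pinned wall zero.

    ``node_y[k, j]`` is the wall-normal distance of node k in column j (can
    be negative outside the lumen); samples shallower than the first valid
    node interpolate between the pin and that node, deeper than the last
    valid node hold its value. Mirrors ``extract_profile`` exactly.
    """
    n_nodes, n_cols = u_cols.shape
    n_y = y.size
    out = np.zeros((n_y, n_cols))
    ky = np.empty(n_nodes + 1)
    ku = np.empty(n_nodes + 1)
    for j in range(n_cols):
        m = 1
        ky[0] = 0.0
        ku[0] = 0.0
        for k in range(n_nodes):
            if valid_cols[k, j] and node_y[k, j] > 0.0:
                ky[m] = node_y[k, j]
                ku[m] = u_cols[k, j]
                m += 1
        out[:, j] = np.interp(y, ky[:m], ku[:m])
        out[0, j] = 0.0
    return out


def _wall_wsr_frame(field, wall_px, inward, config, dz):
    """Shear rate for every column of one wall in one frame (batched)."""
    y = np.linspace(0.0, config.profile_depth, config.n_samples + 1)
    node_y = inward * (field.node_z[:, None] - wall_px[None, :]) * dz
    u_nodes, valid_nodes = field.u, field.valid
    if inward < 0:  # interpolation knots must ascend with distance from wall
        node_y = node_y[::-1]
        u_nodes = u_nodes[::-1]
        valid_nodes = valid_nodes[::-1]
    u = _interp_profiles(
        np.ascontiguousarray(u_nodes), np.ascontiguousarray(valid_nodes), node_y, y
    )
    samples = u[1:]
    n = samples.shape[0]
    win = int(round(config.sg_rel_length * n))
    if win % 2 == 0:
        win += 1
    if win <= config.sg_order or win > n:
        filtered = samples
    else:
        filtered = savgol_filter(samples, win, config.sg_order, axis=0)
    return (filtered[1] - filtered[0]) / (y[2] - y[1])


@dataclass
class WSSRecord:
    """Shear rate/stress per wall point and frame, plus per-frame means."""

    t: np.ndarray  # (T,)
    columns_x: np.ndarray  # lateral node positions (px)
    wsr_top: np.ndarray  # (T, n_cols), 1/s
    wsr_bottom: np.ndarray
    mu: float

    @property
    def wss_top(self) -> np.ndarray:
        return self.mu * self.wsr_top

    @property
    def wss_bottom(self) -> np.ndarray:
        return self.mu * self.wsr_bottom

    def frame_means(self) -> pd.DataFrame:
        top = np.nanmean(self.wss_top, axis=1)
        bottom = np.nanmean(self.wss_bottom, axis=1)
        return pd.DataFrame(
            {
                "t_s": self.t,
                "wss_top_pa": top,
                "wss_bottom_pa": bottom,
                "wss_overall_pa": 0.5 * (top + bottom),
            }
        )


def compute_wss_sequence(
    fields,
    contour: LumenContour,
    config: WSSConfig = WSSConfig(),
    mu: float = 4e-3,
    dz: float = 1.0,
    dx: float = 1.0,
    frame_indices=None,
) -> WSSRecord:
    """WSR/WSS time series for both walls from a velocity-field sequence.

    ``fields`` are the (ensemble-averaged, regularised) vector fields;
    ``frame_indices`` maps each field to its contour frame (defaults to
    enumerate order). Shear rates are median filtered along the wall.
    """
    fields = list(fields)
    if frame_indices is None:
        frame_indices = range(len(fields))
    cols = fields[0].node_x
    wsr_top = np.full((len(fields), cols.size), np.nan)
    wsr_bottom = np.full_like(wsr_top, np.nan)
    times = np.empty(len(fields))
    for i, (f, ci) in enumerate(zip(fields, frame_indices)):
        times[i] = f.t
        top = np.interp(cols, np.arange(contour.top.shape[1]), contour.top[ci])
        bottom = np.interp(cols, np.arange(contour.bottom.shape[1]), contour.bottom[ci])
        wsr_top[i] = median_filter_wsr(_wall_wsr_frame(f, top, +1, config, dz))
        wsr_bottom[i] = median_filter_wsr(_wall_wsr_frame(f, bottom, -1, config, dz))
    return WSSRecord(
        t=times, columns_x=cols, wsr_top=wsr_top, wsr_bottom=wsr_bottom, mu=mu
    )


def _segment_cycles(series: np.ndarray) -> list:
    """Cycle boundaries from upward zero crossings of the series."""
    sign = series >= 0
    ups = np.flatnonzero(~sign[:-1] & sign[1:]) + 1
    segments = []
    for a, b in zip(ups[:-1], ups[1:]):
        if b - a >= 4:
            segments.append((int(a), int(b)))
    return segments


@dataclass
class AlignedWaveform:
    """Cycle-aligned mean waveform with its standard error."""

    mean: np.ndarray
    se: np.ndarray
    shifts: np.ndarray  # circular shift (bins) applied to each cycle
    cycles: np.ndarray  # aligned cycles, one row each
    n_cycles: int

    def __iter__(self):  # allow `mean, se = assemble_waveforms(...)`
        return iter((self.mean, self.se))


def assemble_waveforms(series, n_bins: int | None = None) -> AlignedWaveform:
    """Cycle-aligned mean waveform with standard error.

    The series is segmented into cycles at upward zero crossings, each cycle
    resampled onto a common phase grid and circularly shifted so the negative
    (minimum) peaks coincide (anchored at the first cycle's minimum), then
    averaged per phase bin. With fewer than three detected cycles the input
    is returned as a single cycle with zero standard error and a warning.
    """
    series = np.asarray(series, float)
    segments = _segment_cycles(series)
    if len(segments) < 3:
        warnings.warn("fewer than three cycles detected; returning single-cycle output")
        return AlignedWaveform(
            mean=series.copy(),
            se=np.zeros_like(series),
            shifts=np.zeros(1, int),
            cycles=series[None].copy(),
            n_cycles=1,
        )
    if n_bins is None:
        n_bins = int(np.median([b - a for a, b in segments]))
    phase = np.linspace(0.0, 1.0, n_bins, endpoint=False)
    cycles = []
    for a, b in segments:
        src = np.linspace(0.0, 1.0, b - a, endpoint=False)
        cycles.append(np.interp(phase, src, series[a:b], period=1.0))
    cycles = np.array(cycles)
    anchor = int(np.argmin(cycles[0]))
    shifts = np.array([anchor - int(np.argmin(c)) for c in cycles])
    aligned = np.array([np.roll(c, s) for c, s in zip(cycles, shifts)])
    mean = aligned.mean(axis=0)
    se = aligned.std(axis=0, ddof=1) / np.sqrt(len(aligned))
    return AlignedWaveform(
        mean=mean, se=se, shifts=shifts, cycles=aligned, n_cycles=len(aligned)
    )
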