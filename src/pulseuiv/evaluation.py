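"""Quantitative evaluation: error metrics, agreement statistics and the
scatter-property sweeps of the synthetic Womersley experiment.

Velocity and shear-stress errors are normalised by the acquisition's peak
ground-truth magnitude, flow-angle errors are reported in degrees where the
true speed exceeds 5% of its peak, and medians pool nodes and frames (and
seeds, for the sweeps). The sweep drivers rerun the complete pipeline
(phantom -> imaging -> SVD filter -> PIV -> wall tracking -> WSS) for each
scatter-property level.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from . import clutter as _clutter
from . import lumen as _lumen
from . import piv as _piv
from . import wss as _wss
from .config import (
    AcquisitionConfig,
    PhantomConfig,
    UIVConfig,
    VesselGeometry,
    WSSConfig,
    WallTrackConfig,
    replace,
)
from .datasets import aorta_waveform
from .imaging import FrameStack, simulate_sequence
from .womersley import WomersleyModel

__all__ = [
    "ErrorSummary",
    "AgreementReport",
    "error_metrics",
    "bland_altman",
    "run_pipeline",
    "run_experiment",
    "sweep_scatter_amplitude",
    "sweep_scatter_density",
    "sweep_radial_profile",
    "default_model",
]

AMPLITUDE_LEVELS = (0.1, 0.5, 1.0, 10.0)
DENSITY_LEVELS = (0.1, 1.0, 10.0, 100.0)
RADIAL_LEVELS = ("constant", "linear", "r2", "r4")


@dataclass
class ErrorSummary:
    """Peak-normalised error samples pooled over nodes and frames."""

    velocity_pct: np.ndarray
    wss_pct: np.ndarray
    angle_deg: np.ndarray
    peak_velocity: float
    peak_wss: float

    def medians(self) -> dict:
        out = {}
        for name, arr in (
            ("velocity_pct", self.velocity_pct),
            ("wss_pct", self.wss_pct),
            ("angle_deg", self.angle_deg),
        ):
            arr = arr[np.isfinite(arr)]
            out[f"median_{name}"] = float(np.median(arr)) if arr.size else np.nan
            if arr.size:
                out[f"q1_{name}"] = float(np.percentile(arr, 25))
                out[f"q3_{name}"] = float(np.percentile(arr, 75))
        return out


def error_metrics(
    est_u,
    est_v,
    true_u,
    true_v,
    est_wss=None,
    true_wss=None,
    angle_floor: float = 0.05,
) -> ErrorSummary:
    """Peak-normalised velocity/WSS magnitude errors and angle errors.

    All arrays must be co-registered (same shape); invalid entries are NaN.
    Velocity error is | |v_est| - |v_true| | / max|v_true| x 100 per node;
    the angle error is the absolute angular difference of the vectors,
    evaluated only where the true speed exceeds ``angle_floor`` of its peak.
    """
    est_u, est_v = np.asarray(est_u, float), np.asarray(est_v, float)
    true_u, true_v = np.asarray(true_u, float), np.asarray(true_v, float)
    if est_u.shape != true_u.shape:
        raise ValueError("estimate and truth are not co-registered")
    true_speed = np.hypot(true_u, true_v)
    est_speed = np.hypot(est_u, est_v)
    peak = np.nanmax(true_speed)
    if peak == 0:
        raise ValueError("ground truth is identically zero; cannot normalise")
    vel_err = np.abs(est_speed - true_speed) / peak * 100.0

    dot = est_u * true_u + est_v * true_v
    cross = est_u * true_v - est_v * true_u
    angle = np.degrees(np.abs(np.arctan2(cross, dot)))
    angle = np.where(true_speed > angle_floor * peak, angle, np.nan)

    if est_wss is not None:
        est_wss = np.asarray(est_wss, float)
        true_wss = np.asarray(true_wss, float)
        peak_wss = np.nanmax(np.abs(true_wss))
        wss_err = np.abs(np.abs(est_wss) - np.abs(true_wss)) / peak_wss * 100.0
    else:
        peak_wss = np.nan
        wss_err = np.array([])

    return ErrorSummary(
        velocity_pct=vel_err.ravel(),
        wss_pct=np.asarray(wss_err).ravel(),
        angle_deg=angle.ravel(),
        peak_velocity=float(peak),
        peak_wss=float(peak_wss),
    )


@dataclass
class AgreementReport:
    """Bland-Altman bias/limits plus RMSE and peak-normalised difference."""

    bias: float
    sd: float
    rmse: float
    rmse_pct_peak: float
    correlation: float

    @property
    def limits(self) -> tuple:
        return (self.bias - 1.96 * self.sd, self.bias + 1.96 * self.sd)


def bland_altman(a, b) -> AgreementReport:
    """Agreement between two waveforms: bias, +-1.96 SD limits, RMSE.

    The peak-normalised difference is RMSE / max|b| (b is the reference).
    """
    a = np.asarray(a, float)
    b = np.asarray(b, float)
    if a.shape != b.shape:
        raise ValueError("waveforms must have equal length (resample first)")
    d = a - b
    bias = float(np.mean(d))
    sd = float(np.std(d))
    rmse = float(np.sqrt(np.mean(d**2)))
    peak = float(np.max(np.abs(b)))
    if a.size > 1 and np.std(a) > 0 and np.std(b) > 0:
        corr = float(np.corrcoef(a, b)[0, 1])
    else:
        corr = np.nan
    return AgreementReport(
        bias=bias,
        sd=sd,
        rmse=rmse,
        rmse_pct_peak=rmse / peak * 100.0 if peak > 0 else np.nan,
        correlation=corr,
    )


def default_model(geometry: VesselGeometry | None = None) -> WomersleyModel:
    """The rabbit-aorta Womersley model at the default vessel geometry."""
    geometry = geometry or VesselGeometry()
    return WomersleyModel(aorta_waveform(), geometry)


@dataclass
class PipelineResult:
    """Everything the full UIV pipeline produces for one acquisition."""

    fields: list  # ensemble-averaged, POD-regularised vector fields
    raw_fields: list
    contour: _lumen.LumenContour
    wss: _wss.WSSRecord
    flow_stack: FrameStack
    clutter_stack: FrameStack
    snr: _clutter.SNRReport
    cutoffs: tuple


def run_pipeline(
    stack: FrameStack,
    geometry: VesselGeometry,
    uiv: UIVConfig = UIVConfig(),
    wall: WallTrackConfig = WallTrackConfig(),
    wss_cfg: WSSConfig = WSSConfig(),
    cutoffs: tuple | None = None,
) -> PipelineResult:
    """Complete contrast-free UIV processing of a frame stack.

    SVD clutter filtering (auto cutoffs unless given), lumen tracking on the
    separated signals, window-deformation PIV on consecutive flow frames
    inside the tracked lumen, outlier filtering, ensemble averaging, POD
    regularisation and wall shear estimation.
    """
    decomp = _clutter.svd_decompose(stack)
    if cutoffs is None:
        cutoffs = _clutter.select_cutoffs(decomp)
    low, high = cutoffs
    flow = stack.with_frames(decomp.reconstruct(low, high))
    clutter_stack = stack.with_frames(decomp.reconstruct(0, low))

    contour = _lumen.track_sequence(flow, clutter_stack, wall)

    r = np.abs(stack.z_coords() - geometry.centre_depth)
    lumen_col = r < 0.8 * geometry.radius
    # tissue ROI: outside the vessel, one PSF-guard away from the wall so the
    # measurement is not dominated by point-spread bleed of the lumen speckle
    guard = 0.4e-3
    tissue_col = r > geometry.radius + geometry.wall_thickness + guard
    if not tissue_col.any():
        tissue_col = (r >= geometry.radius) & (
            r < geometry.radius + geometry.wall_thickness
        )
    nx = stack.frames.shape[2]
    lumen_true = np.repeat(lumen_col[:, None], nx, axis=1)
    tissue = np.repeat(tissue_col[:, None], nx, axis=1)
    snr = _clutter.measure_snr(flow, flow, lumen_true, tissue)

    mag = np.abs(flow.frames)
    frame_rate = stack.frame_rate
    raw_fields = []
    for f in range(stack.n_frames - 1):
        mask = contour.lumen_mask(f, mag.shape[1:])
        vf = _piv.iterative_piv(
            mag[f],
            mag[f + 1],
            uiv,
            mask=mask,
            frame_rate=frame_rate,
            dx=stack.dx,
            dz=stack.dz,
            t=0.5 * (stack.timestamps[f] + stack.timestamps[f + 1]),
        )
        vf = _piv.universal_outlier_filter(vf, uiv.outlier_threshold, uiv.outlier_eps)
        raw_fields.append(vf)

    half = uiv.ensemble_length // 2
    averaged = []
    centre_frames = []
    for i in range(len(raw_fields)):
        lo = max(0, i - half)
        hi = min(len(raw_fields), i + half + 1)
        avg = _piv.ensemble_average(raw_fields[lo:hi])
        avg.t = raw_fields[i].t
        averaged.append(avg)
        centre_frames.append(i)
    averaged = _piv.pod_regularize(averaged, uiv.pod_modes)

    record = _wss.compute_wss_sequence(
        averaged,
        contour,
        wss_cfg,
        mu=geometry.mu,
        dz=stack.dz,
        dx=stack.dx,
        frame_indices=centre_frames,
    )
    return PipelineResult(
        fields=averaged,
        raw_fields=raw_fields,
        contour=contour,
        wss=record,
        flow_stack=flow,
        clutter_stack=clutter_stack,
        snr=snr,
        cutoffs=(low, high),
    )


def _evaluate_against_truth(
    result: PipelineResult,
    model: WomersleyModel,
    stack: FrameStack,
) -> ErrorSummary:
    """Compare pipeline output with the analytic field at the vector nodes."""
    geometry = model.geometry
    zc = geometry.centre_depth
    fields = result.fields
    node_z_m = stack.z0 + fields[0].node_z * stack.dz
    r = np.abs(node_z_m - zc)
    in_lumen = r < geometry.radius
    times = np.array([f.t for f in fields])

    est_u, est_v, true_u = [], [], []
    for f in fields:
        sel = f.valid & in_lumen[:, None]
        ut = np.where(
            in_lumen[:, None],
            model.velocity_profile(np.clip(r, 0, geometry.radius), f.t)[:, None],
            0.0,
        ) * np.ones_like(f.u)
        est_u.append(np.where(sel, f.u, np.nan))
        est_v.append(np.where(sel, f.v, np.nan))
        true_u.append(np.where(sel, ut, np.nan))
    est_u = np.stack(est_u)
    est_v = np.stack(est_v)
    true_u = np.stack(true_u)
    # normalise by the acquisition's analytic peak (all lumen nodes, all frames)
    peak_ref = np.nanmax(
        np.abs(model.velocity_profile(np.clip(r[in_lumen], 0, geometry.radius), times))
    )

    wss_true_t = model.wall_shear_stress(result.wss.t)
    true_wss = np.repeat(
        wss_true_t[:, None], result.wss.columns_x.size * 2, axis=1
    )
    est_wss = np.concatenate([result.wss.wss_top, result.wss.wss_bottom], axis=1)

    summary = error_metrics(
        est_u,
        est_v,
        true_u,
        np.zeros_like(true_u),
        est_wss=est_wss,
        true_wss=true_wss,
    )
    # replace the peak estimated from masked nodes with the full-lumen peak
    summary.velocity_pct *= summary.peak_velocity / peak_ref
    summary.peak_velocity = float(peak_ref)
    return summary


def run_experiment(
    phantom: PhantomConfig = PhantomConfig(),
    geometry: VesselGeometry | None = None,
    acq: AcquisitionConfig = AcquisitionConfig(),
    uiv: UIVConfig = UIVConfig(),
    wall: WallTrackConfig | None = None,
    wss_cfg: WSSConfig = WSSConfig(),
    n_frames: int = 450,
    t_start: float = 0.0,
    seed: int = 1,
) -> dict:
    """Simulate one acquisition and run the full pipeline against ground truth.

    Returns the median errors, the post-filter SNR and bookkeeping fields.
    The default acquisition covers one full cardiac cycle (450 compounded
    frames at 1500 Hz), the condition under which the cycle-pooled error
    medians are defined; shorter desk-scale windows over-represent systole
    and inflate the peak-normalised medians.
    """
    if wall is None:
        # symmetric renderer: the empirically calibrated symmetric
        # leading-edge factor (see docs/methods.md, wall-tracking calibration)
        wall = WallTrackConfig(k_top=0.6, k_bottom=0.6)
    model = default_model(geometry)
    stack, gt = simulate_sequence(
        model, phantom, acq, n_frames=n_frames, t_start=t_start, seed=seed
    )
    result = run_pipeline(stack, model.geometry, uiv, wall, wss_cfg)
    summary = _evaluate_against_truth(result, model, stack)
    out = {
        "seed": seed,
        "snr_db": result.snr.snr_db,
        "low_cut": result.cutoffs[0],
        "diameter_mm": float(np.mean(result.contour.diameter_m())) * 1e3,
        **summary.medians(),
    }
    out["_summary"] = summary
    out["_result"] = result
    return out


from functools import lru_cache


@lru_cache(maxsize=16)
def _run_level(cfg: PhantomConfig, n_frames: int, seed: int):
    """One sweep level; cached because the default configuration is shared
    by all three sweeps (amplitude 10, density 10, constant profile)."""
    res = run_experiment(phantom=cfg, n_frames=n_frames, seed=seed)
    res.pop("_result")
    s = res.pop("_summary")
    s.velocity_pct = s.velocity_pct[np.isfinite(s.velocity_pct)].astype(np.float32)
    s.wss_pct = s.wss_pct[np.isfinite(s.wss_pct)].astype(np.float32)
    s.angle_deg = s.angle_deg[np.isfinite(s.angle_deg)].astype(np.float32)
    return res, s


def _sweep(levels, configs, seeds, n_frames) -> pd.DataFrame:
    rows = []
    for level, cfg in zip(levels, configs):
        pooled_v, pooled_w, pooled_a = [], [], []
        snrs, diameters = [], []
        for seed in seeds:
            res, s = _run_level(cfg, n_frames, seed)
            pooled_v.append(s.velocity_pct)
            pooled_w.append(s.wss_pct)
            pooled_a.append(s.angle_deg)
            snrs.append(res["snr_db"])
            diameters.append(res["diameter_mm"])
        vel = np.concatenate(pooled_v)
        wss = np.concatenate(pooled_w)
        ang = np.concatenate(pooled_a)
        rows.append(
            {
                "level": level,
                "median_velocity_pct": float(np.nanmedian(vel)),
                "median_wss_pct": float(np.nanmedian(wss)),
                "median_angle_deg": float(np.median(ang)) if ang.size else np.nan,
                "snr_db": float(np.mean(snrs)),
                "diameter_mm": float(np.mean(diameters)),
                "n_velocity_samples": int(np.isfinite(vel).sum()),
                "n_wss_samples": int(np.isfinite(wss).sum()),
            }
        )
    return pd.DataFrame(rows)


def plot_sweep(table: pd.DataFrame, out_path, title: str = "") -> None:
    """Per-level median errors with interquartile whiskers, saved as PNG."""
    import matplotlib

    matplotlib.use("Agg")
    import matplotlib.pyplot as plt

    fig, axes = plt.subplots(1, 3, figsize=(10, 3.2))
    metrics = [
        ("median_velocity_pct", "velocity error (% of peak)"),
        ("median_wss_pct", "WSS error (% of peak)"),
        ("median_angle_deg", "angle error (deg)"),
    ]
    x = np.arange(len(table))
    for ax, (col, label) in zip(axes, metrics):
        ax.plot(x, table[col], "o-")
        ax.set_xticks(x)
        ax.set_xticklabels([str(v) for v in table["level"]])
        ax.set_ylabel(label)
        ax.set_xlabel("level")
    if title:
        fig.suptitle(title)
    fig.tight_layout()
    fig.savefig(out_path, dpi=150)
    plt.close(fig)


def sweep_scatter_amplitude(
    levels=AMPLITUDE_LEVELS, seeds=(1,), n_frames: int = 450
) -> pd.DataFrame:
    """Accuracy vs scatter amplitude (low-to-high post-filter SNR)."""
    configs = [PhantomConfig(flow_amplitude=a) for a in levels]
    return _sweep(levels, configs, seeds, n_frames)


def sweep_scatter_density(
    levels=DENSITY_LEVELS, seeds=(1,), n_frames: int = 450
) -> pd.DataFrame:
    """Accuracy vs blood scatterer density per resolution cell."""
    configs = [PhantomConfig(flow_density=d) for d in levels]
    return _sweep(levels, configs, seeds, n_frames)


def sweep_radial_profile(
    levels=RADIAL_LEVELS, seeds=(1,), n_frames: int = 450
) -> pd.DataFrame:
    """Accuracy vs radial intensity distribution (uniform to uneven)."""
    configs = [PhantomConfig(radial_profile=p) for p in levels]
    return _sweep(levels, configs, seeds, n_frames)
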