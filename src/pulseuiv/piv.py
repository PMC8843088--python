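"""Echo-PIV engine: iterative window-deformation cross-correlation.

Displacement between two frames is estimated on a regular grid of
interrogation windows. Three passes halve the window (32 -> 16 -> 8 px at the
defaults) with 50% overlap; after the first pass the second frame is
spline-deformed by the interpolated predictor field before correlation, so
later passes only measure the small residual. The correlation peak is refined
per axis with a three-point Gaussian estimator. Spurious vectors are detected
with the normalised-median (universal outlier) test; fields are ensemble
averaged over consecutive frames and finally regularised by truncated proper
orthogonal decomposition of the field sequence.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, replace

import numpy as np
from numpy.lib.stride_tricks import sliding_window_view
from scipy.interpolate import RegularGridInterpolator
from scipy.ndimage import map_coordinates

from .config import UIVConfig

__all__ = [
    "VectorField",
    "correlate_window",
    "gaussian_subpixel",
    "iterative_piv",
    "universal_outlier_filter",
    "ensemble_average",
    "pod_regularize",
]


@dataclass
class VectorField:
    """Gridded 2-D velocity estimates at interrogation-window centres.

    ``u`` is the lateral (x) and ``v`` the axial (z) component; units are m/s
    when a frame rate and pixel pitch were supplied to the engine, otherwise
    pixels of displacement. ``node_z``/``node_x`` are window-centre pixel
    coordinates on the image grid.
    """

    u: np.ndarray
    v: np.ndarray
    valid: np.ndarray
    node_z: np.ndarray
    node_x: np.ndarray
    t: float = 0.0
    units: str = "m/s"
    replaced: np.ndarray | None = None

    def __post_init__(self):
        if self.replaced is None:
            self.replaced = np.zeros_like(self.valid, dtype=bool)

    @property
    def shape(self) -> tuple:
        return self.u.shape

    def speed(self) -> np.ndarray:
        return np.hypot(self.u, self.v)


def _window_starts(length: int, ws: int, overlap: float) -> np.ndarray:
    step = max(1, int(round(ws * (1.0 - overlap))))
    last = length - ws
    if last < 0:
        raise ValueError(f"image extent {length} smaller than window {ws}")
    return np.arange(0, last + 1, step)


def _extract_windows(img: np.ndarray, z0: np.ndarray, x0: np.ndarray, ws: int) -> np.ndarray:
    view = sliding_window_view(img, (ws, ws))
    return view[np.ix_(z0, x0)].reshape(-1, ws, ws)


def gaussian_subpixel(c_minus: float, c_mid: float, c_plus: float) -> float:
    """Three-point Gaussian peak interpolation along one axis.

    Exact for samples of a Gaussian; falls back to a parabolic fit on the raw
    values when any sample is non-positive (logarithms undefined). The result
    is clamped to (-1, 1).
    """
    if min(c_minus, c_mid, c_plus) <= 0:
        denom = 2.0 * (c_minus - 2.0 * c_mid + c_plus)
        offset = (c_minus - c_plus) / denom if denom != 0 else 0.0
    else:
        lm, l0, lp = np.log(c_minus), np.log(c_mid), np.log(c_plus)
        denom = 2.0 * lm - 4.0 * l0 + 2.0 * lp
        offset = (lm - lp) / denom if denom != 0 else 0.0
    return float(np.clip(offset, np.nextafter(-1.0, 0.0), np.nextafter(1.0, 0.0)))


def _subpixel_batch(cm: np.ndarray, c0: np.ndarray, cp: np.ndarray) -> np.ndarray:
    """Vectorised three-point peak interpolation (Gaussian, parabolic fallback)."""
    cm = np.asarray(cm, float)
    c0 = np.asarray(c0, float)
    cp = np.asarray(cp, float)
    pos = (cm > 0) & (c0 > 0) & (cp > 0)
    out = np.zeros(cm.shape)
    with warnings.catch_warnings():
        warnings.simplefilter("ignore", RuntimeWarning)
        lm, l0, lp = np.log(np.where(pos, cm, 1.0)), np.log(np.where(pos, c0, 1.0)), np.log(
            np.where(pos, cp, 1.0)
        )
        den_g = 2.0 * lm - 4.0 * l0 + 2.0 * lp
        gauss = np.where(den_g != 0, (lm - lp) / np.where(den_g != 0, den_g, 1.0), 0.0)
        den_p = 2.0 * (cm - 2.0 * c0 + cp)
        para = np.where(den_p != 0, (cm - cp) / np.where(den_p != 0, den_p, 1.0), 0.0)
    out = np.where(pos, gauss, para)
    limit = np.nextafter(1.0, 0.0)
    return np.clip(out, -limit, limit)


def _correlate_batch(wins_a: np.ndarray, wins_b: np.ndarray, search: int):
    """Normalised circular cross-correlation peak for a batch of window pairs.

    Returns (dz, dx) float displacements and a validity flag per pair. The
    peak is searched within +-search pixels of zero lag; ties are broken
    toward the smallest displacement magnitude.
    """
    n, ws, _ = wins_a.shape
    a = wins_a - wins_a.mean(axis=(1, 2), keepdims=True)
    b = wins_b - wins_b.mean(axis=(1, 2), keepdims=True)
    sa = a.std(axis=(1, 2))
    sb = b.std(axis=(1, 2))
    ok = (sa > 0) & (sb > 0)
    fa = np.fft.rfft2(a)
    fb = np.fft.rfft2(b)
    corr = np.fft.irfft2(np.conj(fa) * fb, s=(ws, ws))
    corr = np.fft.fftshift(corr, axes=(1, 2))
    norm = ws * ws * sa * sb
    norm[~ok] = 1.0
    corr /= norm[:, None, None]

    c0 = ws // 2  # zero-lag index after fftshift
    lo, hi = c0 - search, c0 + search + 1
    sub = corr[:, lo:hi, lo:hi]
    m = sub.shape[1]
    flat = sub.reshape(n, -1)
    best = np.argmax(flat, axis=1)
    peak_val = flat[np.arange(n), best]
    # tie-break (exactly symmetric correlations): smallest displacement
    # magnitude among the joint maxima
    tied = np.flatnonzero(
        np.count_nonzero(flat >= peak_val[:, None] - 1e-15, axis=1) > 1
    )
    if tied.size:
        iz, ix = np.meshgrid(
            np.arange(m) - search, np.arange(m) - search, indexing="ij"
        )
        radius = (iz**2 + ix**2).reshape(-1)
        for i in tied:
            cand = np.flatnonzero(flat[i] >= peak_val[i] - 1e-15)
            best[i] = cand[np.argmin(radius[cand])]
    pz = best // m + lo
    px = best % m + lo

    dz = (pz - c0).astype(float)
    dx = (px - c0).astype(float)
    rows = np.arange(n)
    zi = np.clip(pz, 1, ws - 2)
    xi = np.clip(px, 1, ws - 2)
    dz += np.where(
        ok & (pz > 0) & (pz < ws - 1),
        _subpixel_batch(corr[rows, zi - 1, px], corr[rows, zi, px], corr[rows, zi + 1, px]),
        0.0,
    )
    dx += np.where(
        ok & (px > 0) & (px < ws - 1),
        _subpixel_batch(corr[rows, pz, xi - 1], corr[rows, pz, xi], corr[rows, pz, xi + 1]),
        0.0,
    )
    return dz, dx, ok


def correlate_window(win_a: np.ndarray, win_b: np.ndarray):
    """Subpixel displacement (dz, dx) of win_b relative to win_a.

    Returns (nan, nan) flagged invalid for zero-variance windows rather than
    raising.
    """
    win_a = np.asarray(win_a, float)
    win_b = np.asarray(win_b, float)
    if win_a.shape != win_b.shape or win_a.shape[0] != win_a.shape[1]:
        raise ValueError("windows must be square and of equal size")
    if win_a.shape[0] % 2:
        raise ValueError("window size must be even")
    ws = win_a.shape[0]
    dz, dx, ok = _correlate_batch(win_a[None], win_b[None], search=ws // 2 - 1)
    if not ok[0]:
        return np.nan, np.nan
    return float(dz[0]), float(dx[0])


def _neighbour_stats(arr: np.ndarray):
    """(median of 3x3 neighbours excluding centre, neighbour values) with NaN padding."""
    padded = np.pad(arr, 1, constant_values=np.nan)
    win = sliding_window_view(padded, (3, 3)).reshape(*arr.shape, 9)
    neigh = np.delete(win, 4, axis=-1)
    with warnings.catch_warnings():
        warnings.simplefilter("ignore", RuntimeWarning)
        med = np.nanmedian(neigh, axis=-1)
    return med, neigh


def universal_outlier_filter(field: VectorField, threshold: float = 1.5, eps: float = 0.1) -> VectorField:
    """Normalised-median test on the 3x3 neighbourhood of every vector.

    A vector is spurious when, for either component,
    |value - median(neighbours)| / (median residual of neighbours + eps)
    exceeds the threshold; it is replaced by the neighbourhood median and
    flagged. Invalid vectors are ignored as neighbours.
    """
    new_u, new_v = field.u.copy(), field.v.copy()
    flagged = np.zeros(field.shape, dtype=bool)
    meds = {}
    exceed = np.zeros(field.shape, dtype=bool)
    for name, comp in (("u", field.u), ("v", field.v)):
        arr = np.where(field.valid, comp, np.nan)
        med, neigh = _neighbour_stats(arr)
        with warnings.catch_warnings():
            warnings.simplefilter("ignore", RuntimeWarning)
            res_med = np.nanmedian(np.abs(neigh - med[..., None]), axis=-1)
        norm = np.abs(arr - med) / (res_med + eps)
        exceed |= np.where(np.isfinite(norm), norm > threshold, False)
        meds[name] = med
    flagged = exceed & field.valid & np.isfinite(meds["u"]) & np.isfinite(meds["v"])
    new_u[flagged] = meds["u"][flagged]
    new_v[flagged] = meds["v"][flagged]
    out = replace(field, u=new_u, v=new_v)
    out.replaced = field.replaced | flagged
    return out


def _fill_invalid(u: np.ndarray, v: np.ndarray, valid: np.ndarray):
    """Replace invalid nodes by their neighbourhood median (0 if isolated)."""
    u, v = u.copy(), v.copy()
    for comp in (u, v):
        arr = np.where(valid, comp, np.nan)
        med, _ = _neighbour_stats(arr)
        fill = np.where(np.isfinite(med), med, 0.0)
        comp[~valid] = fill[~valid]
    return u, v


def _predict_dense(node_z, node_x, du, dv, shape):
    """Bilinear interpolation of the node displacements onto the pixel grid."""
    zz, xx = np.meshgrid(np.arange(shape[0]), np.arange(shape[1]), indexing="ij")
    pts = np.column_stack([zz.ravel(), xx.ravel()])
    out = []
    for comp in (dv, du):  # axial first to match (z, x) indexing
        itp = RegularGridInterpolator(
            (node_z, node_x), comp, method="linear", bounds_error=False, fill_value=None
        )
        out.append(itp(pts).reshape(shape))
    return out[0], out[1]  # dense_dv (z), dense_du (x)


def _interp_to_nodes(node_z, node_x, du, dv, new_z, new_x):
    zz, xx = np.meshgrid(new_z, new_x, indexing="ij")
    pts = np.column_stack([zz.ravel(), xx.ravel()])
    out = []
    for comp in (du, dv):
        itp = RegularGridInterpolator(
            (node_z, node_x), comp, method="linear", bounds_error=False, fill_value=None
        )
        out.append(itp(pts).reshape(zz.shape))
    return out


def iterative_piv(
    frame_a: np.ndarray,
    frame_b: np.ndarray,
    config: UIVConfig = UIVConfig(),
    mask: np.ndarray | None = None,
    frame_rate: float | None = None,
    dx: float = 1.0,
    dz: float = 1.0,
    t: float = 0.0,
) -> VectorField:
    """Window-deformation PIV between two frames.

    With ``frame_rate`` (and pixel pitches) given, the returned components
    are velocities in m/s; otherwise raw pixel displacements. ``mask``
    restricts valid vectors to window centres inside it (e.g. the lumen).
    """
    frame_a = np.asarray(frame_a, float)
    frame_b = np.asarray(frame_b, float)
    if frame_a.shape != frame_b.shape:
        raise ValueError("frames must share one grid")
    if min(frame_a.shape) < config.window_size:
        raise ValueError("image smaller than the first interrogation window")

    node_z = node_x = None
    du = dv = None
    for it, ws in enumerate(config.window_sizes):
        z_starts = _window_starts(frame_a.shape[0], ws, config.overlap)
        x_starts = _window_starts(frame_a.shape[1], ws, config.overlap)
        new_z = z_starts + (ws - 1) / 2.0
        new_x = x_starts + (ws - 1) / 2.0

        if du is None:
            b_use = frame_b
            pred_u = np.zeros((new_z.size, new_x.size))
            pred_v = np.zeros_like(pred_u)
        else:
            pred_u, pred_v = _interp_to_nodes(node_z, node_x, du, dv, new_z, new_x)
            dense_v, dense_u = _predict_dense(node_z, node_x, du, dv, frame_a.shape)
            zz, xx = np.meshgrid(
                np.arange(frame_a.shape[0], dtype=float),
                np.arange(frame_a.shape[1], dtype=float),
                indexing="ij",
            )
            b_use = map_coordinates(
                frame_b,
                [zz + dense_v, xx + dense_u],
                order=config.deformation_order,
                mode="nearest",
            )

        wins_a = _extract_windows(frame_a, z_starts, x_starts, ws)
        wins_b = _extract_windows(b_use, z_starts, x_starts, ws)
        search = max(2, ws // 4) if du is not None else ws // 2 - 1
        rdz, rdx, ok = _correlate_batch(wins_a, wins_b, search)
        shape = (new_z.size, new_x.size)
        du = pred_u + rdx.reshape(shape)
        dv = pred_v + rdz.reshape(shape)
        valid = ok.reshape(shape)
        du, dv = _fill_invalid(du, dv, valid)
        node_z, node_x = new_z, new_x

        if it < config.n_iterations - 1:
            predictor = VectorField(
                u=du, v=dv, valid=valid, node_z=node_z, node_x=node_x, units="px"
            )
            predictor = universal_outlier_filter(
                predictor, config.outlier_threshold, config.outlier_eps
            )
            du, dv = predictor.u, predictor.v

    if mask is not None:
        inside = mask[
            np.clip(np.round(node_z).astype(int), 0, mask.shape[0] - 1)[:, None],
            np.clip(np.round(node_x).astype(int), 0, mask.shape[1] - 1)[None, :],
        ]
        valid = valid & inside

    if frame_rate is None:
        return VectorField(
            u=du, v=dv, valid=valid, node_z=node_z, node_x=node_x, t=t, units="px"
        )
    return VectorField(
        u=du * dx * frame_rate,
        v=dv * dz * frame_rate,
        valid=valid,
        node_z=node_z,
        node_x=node_x,
        t=t,
        units="m/s",
    )


def ensemble_average(fields) -> VectorField:
    """Per-node mean of consecutive fields over their valid vectors.

    The result carries the centre timestamp; a node is valid where at least
    half the members were valid. At sequence edges callers may pass fewer
    fields than the nominal ensemble length (shrinking window).
    """
    fields = list(fields)
    if not fields:
        raise ValueError("need at least one field")
    shape = fields[0].shape
    for f in fields:
        if f.shape != shape:
            raise ValueError("ensemble members must share one grid")
    u = np.stack([np.where(f.valid, f.u, np.nan) for f in fields])
    v = np.stack([np.where(f.valid, f.v, np.nan) for f in fields])
    count = np.sum(~np.isnan(u), axis=0)
    valid = count >= int(np.ceil(len(fields) / 2.0))
    with warnings.catch_warnings():
        warnings.simplefilter("ignore", RuntimeWarning)
        mu = np.nanmean(u, axis=0)
        mv = np.nanmean(v, axis=0)
    mu = np.where(count > 0, mu, 0.0)
    mv = np.where(count > 0, mv, 0.0)
    centre = fields[len(fields) // 2]
    return VectorField(
        u=mu,
        v=mv,
        valid=valid,
        node_z=centre.node_z,
        node_x=centre.node_x,
        t=float(np.mean([f.t for f in fields])),
        units=centre.units,
    )


def pod_regularize(fields, n_modes: int = 10):
    """Truncated POD of a velocity-field sequence (snapshot method).

    The u and v components of every frame are stacked into one snapshot
    matrix; only the leading ``n_modes`` spatial modes are retained. Invalid
    nodes are temporarily filled with their temporal mean so they do not leak
    energy into the modes; validity masks are preserved.
    """
    fields = list(fields)
    n_t = len(fields)
    if n_t < n_modes:
        warnings.warn("sequence shorter than the mode count; returning input unchanged")
        return fields
    shape = fields[0].shape
    u = np.stack([np.where(f.valid, f.u, np.nan) for f in fields])
    v = np.stack([np.where(f.valid, f.v, np.nan) for f in fields])
    with warnings.catch_warnings():
        warnings.simplefilter("ignore", RuntimeWarning)
        u_mean = np.nanmean(u, axis=0)
        v_mean = np.nanmean(v, axis=0)
    u_mean = np.nan_to_num(u_mean)
    v_mean = np.nan_to_num(v_mean)
    u = np.where(np.isnan(u), u_mean[None], u)
    v = np.where(np.isnan(v), v_mean[None], v)
    snaps = np.concatenate([u.reshape(n_t, -1), v.reshape(n_t, -1)], axis=1).T
    umat, s, vt = np.linalg.svd(snaps, full_matrices=False)
    recon = (umat[:, :n_modes] * s[:n_modes]) @ vt[:n_modes]
    n_nodes = shape[0] * shape[1]
    out = []
    for i, f in enumerate(fields):
        ru = recon[:n_nodes, i].reshape(shape)
        rv = recon[n_nodes:, i].reshape(shape)
        out.append(replace(f, u=ru, v=rv))
    return out
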