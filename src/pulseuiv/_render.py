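"""Point-spread accumulation kernel for the simplified beamformed renderer.

Each scatterer contributes a separable Gaussian envelope with a carrier phase
that depends on the pixel offset from the scatterer (axial pulse-echo carrier
plus the lateral phase slope of the steered plane wave), mirroring the
shift-invariant point spread of a delay-and-sum beamformer: translating the
scatterer cloud translates the complex image. The hot loop is jitted with
numba when available, with a pure-python fallback.
"""

from __future__ import annotations

import numpy as np

try:  # pragma: no cover - exercised implicitly
    from numba import njit

    _HAVE_NUMBA = True
except ImportError:  # pragma: no cover
    _HAVE_NUMBA = False


def _accumulate_py(re, im, iz0, iz1, ix0, ix1, zpix, xpix, amp, kz, kx, inv2sz2, inv2sx2):
    # separable kernel: complex weights factorise over the two axes
    max_w = 64
    wz_re = np.empty(max_w)
    wz_im = np.empty(max_w)
    wx_re = np.empty(max_w)
    wx_im = np.empty(max_w)
    for k in range(zpix.size):
        a = amp[k]
        nzk = iz1[k] - iz0[k]
        nxk = ix1[k] - ix0[k]
        if nzk <= 0 or nxk <= 0:
            continue
        for i in range(nzk):
            d = iz0[k] + i - zpix[k]
            g = a * np.exp(-d * d * inv2sz2)
            ph = kz * d
            wz_re[i] = g * np.cos(ph)
            wz_im[i] = g * np.sin(ph)
        for j in range(nxk):
            d = ix0[k] + j - xpix[k]
            g = np.exp(-d * d * inv2sx2)
            ph = kx * d
            wx_re[j] = g * np.cos(ph)
            wx_im[j] = g * np.sin(ph)
        for i in range(nzk):
            zr = wz_re[i]
            zi = wz_im[i]
            row = iz0[k] + i
            for j in range(nxk):
                re[row, ix0[k] + j] += zr * wx_re[j] - zi * wx_im[j]
                im[row, ix0[k] + j] += zr * wx_im[j] + zi * wx_re[j]


if _HAVE_NUMBA:
    _accumulate = njit(cache=True, fastmath=True)(_accumulate_py)
else:  # pragma: no cover
    _accumulate = _accumulate_py


def render_complex(
    x,
    z,
    amplitude,
    z0: float,
    x0: float,
    dz: float,
    dx: float,
    nz: int,
    nx: int,
    sigma_z: float,
    sigma_x: float,
    kz: float = 0.0,
    kx: float = 0.0,
    truncate: float = 3.0,
) -> np.ndarray:
    """Complex (analytic) image of a scatterer cloud on the (nz, nx) grid.

    ``kz``/``kx`` are the carrier phase slopes in rad per axial/lateral pixel
    offset from the scatterer. The modulus of the result is the envelope.
    """
    zpix = (np.asarray(z, float) - z0) / dz
    xpix = (np.asarray(x, float) - x0) / dx
    sz = sigma_z / dz
    sx = sigma_x / dx
    hz = max(1, int(np.ceil(truncate * sz)))
    hx = max(1, int(np.ceil(truncate * sx)))

    inside = (zpix > -hz - 1) & (zpix < nz + hz) & (xpix > -hx - 1) & (xpix < nx + hx)
    zpix, xpix = zpix[inside], xpix[inside]
    amp = np.ascontiguousarray(np.asarray(amplitude, float)[inside])

    re = np.zeros((nz, nx))
    im = np.zeros((nz, nx))
    if zpix.size:
        iz0 = np.clip(np.ceil(zpix - hz).astype(np.int64), 0, nz)
        iz1 = np.clip(np.floor(zpix + hz).astype(np.int64) + 1, 0, nz)
        ix0 = np.clip(np.ceil(xpix - hx).astype(np.int64), 0, nx)
        ix1 = np.clip(np.floor(xpix + hx).astype(np.int64) + 1, 0, nx)
        _accumulate(
            re,
            im,
            iz0,
            iz1,
            ix0,
            ix1,
            zpix,
            xpix,
            amp,
            float(kz),
            float(kx),
            1.0 / (2.0 * sz**2),
            1.0 / (2.0 * sx**2),
        )
    return re + 1j * im
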