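"""Plane-wave image formation: PSF rendering, compounding, noise, sequences.

The renderer stands in for a full linear-acoustics simulation: each frame is
the coherent sum of per-scatterer point-spread responses (carrier-modulated
separable Gaussians), kept complex through compounding and clutter filtering
and envelope-detected afterwards. This preserves the speckle statistics the
PIV engine sees while remaining desk-scale; the renderer sits behind this
module's function surface so a full acoustic simulator can be substituted.
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass, replace

import h5py
import numpy as np

from ._render import render_complex
from .config import AcquisitionConfig, PhantomConfig, VesselGeometry
from .phantom import ScattererField, advect, init_scatterers
from .womersley import WomersleyModel

__all__ = [
    "FrameStack",
    "GroundTruth",
    "render_frame",
    "compound",
    "add_noise",
    "simulate_sequence",
    "vessel_masks",
]


@dataclass
class FrameStack:
    """Time-ordered 2-D frames on a fixed pixel grid.

    frames are (T, n_z, n_x); ``kind`` records the value domain: ``iq``
    frames are complex beamformed data (clutter filtering operates on these),
    ``envelope`` frames are their modulus (possibly with signed additive
    noise), ``log-compressed`` frames are display images.
    """

    frames: np.ndarray
    dz: float
    dx: float
    z0: float
    x0: float
    prf: float
    angles_deg: tuple
    timestamps: np.ndarray
    kind: str = "envelope"

    def __post_init__(self):
        dtype = complex if self.kind == "iq" else float
        self.frames = np.asarray(self.frames, dtype=dtype)
        self.timestamps = np.asarray(self.timestamps, dtype=float)
        if self.frames.ndim != 3:
            raise ValueError("frames must be (time, z, x)")
        if self.timestamps.size != self.frames.shape[0]:
            raise ValueError("one timestamp per frame required")
        if self.timestamps.size > 1 and np.any(np.diff(self.timestamps) <= 0):
            raise ValueError("timestamps must be strictly increasing")
        if self.dz <= 0 or self.dx <= 0:
            raise ValueError("pixel spacing must be positive")

    @property
    def n_frames(self) -> int:
        return self.frames.shape[0]

    @property
    def shape(self) -> tuple:
        return self.frames.shape

    @property
    def frame_rate(self) -> float:
        return self.prf / len(self.angles_deg)

    def z_coords(self) -> np.ndarray:
        return self.z0 + self.dz * np.arange(self.frames.shape[1])

    def x_coords(self) -> np.ndarray:
        return self.x0 + self.dx * np.arange(self.frames.shape[2])

    def same_grid(self, other: "FrameStack") -> bool:
        return self.frames.shape[1:] == other.frames.shape[1:] and np.allclose(
            [self.dz, self.dx, self.z0, self.x0],
            [other.dz, other.dx, other.z0, other.x0],
        )

    def with_frames(self, frames) -> "FrameStack":
        frames = np.asarray(frames)
        kind = self.kind
        if np.iscomplexobj(frames) and kind != "iq":
            kind = "iq"
        return replace(self, frames=frames, kind=kind)

    def envelope(self) -> "FrameStack":
        """Envelope-detected copy (modulus of iq frames)."""
        return replace(self, frames=np.abs(self.frames), kind="envelope")

    def save(self, path, ground_truth: "GroundTruth | None" = None) -> None:
        with h5py.File(path, "w") as fh:
            ds = fh.create_dataset("frames", data=self.frames)
            fh.create_dataset("timestamps", data=self.timestamps)
            for key in ("dz", "dx", "z0", "x0"):
                ds.attrs[f"{key}_m"] = getattr(self, key)
            ds.attrs["prf_hz"] = self.prf
            ds.attrs["angles_deg"] = list(self.angles_deg)
            ds.attrs["kind"] = self.kind
            if ground_truth is not None:
                fh.create_dataset("gt_u", data=ground_truth.u)
                fh.create_dataset("gt_v", data=ground_truth.v)
                fh.create_dataset("gt_lumen", data=ground_truth.lumen.astype(np.uint8))

    @classmethod
    def load(cls, path) -> "FrameStack":
        with h5py.File(path, "r") as fh:
            ds = fh["frames"]
            stack = cls(
                frames=ds[...],
                dz=float(ds.attrs["dz_m"]),
                dx=float(ds.attrs["dx_m"]),
                z0=float(ds.attrs["z0_m"]),
                x0=float(ds.attrs["x0_m"]),
                prf=float(ds.attrs["prf_hz"]),
                angles_deg=tuple(ds.attrs["angles_deg"]),
                timestamps=fh["timestamps"][...],
                kind=str(ds.attrs["kind"]),
            )
        return stack


@dataclass
class GroundTruth:
    """Co-registered analytic velocity on the image grid, per compounded frame."""

    u: np.ndarray  # lateral velocity (T, n_z, n_x), m/s
    v: np.ndarray  # axial velocity (identically 0 for axial-only tube flow)
    lumen: np.ndarray  # boolean lumen mask (n_z, n_x)
    timestamps: np.ndarray


def render_frame(
    field: ScattererField,
    acq: AcquisitionConfig,
    angle_deg: float,
    z0: float,
    x0: float,
    kind: str = "envelope",
) -> np.ndarray:
    """Single-angle image of the scatterer field.

    ``kind="envelope"`` returns the envelope (modulus); ``kind="iq"`` returns
    the underlying complex image. Linear in scatterer amplitude before
    envelope detection; a unit scatterer at a pixel centre produces an
    envelope peak of exactly 1.
    """
    sigma_z, sigma_x = acq.psf_sigma
    lam = acq.wavelength
    theta = math.radians(angle_deg)
    # carrier phase slopes per pixel offset from the scatterer:
    # pulse-echo axial carrier and the lateral slope of the steered plane wave
    kz = -4.0 * math.pi * acq.dz / lam
    kx = 2.0 * math.pi * math.sin(theta) * acq.dx / lam
    img = render_complex(
        field.x,
        field.z,
        field.amplitude,
        kz=kz,
        kx=kx,
        z0=z0,
        x0=x0,
        dz=acq.dz,
        dx=acq.dx,
        nz=acq.n_z,
        nx=acq.n_x,
        sigma_z=sigma_z,
        sigma_x=sigma_x,
    )
    if kind == "iq":
        return img
    return np.abs(img)


def compound(images) -> np.ndarray:
    """Pixelwise mean compounding of per-angle images.

    Coherent for complex (iq) inputs, incoherent for envelope inputs.
    """
    images = [np.asarray(im) for im in images]
    shape = images[0].shape
    if any(im.shape != shape for im in images):
        raise ValueError("all angled images must share one grid")
    return np.mean(images, axis=0)


def add_noise(stack: FrameStack, target_snr_db: float, wall_mask, seed=None) -> FrameStack:
    """Additive Gaussian noise calibrated against the wall signal.

    The noise standard deviation is set so that
    20 log10(RMS wall signal / RMS noise) equals ``target_snr_db`` exactly.
    An infinite target returns the stack unchanged.
    """
    if np.isinf(target_snr_db):
        return stack
    wall_mask = np.asarray(wall_mask, dtype=bool)
    wall_rms = float(np.sqrt(np.mean(np.abs(stack.frames[:, wall_mask]) ** 2)))
    if wall_rms == 0:
        raise ValueError("wall signal is zero; cannot reference the noise level")
    target_rms = wall_rms / 10.0 ** (target_snr_db / 20.0)
    rng = np.random.default_rng(seed)
    if np.iscomplexobj(stack.frames):
        sigma = target_rms / np.sqrt(2.0)
        noise = rng.normal(0.0, sigma, stack.frames.shape) + 1j * rng.normal(
            0.0, sigma, stack.frames.shape
        )
    else:
        noise = rng.normal(0.0, target_rms, stack.frames.shape)
    return stack.with_frames(stack.frames + noise)


def vessel_masks(acq: AcquisitionConfig, geometry: VesselGeometry, erode: float = 0.0):
    """(lumen, wall) boolean masks on the image grid.

    ``erode`` shrinks the lumen mask radially by that many metres (useful for
    ROI statistics that should avoid the wall transition).
    """
    z0, _ = acq.grid_origin(geometry)
    z = z0 + acq.dz * np.arange(acq.n_z)
    r = np.abs(z - geometry.centre_depth)
    lumen_col = r < geometry.radius - erode
    wall_col = (r >= geometry.radius) & (r < geometry.radius + geometry.wall_thickness)
    lumen = np.repeat(lumen_col[:, None], acq.n_x, axis=1)
    wall = np.repeat(wall_col[:, None], acq.n_x, axis=1)
    return lumen, wall


def simulate_sequence(
    model: WomersleyModel,
    phantom_cfg: PhantomConfig,
    acq: AcquisitionConfig,
    n_frames: int | None = None,
    duration: float | None = None,
    t_start: float = 0.0,
    seed=None,
):
    """Full synthetic acquisition: init -> {advect -> render x angles -> compound -> noise}.

    Returns the compounded, noise-corrupted FrameStack and the co-registered
    analytic ground truth. One compounded frame consumes one transmission per
    angle, so the effective frame rate is PRF / n_angles; scatterers move
    between the individual transmissions, as they do in a real acquisition.
    """
    if (n_frames is None) == (duration is None):
        raise ValueError("specify exactly one of n_frames or duration")
    if n_frames is None:
        n_frames = int(round(duration * acq.prf / acq.n_angles))
    geometry = model.geometry
    z0, x0 = acq.grid_origin(geometry)
    rng = np.random.default_rng(seed)
    field = init_scatterers(phantom_cfg, geometry, rng)
    basis = model.radial_basis(np.abs(field.z[field.blood] - geometry.centre_depth))

    dt = 1.0 / acq.prf
    n_angles = acq.n_angles
    compounded = np.zeros((n_frames, acq.n_z, acq.n_x), dtype=complex)
    mid = n_angles // 2
    timestamps = t_start + (np.arange(n_frames) * n_angles + mid) * dt
    _, wall_mask = vessel_masks(acq, geometry)
    wall_energy = 0.0  # accumulates per-angle wall signal power for the noise reference
    n_wall = int(np.count_nonzero(wall_mask))
    for f in range(n_frames):
        for a, angle in enumerate(acq.angles_deg):
            img = render_frame(field, acq, angle, z0, x0, kind="iq")
            compounded[f] += img
            wall_energy += float(np.sum(np.abs(img[wall_mask]) ** 2))
            t = t_start + (f * n_angles + a) * dt
            field = advect(field, model, t, dt, config=phantom_cfg, rng=rng, basis=basis)
    compounded /= n_angles

    # per-angle independent complex noise at the image-level target SNR; its
    # compounded sum is one complex Gaussian field with sigma / sqrt(n_angles)
    image_snr = acq.image_noise_snr_db
    if np.isfinite(image_snr) and n_wall == 0:
        warnings.warn("no wall pixels inside the imaging grid; noise disabled")
        image_snr = np.inf
    if np.isfinite(image_snr):
        wall_rms = math.sqrt(wall_energy / (n_wall * n_frames * n_angles))
        sigma = wall_rms / 10.0 ** (image_snr / 20.0) / math.sqrt(2.0 * n_angles)
        compounded += rng.normal(0.0, sigma, compounded.shape) + 1j * rng.normal(
            0.0, sigma, compounded.shape
        )

    grid = dict(dz=acq.dz, dx=acq.dx, z0=z0, x0=x0, prf=acq.prf, angles_deg=tuple(acq.angles_deg))
    stack = FrameStack(frames=compounded, timestamps=timestamps, kind="iq", **grid)

    z = z0 + acq.dz * np.arange(acq.n_z)
    r = np.abs(z - geometry.centre_depth)
    lumen_col = r < geometry.radius
    u_col = np.zeros((n_frames, acq.n_z))
    u_col[:, lumen_col] = model.velocity_profile(r[lumen_col], timestamps)
    u = np.repeat(u_col[:, :, None], acq.n_x, axis=2)
    lumen = np.repeat(lumen_col[:, None], acq.n_x, axis=1)
    gt = GroundTruth(u=u, v=np.zeros_like(u), lumen=lumen, timestamps=timestamps)
    return stack, gt
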