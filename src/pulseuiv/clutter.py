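"""SVD spatiotemporal clutter filtering of frame stacks.

The stack is reshaped into a Casorati matrix (one flattened frame per
column); tissue clutter is spatially coherent and slowly varying, so it
concentrates in the leading singular components, while blood speckle spreads
across the higher ones. Removing the leading components reveals the flow
signal. Cutoffs are either supplied manually or derived from the
spatial-similarity matrix of the singular vectors.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .imaging import FrameStack

__all__ = [
    "SVDDecomposition",
    "SNRReport",
    "svd_decompose",
    "spatial_similarity",
    "select_cutoffs",
    "svd_filter",
    "measure_snr",
]


@dataclass
class SVDDecomposition:
    """Thin SVD of the space x time Casorati matrix of a frame stack."""

    u: np.ndarray  # (n_pixels, rank) spatial singular vectors
    s: np.ndarray  # (rank,) non-increasing singular values
    vt: np.ndarray  # (rank, n_frames) temporal singular vectors
    frame_shape: tuple

    @property
    def rank(self) -> int:
        return self.s.size

    def reconstruct(self, low: int = 0, high: int | None = None) -> np.ndarray:
        """Frames rebuilt from singular components [low, high)."""
        high = self.rank if high is None else high
        band = slice(low, high)
        casorati = (self.u[:, band] * self.s[band]) @ self.vt[band]
        n_frames = self.vt.shape[1]
        return casorati.T.reshape((n_frames, *self.frame_shape))


def svd_decompose(stack: FrameStack) -> SVDDecomposition:
    if stack.n_frames < 2:
        raise ValueError("need at least two frames for spatiotemporal SVD")
    n_frames = stack.n_frames
    casorati = stack.frames.reshape(n_frames, -1).T  # (pixels, time)
    u, s, vt = np.linalg.svd(casorati, full_matrices=False)
    return SVDDecomposition(u=u, s=s, vt=vt, frame_shape=stack.frames.shape[1:])


def spatial_similarity(decomp: SVDDecomposition) -> np.ndarray:
    """Pairwise correlation of the magnitudes of the spatial singular vectors."""
    return np.corrcoef(np.abs(decomp.u), rowvar=False)


def select_cutoffs(
    decomp: SVDDecomposition,
    similarity: np.ndarray | None = None,
    strategy: str = "auto",
    manual: tuple | None = None,
    block_threshold: float = 0.6,
    static_threshold: float = 0.5,
    lookback: int = 5,
) -> tuple:
    """Choose the (low, high) singular-component band kept as flow signal.

    ``manual`` passes user indices through. ``auto`` mechanises the usual
    manual reading of the similarity matrix: clutter forms a leading block of
    highly similar spatial vectors, so the block is grown while each next
    component's mean similarity to (the last ``lookback`` members of) the
    block stays above ``block_threshold``; the low cutoff is the block size.
    Component 0 only counts as clutter if its spatial magnitude resembles the
    temporal-mean image (correlation above ``static_threshold``); otherwise
    there is no static clutter and the low cutoff is 0. The high cutoff
    defaults to the full rank (no noise cut).
    """
    if strategy == "manual":
        if manual is None:
            raise ValueError("manual strategy requires explicit cutoffs")
        low, high = manual
    elif strategy == "auto":
        if similarity is None:
            similarity = spatial_similarity(decomp)
        rank = decomp.rank
        low = 1
        while low < rank:
            past = similarity[low, max(0, low - lookback) : low]
            if float(np.mean(np.abs(past))) < block_threshold:
                break
            low += 1
        # no clutter at all: leading component does not resemble the mean image
        mean_image = np.abs((decomp.u * decomp.s) @ decomp.vt.mean(axis=1))
        c = np.corrcoef(np.abs(decomp.u[:, 0]), mean_image)[0, 1]
        if not np.isfinite(c) or c < static_threshold:
            low = 0
        low = min(low, rank - 1)
        high = rank
    else:
        raise ValueError(f"unknown strategy {strategy!r}")
    if not (0 <= low < high <= decomp.rank):
        raise ValueError(f"invalid cutoffs ({low}, {high}) for rank {decomp.rank}")
    return int(low), int(high)


def svd_filter(stack: FrameStack, low_cut: int, high_cut: int | None = None):
    """Split a stack into (flow, clutter) stacks.

    flow = components [low_cut, high_cut); clutter = [0, low_cut); the
    discarded tail is [high_cut, rank), so flow + clutter + tail = input
    exactly.
    """
    decomp = svd_decompose(stack)
    high_cut = decomp.rank if high_cut is None else high_cut
    if not (0 <= low_cut < high_cut <= decomp.rank):
        raise ValueError(f"cutoffs ({low_cut}, {high_cut}) out of range for rank {decomp.rank}")
    flow = stack.with_frames(decomp.reconstruct(low_cut, high_cut))
    clutter = stack.with_frames(decomp.reconstruct(0, low_cut))
    return flow, clutter


@dataclass
class SNRReport:
    """Flow-to-tissue intensity ratio, mean over the acquisition."""

    s_flow: float
    s_tissue: float

    @property
    def snr_db(self) -> float:
        return 20.0 * np.log10(self.s_flow / self.s_tissue)

    def to_dict(self) -> dict:
        return {"s_flow": self.s_flow, "s_tissue": self.s_tissue, "snr_db": self.snr_db}


def measure_snr(
    flow_stack: FrameStack,
    reference_stack: FrameStack,
    lumen_mask,
    tissue_mask,
) -> SNRReport:
    """20 log10(mean |flow| in lumen / mean |reference| in tissue).

    Intensity is the envelope magnitude, averaged over pixels and frames.
    The masks must be non-empty and disjoint.
    """
    lumen_mask = np.asarray(lumen_mask, bool)
    tissue_mask = np.asarray(tissue_mask, bool)
    if not lumen_mask.any() or not tissue_mask.any():
        raise ValueError("ROI masks must be non-empty")
    if np.any(lumen_mask & tissue_mask):
        raise ValueError("lumen and tissue ROIs must be disjoint")
    s_flow = float(np.mean(np.abs(flow_stack.frames[:, lumen_mask])))
    s_tissue = float(np.mean(np.abs(reference_stack.frames[:, tissue_mask])))
    return SNRReport(s_flow=s_flow, s_tissue=s_tissue)
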