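"""Bundled reference data: the rabbit abdominal-aorta waveform harmonics."""

from __future__ import annotations

from importlib import resources

import numpy as np
import pandas as pd

from .womersley import FlowWaveform

__all__ = ["aorta_waveform_table", "aorta_waveform"]


def aorta_waveform_table() -> pd.DataFrame:
    """Harmonic table (n, f_hz, alpha, vj_ms) of the rabbit aorta waveform."""
    with resources.files("pulseuiv.data").joinpath("aorta_waveform_table.csv").open() as fh:
        return pd.read_csv(fh, comment="#")


def aorta_waveform() -> FlowWaveform:
    """Mean-velocity waveform of the rabbit abdominal aorta (8 harmonics).

    The tabulated magnitudes are stored as real positive coefficients (the
    measured phases were not recorded), which places the systolic peak at
    t = 0 and a mild retrograde dip half a period later.
    """
    table = aorta_waveform_table()
    f1 = float(table["f_hz"].iloc[1])
    mags = table["vj_ms"].to_numpy(dtype=float)
    return FlowWaveform.from_magnitudes(period=1.0 / f1, magnitudes=mags)


def tabulated_womersley_numbers() -> np.ndarray:
    """The alpha column of the bundled harmonic table (j = 1..8)."""
    return aorta_waveform_table()["alpha"].to_numpy(dtype=float)[1:]
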