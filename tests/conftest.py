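import numpy as np
import pytest

from pulseuiv.config import AcquisitionConfig, PhantomConfig, VesselGeometry
from pulseuiv.datasets import aorta_waveform
from pulseuiv.womersley import FlowWaveform, WomersleyModel


@pytest.fixture(scope="session")
def geometry():
    return VesselGeometry()


@pytest.fixture(scope="session")
def aorta_model(geometry):
    """Womersley model of the bundled rabbit-aorta waveform."""
    return WomersleyModel(aorta_waveform(), geometry)


@pytest.fixture(scope="session")
def steady_model(geometry):
    """Steady (Poiseuille) flow with mean velocity 0.3 m/s."""
    wf = FlowWaveform(period=0.3, coeffs=np.array([0.3 + 0j]))
    return WomersleyModel(wf, geometry)


@pytest.fixture()
def rng():
    return np.random.default_rng(20260920)


@pytest.fixture(scope="session")
def speckle_image():
    """A band-limited speckle-like test image for PIV tests."""
    from scipy.ndimage import gaussian_filter

    g = np.random.default_rng(7)
    return gaussian_filter(g.normal(size=(120, 128)), 1.0)


@pytest.fixture(scope="session")
def small_stack(aorta_model):
    """Short noise-free-ish phantom acquisition shared across tests."""
    from pulseuiv.imaging import simulate_sequence

    acq = AcquisitionConfig()
    stack, gt = simulate_sequence(
        aorta_model, PhantomConfig(), acq, n_frames=40, t_start=-0.01, seed=11
    )
    return stack, gt, acq
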