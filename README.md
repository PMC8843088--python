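# pulseuiv

Contrast-free ultrasound image velocimetry (UIV / echo-PIV) for blood-flow
and wall-shear-stress measurement, with a Womersley-flow digital phantom
that provides exact analytic ground truth.

## The problem

Wall shear stress (WSS) — the tangential drag of flowing blood on the vessel
wall, τ_w = µ·∂u/∂y|_{y=0} — modulates endothelial function and marks sites
prone to atherosclerosis, but it is hard to measure. High-frame-rate
plane-wave ultrasound can track native red-blood-cell speckle between
consecutive frames (no microbubble contrast agent needed), yielding 2-D
velocity fields from which the near-wall velocity gradient, and hence WSS,
can be estimated. This package implements that pipeline and the synthetic
study that quantifies its accuracy as a function of blood-speckle
signal-to-noise ratio, scatterer density and radial intensity variation.

## What is inside

| stage | module | method |
|---|---|---|
| ground truth | `pulseuiv.womersley` | inverse-Womersley pulsatile flow: V(t) = Re{Σ V̂_j e^{ijωt}}, Bessel-function harmonic profiles, closed-form wall shear rate |
| phantom | `pulseuiv.phantom` | wall + blood point scatterers, radial intensity laws, analytic advection |
| imaging | `pulseuiv.imaging` | shift-invariant Gaussian-PSF renderer, 3-angle plane-wave compounding at PRF 4500 Hz, calibrated noise |
| clutter filter | `pulseuiv.clutter` | SVD of the space×time Casorati matrix, similarity-based cutoffs, flow SNR metric |
| velocimetry | `pulseuiv.piv` | 3-pass window-deformation cross-correlation (32→8 px, 50% overlap), Gaussian subpixel peak, universal outlier test, 11-frame ensembles, 10-mode POD |
| wall tracking | `pulseuiv.lumen` | contour image, narrow-band Chan–Vese level set, directional peak fitting with leading-edge correction |
| wall shear | `pulseuiv.wss` | Savitzky–Golay-filtered wall-normal profiles, two-point gradient, cycle-aligned waveforms |
| experiments | `pulseuiv.evaluation` | peak-normalised error metrics, Bland–Altman agreement, scatter-property sweeps |

See `docs/methods.md` for the models, parameter choices and limitations.

## Worked example

```python
import numpy as np
import pulseuiv as p

model = p.evaluation.default_model()          # rabbit-aorta Womersley flow
stack, truth = p.simulate_sequence(           # 450 compounded frames = 1 cycle
    model, p.PhantomConfig(), p.AcquisitionConfig(), n_frames=450, seed=1)
result = p.run_pipeline(stack, model.geometry,
                        wall=p.WallTrackConfig(k_top=0.6, k_bottom=0.6))

print(f"post-filter flow SNR : {result.snr.snr_db:5.1f} dB")
print(f"tracked diameter     : {np.mean(result.contour.diameter_m())*1e3:5.3f} mm")
wss = result.wss.frame_means()
print(f"peak |WSS|           : {wss['wss_overall_pa'].abs().max():5.2f} Pa")
```

prints (seed 1):

```
post-filter flow SNR :  35.7 dB
tracked diameter     : 4.002 mm
peak |WSS|           :  7.90 Pa
```

i.e. after clutter filtering the blood speckle sits ~36 dB above the tissue
residual, the level-set/peak-fitting tracker recovers the 4-mm lumen to a
fraction of a pixel, and the estimated peak wall shear stress is close to
the analytic peak of 6.8 Pa for this waveform (µ = 4.1 mPa·s). The
scatter-property sweeps are one call each, e.g.
`p.evaluation.sweep_scatter_amplitude()` returns a table of median
peak-normalised velocity/WSS errors and flow SNR per amplitude level.

A thin CLI wraps the same functions:

```bash
pulseuiv simulate -o stack.h5 --seed 1
pulseuiv filter stack.h5 --auto -o flow.h5
pulseuiv pipeline stack.h5 -o wss.csv
pulseuiv sweep amplitude -o amplitude.csv
```

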