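# Methods

`pulseuiv` estimates 2-D blood velocity fields and wall shear stress (WSS)
from ultrafast plane-wave ultrasound speckle, without contrast agents, and
ships a digital phantom with exact analytic ground truth for validating the
whole chain. This note records the models, the numerical choices, and what
the synthetic experiments do and do not demonstrate.

## Pulsatile flow model

Flow in a rigid, straight, cylindrical vessel of radius R is modelled as
fully developed laminar pulsatile (Womersley) flow of a Newtonian fluid. The
cross-sectional mean velocity is a truncated Fourier series

    V(t) = Re{ Σ_{j=0}^{n} V̂_j e^{i j ω t} },   ω = 2π/T,

and each harmonic's radial profile follows from the axial Navier–Stokes
equation: the steady term is the Poiseuille paraboloid 2V̂₀(1 − r²/R²), and
harmonic j has the Bessel-function shape governed by its Womersley number
α_j = R√(jω/ν), normalised so its cross-sectional mean is exactly
V̂_j e^{ijωt}. The wall shear rate (WSR) is evaluated in closed form from the
derivative of that series at r = R, with the sign convention that forward
centreline flow gives positive WSR; WSS = µ·WSR.

The bundled reference waveform is a rabbit abdominal-aorta mean-velocity
waveform represented by nine harmonic magnitudes (V̂₀ = 0.10 m/s,
|V̂₁| = 0.154 m/s, … |V̂₈| = 0.003 m/s) at f₁ = 3.3225 Hz. The measured
phases were not recorded; the fixture stores real positive coefficients,
which places a sharp systolic peak at t = 0 (peak mean velocity 0.485 m/s,
peak centreline ≈ 0.72 m/s) and a mild retrograde dip half a period later —
a physiologically plausible aortic pulse. The fluid properties are derived
from the tabulated Womersley numbers: a least-squares fit of the nine
printed α values gives α₁ = 4.6422, hence ν = R²·2πf₁/α₁² = 3.875×10⁻⁶ m²/s
and, with ρ = 1060 kg/m³, µ = 4.11×10⁻³ Pa·s. All of these are configurable
(`VesselGeometry`, `FlowWaveform`).

Assumptions inherited from the model: rigid walls, axisymmetric flow, no
radial fluid motion, Newtonian rheology. None of these hold exactly in vivo.

## Digital phantom

The phantom is a 2-D slab through the vessel axis, one elevational
resolution cell thick. Blood scatterers fill the lumen at a configurable
density per resolution cell (default 10), with zero-mean normal base
amplitudes scaled by the flow amplitude factor (default 10) and modulated by
a radial intensity profile (constant, 1 − r/R, 1 − (r/R)², 1 − (r/R)⁴) that
mimics shear-dependent red-cell aggregation as a static weighting. The wall
is a single 200-µm layer of constant-amplitude scatterers (factor 20,
20 per cell). The resolution cell is the −6 dB in-plane point-spread extent
(187.5 × 130 µm² at the defaults). Scatterers advect with the analytic
velocity at their (invariant) radial position, using one forward-Euler step
per transmission; scatterers leaving the lateral domain wrap around with a
fresh amplitude draw to avoid periodic speckle.

## Image formation

A full linear-acoustics simulation is replaced by a point-spread renderer:
each scatterer contributes a separable Gaussian envelope carrying a complex
carrier whose phase depends on the pixel *offset* from the scatterer (axial
pulse-echo carrier at λ = c/f_tx with f_tx = 8 MHz, plus the lateral phase
slope of the steered plane wave). Offset-dependent phase mirrors the
shift-invariant point spread of a delay-and-sum beamformer, so translating
the scatterers translates the complex image — the property the speckle
tracker relies on. Three steered transmissions (−6°, 0°, 6°) at PRF 4500 Hz
are coherently compounded into frames at 1500 Hz; scatterers move between
the individual transmissions, as in a real acquisition.

Pixel pitch is 75 µm lateral × 52 µm axial. The default −6 dB point-spread
widths are 2.5× the pitch so the speckle grain is Nyquist-sampled and
correlation peaks span 2–3 px; a point spread as narrow as one pixel would
alias the speckle and peak-lock the subpixel estimator.

Noise: the acquisition specifies a channel-level SNR of 12 dB relative to
the wall signal. Because the renderer produces beamformed images directly,
this is converted to an image-level target by adding the delay-and-sum array
gain 10·log₁₀(128 elements) and the band-limiting gain
10·log₁₀((fs/2)/ENBW) of the Gaussian receive pulse (fs = 25 MHz), ≈ 41 dB
re wall in total. Complex white Gaussian noise at that level is added per
transmission (equivalently, once after compounding with σ/√3). An
image-level reading of "12 dB re wall" is not tenable: it would put the
noise only ~3 dB below the blood speckle and cap the post-filter flow SNR
near 10 dB, inconsistent with the tens-of-dB flow SNRs this class of
simulation reports at high scatter amplitude.

## Clutter filtering

Each compounded complex (IQ) stack is reshaped into a Casorati matrix (one
flattened frame per column) and filtered by thin SVD: tissue clutter is
spatially coherent and slowly varying, so it concentrates in the leading
singular components; blood speckle spreads over the rest. Filtering operates
on the complex data and the envelope is taken afterwards — filtering
envelope frames instead would move the (positive) temporal mean of the blood
speckle into the clutter component.

Cutoffs can be set manually or automatically. The automatic rule mechanises
the usual manual reading of the spatial-similarity matrix
(|corr| of the spatial singular-vector magnitudes): the clutter block is
grown from component 0 while each next component's mean similarity to the
block stays ≥ 0.6, and component 0 only counts as clutter if its magnitude
correlates (> 0.5) with the temporal-mean image; otherwise nothing is
removed. The high cutoff defaults to the full rank (no noise cut). The flow
SNR metric is 20·log₁₀(mean |flow| in a lumen ROI / mean |flow residual| in
a tissue ROI); on the phantom the tissue ROI is placed outside the vessel
with a 0.4-mm guard from the wall so the measurement is not dominated by
point-spread bleed of the lumen speckle.

## Velocity estimation (echo-PIV)

Iterative window-deformation cross-correlation: three passes with windows
32 → 16 → 8 px at 50% overlap. After the first pass the second frame is
deformed by the bilinearly interpolated predictor field (cubic-spline image
resampling); later passes measure only the residual within ±window/4.
Correlation is mean-subtracted circular FFT correlation normalised by the
window standard deviations; the peak is refined per axis with a three-point
Gaussian estimator (log-parabola, exact for Gaussian peaks), falling back to
a parabolic fit on the raw values when a sample is non-positive. Ties in the
peak search resolve to the smallest displacement magnitude. Zero-variance
windows yield invalid vectors.

Between passes (and once after the final pass, in the pipeline) vectors are
validated by the universal outlier (normalised-median) test on the 3×3
neighbourhood with threshold 1.5 and ε = 0.1 px; flagged vectors are
replaced by the neighbourhood median. Fields are ensemble averaged over 11
consecutive frames (velocity-domain averaging; shrinking window at sequence
edges; a node stays valid where at least half the members were valid) and
finally regularised by truncated POD: u and v of all frames form one
snapshot matrix and the leading 10 modes are retained. For the
150–450-frame sequences used here the Womersley field itself has rank ≤ 17,
so 10 modes keep the main harmonics while discarding most node-level noise.

## Lumen tracking

A contour image is built per frame as smoothed normalised clutter minus
smoothed normalised flow (per-frame min-max normalisation of the envelope,
Gaussian σ = 1.5 px, 3×3 moving average): positive at the walls, negative in
the lumen. A narrow-band two-phase Chan–Vese level set segments it: band
pixels join the region whose mean intensity they match better (threshold
dynamics), a short Gaussian blur of the indicator regularises the interface,
and the signed distance function is rebuilt each iteration; iteration stops
when fewer than 0.1% of band pixels change phase over three consecutive
iterations (cap 500, warm-started frames 80). A final force-weighted
perturbation of the signed distance near the interface gives subpixel
zero crossings. Per-column top/bottom crossings form the wall trace, which
is smoothed across columns (9-column rolling mean — the wall is smooth on
that scale while the raw trace carries pixel-quantised steps).

Directional peak fitting then moves each column's trace outward to the
nearest local maximum of the (3-sample smoothed) clutter intensity within
20 px, with three-point parabolic subpixel refinement of the peak;
displacements are rolling-averaged over 9 columns and scaled by a per-wall
correction factor k before application. In transducer data the leading-edge
physics differs between the near and far wall, hence the published
asymmetric pair (k_top = 1, k_bottom = 0.6), which remains the default for
real data. The symmetric renderer has no leading-edge asymmetry, so the
synthetic studies use a symmetric k calibrated once on dedicated full-cycle
phantom realisations (seeds 997–999, never reused in the studies): k = 0.6
centres the tracked diameter at 3.995 ± 0.004 mm against the known 4 mm.
This mirrors how the published factors were determined empirically. The
outward peak search additionally requires a candidate peak to reach half the
maximum intensity within the search span, so faint speckle bumps of the
clutter residual inside the lumen cannot arrest the search before the wall
echo — essential when a radial intensity profile dims the near-wall blood
speckle.

## Wall shear estimation

For every lateral vector column and both walls, the lateral velocity is
sampled at 20 evenly spaced points over a 1-mm inward normal (defaults), by
linear interpolation along the column's valid vector nodes with a
zero-velocity sample pinned at the tracked wall. The samples (excluding the
pin, so no-slip is not hard-coded into the estimate) are smoothed with a
third-order Savitzky–Golay filter whose window is 0.4× the sample count
(forced odd), and the WSR is the two-point gradient of the two filtered
samples closest to the wall. WSR is median filtered (3-point) along the
wall; WSS = µ·WSR. Multi-cycle recordings are assembled into cycle-aligned
mean waveforms: cycles are segmented at upward zero crossings, resampled to
a common phase grid, circularly shifted so their negative peaks coincide,
and averaged with a standard error per phase bin.

Known limitation: the gradient draws its information from vector nodes
~150–250 µm inside the wall (node spacing 208 µm axially), so the estimate
carries the oscillatory boundary layer's phase lag at that depth — during
rapid deceleration the estimated WSR trails the analytic truth by a few
milliseconds. This is intrinsic to profile-based WSS estimation at this
resolution, not a defect of the implementation.

## Evaluation protocol

Velocity errors are | |v̂| − |v| | per node, normalised by the acquisition's
peak true speed; WSS errors analogous with the peak true |WSS|; angle errors
are absolute vector-angle differences where the true speed exceeds 5% of its
peak (undefined near zero flow). Medians pool nodes and frames (and
realisations). Agreement between waveforms uses Bland–Altman bias ± 1.96 SD
limits, RMSE, and RMSE as a percentage of the reference peak.

The scatter-property sweeps (amplitude 0.1–10, density 0.1–100 per cell,
four radial profiles; non-varied properties at their defaults) each simulate
one full cardiac cycle — 450 compounded frames at 1500 Hz — and run the
complete pipeline with automatic clutter cutoffs. One realisation per level
is used, matching the reference protocol; the pooled medians (~3×10⁵
velocity and ~3×10⁴ WSS samples per level) are stable to well under the
reported differences except where levels are genuinely tied (see below). A
shortened window was considered and rejected: the error medians are defined
over the cycle, and any 0.1-s sub-window over-represents systole, inflating
the peak-normalised WSS median ~2.3× (full-cycle median|WSR|/peak = 0.063;
≥ 0.14 for every 0.1-s window).

What passing these tests shows — and does not. The phantom shares the
speckle statistics, compounding geometry, clutter structure and noise floor
of a real acquisition, so the pipeline's tracking, filtering and gradient
machinery is exercised end to end against exact ground truth. It does not
model wall motion, beam aberration, reverberation, elevational flow,
non-Newtonian rheology or shear-dependent aggregation dynamics (only the
static radial intensity proxies), so absolute in-vivo accuracy will be
worse than the synthetic figures. Because the renderer is also free of
sampling and sidelobe artefacts of a full acoustic simulation, the synthetic
errors at high SNR sit below the reference values rather than matching them
exactly; the study's comparisons are therefore phrased as upper bounds and
orderings. Two orderings are at the resolution limit of the study design:
above ~1 scatterer per cell the density levels are statistically tied
(differences of ~0.1 percentage point), and the r²/linear radial profiles
are similarly close, so the identity of the argmin/argmax among tied levels
can change between realisations.

## Numerical details

- Fourier decomposition of a sampled waveform requires ≥ 2n+1 uniform
  samples; V̂₀ is the time average.
- Bessel functions of complex argument via `scipy.special.jv`; the analytic
  WSR uses the closed-form derivative, validated against Richardson-
  extrapolated finite differences and a 50-digit `mpmath` evaluation.
- The renderer truncates the Gaussian point spread at 3σ; the accumulation
  kernel is numba-jitted with a pure-python fallback.
- Determinism: every stochastic step (scatterer placement, amplitude
  redraws, noise) derives from one `numpy` Generator seeded by the caller;
  identical seeds give bit-identical stacks and pipeline outputs.
- Degenerate inputs: zero-variance interrogation windows, empty scatterer
  regions, all-flat contour images, profiles leaving the lumen and
  sequences shorter than the POD mode count are all flagged or handled
  explicitly rather than raising mid-pipeline.
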