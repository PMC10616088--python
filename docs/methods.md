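# Methods

## The breathing-lung phantom

The phantom is a parametric mouse thorax: a soft-tissue cylinder
(radius 8.2 mm, μ = 0.04 /mm) containing two ellipsoidal lung fields
(semi-axes 6.5 × 3.2 × 3.5 mm each, 0.61 ml envelope pair) and five
rib-like rings at bone attenuation (0.10 /mm).  Breathing is *geometric*:
inside each lung field an air-compartment ellipsoid is rescaled every time
point so that its analytic volume equals the instantaneous air content

    A(t) = V_exp + TV · w(t),

with resting (end-expiratory) volume V_exp = 0.32 ml and tidal volume
TV = 0.15 ml at severity 0.  The geometric model was chosen over uniform
density modulation of a fixed lung region because the volumetric readout of
the gated-CT pipeline is a segmented voxel count: only a phantom in which
the *air compartment itself* changes size makes that count comparable to an
analytic truth.  Attenuation at compartment boundaries is anti-aliased by
2×2×2 supersampled occupancy.

The amplitude waveform w(t) ∈ [0, 1] at breathing frequency f (default
0.7 Hz, the anesthetized-mouse rate) has three limbs per cycle: a linear
rise over the first 2/3 of the inspiration fraction (default 0.3 of the
period), an end-inspiratory pause at the peak, and an exponential
relaxation with rate constant k (default 3.0 /s), normalised as
(e^(−kτ) − w_end)/(1 − w_end) so that the baseline is *attained* at
end-cycle.  Two design points deserve note:

- the end-inspiratory pause exists because amplitude-percentile gating of a
  waveform whose peak is a single instant would reconstruct "inspiration"
  at ~90% of peak amplitude and systematically truncate the tidal volume; a
  brief pause at full inflation is also what pressure-controlled isoflurane
  breathing looks like;
- the normalisation keeps the limb exactly mono-exponential with rate k
  (toward a slightly shifted asymptote), so decay-rate estimators see a
  pure exponential, while end-expiration becomes a reachable state and the
  generator's tidal volume is exactly V_insp − V_exp.

A severity scalar s ∈ [0, 1] models fibrosis: k, TV and V_exp shrink by
60%, 60% and 35% respectively at s = 1, and the parenchymal density rises
by 20% — the directional fingerprint of bleomycin fibrosis (slower
expiration, smaller breaths, denser and less aerated lung).  The exact
coefficients are configuration (`SeverityCoupling`), chosen once to give
clearly separated but overlapping groups; no quantitative claim attaches
to them.

All generators are deterministic given (spec, seed); Poisson photon noise
is optional and seeded.

## XLF metrics

The transmission curve is the mean detector value over a rectangular lung
ROI.  Cycles are detected as prominence-filtered peaks separated by at
least 1/f_max; the cycle baseline is the 10th percentile of the final third
of the cycle (robust to noise floors).  The decay rate is fitted on the
expiration limb — from the peak (skipping any pause plateau) until the
curve first comes within 5% of the baseline — by log-linear regression
after baseline subtraction, refined by nonlinear least squares with the
baseline free.  The refinement is the default because it makes the
noiseless case exact (the percentile baseline is biased upward) and removes
most of the log-domain noise bias; measured bias at 20 dB SNR is under 2%
for k ∈ {1, 2, 4} /s.  Cycles with non-monotone or too-short expiration
windows are excluded and counted, never imputed.  AUC is the trapezoidal
area above zero (a baseline-relative variant sits behind a flag).

On full radiograph pipelines the *fitted* rate is compressed relative to
the generator's k (≈ 2.2 vs 3.0 /s at severity 0) because transmission is
a nonlinear (exponential) function of the air volume; the mapping is
strictly monotone, so within-study contrasts and time courses are
preserved.  This is why the cohort analysis makes directional, not
absolute, claims about decay rates.

## Gated reconstruction and volumetry

The respiratory surrogate is the mean of −log(I/I0) along one detector row
through the lung; a moving-average baseline spanning three breathing
periods (period estimated from the periodogram when not given) removes the
slow angular variation of the anatomy.  The surrogate is an attenuation and
therefore *falls* during inspiration; `as_inspiration_positive` flips it
before percentile gating.  Gating thresholds default to the 80th/20th
percentiles; the volumetry pipeline operates at 85/10, chosen from waveform
arithmetic (mean retained amplitude ≈ 0.98 at inspiration, ≈ 0.06 at
expiration) to place both phase reconstructions close to the breathing
extremes while keeping ≥ 10% of views per phase.

Reconstruction is per-slice parallel-beam filtered backprojection.  The
ramp filter is the DFT of the band-limited real-space Ram–Lak kernel
(sampling |ν| directly biases reconstructed densities low by ~4%), and each
projection is weighted by half its circular midpoint angular spacing, which
is what makes irregular gated subsets reconstruct quantitatively.  The
projector/reconstructor pair is validated against the analytic sinogram of
a uniform disk (density recovered to 0.15%, background bias < 2%) and
cross-checked against `skimage.transform.iradon` on uniform angle sets.

Post-processing follows the standard recipe: subtraction of a reference
slice below the lung to level the background, 3-D Gaussian smoothing
(σ = 1 voxel), then 26-connected region growing from one seed per lung
field at a threshold midway between the air and tissue histogram modes
(mode finding uses a smoothed histogram with a minimum mode separation and
a required inter-mode dip; Otsu or a fixed value are alternatives), and
morphological closing with a ball of radius 2 voxels to bridge vessel-sized
gaps.  Lung volume is voxel count × voxel volume.

Known systematic effects, visible in the validation numbers: Gaussian
smoothing erodes a convex air region by ~σ²κ per surface point (curvature
flow), ~1% of V_insp at 128³ and ~7% at the 48³ cohort grid; amplitude
gating reconstructs slightly inside the breathing extremes.  Together they
put the end-to-end error at −2% for V_insp and −13% for the tidal volume at
128³ — tidal volume is a small difference of two large numbers and
inherits both errors.  Reconstructing without gating misses V_insp by ~22%,
which is the quantitative argument for retrospective gating.

## Plethysmography

The pressure trace is band-passed at 0.5–20 Hz with a zero-phase
(forward–backward) 4th-order Butterworth; padding is extended to ~3/f_lo
seconds because the low corner's long impulse response otherwise distorts
the first and last breaths.  Cycle boundaries are positive-going zero
crossings detected with a hysteresis band of 2% of the signal SD;
within each cycle the running trapezoidal integral is reset, and TV is the
calibration factor times its cycle maximum.  The per-recording summary is a
robust mean (cycles outside median ± 3 MAD are excluded and counted).
Pressure→volume calibration is a user-supplied linear factor; a helper
derives it from a known-volume injection recording (baseline-corrected,
not band-passed, since a one-shot transient would be distorted by the
breathing band-pass).  Temperature and humidity are recorded but no
correction is applied.

One systematic is documented rather than corrected: at 0.7 Hz the breathing
fundamental sits near the 0.5 Hz corner, and the squared magnitude response
of the zero-phase filter attenuates TV by ~5–6%.  This is a fixed
calibration-like factor at fixed breathing rate; it cancels in group
contrasts and correlations, and mid-band recovery (2 Hz) is exact to
< 0.05%.

## Phase retrieval and morphometry

The Fresnel forward model propagates the exit wave
exp(−μt/2 − i·2πδt/λ) with the paraxial transfer function
exp(−iπλz|f|²); Paganin retrieval divides the intensity spectrum by
1 + (δ/β)λzπ|f|² and converts to thickness with μ = 4πβ/λ.  At δ/β = 0 the
filter is the identity and retrieval reduces exactly to −ln(I)/μ.  The
round trip at 23.6 keV, z = 150 mm, 2 µm pixels and δ/β = 100 recovers a
smooth blob's thickness to well under 1% RMSE of peak away from edges.  A
band-limit guard rejects distances at which the propagator phase would
alias at the sampling in use.

Cube morphometry thresholds a cubic ROI (Otsu by default) into air and
tissue.  The interface area comes from a marching-cubes mesh at level 0.5
computed on a σ = 1 voxel Gaussian-smoothed copy of the binary mask:
meshing raw binary labels produces faceted staircase surfaces that
overestimate smooth interfaces by several percent, while the smoothed field
restores sub-voxel interface positions (the level set of the smoothed
indicator shifts only by ~σ²·curvature, negligible for the sphere sizes
used).  Surfaces cut by the ROI boundary are left open, not capped, so a
flat half-space interface recovers SA:V = 2/mm in the unit cube.  Against
the closed forms for a single air sphere (r = 0.4 mm in a 1.75 mm cube) the
measured air ratio and SA:V are within 0.5% at 256³ and move by < 0.1%
under 2× voxel refinement.  Random non-overlapping cube placement inside a
mask is seeded rejection sampling.

## The synthetic study

The standard cohort is 3 arms × 5 animals × 4 days (0, 7, 14, 21).
Severity trajectories: healthy 0 throughout; vehicle 0 → 0.50 → 0.65 →
0.55 (peak fibrosis with mild late self-resolution); treated 0 → 0.50 →
0.20 → 0.12 (recovery beginning one week after treatment start).  Animal
realism enters through three seeded effects chosen a priori: a persistent
per-animal volume-scale factor (6% SD, log-normal) shared by the CT and WBP
ground truths (body-size scaling — this is what generates the within-arm
V_insp–TV correlation in the *healthy* arm, where severity does not vary);
a persistent severity offset in the bleomycin arms (4% SD response
heterogeneity); and a per-session tidal-volume jitter (3% SD) common to the
simultaneously acquired CT and WBP, emulating a combined acquisition set-up.

Problem sizes are the package's own scale choices: cohort CT at 48³ with
240 views over 270 s, XLF series of 84 frames at 14 fps with Poisson noise
at 5·10⁴ photons, WBP traces of 30 s at 1 kHz with 15%/10% drift/noise,
and three 96³ morphometry cubes per day-21 animal; the single-phantom
volumetry validation runs at 128³ with 400 views.  Gated projection sets
quantise the breathing amplitude into 32 levels so that views sharing a
state can be batched through the slice-wise Radon transform (worst-case
volume error TV/64; `state_bins=None` disables this).

## What the phantom does and does not show

The generators emulate the *structure* of the measurement problems —
Beer–Lambert transmission, many-breath rotational sampling, drifting noisy
flow signals, porous two-phase microstructure — with exactly known truth,
so passing tests demonstrate that each estimator recovers what it claims
from data of that structure, at the stated noise levels, and that the whole
chain preserves group contrasts.  They do not contain cardiac motion,
scatter or beam hardening, detector blur, anatomical variation beyond a
size factor, cone-beam geometry (the rotational model is parallel-beam per
slice), or calibrated absolute physiology; absolute metric values
(decay rates in 1/s, TV in ml, air ratios) are therefore internally
consistent but not comparable to real animals, and the cohort analysis
asserts orderings, time courses and correlations only.

## Degenerate inputs and numerical conventions

Flat curves yield empty cycle lists with a warning; zero-variance breathing
signals, single-phase cubes, non-bimodal histograms under the midpoint
policy, seeds above threshold, overlapping or out-of-bounds spheres,
sub-Nyquist frame rates, short rotations (< 10 breaths) and non-normalised
phase-contrast inputs all raise `ValueError` with an explanatory message.
Voxel indices are 0-based (z, y, x) with the rotation axis first; the
reconstruction centre is at index n//2, matching the Radon convention of
scikit-image; volumes are written as float32 multi-page TIFF with JSON
sidecars; 1 ml = 1000 mm³.
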