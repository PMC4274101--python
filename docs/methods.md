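# Methods

This note documents the models behind `cuffmap`, the parameters that matter,
and the choices made where the design was genuinely open.

## Coordinate conventions

All lengths are micrometres unless a name says otherwise.  The longitudinal
coordinate x is expressed in the *cuff frame*: x = 0 at the cuff's narrow end
(the throat), flow in +x.  A forward cuff (wide end upstream, the
conventional orientation) occupies [−L, 0] with L = 1500 µm; a reversed cuff
occupies [0, +L].  In image stacks, z is depth from the luminal face,
increasing into the wall; voxel indices are 0-based with centres at
(i + 0.5)·spacing.

## Cuff model

The cuff bore narrows linearly from 500 to 250 µm in diameter over its
1.5 mm length.  Where the cuff constrains the vessel, the maximal lumen
follows the bore minus the wall, with wall thickness taken as 10% of the
luminal diameter on each side, so lumen = bore / 1.2 (≈ 208 µm at the
throat).  When fitting the cuff to a reconstructed lumen, the narrow end is
placed at the station of minimum equivalent diameter 2√(A/π) (robust to the
highly non-circular throats real casts show), and the axis runs through the
centreline point one cuff length upstream (downstream when reversed).
Contact stations are reported after correcting cast diameters for 10%
resin shrinkage.

## Synthetic en-face stacks

The generator emulates a half-vessel mounted luminal side down and imaged
en face:

- **Field and sampling**: 0.5 × 5 mm at 3 × 3 µm pixels (the instrument's
  pixel-size limit), 40 z-planes at 2 µm.  The 2 µm z-step keeps the 0–25 µm
  analysis window inside the stack under the curved surface.
- **Luminal surface**: a shallow parabolic sag across the circumferential
  axis (8 µm amplitude) plus a 0.5 µm/mm longitudinal tilt, voxelised onto
  the z grid; the voxelised depth map is the stored surface truth.
- **Uptake truth**: baseline 100 AU plus two smoothed top-hat peaks
  (rectangle of width = cuff length convolved with a 150 µm Gaussian — the
  observed peaks are "about a cuff length" long with no finer structure
  reported).  The upstream peak is centred on the upstream cuff margin, the
  downstream peak 0.5 mm beyond the narrow end, amplitudes 400 and 250 AU
  (many-fold elevation over baseline, upstream > downstream with a window-
  mean ratio near 1.5).  The L-NAME scenario flag sets the two amplitudes
  equal and halves the baseline — an effect-size scenario, not a
  pharmacological model.
- **Tracer channel**: uptake truth × exp(−d/20 µm) below the surface, so the
  in-window maximum at the surface voxel equals the truth exactly when no
  degradation is applied.
- **Autofluorescence channel**: zero above the surface, 20% of baseline
  inside the wall (the relative magnitude is not reported; 20% is an exposed
  parameter), plus high-intensity glare foci (Gaussian blobs, σ = 30 µm,
  3 per margin) at the cuff margins only.
- **Degradations**: a smooth multiplicative x–y sensitivity bias (±10%,
  random low-order cosine pattern), exponential z-attenuation
  (0.01 µm⁻¹), and shot noise (Poisson with unit quantum).  The flat-field
  calibration image is the bias as seen on a uniform slide with 1% pixel
  noise; the attenuation curve is stored exactly.  All randomness flows from
  a single integer seed; regeneration is bit-identical.

Not emulated: the optical point-spread function, refraction, scattering,
vessel-to-vessel biological variability of uptake, tissue deformation during
mounting, and registration error between segments.  Passing tests therefore
demonstrate correctness of the measurement chain, not robustness to every
degradation of real microscopy.

## Uptake quantification

Flat-field correction multiplies every z-plane by mean(calibration)/calibration
(mean-preserving for a uniform specimen); z-correction divides each plane by
its gain.  Surface detection thresholds the autofluorescence channel — Otsu
per stack by default (the thresholding algorithm is not specified by the
source workflow; Otsu is parameter-free and reproducible, and a fixed
threshold override is available).  Detection runs on 3×3 median-filtered
planes by default, which suppresses the glare-focus surface errors that
motivated the max-projection readout in the first place.  The projection
takes the maximum over the closed window [0, 25] µm measured from the
detected surface voxel centre.  Circumferential averages carry an `n_pixels`
count per station; stations with under 25% of the circumference present are
reported missing.  The two longitudinal halves of each vessel are averaged
(linear interpolation on the overlap) before any group statistics; group
SEM uses n = mice (sample SD/√n).

## Lumen morphometrics

Cross-sections are resampled at uniform 5 µm arc-length stations in planes
orthogonal to the tangent of a lightly smoothed centreline (25 µm moving
average — the original VMTK-based convention is not detailed).  Area and
perimeter come from the planar polygon; SI = 4πA/P² is clipped to 1 only
within 1e-9.  The maximum inscribed circle uses the GEOS
maximum-inscribed-circle algorithm at a configurable resolution (default
1 µm); the test suite validates it against an exhaustive grid
distance-to-boundary oracle to within one grid cell.

## Hemodynamic post-processing

Bands are half-open intervals [k·40, (k+1)·40) µm anchored at the upstream
end of the mapped domain (the anchor is unstated in the source convention).
The "band minimum" is the mean of the lower-5th-percentile set under the
nearest-rank rule — the ⌈0.05 n⌉ smallest nodal values; with fewer than 20
nodes the set degenerates to the single minimum, so it is always non-empty.
Band means are node-count-weighted (area weighting optional).  Reference
pressure is the band 2 mm (forward) or 3 mm (reversed) downstream of the
throat; subtraction is idempotent.

The quasi-1D surrogate assumes locally fully developed Poiseuille flow:
τ = 32µQ/(πD³), dp/dx = −128µQ/(πD⁴) with D = 2√(A/π), integrated by the
trapezoid rule.  This captures the viscous-dominated behaviour at carotid
Reynolds numbers of order 10 — monotonically falling pressure with no
Bernoulli recovery after the throat, and the D⁻³ shear amplification at the
stenosis — but none of the 3-D phenomena (flow separation, recirculation
bubbles, circumferential WSS variation, the ~300 Pa peak values a
Navier–Stokes solver produces).  Those are outside this package's scope;
surface fields from an external solver can be post-processed through the
same band statistics.

Fluid properties default to µ = 0.004 kg/(m·s), ρ = 1015 kg/m³.  Velocity
bookkeeping: centreline velocities are halved to cross-sectional means
(parabolic profile); anaesthetised velocities scale by 1.05 (minimum
anaesthesia effect), 1.72 (maximum), and a further 1.88 for active animals;
bifurcation flow splits follow Murray's law (r³ weighting).  The worked
Reynolds number in the tests, Re = ρvD/µ = 15.2 at v = 12 cm/s and
D = 500 µm, treats the diameter as an explicit input.

## Doppler envelopes

The generator's beat waveform is a sin² systolic upstroke peaking at 15% of
the cycle, followed by a power-law decay ((1−φ)/(1−φₚ))^q that reaches the
end-diastolic velocity exactly at the beat boundary — making the
pre-systolic boundary the strict within-beat minimum, which is what the
segmenter assumes.  The decay exponent q is solved from a requested cycle
mean when one is given (this is how the measured mean/peak/diastolic triples
are reproduced); default q = 3.  Breathing modulation multiplies the
envelope by 1 + m·sin(2πt/T_b) with one breathing cycle per 10 beats, so
10-beat averages cancel it to within 1%.  Default envelope jitter is 0.5%
multiplicative — the traces analysed are instrument-processed maximum-
frequency envelopes, which are smooth; at this level 10-beat averages stay
within 1% of truth.

Beat segmentation is automated (the original workflow used manual cycle
definition): systolic peaks are detected on a low-pass-filtered copy
(2nd-order Butterworth, 5 harmonics of the expected rate, zero-phase) with
0.6/rate minimum separation, and boundaries are the envelope minima between
consecutive peaks.  Zero-phase filtering can shift the flat pre-systolic
minimum by a few samples (<10% of a beat); on unfiltered noise-free traces
boundaries are exact.  EDV is read at the boundary sample, matching standard
Doppler practice.  Angle correction (v/cosθ) is available but off by
default, since whether instrument velocities are already angle-corrected is
situation-dependent.

## Statistics

Window means span 0.7 mm centred on peak uptake.  Peak centres are the
argmax within one cuff length around the upstream margin and within two
cuff lengths downstream of the downstream margin, with ties broken toward
the cuff and boundary maxima flagged; because the synthetic peaks are
plateau-topped, the pipeline smooths profiles with a 350 µm moving average
before the argmax, which stabilises the located centre under station noise.
Each mouse's windows are centred on its own peaks by default (group-peak
mode available).  The paired test is classical Student's on differences;
the unpaired test uses pooled variance (matching the classical naming), with
Welch optional.  Zero-variance difference vectors are reported as exact
edge cases (p = 0 or 1) with no NaNs.  No multiple-testing correction is
applied — the contrasts are single and planned.

Monte-Carlo calibration of the paired contrast (type-I error 5% ± 1.5% over
2000 null groups; >90% direction recovery at a true window-mean ratio of
1.5, n = 10, CV 0.15) is simulated at the window-mean level with
multiplicative noise matching the pipeline's observed profile variability;
rendering thousands of image-level groups would add cost without changing
what the calibration tests — the t-test's behaviour on window means.

## Problem sizes in the test suite

Unit tests use small stacks (600 × 120 µm) that exercise every code path;
end-to-end pipeline tests use 4800 × 150 µm stacks, which preserve the full
cuff-frame extent (both peaks plus 0.7 mm windows) while keeping a scenario
run under half a minute.  The acceptance script uses full-size
(5000 × 500 µm) default stacks for the uncuffed-CV bound.  These sizes are
the package's own test-design choice; all defaults remain full-size.

## Known limitations

- Peak localisation on plateau-topped profiles is intrinsically degenerate:
  under noise the argmax wanders within the plateau (hundreds of µm), though
  0.7 mm window means are insensitive to this.
- Surface detection near steep circumferential steps can be off by one
  voxel when median filtering is enabled; disable `smooth_surface` for
  voxel-exact detection on clean data.
- The quasi-1D surrogate is a trend model, not a flow solver (see above).
- Mesh slicing assumes a tubular, centreline-orthogonal topology; branching
  geometries (e.g. the bifurcation itself) are not handled.
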