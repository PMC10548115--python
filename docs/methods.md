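# Methods

This note records the models, conventions, and numerical choices behind
`needleoct`, and what the synthetic phantoms do and do not establish about
real tissue data.

## Probe and signal model

The simulated instrument is a swept-source PS-OCT system at
λc = 1310 nm, 50 kHz sweep rate, with the launch polarization alternating
between two states (horizontal and +45°, 90° apart on the Poincaré sphere)
on successive sweeps, so consecutive same-state A-lines are T = 40 µs
apart. Detection is polarization-diverse (two orthogonal channels). The
probe is a bare fiber in a needle: forward-viewing, unscanned, one depth
axis. The fiber end sits slightly recessed behind a thin epoxy window, so
the strong static fiber-end reflection (`tip_pixel`) lies a few pixels
above the tissue-contact surface (`tip_standoff_px`, default 8 px ≈ 15 µm).
This standoff matters: the tip echo is orders of magnitude brighter than
tissue, and without the separation its point-spread leakage into the first
tissue pixels (and tissue leakage into the reference pixel) would bias the
Doppler estimate by 5–10%.

Fringes are synthesized at the wavenumber level so that spectral binning is
a real operation, with K linear-in-k samples per sweep (default 1024). The
depth-pixel pitch in tissue is fixed at 1.87 µm (so 46 pixels ↔ 86 µm);
this pins the sampled k-span. The source envelope is Gaussian, its width
back-calculated from the configured axial resolution (10.6 µm in air,
intensity FWHM); the bandwidth itself is a free parameter of the simulator.
Synthesis places each discrete scatterer at its nearest depth pixel for the
envelope while imprinting the exact carrier phase 4π·n·d/λc for its
instantaneous depth-below-tip d, so per-interval Doppler phase steps are
analytically exact while the speckle pattern reconfigures realistically as
scatterers cross pixel boundaries. A stationary block of A-lines is
rendered once and rotated by the common-mode phase, which keeps long
stationary runs cheap.

## Phantoms

Phantoms are layered stacks of discrete reflectors (mean spacing 10 µm,
log-normal amplitudes, uniform phases) with per-layer reflectivity,
attenuation (single-pass amplitude exp(−µz)), birefringence Δn, and optic
axis. Polarization transport is by Jones matrices: each layer is a linear
retarder, one-way matrices compose multiplicatively along the path, and the
round trip is M = JᵀJ (transpose-symmetric by reciprocity). This same
transport is the test oracle: the cumulative retardation at depth z below
the reference is the SU(2) rotation angle of M, wrapped to [0, π], and the
axis is the azimuth of its rotation axis in the Q–U plane, halved.

Three presets mirror the experimental archetypes:

* **salmon** — five birefringent "muscle" layers (700 µm, Δn = 1×10⁻³,
  common axis) alternating with four non-birefringent "connective" layers
  (450 µm): retardation contrast.
* **shrimp** — three equally birefringent muscle layers (1600 µm,
  Δn = 1×10⁻³) with axes −50°/0°/+50°: axis contrast.
* **spine** — skin (weakly birefringent), subcutaneous fat (isotropic),
  three strongly birefringent ligament layers, terminated by a
  low-scattering void whose occupancy boosts the tip reflection ×5
  (index mismatch at the uncovered tip): the epidural archetype.

Layer thicknesses and optical parameters are plausible round numbers for
these tissues, chosen once; Δn ≈ 10⁻³ is typical of oriented muscle. A
static random unitary can be applied at launch and return (`fiber_jones`)
to emulate the fiber lead; tests use it to verify that retardation is
similarity-invariant and the axis only acquires a global offset.

Noise comprises additive detector noise (scaled to the tissue signal, not
the tip-dominated raw fringe), per-A-line common-mode phase glitches
("laser jitter", default magnitude 3 rad > the 2.5 rad gate), and slow
common-mode drift (0.5 rad/s). Motion profiles are piecewise linear and are
validated to stay below the 4.7 mm/s gate velocity, as in the experiments.

## Reconstruction and polarimetry

Reconstruction apodizes the fringe, FFTs wavenumber → depth, and keeps the
positive-delay half. Five equal-width Hann windows with 50% overlap are
laid over the *occupied* source band (envelope ≥ 5% of peak) — laying them
over the full digitized span would leave the outer bins without signal.
Per bin and per launch-state pair, Stokes vectors are formed from the two
detection channels, smoothed axially over 3 pixels on the unnormalized
components (intensity-weighted averaging against polarization speckle), and
the rotation taking the reference pair (at the tip reflection) to the pair
at depth z is fitted symmetrically: both measured states and their cross
product form an observation triad, and the matrix Σᵢ tᵢrᵢᵀ is projected
onto SO(3) by Löwdin orthogonalization (three Newton–Schulz iterations).
The one-sided triad construction was rejected because it dumps all
measurement inconsistency into the second state, making the error depend on
the fiber orientation. Per-bin retardation and axis are combined by
circular means on doubled angles; retardation at the reference pixel is
zero by definition; axis and retardation are masked where intensity is
within 5 dB of the noise floor or retardation is below 0.05 rad. A
degenerate reference (parallel launch states) flags the mask rather than
raising.

Polarization speckle limits any single A-line: with ~1 scatterer per
resolution length, the speckle-weighted mixture of Jones matrices inside a
PSF is slightly non-unitary, and the best-fit rotation at a single pixel
scatters by ~0.1–0.2 rad. The estimator therefore quotes circular
time-averages; a moving needle decorrelates speckle at a fixed
depth-below-tip (fresh scatterers every PSF length of travel), and
averaging over ≥0.5 mm of travel brings the retardation error to a few
mrad and the axis error below 1°.

## Doppler odometry

Exactly the narrative order of the method: per-depth wrapped phase
difference of one launch state (channels combined phase-coherently,
power-weighted) → zero samples with |Δφ| > 2.5 rad → causal sliding median
over the past 72 intervals per depth pixel (growing prefix windows at
start-up, so tracking begins at t = 0; the gate's zeros are left in the
median population, whose robustness is the point) → subtract the phase at
the tip pixel → mean over the 46 pixels below the contact surface →
v = λcΔφ/(4πnT), d = λcΔφ/(4πn), p = Σd. Gating is on |Δφ|: retraction
produces negative steps of equal physical meaning. n is fixed at 1.37
(muscle); in adipose tissue (n ≈ 1.46) displacement is overestimated by
n_fat/1.37 − 1 ≈ 6.6%, cancelling on retraction. The causal median imposes
a known lag: at an instantaneous velocity reversal the output holds the old
value for ~(window/2) intervals, which shows up as a deterministic closure
offset of 2·v·T·window/2 (≈1.75 µm at 0.62 mm/s) — inherent to the causal
chain, not a defect of the implementation.

The exact median (mean of the two central order statistics for even
windows) is computed with a pair of rank filters; origin handling is tested
against a brute-force sorted-window oracle.

## Visualization

The needle-referenced map is verbatim concatenation. The surface canvas
quantizes the tracked tip depth to rows (nearest-row rounding; the
quantization is one row), writes the current A-line from the tip row down,
and copies shallower rows forward — the frozen record of traversed tissue.
On retraction, rows above the (shallower) tip stay frozen and re-exposed
rows below it resume updating. Mirroring about the needle axis is applied
at render time only; the canvas is single-sided. Frames are PNG via
imageio; video encoding is out of scope.

## Problem sizes

Full experimental scale (e.g. 13 s at 50 kHz ≈ 3×10⁵ same-state intervals)
is supported but unnecessary for verification; the shipped tests and the
acceptance script use:

* displacement recovery: a tenth-scale traverse (0.4 mm peak, 0.65 s each
  way) at the full experimental speed and 40 µs clock — decimating the
  clock instead would push the per-interval phase step over the gate;
* jitter immunity: the full 10 s (2.5×10⁵ intervals) with a 128-sample
  sweep and shallow depth window;
* archetypes: ~2.8–3 s traverses (≈1.4×10⁵ A-lines) with 384-sample sweeps,
  polarimetry on every 16th state pair.

## Limitations

One-dimensional probe: no lateral scanning, no beam profile beyond a
radial amplitude roll-off. No polarization-mode dispersion is simulated, so
spectral binning is exercised structurally but its PMD benefit is only
checked as variance reduction. No tissue mechanics (deformation, hole
closure, retraction SNR asymmetry), no depth-resolved (local)
birefringence, no absolute axis calibration through the fiber, no phase
unwrapping beyond (−π, π]. Passing tests on these phantoms demonstrates
the correctness of the processing chain against a known optical model, not
the biological variability of real tissue.
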