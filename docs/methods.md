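# Methods

`pradstack` reconstructs super-resolved water-equivalent-thickness (WET)
radiographs from single-event proton radiography (pRad) data by focus
stacking a series of distance-driven-binned (DDB) projections, and reads the
per-pixel focal depth as an estimate of each feature's radiological depth.
This note records the models, the parameters that matter, and the choices
made where the design was open.

## The imaging model

In single-event pRad every proton is measured individually at two ideal
tracker planes bracketing the object: transverse position (t, v), direction
(as slopes dt/du, dv/du with u the beam axis), and kinetic energy before and
after. The water-equivalent path length of each proton is obtained from the
energy loss,

    WEPL = R(E_in) - R(E_out),

with R the residual range in water. A DDB projection at depth u bins each
proton into the image pixel containing its estimated lateral position at u
and assigns the pixel the mean WEPL of its events. Because multiple Coulomb
scattering (MCS) makes the trajectory uncertain between the trackers, the
spatial resolution of a DDB image is best for features located near the
binning depth; a stack of DDB images at many depths therefore contains, for
each feature, a plane of focus.

Focus stacking collapses the stack per pixel:

    f_fs[i,j] = f^{n*}[i,j],   n* = argmax_n | (L * G * f^n)[i,j] |

where G is a 5x5 Gaussian blur (default sigma 1 px) that suppresses noise
oversampling, L a fixed zero-sum 5x5 Laplacian kernel, and the per-pixel
|Laplacian|-versus-depth profile is smoothed with a Savitzky-Golay filter
(default window 11 planes, order 3) before the argmax. The FS image samples
the *raw* stack at the selected plane, so neither convolution touches the
reported WET values. The depth of the selected plane, mapped over the image,
is the focal-depth map; the median focal depth over a small ROI straddling a
feature edge estimates the feature's radiological depth.

## Transport model (synthetic data)

The bundled Monte Carlo simulator generates list-mode data with the
statistical structure this method exploits, at desk scale. It is a
condensed-history model, not a general-purpose physics engine:

* **Energy loss**: Bragg-Kleeman range-energy relation R(E) = alpha E^p with
  alpha = 0.022 mm/MeV^p, p = 1.77 (water), scaled by the local relative
  stopping power (RSP). Stepping updates the residual range by the
  water-equivalent step, which makes a deterministic ray's WEPL equal the
  RSP line integral exactly (no Euler drift).
* **Straggling**: Bohr model, variance rate 0.0087 MeV^2/mm scaled by local
  RSP. An energy fluctuation dE at depth x persists to the track end as a
  residual-range shift dR/dE(E(x)) dE, so the variance is accumulated in
  range space with the local dR/dE weight and applied as one Gaussian draw
  at the rear face — statistically identical to per-step energy kicks for
  this Gaussian model, and cheaper. For 200 MeV through 20 cm of water this
  gives a per-proton WEPL sigma of about 2.5 mm.
* **Scattering**: Highland formula per 1 mm step,
  theta_0 = 13.6 MeV/(beta c p) sqrt(x/X0) (1 + 0.038 ln(x_cum/X0)), with
  X0 = 360.8 mm (water), the logarithmic correction evaluated on the
  *cumulative* water-equivalent depth of the proton (bracket floored at 0),
  and the step's scattering power scaled by the local RSP. Direction kicks
  are applied at the end of each step after the position advance.
* **Beam**: pencil-beam scanning — square spot grid (3 mm spacing) covering
  the field, Gaussian spots (3 mm sigma), Gaussian divergence (2 mrad),
  source on the front tracker plane. Standard study conditions: 10x10 cm^2
  field, 200 MeV, 10^7 primaries.
* **Nuclear interactions are not modeled.** Instead an explicit synthetic
  outlier channel (default 2% of events in the study configuration) shifts
  WEPLs upward by 10-20 straggling sigmas, exercising the downstream
  3-sigma filters the way nuclear-contaminated events would.
* **Scorers are ideal**: exact positions, directions and energies at the
  tank faces; no material budget or pixelation.

Protons whose residual range is exhausted inside the phantom are excluded
and counted. Transport is vectorized over events (chunked at 2x10^6), uses a
clamped nearest-voxel RSP lookup at the step midpoint (positions outside the
lateral grid clamp to the border voxel; the standard phantom is much wider
than the field, so this is unreachable in practice), and is byte-reproducible
for fixed seeds.

### What the simulator does and does not emulate

It reproduces the mechanisms focus stacking relies on — depth-dependent MCS
blur, tracker-exact endpoints, straggling-dominated WET noise, and gross
outliers — so resolution-versus-depth behavior and the relative FS/DDB
comparisons are meaningful. It does not reproduce Moliere/nuclear-elastic
scattering tails, Vavilov straggling tails, or secondary production, all of
which broaden real edge responses and inflate per-proton WET noise in a
full physics engine. Consequently the absolute resolution of cubes close to
a tracker (where the model's trajectory uncertainty is nearly zero and the
erf fit resolves the pixel-aperture floor) and the absolute noise level come
out *better* than full-physics Monte Carlo (e.g. Geant4) simulations of the
same setup produce; passing tests demonstrate correct
method behavior under the stated Gaussian model, not absolute agreement
with full nuclear-physics transport.

## Phantom

20x20x20 cm^3 water tank (RSP 1) with five 1 cm bone cubes (RSP 1.27,
2.7 mm WET excess per full crossing), proximal faces at radiological depths
10/50/100/150/190 mm, staggered 20 mm in both transverse directions along
the image diagonal, tilted 2.5 degrees about the beam axis (which is what
makes slanted-edge analysis possible on every cube face). Default voxel
size 0.5 mm. Transverse boundary voxels carry the partial-volume RSP
(area fraction on an 8x8 subgrid): a center-sampled mask on a lattice
commensurate with the 0.5 mm image grid would turn the tilted faces into
pixel-aligned staircases and remove the pixel-aperture component of the
edge response that continuous geometry produces. The cubes' axial faces
align exactly with voxel boundaries, so a deterministic interior ray keeps
the exact 202.7 mm WET.

## Path estimate

Per event and transverse axis, a cubic Hermite interpolant on the
normalized depth s in [0, 1]: endpoint values are the measured tracker
positions, endpoint tangents the measured slopes times the tracker
separation, optionally scaled by lambda0/lambda1 (default 1.0 — the plain
Hermite spline; the optimized tangent scalings from the cubic-spline-path
literature can be set in the `[path]` config section). Depth is
parameterized geometrically, not in water-equivalent units; for this
water-dominated phantom the two coincide to within ~1%.

## Reconstruction and data cuts

Images use 0.5 mm pixels on a 110x110 mm grid (field plus margin); the
stack spans [u_front, u_rear] at 1 mm steps (201 planes for the 20 cm
tank). Two cuts:

1. a global 3-sigma cut on the relative angle (magnitude of the
   exit-minus-entry direction vector) over the whole field, applied once;
2. a per-pixel 3-sigma WEPL cut at binning time, single pass (mean/std of
   the pixel population, discard, recompute the mean), applied
   independently per plane because pixel membership changes with depth.
   Zero-variance pixels keep all events.

The per-pixel cut is deliberately not iterated to convergence; with the
outlier channel at +10 sigma or more, a single pass removes every injected
outlier (the inflated first-pass std still puts the cut threshold well
below +10 sigma). Pixels with zero accepted events are invalid and carried
as NaN with a mask, never zero-filled. Binning uses half-open pixel
intervals; an event exactly on a boundary goes to the higher-index pixel.
The binning hot path evaluates splines in float32 (sub-micrometre position
error, irrelevant at 0.5 mm pixels) for speed.

## Focus stacking parameters

The Gaussian sigma (1 px), the Laplacian kernel (fixed
LoG-style 5x5, zero-sum enforced at load), and the Savitzky-Golay window
and order (11 planes, cubic) are configurable under `[fs]`; the defaults
were chosen once as reasonable smoothing scales for 1 mm plane spacing and
are used for all reported numbers. Argmax ties break toward the shallowest
plane, making output deterministic. A pixel invalid at its best plane falls
back to its best *valid* plane; a pixel invalid everywhere stays invalid.
The smoothed profile drives the argmax; the raw stack supplies the value.

## Image quality analysis

Slanted-edge MTF: pixel centers in an oriented band across a cube face are
projected onto the edge normal (known from the phantom geometry), pooled
into 0.1 mm bins to form an oversampled ESF; the four faces of each cube
are polarity-aligned and averaged bin-wise; a least-squares error-function
fit yields the edge width sigma, and the Gaussian-LSF closed form gives

    MTF(f) = exp(-2 pi^2 sigma^2 f^2),   MTF10% = sqrt(ln 10/(2 pi^2))/sigma.

The closed form is the exact continuum limit of the fit-differentiate-
Fourier chain and is what all reported MTF10% values use; a discrete-FFT
cross-check on the raw ESF is provided. MTF10% may legitimately exceed the
pixel Nyquist frequency (1 lp/mm at 0.5 mm pixels) because the slanted edge
oversamples; an optional Nyquist cap is off by default. Noise is the
standard deviation of valid pixels in a homogeneous 25x25 mm^2 water ROI
centered at (30, -30) mm, far from all cubes.

## Depth detection

For each cube, a 20x4-pixel ROI centered on the bottom (lowest-v) face
collects the per-pixel focal depths; the median is the depth estimate and
the interquartile range its spread. Only regions with a WET gradient carry
depth information — homogeneous ROIs return spreads covering a large part
of the depth range by design. Estimates are invariant under a constant WET
offset applied to every plane.

## Numerical and reproducibility choices

* Master seed in the run config; the beam and transport seeds derive from
  it. All randomness flows through `numpy.random.default_rng`; identical
  seeds give byte-identical phase-space files and pipeline outputs.
* Degenerate inputs: empty event sets, non-positive energies, out-of-span
  depths, non-finite records, even-sized smoothing windows and non-zero-sum
  Laplacian kernels are rejected with explicit errors; records violating
  e_out <= e_in or carrying non-finite fields are dropped on file read with
  a logged count.
* Problem sizes: the standard study uses 10^7 primaries (about 7 minutes
  end-to-end on one CPU); reduced-statistics runs at 5x10^6 and 10^6
  primaries populate the noise ladder. Multi-seed depth-recovery checks run
  at 5x10^6-10^7 per seed — the fluence range in which the FS image is
  usable; at 10^6 the pixel-wise Laplacian is noise-dominated and depth
  inference fails by design. Unit and property tests use phantoms and event
  counts small enough to run in seconds.

## Known limitations

* Gaussian-only scattering and straggling: no Moliere/nuclear tails, so
  absolute edge widths near the trackers and absolute noise undershoot
  full-physics simulations (see above); relative comparisons (FS versus
  DDB, depth ordering, noise scaling with fluence) are the robust outputs.
* The shallow 50 mm cube's depth is systematically underestimated — the
  same qualitative bias the depth-from-focus approach shows in full-physics
  studies; it is reported but not corrected.
* Geometric (not water-equivalent) depth parameterization limits use to
  water-like objects.
* The MLR reconstruction baseline, patient CT geometries and 4D/motion are
  out of scope.
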