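# Methods

`fovlfm` models a compact foveated light-field imager: a concave hexagonal
array of seven logarithmic-axicon lenslets sharing one CMOS sensor, whose
seven elemental images are computationally refocused into a volume with
three concentric acuity zones (peripheral / blend / foveated). This note
records the model, its assumptions, the parameters that matter, and the
design choices made where the published description left the design open.

## Optical model

**Geometry (chief rays).** Each lenslet is an ideal pinhole at its vertex.
The central lenslet sits at the origin with its axis along +z; six ring
lenslets at radius 370 μm (60° spacing) are tilted inward by 7.057° so all
seven axes cross the central axis near z = 3 mm (the best-fit common point
is at ring_radius / tan(tilt) = 2.989 mm; the printed tilt is not exactly
arctan(370/3000), and both the tilt and ring radius are configurable). The
sensor lies 3 mm below the lenslet plane. Projection of an object point
(x, y, z) through lenslet p is the straight line through the vertex:

    s = p + (d_s / z) · (p − q),      m(z) = d_s / z,

inverted and scaled by the pinhole magnification m(z) (exactly 1 at the
3 mm axis intersection; depth-averaged 1.0397 over 2–4 mm). A single 600 μm
field stop above the array bounds each lenslet's object-side visibility to
a disk of diameter a·z/h centred at p·(1 − z/h) — the analytic form behind
the field-of-view windows, their linear scaling with depth, and the
overlap-count zones.

**Stop height.** The stop's height above the lenslets is not a published
quantity, but it controls both the zone diameters and whether the seven
elemental footprints overlap on the sensor. The default is h = 2.0 mm: at
1.5 mm the footprints (radius a/2·d_s/h) would overlap, defeating the
stop's purpose, while at 2.0 mm they clear each other by ~25 px and the
depth-averaged foveated diameter lands near 0.55 mm, consistent with the
~0.6 mm design figure.

**Zones.** The shading map counts, per reconstructed pixel, how many
translated lenslet footprints cover it. Zone labels partition the field:
foveated (count ≥ 6), blend (3–5), peripheral (1–2), outside (0). The
published description assigns "≤ 3" to peripheral, which collides with
blend's "3–5"; we resolve the boundary to disjoint intervals (peripheral
1–2) and expose both thresholds in the config. We count all seven
footprints; a shading map topping out at 6 would correspond to excluding
the central element from the count, which we do not do.

**Diffraction.** Lenslets carry a logarithmic-axicon phase with the
quadratic radius-to-focus mapping

    f(r) = f_min + (f_max − f_min) · r²/R²,
    φ(r) = −(k/2α) · ln(1 + α r²/f_min),   α = (f_max − f_min)/R²,

which integrates the local focusing condition dφ/dr = −k r / f(r) and
reduces to the paraxial spherical phase as f_max → f_min. Central lenslet:
f ∈ [1250, 1750] μm (object conjugates 2.14–4.20 mm at the 3 mm sensor
distance — the ~2 mm detection range); ring lenslets: [1500, 2000] μm.
Fields propagate by the band-limited angular-spectrum method (evanescent
components dropped, transfer clipped at the Matsushima sampling limit);
object points are diverging spherical waves sampled at the lens plane.
Default characterization wavelength 635 nm; grids 2048² with a 2× aperture
guard band for headline numbers, 512–1024² in tests (results are
grid-converged at 512 for the quantities we report). The field stop never
clips the on-axis cone for z ∈ [2, 4.2] mm, so the diffraction path omits
it. A tabulated phase override is accepted wherever a `PhaseProfile` is,
since the exact fabricated profile is a design unknown.

## Synthetic data

The phantom generator reproduces the physical characterization targets:

- a 2.5 μm on-axis bead stepped through 2–4 mm in 100 μm steps (the
  calibration stack);
- three layers of 15.4 μm beads, 170 μm apart (one coverslip), beads
  placed uniformly with a two-diameter minimum separation, seeded;
- a planar 100 μm-pitch grid target at a chosen depth;
- the white-light aperture frame: one anti-aliased disk per elemental
  footprint (radius a/2 · d_s/h at centre p·(1 + d_s/h)).

Rendering projects every emitter through every non-occluded lenslet and
stamps a point-spread function carrying the emitter's full intensity per
visible lenslet. The default stamp is a Gaussian whose width is the
scalar-diffraction core FWHM computed exactly at the emitter's depth
(memoized per profile and depth — interpolating widths across the focal
range's conjugate boundaries is unsafe, as the core width jumps by factors
of several there), broadened in quadrature by the magnified bead diameter
(disk ≈ Gaussian with σ = m·d/4). The full wave-optics kernel path
(`psf_source="wave_optics"`) stamps the actual diffraction PSF. Noise is
Poisson shot noise (variance mean/photon_scale) followed by Gaussian read
noise and an offset, clipped at zero, all seeded.

What the generator does *not* emulate: the out-of-focus halo around the
Gaussian core (the fast path keeps core width but not halo energy),
partial vignetting near the stop edge (occlusion is binary per chief ray),
Bayer sampling, chromatic spread, and scattering. Passing tests therefore
validate the geometry, calibration and reconstruction logic under an
idealized PSF; they do not certify contrast or SNR behaviour on real,
scattering samples.

## Calibration

Aperture segmentation: Otsu (or fixed) threshold, connected components,
minimum area 100 px, labels ordered centre-first then counterclockwise
from +x. PSF localization: per footprint, background floor = median +
3·MAD; the spot is the smoothed intensity peak, and its position the
intensity-weighted centroid within a 48 px radius of that peak, keeping
pixels above max(10% of peak, 5·MAD) — the windowing keeps diffuse noise
over the ~3·10⁵-pixel footprint from biasing wide spots. On noiseless
frames this localizes to <10⁻³ px of the projection oracle.

Translation curves map depth to the shift registering each edge element to
the central one (centre − edge centroid). Three models:

- `linear` (default of the fit function): one least-squares line per
  lenslet and axis, the literal reading of the published fit. Because the
  true parallax is affine in 1/z, this line carries a ~11 px RMS residual
  over 2–4 mm (reported with the model) and scales depth *differences* by
  0.84–1.16× across the range;
- `piecewise` (default of the pipeline): linear interpolation through the
  measured shifts at the 100 μm calibration steps — the other reading of
  "translation distances at unsampled depths are interpolated" — exact to
  ~0.25 px and metrically faithful, which bead-layer separation recovery
  requires;
- `inverse`: a + b/z, the pinhole closed form (residual ~10⁻³ px).

Magnification is parametric (m(z) = d_s/z) or tabulated from measured
grid-pitch ratios, interpolated linearly in 1/z.

## Reconstruction

Five stages: (1) rolling-ball background subtraction (skimage's exact
algorithm; large frames use an ImageJ-style downscale ≈ radius/12 with
bilinear background upsampling); (2) aperture-mask segmentation into seven
elemental images; (3) shift-and-add refocusing per depth, bilinear
sub-pixel translation (windowed translation makes region-of-interest
sweeps O(window)); (4) shading-map zone classification plus a feature mask
from the central element (local-mean adaptive threshold with a small
absolute floor — the running-sum mean filter leaves ±10⁻¹³ debris in empty
regions — then morphological opening, disk radius 2) that zeroes
blend+foveated voxels absent from the central view, suppressing
cross-lenslet collision ghosts; the peripheral zone is never
feature-masked; (5) per-layer rescale by m(z_ref)/m(z) about the frame
centre to a uniform object-space pixel (reference: the depth where m = 1).

**Depth from focus.** `estimate_depth` scores a focal stack (variance of
Laplacian by default; Tenengrad and peak intensity selectable) and refines
the arg-max with three-point parabolic interpolation, ties toward smaller
z. `autofocus` is the robust protocol for full frames: each refocused
layer is scored only inside the eroded fully-overlapped region (shading
count = 7), after a σ = 1.5 px Gaussian pre-smooth. Restricting to this
region is essential: the hard elemental-footprint rims sweep across the
field as the refocus depth changes and otherwise dominate the Laplacian
variance; pre-smoothing removes the dependence of refocused *noise*
variance on the fractional part of the bilinear shift.

## Problem sizes and numerical choices

Headline quantities are computed at: EDOF ratio — 2048² fields, 25 μm
object-depth steps over 1.8–4.5 mm; autofocus — full 5 MP frames, 25 μm
refocus steps over 2–4 mm, target depths 2.15/3.85 mm (symmetric about the
axis intersection), Poisson noise at peak SNR ≈ 14, five seeds; axial
response of the reconstructed point — 25 μm steps. The test suite uses
512–1024² grids and coarser sweeps of the same procedures. Half-maximum
widths and FWHMs are linearly interpolated at threshold crossings.
Refocusing at depths outside the calibrated range is flagged, not refused.

## Known limitations

- The extended-depth-of-focus *ratio* measured by a half-maximum
  focus-score criterion on this idealized profile is ~2.5–4 depending on
  criterion, well short of the ≥6-fold figure the hardware achieves; the
  half-max of a quadratic sharpness score is a conservative width measure
  (the ray-optic span/DOF ratio for the same geometry is ~12), and the
  fabricated profile differs from the adopted closed form in unpublished
  ways. The criterion and thresholds are exposed, not tuned.
- With the printed ring-lenslet focal range (1.5–2.0 mm) their sharp
  conjugate span begins near z ≈ 3 mm; at nearer depths the edge views
  keep a sharp diffraction core but lose halo energy, which the Gaussian
  render path does not represent.
- Pure translation registration only (no per-lenslet rotation/affine), no
  wave-optics deconvolution, no scattering model, monochrome radiometry.
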