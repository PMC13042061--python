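# fovlfm — foveated light-field compound imaging, simulated end to end

`fovlfm` is a forward simulator and reconstruction pipeline for a compact
bioinspired imager: seven logarithmic-axicon lenslets in a concave
hexagonal array (one on-axis, six tilted inward by 7.057° so their optical
axes converge 3 mm above the array) share a single CMOS sensor. Each
lenslet forms its own *elemental image*; together the seven views sample
the light field, so a single camera frame supports synthetic refocusing
and volumetric reconstruction of fluorescent specimens over a ~2 mm depth
range, with three concentric acuity zones — *peripheral* (wide 2D
context), *blend* (moderate parallax), and *foveated* (all seven views
overlap; full 3D acuity).

The package is aimed at computational-imaging researchers who want to
study or extend this architecture without hardware: every published
processing step is implemented against a physically explicit synthetic
scene model, so ground truth is always available.

## What is modelled

- **Geometry** (`array_model`): pinhole projection through the tilted
  array, thin-lens conjugates, magnification m(z) = d_s/z, and the
  field-stop visibility windows whose overlap counts define the zones.
  The lenslets have NA = sin(arctan((D/2)/f)) ≈ 0.105 (D = 370 μm,
  f = 1.75 mm) and the central focal range 1.25–1.75 mm maps through
  1/u = 1/f − 1/d_s to an object-side detection range of 2.14–4.20 mm.
- **Diffraction** (`wave_optics`): the logarithmic-axicon phase
  φ(r) = −(k/2α)·ln(1 + α r²/f_min) with the quadratic radius-to-focus
  mapping f(r) = f_min + Δf·r²/R², band-limited angular-spectrum
  propagation, axial responses, extended-depth-of-focus metrics, and
  depth-dependent PSF kernels.
- **Phantoms** (`phantoms`): seeded bead layers (15.4 μm), PSF
  calibration stacks (2.5 μm bead, 100 μm steps), grid targets, the
  white-light aperture frame, and a Poisson + read-noise model.
- **Calibration** (`calibration`): aperture segmentation, sub-pixel PSF
  localization, per-lenslet translation-versus-depth curves (global
  linear fit, piecewise interpolation, or 1/z), magnification models.
- **Reconstruction** (`reconstruction`): the five-stage pipeline —
  rolling-ball background subtraction, elemental extraction,
  shift-and-add refocusing, shading-map zone classification plus
  feature-mask ghost suppression, and depth-dependent magnification
  rescaling — plus depth-from-focus autofocus.
- **Interface** (`interface`): strict YAML configs, TIFF/CSV/JSON
  artifacts with provenance, and the `fovlfm` CLI
  (`simulate`, `calibrate`, `reconstruct`, `characterize`).

## Worked example

Calibrate from a synthetic PSF stack, then measure a known 1.7 mm stage
translation of a grid target by autofocus:

```python
import numpy as np
from fovlfm import array_model, calibration, phantoms, reconstruction

array = __import__("fovlfm").default_array()
mask = calibration.segment_apertures(phantoms.render_aperture_frame(array))

zrange = array_model.DepthRange(2000.0, 4000.0, 100.0)   # μm
stack = [(z, phantoms.render_capture(s, array))
         for z, s in phantoms.psf_calibration_stack_scene(zrange)]
model = calibration.fit_translation_model(
    calibration.localize_psfs(stack, mask), model="piecewise")

h, w = array.sensor.height_px, array.sensor.width_px
roi = (h//2 - 250, h//2 + 250, w//2 - 250, w//2 + 250)
zs = np.arange(2000.0, 4001.0, 25.0)
estimates = []
for z_true in (2150.0, 3850.0):
    scene = phantoms.grid_target_scene(100.0, 800.0, z_true, intensity=5000.0)
    frame = phantoms.render_capture(
        scene, array, noise=phantoms.NoiseModel(1.0, 2.0, seed=0))
    elements = reconstruction.extract_elementals(frame, mask)
    z_hat, _ = reconstruction.autofocus(elements, mask, model, zs, roi=roi)
    estimates.append(z_hat)
    print(f"true {z_true:.0f} μm -> estimated {z_hat:.0f} μm")
print(f"translation: {estimates[1] - estimates[0]:.0f} μm (truth 1700)")
```

prints

```
true 2150 μm -> estimated 2150 μm
true 3850 μm -> estimated 3851 μm
translation: 1701 μm (truth 1700)
```

i.e. the calibrated shift-and-add stack recovers the axial translation to
about 0.1% — each depth is found where the seven views converge, and the
difference of the two focus peaks measures the stage motion. The same
machinery reconstructs a three-layer 15.4 μm bead phantom with layer
separations recovered to better than 1% and lateral positions to within
one object pixel inside the foveated zone (see
`tests/test_acceptance.py`).

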