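"""Synthetic scenes and the forward renderer — the package's fixture factory.

Scenes emulate the physical characterization targets: 2.5 μm calibration
beads stepped along the axis at 100 μm, three stacked layers of 15.4 μm
fluorescent beads, and planar 100 μm-pitch grid targets.  Rendering stamps
each emitter through every non-occluded lenslet with a depth-dependent PSF
and accumulates a single full-sensor frame, exactly as the seven elemental
images form on the shared chip.

Pixel convention: frame[row, col]; col grows with sensor +x, row with
sensor +y; the sensor centre sits between pixels at ((H-1)/2, (W-1)/2).
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass, field, replace

import numpy as np

from . import array_model, wave_optics
from .array_model import ArraySpec, DepthRange, InvalidParameterError

__all__ = [
    "Emitter",
    "Scene",
    "CaptureFrame",
    "NoiseModel",
    "PlacementError",
    "bead_layers_phantom",
    "psf_calibration_stack_scene",
    "grid_target_scene",
    "render_capture",
    "render_aperture_frame",
    "add_noise",
    "sensor_xy_to_px",
    "px_to_sensor_xy",
]


class PlacementError(ValueError):
    """Requested emitter count does not fit the extent without overlap."""


@dataclass(frozen=True)
class Emitter:
    """Point-like fluorophore or bead."""

    position: tuple[float, float, float]   # μm, (x, y, z), z > 0
    diameter: float = 2.5                  # μm
    intensity: float = 1.0
    color: tuple[float, ...] = (1.0,)

    def __post_init__(self) -> None:
        if self.diameter < 0 or self.intensity < 0:
            raise InvalidParameterError("diameter and intensity must be >= 0")


@dataclass(frozen=True)
class Scene:
    emitters: tuple[Emitter, ...]
    background_level: float = 0.0
    extent: tuple[float, float, float] = (2000.0, 2000.0, 4500.0)

    def __post_init__(self) -> None:
        if self.background_level < 0:
            raise InvalidParameterError("background_level must be >= 0")
        ex, ey, ez = self.extent
        for e in self.emitters:
            x, y, z = e.position
            if abs(x) > ex / 2 or abs(y) > ey / 2 or not (0 < z <= ez):
                raise InvalidParameterError(
                    f"emitter at {e.position} outside scene extent {self.extent}"
                )


@dataclass
class CaptureFrame:
    """Sensor frame plus provenance metadata."""

    image: np.ndarray                      # (H, W) or (H, W, 3), >= 0
    pixel_pitch: float                     # μm
    metadata: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        if np.any(self.image < 0):
            raise InvalidParameterError("frame values must be nonnegative")


@dataclass(frozen=True)
class NoiseModel:
    """Poisson shot noise + Gaussian read noise + constant offset.

    ``photon_scale`` converts image units to expected photon counts
    (variance of the shot component is mean/photon_scale); 0 disables it.
    """

    photon_scale: float = 50.0
    read_sigma: float = 1.0
    offset: float = 0.0
    seed: int = 0

    def __post_init__(self) -> None:
        if self.photon_scale < 0 or self.read_sigma < 0 or self.offset < 0:
            raise InvalidParameterError("noise parameters must be >= 0")


# ---------------------------------------------------------------------------
# scenes
# ---------------------------------------------------------------------------

def bead_layers_phantom(
    n_layers: int = 3,
    beads_per_layer: int = 8,
    layer_spacing: float = 170.0,
    bead_diameter: float = 15.4,
    lateral_extent: float = 500.0,
    z_center: float = 3000.0,
    seed: int = 0,
    min_separation: float | None = None,
    intensity: float = 1.0,
) -> Scene:
    """Multi-layer fluorescent bead slide.

    Defaults model the three-layer phantom: 15.4 μm beads on planes one
    coverslip (~170 μm) apart, centred mid detection range.  Bead x/y are
    uniform over the lateral extent with a minimum pairwise separation of
    two bead diameters per layer (placement fails loudly if the extent
    cannot host the request).  Ground-truth layer depths live in the
    returned scene's emitter z values.
    """
    if n_layers < 1 or beads_per_layer < 1:
        raise InvalidParameterError("counts must be >= 1")
    if layer_spacing < 0:
        raise InvalidParameterError("layer_spacing must be >= 0")
    sep = 2.0 * bead_diameter if min_separation is None else min_separation
    if beads_per_layer > 1 and lateral_extent < sep * math.sqrt(beads_per_layer):
        raise PlacementError(
            f"extent {lateral_extent} μm too small for {beads_per_layer} beads "
            f"at separation {sep} μm"
        )
    rng = np.random.default_rng(seed)
    z0 = z_center - layer_spacing * (n_layers - 1) / 2.0
    emitters: list[Emitter] = []
    for layer in range(n_layers):
        z = z0 + layer * layer_spacing
        placed: list[np.ndarray] = []
        tries = 0
        while len(placed) < beads_per_layer:
            xy = rng.uniform(-lateral_extent / 2, lateral_extent / 2, size=2)
            if all(np.hypot(*(xy - q)) >= sep for q in placed):
                placed.append(xy)
            tries += 1
            if tries > 10000 * beads_per_layer:
                raise PlacementError("could not place beads without overlap")
        for xy in placed:
            emitters.append(
                Emitter(position=(float(xy[0]), float(xy[1]), float(z)),
                        diameter=bead_diameter, intensity=intensity)
            )
    ext = max(2 * lateral_extent, 1000.0)
    return Scene(tuple(emitters), extent=(ext, ext, z0 + n_layers * layer_spacing + 500))


def psf_calibration_stack_scene(
    zrange: DepthRange, bead_diameter: float = 2.5, intensity: float = 1.0
) -> list[tuple[float, Scene]]:
    """One on-axis sub-resolution bead per depth step — the calibration stack.

    Mirrors the physical procedure of translating a 2.5 μm bead along z in
    100 μm steps through the detection range.
    """
    out = []
    for z in zrange.samples():
        scene = Scene(
            (Emitter(position=(0.0, 0.0, float(z)), diameter=bead_diameter,
                     intensity=intensity),),
            extent=(1000.0, 1000.0, zrange.z_max + 1000.0),
        )
        out.append((float(z), scene))
    return out


def grid_target_scene(
    pitch: float = 100.0,
    extent: float = 1000.0,
    z: float = 3000.0,
    diameter: float = 5.0,
    intensity: float = 1.0,
) -> Scene:
    """Planar square lattice of emitters at one depth (100 μm grid target).

    Emitter count is (floor(extent/pitch)+1)²; a sub-pitch extent leaves the
    single on-axis emitter.
    """
    if pitch <= 0:
        raise InvalidParameterError("pitch must be > 0")
    n_side = int(math.floor(extent / pitch)) + 1
    offs = (np.arange(n_side) - (n_side - 1) / 2.0) * pitch
    emitters = tuple(
        Emitter(position=(float(x), float(y), float(z)), diameter=diameter,
                intensity=intensity)
        for x in offs
        for y in offs
    )
    return Scene(emitters, extent=(2 * extent + 2 * pitch, 2 * extent + 2 * pitch,
                                   z + 1000.0))


# ---------------------------------------------------------------------------
# rendering
# ---------------------------------------------------------------------------

def sensor_xy_to_px(array: ArraySpec, xy) -> np.ndarray:
    """Sensor-plane μm -> fractional (row, col)."""
    xy = np.asarray(xy, dtype=float)
    s = array.sensor
    col = xy[..., 0] / s.pixel_pitch + (s.width_px - 1) / 2.0
    row = xy[..., 1] / s.pixel_pitch + (s.height_px - 1) / 2.0
    return np.stack([row, col], axis=-1)


def px_to_sensor_xy(array: ArraySpec, rowcol) -> np.ndarray:
    rc = np.asarray(rowcol, dtype=float)
    s = array.sensor
    x = (rc[..., 1] - (s.width_px - 1) / 2.0) * s.pixel_pitch
    y = (rc[..., 0] - (s.height_px - 1) / 2.0) * s.pixel_pitch
    return np.stack([x, y], axis=-1)


def _stamp_gaussian(frame: np.ndarray, row: float, col: float,
                    sigma_px: float, weight: float) -> None:
    """Accumulate a unit-sum Gaussian spot at a continuous pixel position."""
    half = max(3, int(math.ceil(4.0 * sigma_px)))
    r0 = int(math.floor(row)) - half
    c0 = int(math.floor(col)) - half
    r1 = r0 + 2 * half + 1
    c1 = c0 + 2 * half + 1
    rr0, cc0 = max(r0, 0), max(c0, 0)
    rr1, cc1 = min(r1, frame.shape[0]), min(c1, frame.shape[1])
    if rr0 >= rr1 or cc0 >= cc1:
        return
    rows = np.arange(r0, r1, dtype=float)
    cols = np.arange(c0, c1, dtype=float)
    gy = np.exp(-0.5 * ((rows - row) / sigma_px) ** 2)
    gx = np.exp(-0.5 * ((cols - col) / sigma_px) ** 2)
    patch = np.outer(gy, gx)
    patch *= weight / patch.sum()
    frame[rr0:rr1, cc0:cc1] += patch[rr0 - r0: rr1 - r0, cc0 - c0: cc1 - c0]


def _stamp_kernel(frame: np.ndarray, row: float, col: float,
                  kernel: np.ndarray, weight: float) -> None:
    """Accumulate a precomputed unit-sum kernel with bilinear sub-pixel shift."""
    kh, kw = kernel.shape
    fr, fc = row - math.floor(row), col - math.floor(col)
    # bilinear split over the four integer offsets
    shifted = np.zeros((kh + 1, kw + 1))
    shifted[:kh, :kw] += kernel * (1 - fr) * (1 - fc)
    shifted[1:, :kw] += kernel * fr * (1 - fc)
    shifted[:kh, 1:] += kernel * (1 - fr) * fc
    shifted[1:, 1:] += kernel * fr * fc
    r0 = int(math.floor(row)) - kh // 2
    c0 = int(math.floor(col)) - kw // 2
    r1, c1 = r0 + kh + 1, c0 + kw + 1
    rr0, cc0 = max(r0, 0), max(c0, 0)
    rr1, cc1 = min(r1, frame.shape[0]), min(c1, frame.shape[1])
    if rr0 >= rr1 or cc0 >= cc1:
        return
    frame[rr0:rr1, cc0:cc1] += (
        weight * shifted[rr0 - r0: rr1 - r0, cc0 - c0: cc1 - c0]
    )


def render_capture(
    scene: Scene,
    array: ArraySpec,
    psf_source: str = "gaussian_approx",
    noise: NoiseModel | None = None,
    fwhm_focus: float | None = None,
    wavelength: float = wave_optics.DEFAULT_WAVELENGTH_NM,
    psf_grid_n: int = 1024,
    dtype=np.float32,
) -> CaptureFrame:
    """Forward-render a scene into a single full-sensor frame.

    Every emitter is chief-ray projected through each lenslet; occluded
    (stop-blocked) views are skipped, emitters invisible to all lenslets are
    counted in ``metadata['clipped']``.  The spot is the depth-dependent PSF
    — for the fast default path a Gaussian whose width follows the cached
    wave-optics core FWHM (pass ``fwhm_focus`` to pin a fixed in-focus
    width via the geometric model instead), or the full scalar-diffraction
    kernel for ``psf_source='wave_optics'`` — widened by the magnified bead
    diameter, carrying the emitter's full intensity per visible lenslet.
    Noise (if any) is applied last; the render is deterministic given the
    noise seed.
    """
    s = array.sensor
    frame = np.zeros((s.height_px, s.width_px), dtype=np.float64)
    clipped = 0
    kernel_cache: dict[tuple[int, float], np.ndarray] = {}
    profiles = {
        lens.id: wave_optics.log_axicon_phase(
            lens.diameter / 2.0, lens.focal_min, lens.focal_max, wavelength
        )
        for lens in array.lenslets
    }
    for e in scene.emitters:
        z = e.position[2]
        m = array_model.magnification_at_depth(array, z)
        visible = 0
        for lens in array.lenslets:
            xy = array_model.project_point(array, lens.id, e.position)
            if xy is None:
                continue
            visible += 1
            row, col = sensor_xy_to_px(array, xy)
            if psf_source == "gaussian_approx":
                if fwhm_focus is not None:
                    fwhm = wave_optics.approx_fwhm_at_depth(
                        lens, array, z, fwhm_focus
                    )
                else:
                    fwhm = wave_optics.psf_fwhm_at_depth(
                        profiles[lens.id], array.sensor_distance, z
                    )
                sigma = math.hypot(fwhm / 2.3548, m * e.diameter / 4.0)
                _stamp_gaussian(frame, row, col, sigma / s.pixel_pitch, e.intensity)
            elif psf_source == "wave_optics":
                key = (lens.id, round(z, 1))
                if key not in kernel_cache:
                    kernel_cache[key], _ = wave_optics.psf_kernel_at_depth(
                        profiles[lens.id], z, array, grid_n=psf_grid_n
                    )
                kern = kernel_cache[key]
                if e.diameter > 0:
                    sig_px = m * e.diameter / 4.0 / s.pixel_pitch
                    if sig_px > 0.3:
                        from scipy.ndimage import gaussian_filter

                        kern = gaussian_filter(kern, sig_px, mode="constant")
                        kern = kern / kern.sum()
                _stamp_kernel(frame, row, col, kern, e.intensity)
            else:
                raise InvalidParameterError(f"unknown psf_source {psf_source!r}")
        if visible == 0:
            clipped += 1
    frame += scene.background_level
    meta = {
        "clipped": clipped,
        "n_emitters": len(scene.emitters),
        "psf_source": psf_source,
    }
    out = CaptureFrame(frame.astype(dtype), s.pixel_pitch, meta)
    if noise is not None:
        out = add_noise(out, noise)
    return out


def render_aperture_frame(array: ArraySpec, level: float = 1.0,
                          dtype=np.float32) -> CaptureFrame:
    """White-light image of the physical apertures: one bright disk per lenslet.

    Each disk is the stop-limited elemental footprint — centre at
    p·(1 + d_s/h), radius (a/2)·(d_s/h) — the input for aperture
    segmentation.  Overlapping footprints trigger a warning, since the stop
    exists precisely to prevent elemental-image overlap.
    """
    s = array.sensor
    h = array.stop.height_above_lenslets
    d_s = array.sensor_distance
    if h == 0:
        raise InvalidParameterError("stop in the lenslet plane has no footprint scale")
    radius = (array.stop.diameter / 2.0) * (d_s / h)
    centers = {}
    for lens in array.lenslets:
        p = np.asarray(lens.center, dtype=float)
        centers[lens.id] = p * (1.0 + d_s / h)
    ids = list(centers)
    for i, a in enumerate(ids):
        for b in ids[i + 1:]:
            if np.hypot(*(centers[a] - centers[b])) < 2 * radius:
                warnings.warn(
                    f"elemental footprints of lenslets {a} and {b} overlap; "
                    "raise the stop or shrink its diameter",
                    RuntimeWarning,
                    stacklevel=2,
                )
    cols = np.arange(s.width_px) - (s.width_px - 1) / 2.0
    rows = np.arange(s.height_px) - (s.height_px - 1) / 2.0
    xx = cols[None, :] * s.pixel_pitch
    yy = rows[:, None] * s.pixel_pitch
    frame = np.zeros((s.height_px, s.width_px), dtype=dtype)
    for c in centers.values():
        dist = np.sqrt((xx - c[0]) ** 2 + (yy - c[1]) ** 2)
        # anti-aliased rim: linear ramp over one pixel, like the physical
        # stop penumbra; keeps disk centroids sub-pixel accurate
        frame += level * np.clip(
            (radius - dist) / s.pixel_pitch + 0.5, 0.0, 1.0
        ).astype(dtype)
    np.clip(frame, 0.0, level, out=frame)
    return CaptureFrame(frame, s.pixel_pitch, {"kind": "aperture", "radius_um": radius})


def add_noise(frame: CaptureFrame, model: NoiseModel) -> CaptureFrame:
    """Apply the shot/read/offset noise chain (clipped at zero)."""
    rng = np.random.default_rng(model.seed)
    img = np.asarray(frame.image, dtype=np.float64)
    if model.photon_scale > 0:
        img = rng.poisson(img * model.photon_scale) / model.photon_scale
    if model.read_sigma > 0:
        img = img + rng.normal(0.0, model.read_sigma, size=img.shape)
    img = np.clip(img + model.offset, 0.0, None)
    meta = dict(frame.metadata)
    meta["noise"] = {
        "photon_scale": model.photon_scale,
        "read_sigma": model.read_sigma,
        "offset": model.offset,
        "seed": model.seed,
    }
    return CaptureFrame(img.astype(frame.image.dtype), frame.pixel_pitch, meta)
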