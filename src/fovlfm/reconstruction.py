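"""Five-stage volumetric reconstruction and depth-from-focus estimation.

The pipeline mirrors how the seven elemental images become a volume:

1. background subtraction (rolling-ball) on the raw frame;
2. aperture-mask segmentation into seven elemental images;
3. depth-dependent shift-and-add: each edge element is translated by its
   calibrated parallax at the target depth and summed with the central
   element — features at that depth converge (synthetic refocusing);
4. a shading map (the aperture footprints, identically translated and
   counted) classifies every pixel into peripheral / blend / foveated
   zones, and a feature mask from the central element suppresses
   cross-lenslet collision ghosts inside the blend+foveated zones;
5. layer-by-layer rescale by the depth-dependent magnification into a
   metrically uniform object-space volume.

Depth estimation runs a focus measure (variance of Laplacian by default)
over a refocus stack and interpolates the peak parabolically.
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass, field

import numpy as np
from scipy import ndimage
from skimage import filters, morphology, restoration

from .array_model import InvalidParameterError
from .calibration import ApertureMask, MagnificationModel, TranslationModel, shift_at_depth
from .phantoms import CaptureFrame

__all__ = [
    "ElementalSet",
    "FocalStack",
    "ShadingMap",
    "FeatureMask",
    "ReconVolume",
    "ZONE_OUTSIDE",
    "ZONE_PERIPHERAL",
    "ZONE_BLEND",
    "ZONE_FOVEATED",
    "subtract_background",
    "extract_elementals",
    "translate_image",
    "refocus",
    "focal_stack",
    "build_shading_map",
    "classify_zones",
    "build_feature_mask",
    "apply_masks",
    "rescale_stack",
    "reconstruct",
    "estimate_depth",
    "flat_field",
    "FOCUS_MEASURES",
]

ZONE_OUTSIDE, ZONE_PERIPHERAL, ZONE_BLEND, ZONE_FOVEATED = 0, 1, 2, 3


# ---------------------------------------------------------------------------
# containers
# ---------------------------------------------------------------------------

@dataclass
class ElementalSet:
    """The seven per-lenslet sub-images, each masked into the common frame."""

    images: dict[int, np.ndarray]
    masks: dict[int, np.ndarray]
    pixel_pitch: float
    center_label: int = 1

    def __post_init__(self) -> None:
        shapes = {im.shape for im in self.images.values()}
        if len(shapes) != 1:
            raise InvalidParameterError("elemental images must share dimensions")

    @property
    def shape(self) -> tuple[int, int]:
        return next(iter(self.images.values())).shape


@dataclass
class FocalStack:
    """Refocused layers at increasing depth (z × y × x)."""

    data: np.ndarray               # (nz, H, W)
    zs: np.ndarray                 # μm, strictly increasing
    pixel_pitch: float             # μm on the sensor (pre-rescale)
    rescaled: bool = False
    metadata: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        self.zs = np.asarray(self.zs, dtype=float)
        if self.data.shape[0] != self.zs.size:
            raise InvalidParameterError("layer count must match z samples")
        if np.any(np.diff(self.zs) <= 0):
            raise InvalidParameterError("z samples must be strictly increasing")


@dataclass
class ShadingMap:
    """Lenslet-overlap count per pixel (0..7) with the zone thresholds."""

    counts: np.ndarray
    foveated_min: int = 6
    blend_min: int = 3


@dataclass
class FeatureMask:
    """Binary structural mask derived from the central elemental image."""

    mask: np.ndarray
    window: int = 31
    opening_radius: int = 2


@dataclass
class ReconVolume:
    """Rescaled focal stack in object-space coordinates plus zone context."""

    volume: np.ndarray             # (nz, H, W), float32
    zs: np.ndarray                 # μm
    object_pixel: float            # μm per voxel laterally
    shading: np.ndarray | None = None       # (nz, H, W) small ints
    zones: np.ndarray | None = None         # (nz, H, W) zone codes
    provenance: dict = field(default_factory=dict)


# ---------------------------------------------------------------------------
# stage 1: background subtraction
# ---------------------------------------------------------------------------

def subtract_background(
    frame: CaptureFrame, radius: float = 50.0, downscale: int | None = None
) -> CaptureFrame:
    """Rolling-ball background removal (grayscale opening with a ball).

    For large frames the ball is applied on a ``downscale``-reduced copy
    (chosen automatically, ImageJ-style) and the background upsampled
    before subtraction; pass ``downscale=1`` to force the exact version.
    """
    img = np.asarray(frame.image, dtype=float)
    if radius <= 0:
        raise InvalidParameterError("radius must be > 0")
    if radius >= min(img.shape[:2]):
        raise InvalidParameterError("radius must be smaller than the image")
    if downscale is None:
        downscale = max(1, int(radius // 12))
    if downscale > 1:
        small = img[::downscale, ::downscale]
        bg_small = restoration.rolling_ball(small, radius=radius / downscale)
        bg = ndimage.zoom(
            bg_small,
            (img.shape[0] / bg_small.shape[0], img.shape[1] / bg_small.shape[1]),
            order=1,
        )
    else:
        bg = restoration.rolling_ball(img, radius=radius)
    out = np.clip(img - bg, 0.0, None)
    meta = dict(frame.metadata)
    meta["background"] = {"method": "rolling_ball", "radius": radius,
                          "downscale": downscale}
    return CaptureFrame(out.astype(frame.image.dtype), frame.pixel_pitch, meta)


# ---------------------------------------------------------------------------
# stage 2: elemental extraction
# ---------------------------------------------------------------------------

def extract_elementals(frame: CaptureFrame, mask: ApertureMask) -> ElementalSet:
    """Split the frame into per-lenslet masked copies (zero outside each label)."""
    img = np.asarray(frame.image, dtype=np.float32)
    if img.ndim == 3:
        img = img.mean(axis=-1)
    if img.shape != mask.labels.shape:
        raise InvalidParameterError(
            f"frame shape {img.shape} != mask shape {mask.labels.shape}"
        )
    images, masks = {}, {}
    for label in range(1, mask.n_labels + 1):
        m = mask.labels == label
        images[label] = np.where(m, img, 0.0).astype(np.float32)
        masks[label] = m
    return ElementalSet(images, masks, frame.pixel_pitch)


# ---------------------------------------------------------------------------
# stage 3: shift-and-add refocusing
# ---------------------------------------------------------------------------

def translate_image(
    img: np.ndarray,
    d_row: float,
    d_col: float,
    roi: tuple[int, int, int, int] | None = None,
    order: int = 1,
) -> np.ndarray:
    """Translate ``img`` by (d_row, d_col) with zero fill.

    ``roi = (r0, r1, c0, c1)`` restricts the computation to that output
    window (the window's content only needs the matching source slice, so
    focus sweeps over small regions cost O(roi), not O(frame)).
    ``order`` 1 is bilinear, 0 nearest-integer.
    """
    h, w = img.shape
    r0, r1, c0, c1 = roi if roi is not None else (0, h, 0, w)
    out = np.zeros((r1 - r0, c1 - c0), dtype=np.float32)
    if order == 0:
        taps = [(int(round(d_row)), int(round(d_col)), 1.0)]
    else:
        ir, ic = math.floor(d_row), math.floor(d_col)
        fr, fc = d_row - ir, d_col - ic
        taps = [
            (ir, ic, (1 - fr) * (1 - fc)),
            (ir + 1, ic, fr * (1 - fc)),
            (ir, ic + 1, (1 - fr) * fc),
            (ir + 1, ic + 1, fr * fc),
        ]
    for tr, tc, wgt in taps:
        if wgt == 0.0:
            continue
        sr0, sr1 = r0 - tr, r1 - tr          # source rows feeding the roi
        sc0, sc1 = c0 - tc, c1 - tc
        vr0, vr1 = max(sr0, 0), min(sr1, h)
        vc0, vc1 = max(sc0, 0), min(sc1, w)
        if vr0 >= vr1 or vc0 >= vc1:
            continue
        out[vr0 - sr0: vr1 - sr0, vc0 - sc0: vc1 - sc0] += (
            wgt * img[vr0:vr1, vc0:vc1]
        )
    return out


def refocus(
    elements: ElementalSet,
    model: TranslationModel,
    z: float,
    roi: tuple[int, int, int, int] | None = None,
) -> np.ndarray:
    """Synthetic refocusing at depth z: translate edge elements, sum with centre.

    Features physically at depth z converge across the seven views; a wrong
    depth spreads a point into a ring of up to seven sub-spots (parallax
    defocus).  Extrapolation beyond the calibrated depth range is flagged by
    the translation model.
    """
    total: np.ndarray | None = None
    for label, img in elements.images.items():
        dr, dc = shift_at_depth(model, label, z)
        layer = translate_image(img, dr, dc, roi=roi)
        total = layer if total is None else total + layer
    return total


def focal_stack(
    elements: ElementalSet,
    model: TranslationModel,
    zs,
    roi: tuple[int, int, int, int] | None = None,
) -> FocalStack:
    """Refocus at every depth in ``zs`` (increasing) into one stack."""
    zs = np.asarray(zs, dtype=float)
    layers = np.stack([refocus(elements, model, float(z), roi=roi) for z in zs])
    return FocalStack(layers, zs, elements.pixel_pitch,
                      metadata={"roi": roi})


# ---------------------------------------------------------------------------
# stage 4a: shading map and zones
# ---------------------------------------------------------------------------

def build_shading_map(
    mask: ApertureMask,
    model: TranslationModel,
    z: float,
    roi: tuple[int, int, int, int] | None = None,
    foveated_min: int = 6,
    blend_min: int = 3,
) -> ShadingMap:
    """Overlap-count map: aperture footprints, translated like the elements.

    Counts are integers 0..n_lenslets (nearest-pixel shifts), so zone
    classification is exact.  With all seven footprints counted the centre
    of the field reaches 7 at the convergence depth.
    """
    counts: np.ndarray | None = None
    for label, m in (
        (lab, mask.region(lab)) for lab in range(1, mask.n_labels + 1)
    ):
        dr, dc = shift_at_depth(model, label, z)
        shifted = translate_image(m.astype(np.float32), dr, dc, roi=roi, order=0)
        counts = shifted if counts is None else counts + shifted
    return ShadingMap(counts.astype(np.uint8), foveated_min, blend_min)


def classify_zones(shading: ShadingMap) -> np.ndarray:
    """Zone labels from overlap counts: disjoint partition of every pixel.

    foveated: count >= foveated_min (default 6); blend: blend_min..foveated_min-1
    (default 3–5); peripheral: 1..blend_min-1; outside: 0.
    """
    c = shading.counts
    zones = np.full(c.shape, ZONE_OUTSIDE, dtype=np.uint8)
    zones[(c >= 1) & (c < shading.blend_min)] = ZONE_PERIPHERAL
    zones[(c >= shading.blend_min) & (c < shading.foveated_min)] = ZONE_BLEND
    zones[c >= shading.foveated_min] = ZONE_FOVEATED
    return zones


# ---------------------------------------------------------------------------
# stage 4b: feature mask
# ---------------------------------------------------------------------------

def build_feature_mask(
    central_element: np.ndarray,
    window: int = 31,
    opening_radius: int = 2,
    offset: float = 0.0,
) -> FeatureMask:
    """Structural mask from the central view: adaptive threshold + opening.

    Pixels above their local-mean threshold survive; morphological opening
    removes speckle smaller than the structuring disk.  Because the central
    element is never shifted, the mask is aligned with every refocused layer.
    """
    if window < 3 or window % 2 == 0:
        raise InvalidParameterError("window must be odd and >= 3")
    img = np.asarray(central_element, dtype=float)
    thresh = filters.threshold_local(img, block_size=window, method="mean",
                                     offset=-offset)
    # the running-sum mean filter leaves ±1e-13 debris in empty regions;
    # demand a minimal absolute signal as well as exceeding the local mean
    floor = 1e-6 * img.max() if img.max() > 0 else np.inf
    binary = (img > thresh) & (img > floor)
    if opening_radius > 0:
        binary = morphology.opening(binary, morphology.disk(opening_radius))
    return FeatureMask(binary, window, opening_radius)


def apply_masks(
    stack: FocalStack,
    feature: FeatureMask,
    shading_stack: list[ShadingMap],
    mode: str = "feature",
) -> FocalStack:
    """Suppress ghosts and (optionally) flatten the zone intensity gradient.

    Within the blend+foveated zones, voxels absent from the central-view
    feature mask are zeroed — cross-lenslet collision artefacts cannot
    survive, since a real feature at that location must appear in the
    central element.  The peripheral zone is never feature-masked.
    ``mode='feature+normalize'`` additionally divides by the overlap count.
    """
    if len(shading_stack) != stack.data.shape[0]:
        raise InvalidParameterError("need one shading map per layer")
    if feature.mask.shape != stack.data.shape[1:]:
        raise InvalidParameterError("feature mask shape must match layers")
    if mode not in ("feature", "feature+normalize", "normalize"):
        raise InvalidParameterError(f"unknown mode {mode!r}")
    out = stack.data.copy()
    for i, shading in enumerate(shading_stack):
        counts = shading.counts
        if "feature" in mode:
            inner = counts >= shading.blend_min
            out[i][inner & ~feature.mask] = 0.0
        if "normalize" in mode:
            out[i] = np.where(counts > 0, out[i] / np.maximum(counts, 1), out[i])
    meta = dict(stack.metadata)
    meta["masking"] = mode
    return FocalStack(out, stack.zs, stack.pixel_pitch, stack.rescaled, meta)


# ---------------------------------------------------------------------------
# stage 5: magnification rescaling
# ---------------------------------------------------------------------------

def rescale_stack(
    stack: FocalStack,
    mag: MagnificationModel,
    reference_z: float | None = None,
    shading_stack: list[ShadingMap] | None = None,
) -> ReconVolume:
    """Resample every layer to a common object-space pixel size.

    Layer pixels subtend pitch/m(z) μm in the object; each layer is scaled
    about the frame centre by m(z_ref)/m(z) so all layers share the pixel
    size at ``reference_z`` (default: the depth where m = 1, i.e. the axis
    intersection for the parametric model).
    """
    ms = np.asarray([mag(float(z)) for z in stack.zs])
    if np.any(ms <= 0):
        raise InvalidParameterError("magnification must be positive")
    if reference_z is None:
        m_ref = 1.0
    else:
        m_ref = float(mag(reference_z))
    h, w = stack.data.shape[1:]
    center = np.array([(h - 1) / 2.0, (w - 1) / 2.0])
    out = np.empty_like(stack.data, dtype=np.float32)
    zones = None
    shading_out = None
    if shading_stack is not None:
        shading_out = np.empty((len(shading_stack), h, w), dtype=np.uint8)
    for i, m in enumerate(ms):
        s = m_ref / m                    # enlargement applied to the layer
        matrix = np.array([1.0 / s, 1.0 / s])
        offset = center * (1.0 - 1.0 / s)
        out[i] = ndimage.affine_transform(
            stack.data[i], matrix, offset=offset, order=1, output=np.float32
        )
        if shading_out is not None:
            shading_out[i] = ndimage.affine_transform(
                shading_stack[i].counts, matrix, offset=offset, order=0
            )
    if shading_out is not None:
        fov_min = shading_stack[0].foveated_min
        bl_min = shading_stack[0].blend_min
        zones = np.stack(
            [classify_zones(ShadingMap(c, fov_min, bl_min)) for c in shading_out]
        )
    return ReconVolume(
        volume=out,
        zs=stack.zs.copy(),
        object_pixel=stack.pixel_pitch / m_ref,
        shading=shading_out,
        zones=zones,
        provenance={"reference_magnification": m_ref, **stack.metadata},
    )


# ---------------------------------------------------------------------------
# composed pipeline
# ---------------------------------------------------------------------------

def reconstruct(
    frame: CaptureFrame,
    mask: ApertureMask,
    model: TranslationModel,
    mag: MagnificationModel,
    zs,
    background_radius: float | None = 50.0,
    feature_window: int = 31,
    feature_opening: int = 2,
    mask_mode: str = "feature",
    rescale: bool = True,
    roi: tuple[int, int, int, int] | None = None,
) -> ReconVolume:
    """Run the full five-stage pipeline on one capture frame.

    Deterministic given its inputs; stage failures propagate with the stage
    named.  ``roi`` restricts refocusing to an output window (zone maps and
    rescaling then apply to that window).
    """
    zs = np.asarray(zs, dtype=float)

    def _stage(name, fn, *args, **kw):
        try:
            return fn(*args, **kw)
        except Exception as exc:
            raise RuntimeError(f"reconstruction stage '{name}' failed: {exc}") from exc

    if background_radius is not None:
        frame = _stage("background", subtract_background, frame, background_radius)
    elements = _stage("segmentation", extract_elementals, frame, mask)
    stack = _stage("refocus", focal_stack, elements, model, zs, roi=roi)
    shading = [
        _stage("shading", build_shading_map, mask, model, float(z), roi=roi)
        for z in zs
    ]
    central = elements.images[elements.center_label]
    if roi is not None:
        r0, r1, c0, c1 = roi
        central = central[r0:r1, c0:c1]
    if mask_mode != "none":
        feature = _stage("feature", build_feature_mask, central,
                         feature_window, feature_opening)
        stack = _stage("masking", apply_masks, stack, feature, shading, mask_mode)
    if rescale:
        vol = _stage("rescale", rescale_stack, stack, mag, None, shading)
    else:
        vol = ReconVolume(
            volume=stack.data,
            zs=zs,
            object_pixel=stack.pixel_pitch,
            shading=np.stack([s.counts for s in shading]),
            zones=np.stack([classify_zones(s) for s in shading]),
            provenance={"rescaled": False},
        )
    vol.provenance.update(
        {
            "n_layers": int(zs.size),
            "background_radius": background_radius,
            "mask_mode": mask_mode,
            "roi": roi,
        }
    )
    return vol


# ---------------------------------------------------------------------------
# depth from focus
# ---------------------------------------------------------------------------

def _tenengrad(img: np.ndarray) -> float:
    gx = ndimage.sobel(img, axis=1)
    gy = ndimage.sobel(img, axis=0)
    return float(np.mean(gx**2 + gy**2))


FOCUS_MEASURES = {
    "var_laplacian": lambda im: float(
        np.var(ndimage.laplace(np.asarray(im, dtype=np.float32)))
    ),
    "tenengrad": _tenengrad,
    "intensity_max": lambda im: float(np.max(im)),
}


def _parabolic_peak(zs: np.ndarray, scores: np.ndarray) -> float:
    """Arg-max with three-point parabolic refinement (ties toward smaller z)."""
    i = int(np.argmax(scores))
    z_hat = float(zs[i])
    if 0 < i < len(scores) - 1:
        y0, y1, y2 = scores[i - 1], scores[i], scores[i + 1]
        denom = y0 - 2 * y1 + y2
        if denom < 0:
            delta = float(np.clip(0.5 * (y0 - y2) / denom, -0.5, 0.5))
            step = 0.5 * (zs[i + 1] - zs[i - 1])
            z_hat = float(zs[i] + delta * step)
    return z_hat


def estimate_depth(
    stack: FocalStack,
    roi: tuple[int, int, int, int] | None = None,
    measure: str = "var_laplacian",
) -> tuple[float, np.ndarray]:
    """Autofocus depth estimate from the focus-score curve of a stack.

    Scores each layer (within ``roi`` if given), takes the arg-max (ties
    toward smaller z) and refines it with a three-point parabolic
    interpolation.  Returns (z_hat [μm], scores).  A flat curve yields the
    first depth with a no-focus warning.
    """
    if stack.data.shape[0] < 3:
        raise InvalidParameterError("need >= 3 layers for depth estimation")
    fn = FOCUS_MEASURES[measure]
    if roi is not None:
        r0, r1, c0, c1 = roi
        layers = stack.data[:, r0:r1, c0:c1]
    else:
        layers = stack.data
    scores = np.array([fn(layer) for layer in layers])
    if np.ptp(scores) == 0:
        warnings.warn("flat focus-score curve; no focus found", RuntimeWarning,
                      stacklevel=2)
        return float(stack.zs[0]), scores
    return _parabolic_peak(stack.zs, scores), scores


def autofocus(
    elements: ElementalSet,
    mask: ApertureMask,
    model: TranslationModel,
    zs,
    roi: tuple[int, int, int, int] | None = None,
    min_count: int | None = None,
    erode: int = 3,
    smooth: float = 1.5,
) -> tuple[float, np.ndarray]:
    """Depth estimate scored inside the fully-overlapped (rim-free) region.

    Refocuses layer by layer and evaluates the variance of the (Gaussian
    pre-smoothed) Laplacian only where the translated aperture footprints
    all overlap — the shading-map count reaches ``min_count`` (default: all
    lenslets).  Restricting the score to this region excludes the sharp
    aperture-rim edges that sweep through the field as the refocus depth
    changes, which would otherwise swamp the true focus peak; eroding by a
    few pixels guards the region boundary.  Returns (z_hat, scores).
    """
    zs = np.asarray(zs, dtype=float)
    if zs.size < 3:
        raise InvalidParameterError("need >= 3 depths")
    if min_count is None:
        min_count = mask.n_labels
    scores = np.empty(zs.size)
    for i, z in enumerate(zs):
        layer = refocus(elements, model, float(z), roi=roi)
        shading = build_shading_map(mask, model, float(z), roi=roi)
        valid = ndimage.binary_erosion(shading.counts >= min_count,
                                       iterations=erode)
        if valid.sum() < 100:
            scores[i] = 0.0
            continue
        if smooth > 0:
            layer = ndimage.gaussian_filter(layer, smooth)
        scores[i] = float(np.var(ndimage.laplace(layer)[valid]))
    if np.ptp(scores) == 0:
        warnings.warn("flat focus-score curve; no focus found", RuntimeWarning,
                      stacklevel=2)
        return float(zs[0]), scores
    return _parabolic_peak(zs, scores), scores


# ---------------------------------------------------------------------------
# flat-field correction
# ---------------------------------------------------------------------------

def flat_field(
    image: np.ndarray, reference: np.ndarray, eps_fraction: float = 1e-6
) -> np.ndarray:
    """Divide by a mean-normalized reference, guarding small denominators.

    Used to flatten the zone-boundary intensity steps a uniform scene shows
    after shift-and-add (each zone sums a different number of views).
    """
    img = np.asarray(image, dtype=float)
    ref = np.asarray(reference, dtype=float)
    if img.shape != ref.shape:
        raise InvalidParameterError("reference shape must match image")
    pos = ref > 0
    if not pos.any():
        raise InvalidParameterError("reference has no positive support")
    norm = ref / ref[pos].mean()
    eps = eps_fraction * float(norm.max())
    guarded = norm < eps
    if guarded.any():
        warnings.warn(
            f"flat-field reference below guard in {int(guarded.sum())} px",
            RuntimeWarning,
            stacklevel=2,
        )
    return img / np.maximum(norm, eps)
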