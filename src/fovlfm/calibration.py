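"""Calibration: aperture segmentation, PSF localization, translation curves.

The reconstruction needs, per edge lenslet, the sensor-plane shift that
registers its elemental image to the central one as a function of object
depth.  These translation curves are measured, not assumed: a sub-resolution
bead is stepped through the detection range, the PSF spot is localized in
every elemental footprint, the central spot is taken as the zero point, and
a least-squares line of (centre − edge) displacement versus depth is fitted
per edge lenslet and axis.  Depths between calibration steps are read off
the fitted line.

The underlying pinhole parallax is affine in 1/z, not z, so the linear fit
carries a systematic residual over a 2 mm range; the residual is reported
with the model and an exact 1/z fit is available via ``model='inverse'``.

Depth-dependent magnification is calibrated either parametrically
(m(z) = d_s/z) or from measured grid pitches at known depths.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from skimage import filters, measure

from .array_model import ArraySpec, InvalidParameterError
from .phantoms import CaptureFrame

__all__ = [
    "ApertureMask",
    "TranslationModel",
    "MagnificationModel",
    "SegmentationCountError",
    "UnderdeterminedFitError",
    "segment_apertures",
    "localize_psfs",
    "fit_translation_model",
    "shift_at_depth",
    "fit_magnification",
]


class SegmentationCountError(RuntimeError):
    """Aperture segmentation found the wrong number of footprints."""

    def __init__(self, found: int, expected: int):
        super().__init__(
            f"aperture segmentation found {found} components, expected {expected}"
        )
        self.found = found
        self.expected = expected


class UnderdeterminedFitError(RuntimeError):
    """Fewer than two valid depths for a lenslet's translation fit."""


class MissingPsfWarning(RuntimeWarning):
    """A (lenslet, depth) pair had no signal above the background floor."""


# ---------------------------------------------------------------------------
# aperture segmentation
# ---------------------------------------------------------------------------

@dataclass
class ApertureMask:
    """Labelled elemental footprints: 0 background, 1..n lenslets.

    Label 1 is the footprint nearest the sensor centre (the central
    lenslet); 2..n proceed counterclockwise from +x, ties broken toward
    smaller y.  ``centroids`` are (row, col) per label.
    """

    labels: np.ndarray
    centroids: dict[int, tuple[float, float]] = field(default_factory=dict)
    bboxes: dict[int, tuple[int, int, int, int]] = field(default_factory=dict)

    @property
    def n_labels(self) -> int:
        return int(self.labels.max())

    def region(self, label: int) -> np.ndarray:
        return self.labels == label


def segment_apertures(
    aperture_frame: CaptureFrame,
    threshold_method: str = "otsu",
    fixed_threshold: float | None = None,
    min_area: int = 100,
    expected: int = 7,
) -> ApertureMask:
    """Threshold + connected components on the white-light aperture frame.

    Components below ``min_area`` pixels are discarded; a component count
    different from ``expected`` raises :class:`SegmentationCountError`
    naming the count found.
    """
    img = np.asarray(aperture_frame.image, dtype=float)
    if img.ndim == 3:
        img = img.mean(axis=-1)
    if threshold_method == "fixed":
        if fixed_threshold is None:
            raise InvalidParameterError("fixed threshold requires a value")
        thresh = fixed_threshold
    elif threshold_method == "otsu":
        if img.max() <= img.min():
            raise SegmentationCountError(0, expected)
        thresh = filters.threshold_otsu(img)
    else:
        raise InvalidParameterError(f"unknown threshold_method {threshold_method!r}")
    binary = img > thresh
    lab = measure.label(binary)
    props = [p for p in measure.regionprops(lab) if p.area >= min_area]
    if len(props) != expected:
        raise SegmentationCountError(len(props), expected)

    center = np.array([(img.shape[0] - 1) / 2.0, (img.shape[1] - 1) / 2.0])
    cents = [np.asarray(p.centroid) for p in props]
    dists = [np.linalg.norm(c - center) for c in cents]
    order = [int(np.argmin(dists))]
    rest = [i for i in range(len(props)) if i != order[0]]

    def angle_key(i: int):
        d = cents[i] - cents[order[0]]
        # ccw from +x in sensor coordinates (col = x, row = y)
        ang = np.arctan2(d[0], d[1]) % (2 * np.pi)
        return (round(ang, 6), d[0])

    rest.sort(key=angle_key)
    order += rest

    labels = np.zeros_like(lab)
    centroids, bboxes = {}, {}
    for new, idx in enumerate(order, start=1):
        labels[lab == props[idx].label] = new
        centroids[new] = tuple(float(v) for v in props[idx].centroid)
        bboxes[new] = tuple(int(v) for v in props[idx].bbox)
    return ApertureMask(labels.astype(np.uint8), centroids, bboxes)


# ---------------------------------------------------------------------------
# PSF localization
# ---------------------------------------------------------------------------

def localize_psfs(
    stack: list[tuple[float, CaptureFrame]],
    mask: ApertureMask,
    window_px: int = 48,
) -> pd.DataFrame:
    """Sub-pixel PSF centroids per (lenslet, depth).

    Within each footprint the background floor is median + 3·MAD of the
    region.  The spot is first detected as the smoothed intensity peak,
    then localized as the intensity-weighted centroid of the above-floor
    excess inside a ``window_px``-radius disk around the peak, keeping
    pixels above 10% of the spot peak and 5 MAD above the floor — the
    windowing stops diffuse noise spread over the (much larger) footprint
    from dragging the estimate, without biasing the symmetric spot.
    Footprints with no signal above the floor are dropped with a
    :class:`MissingPsfWarning`.

    Returns a DataFrame with columns lenslet, z, row, col (pixels).
    """
    from scipy import ndimage

    rows = []
    for z, frame in stack:
        img = np.asarray(frame.image, dtype=float)
        if img.ndim == 3:
            img = img.mean(axis=-1)
        for label in range(1, mask.n_labels + 1):
            r0, c0, r1, c1 = mask.bboxes[label]
            sub = img[r0:r1, c0:c1]
            reg = mask.labels[r0:r1, c0:c1] == label
            vals = sub[reg]
            med = np.median(vals)
            mad = np.median(np.abs(vals - med))
            floor = med + 3.0 * mad
            excess = np.where(reg, sub - floor, 0.0)
            excess[excess < 0] = 0.0
            if excess.any():
                smoothed = ndimage.gaussian_filter(excess, 2.0)
                pr, pc = np.unravel_index(np.argmax(smoothed), smoothed.shape)
                yy, xx = np.mgrid[0: excess.shape[0], 0: excess.shape[1]]
                excess[(yy - pr) ** 2 + (xx - pc) ** 2 > window_px**2] = 0.0
                if excess.any():
                    excess[excess < max(0.1 * excess.max(), 5.0 * mad)] = 0.0
            total = excess.sum()
            if total <= 0:
                warnings.warn(
                    f"no PSF signal for lenslet {label} at z={z:.0f} μm",
                    MissingPsfWarning,
                    stacklevel=2,
                )
                continue
            rr, cc = np.nonzero(excess)
            w = excess[rr, cc]
            rows.append(
                {
                    "lenslet": label,
                    "z": float(z),
                    "row": float(np.sum(rr * w) / total) + r0,
                    "col": float(np.sum(cc * w) / total) + c0,
                }
            )
    return pd.DataFrame(rows, columns=["lenslet", "z", "row", "col"])


# ---------------------------------------------------------------------------
# translation model
# ---------------------------------------------------------------------------

@dataclass
class TranslationModel:
    """Per-lenslet registration shift (centre − edge) versus depth.

    ``curves[lenslet]`` holds dict(axis -> (slope, intercept)) with the
    shift in pixels; for ``model='linear'`` the shift is slope·z +
    intercept, for ``'inverse'`` it is slope/z + intercept.  For
    ``'piecewise'`` the shift interpolates linearly between the measured
    calibration depths in ``tables`` (exactly through every localized
    shift, so no fit residual and no metric distortion between samples).
    The central lenslet's shift is identically zero.  ``residual_rms``
    [px] quantifies the fit over the calibrated range; evaluations
    outside [z_min, z_max] are flagged extrapolation.
    """

    center_lenslet: int
    curves: dict[int, dict[str, tuple[float, float]]]
    residual_rms: dict[int, float]
    z_min: float
    z_max: float
    model: str = "linear"
    tables: dict[int, dict[str, tuple[tuple[float, ...], tuple[float, ...]]]] | None = None

    def to_dict(self) -> dict:
        return {
            "center_lenslet": self.center_lenslet,
            "model": self.model,
            "z_min": self.z_min,
            "z_max": self.z_max,
            "curves": {
                str(k): {ax: list(v) for ax, v in axes.items()}
                for k, axes in self.curves.items()
            },
            "residual_rms": {str(k): v for k, v in self.residual_rms.items()},
            "tables": None if self.tables is None else {
                str(k): {ax: [list(v[0]), list(v[1])] for ax, v in axes.items()}
                for k, axes in self.tables.items()
            },
        }

    @classmethod
    def from_dict(cls, d: dict) -> "TranslationModel":
        tables = d.get("tables")
        return cls(
            center_lenslet=int(d["center_lenslet"]),
            curves={
                int(k): {ax: tuple(v) for ax, v in axes.items()}
                for k, axes in d["curves"].items()
            },
            residual_rms={int(k): float(v) for k, v in d["residual_rms"].items()},
            z_min=float(d["z_min"]),
            z_max=float(d["z_max"]),
            model=d.get("model", "linear"),
            tables=None if tables is None else {
                int(k): {
                    ax: (tuple(v[0]), tuple(v[1])) for ax, v in axes.items()
                }
                for k, axes in tables.items()
            },
        )


class ExtrapolationWarning(RuntimeWarning):
    """Translation curve evaluated outside its calibrated depth range."""


def fit_translation_model(
    localizations: pd.DataFrame,
    center_lenslet_id: int = 1,
    model: str = "linear",
) -> TranslationModel:
    """Least-squares translation curves from a PSF localization table.

    For each edge lenslet, the registration shift (centre − edge) in row
    and col is regressed on z (or 1/z for ``model='inverse'``); for
    ``model='piecewise'`` the per-depth shifts are kept verbatim and
    linearly interpolated between calibration steps.  At least two depths
    per lenslet are required.
    """
    if model not in ("linear", "inverse", "piecewise"):
        raise InvalidParameterError(f"unknown translation model {model!r}")
    locs = localizations
    center = locs[locs.lenslet == center_lenslet_id].set_index("z")
    if len(center) < 2:
        raise UnderdeterminedFitError("need >= 2 depths for the central lenslet")
    curves: dict[int, dict[str, tuple[float, float]]] = {
        center_lenslet_id: {"row": (0.0, 0.0), "col": (0.0, 0.0)}
    }
    tables: dict[int, dict[str, tuple[tuple[float, ...], tuple[float, ...]]]] = {
        center_lenslet_id: {
            "row": ((0.0, 1.0), (0.0, 0.0)),
            "col": ((0.0, 1.0), (0.0, 0.0)),
        }
    }
    residual: dict[int, float] = {center_lenslet_id: 0.0}
    for lens_id, grp in locs.groupby("lenslet"):
        lens_id = int(lens_id)
        if lens_id == center_lenslet_id:
            continue
        merged = grp.set_index("z").join(center, rsuffix="_c", how="inner")
        if len(merged) < 2:
            raise UnderdeterminedFitError(
                f"lenslet {lens_id}: only {len(merged)} depths with a central match"
            )
        merged = merged.sort_index()
        z = merged.index.to_numpy(dtype=float)
        x = 1.0 / z if model == "inverse" else z
        axes = {}
        axes_tab = {}
        sq = 0.0
        for ax in ("row", "col"):
            shift = (merged[f"{ax}_c"] - merged[ax]).to_numpy(dtype=float)
            slope, intercept = np.polyfit(x, shift, 1)
            axes[ax] = (float(slope), float(intercept))
            axes_tab[ax] = (tuple(float(v) for v in z),
                            tuple(float(v) for v in shift))
            if model != "piecewise":
                sq += float(np.mean((shift - (slope * x + intercept)) ** 2))
        curves[lens_id] = axes
        tables[lens_id] = axes_tab
        residual[lens_id] = float(np.sqrt(sq))
    zs = locs.z.to_numpy(dtype=float)
    return TranslationModel(
        center_lenslet=center_lenslet_id,
        curves=curves,
        residual_rms=residual,
        z_min=float(zs.min()),
        z_max=float(zs.max()),
        model=model,
        tables=tables if model == "piecewise" else None,
    )


def shift_at_depth(
    model: TranslationModel, lenslet: int, z: float
) -> tuple[float, float]:
    """Registration shift (d_row, d_col) [px] for one lenslet at depth z."""
    if lenslet not in model.curves:
        raise KeyError(f"lenslet {lenslet} not in translation model")
    if not (model.z_min <= z <= model.z_max):
        warnings.warn(
            f"z={z:.0f} μm outside calibrated range "
            f"[{model.z_min:.0f}, {model.z_max:.0f}]",
            ExtrapolationWarning,
            stacklevel=2,
        )
    if model.model == "piecewise":
        tab = model.tables[lenslet]
        return (
            float(np.interp(z, tab["row"][0], tab["row"][1])),
            float(np.interp(z, tab["col"][0], tab["col"][1])),
        )
    x = 1.0 / z if model.model == "inverse" else z
    axes = model.curves[lenslet]
    return (
        axes["row"][0] * x + axes["row"][1],
        axes["col"][0] * x + axes["col"][1],
    )


# ---------------------------------------------------------------------------
# magnification model
# ---------------------------------------------------------------------------

@dataclass
class MagnificationModel:
    """Depth -> lateral magnification, strictly positive and decreasing.

    Parametric mode is the pinhole law m(z) = d_s/z; tabulated mode
    interpolates measured (z, m) pairs linearly in 1/z (the exact functional
    form of the pinhole law, so two clean calibration depths suffice).
    """

    mode: str
    sensor_distance: float | None = None
    table: tuple[tuple[float, float], ...] | None = None   # (z, m) pairs

    def __call__(self, z) -> np.ndarray | float:
        z = np.asarray(z, dtype=float)
        if np.any(z <= 0):
            raise InvalidParameterError("depth must be > 0")
        if self.mode == "parametric":
            out = self.sensor_distance / z
        else:
            zs = np.array([p[0] for p in self.table])
            ms = np.array([p[1] for p in self.table])
            order = np.argsort(1.0 / zs)
            out = np.interp(1.0 / z, (1.0 / zs)[order], ms[order])
        return float(out) if out.ndim == 0 else out

    def to_dict(self) -> dict:
        return {
            "mode": self.mode,
            "sensor_distance": self.sensor_distance,
            "table": [list(p) for p in self.table] if self.table else None,
        }

    @classmethod
    def from_dict(cls, d: dict) -> "MagnificationModel":
        table = d.get("table")
        return cls(
            mode=d["mode"],
            sensor_distance=d.get("sensor_distance"),
            table=tuple(tuple(p) for p in table) if table else None,
        )


def fit_magnification(
    mode: str = "parametric",
    array: ArraySpec | None = None,
    sensor_distance: float | None = None,
    measurements: list[tuple[float, float]] | None = None,
) -> MagnificationModel:
    """Build the magnification model.

    Parametric mode needs the sensor distance (directly or via ``array``);
    tabulated mode needs >= 2 (depth [μm], measured magnification) pairs,
    e.g. grid-pitch ratios from a known 100 μm grid target.
    """
    if mode == "parametric":
        d_s = sensor_distance if sensor_distance is not None else (
            array.sensor_distance if array is not None else None
        )
        if d_s is None:
            raise InvalidParameterError("parametric mode needs sensor_distance")
        return MagnificationModel("parametric", sensor_distance=float(d_s))
    if mode == "tabulated":
        if not measurements or len(measurements) < 2:
            raise InvalidParameterError("tabulated mode needs >= 2 measurements")
        table = tuple(sorted((float(z), float(m)) for z, m in measurements))
        if any(m <= 0 for _, m in table):
            raise InvalidParameterError("magnifications must be positive")
        return MagnificationModel("tabulated", table=table)
    raise InvalidParameterError(f"unknown magnification mode {mode!r}")
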