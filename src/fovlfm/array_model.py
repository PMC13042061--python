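"""Geometric model of the concave seven-lenslet compound array.

The imager is a hexagonal array of seven logarithmic-axicon lenslets (one
central, six in a ring) mounted above a shared CMOS sensor.  The ring
lenslets are tilted inward so that all seven optical axes converge on a
single point on the central axis, 3 mm above the lenslet plane — the middle
of the axial detection range.  A single circular field stop above the array
limits each lenslet's field of view and prevents the seven elemental images
from overlapping on the sensor.

Coordinate convention: origin at the central lenslet vertex, +z toward the
object, sensor plane at z = -sensor_distance.  All lengths are micrometres
internally; millimetre values are converted once at construction / config
time.  Sensor-plane positions are in micrometres relative to the sensor
centre, with +x/+y parallel to the lenslet-plane axes.

Everything here is chief-ray (pinhole) optics: each lenslet is an ideal
pinhole at its vertex, so projection, parallax, field of view and
magnification are exact similar-triangle relations.  Diffraction blur is
the province of :mod:`fovlfm.wave_optics`.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, replace

import numpy as np

__all__ = [
    "LensletSpec",
    "SensorSpec",
    "ApertureSpec",
    "ArraySpec",
    "DepthRange",
    "InvalidParameterError",
    "NoRealConjugateError",
    "default_array",
    "lenslet_na",
    "tilt_for_intersection",
    "magnification_at_depth",
    "mean_magnification",
    "conjugate_object_range",
    "axis_sensor_intersection",
    "project_point",
    "fov_window",
    "fov_windows_at_depth",
    "coverage_count_grid",
    "zone_extents",
]

MM = 1000.0  # μm per mm


class InvalidParameterError(ValueError):
    """A geometric parameter is outside its physical domain."""


class NoRealConjugateError(ValueError):
    """Thin-lens conjugate does not exist (sensor inside the focal range)."""


class UnknownLensletError(KeyError):
    """Lenslet id not present in the array."""


# ---------------------------------------------------------------------------
# specs
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class LensletSpec:
    """One lenslet: position in the array plane, aperture and focal range.

    ``tilt_azimuth`` is the in-plane direction (degrees, from +x) toward
    which the optical axis leans; for ring lenslets it points at the array
    centre so that the axes converge.
    """

    id: int
    center: tuple[float, float]          # μm, lenslet plane
    diameter: float                      # μm
    focal_min: float                     # μm
    focal_max: float                     # μm
    tilt_angle: float = 0.0              # deg, 0 = optical axis along +z
    tilt_azimuth: float = 0.0            # deg

    def __post_init__(self) -> None:
        if self.diameter <= 0:
            raise InvalidParameterError("lenslet diameter must be > 0")
        if not (0 < self.focal_min <= self.focal_max):
            raise InvalidParameterError("need 0 < focal_min <= focal_max")

    @property
    def focal_mid(self) -> float:
        return 0.5 * (self.focal_min + self.focal_max)

    def axis_direction(self) -> np.ndarray:
        """Unit vector of the optical axis, pointing toward the object (+z)."""
        t = math.radians(self.tilt_angle)
        a = math.radians(self.tilt_azimuth)
        return np.array(
            [math.sin(t) * math.cos(a), math.sin(t) * math.sin(a), math.cos(t)]
        )


@dataclass(frozen=True)
class SensorSpec:
    """Pixel grid of the shared sensor (defaults: OV5647-class 5 MP chip)."""

    pixel_pitch: float = 1.4             # μm
    width_px: int = 2592
    height_px: int = 1944
    channels: int = 1

    def __post_init__(self) -> None:
        if self.pixel_pitch <= 0 or self.width_px <= 0 or self.height_px <= 0:
            raise InvalidParameterError("sensor dimensions must be positive")
        if self.channels not in (1, 3):
            raise InvalidParameterError("channels must be 1 or 3")

    @property
    def width_um(self) -> float:
        return self.width_px * self.pixel_pitch

    @property
    def height_um(self) -> float:
        return self.height_px * self.pixel_pitch


@dataclass(frozen=True)
class ApertureSpec:
    """Single circular field stop shared by all lenslets."""

    diameter: float = 600.0              # μm
    height_above_lenslets: float = 2.0 * MM  # μm

    def __post_init__(self) -> None:
        if self.diameter <= 0:
            raise InvalidParameterError("stop diameter must be > 0")
        if self.height_above_lenslets < 0:
            raise InvalidParameterError("stop height must be >= 0")


@dataclass(frozen=True)
class DepthRange:
    """Axial sweep specification: object distances above the lenslet plane."""

    z_min: float                         # μm
    z_max: float                         # μm
    step: float = 100.0                  # μm

    def __post_init__(self) -> None:
        if not (0 < self.z_min < self.z_max):
            raise InvalidParameterError("need 0 < z_min < z_max")
        if self.step <= 0:
            raise InvalidParameterError("step must be > 0")

    def samples(self) -> np.ndarray:
        n = int(math.floor((self.z_max - self.z_min) / self.step + 1e-9)) + 1
        return self.z_min + self.step * np.arange(n)


@dataclass(frozen=True)
class ArraySpec:
    """The complete concave compound geometry.

    ``intersection_distance`` is where the tilted axes cross the central
    axis (above the lenslet plane); ``sensor_distance`` is the lenslet-plane
    to sensor-plane gap.  Both in μm.
    """

    lenslets: tuple[LensletSpec, ...]
    ring_radius: float = 370.0
    intersection_distance: float = 3.0 * MM
    sensor_distance: float = 3.0 * MM
    sensor: SensorSpec = field(default_factory=SensorSpec)
    stop: ApertureSpec = field(default_factory=ApertureSpec)

    def __post_init__(self) -> None:
        if self.intersection_distance <= 0 or self.sensor_distance <= 0:
            raise InvalidParameterError("distances must be positive")

    def lenslet(self, lens_id: int) -> LensletSpec:
        for lens in self.lenslets:
            if lens.id == lens_id:
                return lens
        raise UnknownLensletError(f"no lenslet with id {lens_id}")

    @property
    def center_lenslet_id(self) -> int:
        # smallest |center| wins; the default builder puts it at the origin
        return min(self.lenslets, key=lambda l: math.hypot(*l.center)).id

    def axis_common_point(self) -> np.ndarray:
        """Least-squares common crossing point of the 7 optical axes [μm].

        With the printed 7.057° tilt the crossing sits at z = ring_radius /
        tan(tilt) ≈ 2.989 mm, slightly below the nominal 3 mm (the printed
        tilt is not exactly arctan(r/Z)); the offset is well under 1% of the
        intersection distance.
        """
        a = np.zeros((3, 3))
        b = np.zeros(3)
        for lens in self.lenslets:
            p = np.array([lens.center[0], lens.center[1], 0.0])
            d = lens.axis_direction()
            proj = np.eye(3) - np.outer(d, d)
            a += proj
            b += proj @ p
        return np.linalg.solve(a, b)

    def axis_convergence_error(self, target=None) -> float:
        """Max distance [μm] of any axis from ``target`` (default: best fit)."""
        t = self.axis_common_point() if target is None else np.asarray(target, float)
        worst = 0.0
        for lens in self.lenslets:
            p = np.array([lens.center[0], lens.center[1], 0.0])
            d = lens.axis_direction()
            v = t - p
            dist = np.linalg.norm(v - np.dot(v, d) * d)
            worst = max(worst, float(dist))
        return worst


def default_array(
    *,
    lens_diameter: float = 370.0,
    ring_radius: float = 370.0,
    tilt_angle: float = 7.057,
    intersection_mm: float = 3.0,
    sensor_mm: float = 3.0,
    central_focal: tuple[float, float] = (1250.0, 1750.0),
    edge_focal: tuple[float, float] = (1500.0, 2000.0),
    sensor: SensorSpec | None = None,
    stop: ApertureSpec | None = None,
) -> ArraySpec:
    """Build the default seven-lenslet geometry.

    One untilted central lenslet (focal range 1.25–1.75 mm) plus six ring
    lenslets (1.5–2.0 mm) at 60° increments, each tilted toward the centre
    by ``tilt_angle`` so the axes meet ~3 mm above the array.
    """
    lenslets = [
        LensletSpec(
            id=1, center=(0.0, 0.0), diameter=lens_diameter,
            focal_min=central_focal[0], focal_max=central_focal[1],
        )
    ]
    for k in range(6):
        phi = 60.0 * k
        cx = ring_radius * math.cos(math.radians(phi))
        cy = ring_radius * math.sin(math.radians(phi))
        lenslets.append(
            LensletSpec(
                id=2 + k, center=(cx, cy), diameter=lens_diameter,
                focal_min=edge_focal[0], focal_max=edge_focal[1],
                tilt_angle=tilt_angle, tilt_azimuth=(phi + 180.0) % 360.0,
            )
        )
    return ArraySpec(
        lenslets=tuple(lenslets),
        ring_radius=ring_radius,
        intersection_distance=intersection_mm * MM,
        sensor_distance=sensor_mm * MM,
        sensor=sensor or SensorSpec(),
        stop=stop or ApertureSpec(),
    )


# ---------------------------------------------------------------------------
# scalar geometry
# ---------------------------------------------------------------------------

def lenslet_na(lens: LensletSpec, focal: float | None = None) -> float:
    """Geometric numerical aperture sin(arctan((D/2)/f)).

    With the printed design values (D = 370 μm, f = 1.75 mm — the edge
    lenslet's representative mid focal) this evaluates to ~0.105.
    ``focal`` defaults to the lenslet's focal_mid.
    """
    f = lens.focal_mid if focal is None else focal
    if f <= 0:
        raise InvalidParameterError("focal length must be > 0")
    return math.sin(math.atan((lens.diameter / 2.0) / f))


def tilt_for_intersection(ring_radius: float, intersection_distance: float) -> float:
    """Tilt angle [deg] for a ring lenslet axis to hit the central axis.

    ring_radius = 0 is the central lenslet (0°); otherwise both lengths
    must be positive and share units.
    """
    if ring_radius < 0 or intersection_distance <= 0:
        raise InvalidParameterError("lengths must be positive")
    return math.degrees(math.atan(ring_radius / intersection_distance))


def magnification_at_depth(array: ArraySpec, z: float) -> float:
    """Pinhole magnification m(z) = sensor_distance / z (z in μm)."""
    if z <= 0:
        raise InvalidParameterError("object distance must be > 0")
    return array.sensor_distance / z


def mean_magnification(array: ArraySpec, z_min: float, z_max: float) -> float:
    """Depth-averaged magnification (closed form d_s·ln(z2/z1)/(z2−z1))."""
    if not (0 < z_min < z_max):
        raise InvalidParameterError("need 0 < z_min < z_max")
    return array.sensor_distance * math.log(z_max / z_min) / (z_max - z_min)


def conjugate_object_range(
    lens: LensletSpec, sensor_distance: float
) -> tuple[float, float]:
    """Object-side detection range from thin-lens conjugates of the focal span.

    With image distance fixed at the sensor (v = sensor_distance), the focal
    range [f_min, f_max] maps to object distances u(f) = 1/(1/f − 1/v).
    For the central lenslet (1.25–1.75 mm, v = 3 mm) this is the printed
    ≈2 mm detection range (2.143–4.200 mm).
    """
    if sensor_distance <= lens.focal_max:
        raise NoRealConjugateError(
            "sensor_distance must exceed focal_max for a real object conjugate"
        )
    u = lambda f: 1.0 / (1.0 / f - 1.0 / sensor_distance)
    return (u(lens.focal_min), u(lens.focal_max))


# ---------------------------------------------------------------------------
# projection and field of view
# ---------------------------------------------------------------------------

def axis_sensor_intersection(array: ArraySpec, lens_id: int) -> np.ndarray:
    """Elemental-image reference centre: where the lenslet axis meets the sensor.

    For the pinhole model this is the image of the common intersection point,
    so an on-axis emitter at the intersection depth lands exactly here in
    every elemental image.
    """
    lens = array.lenslet(lens_id)
    p = np.asarray(lens.center, dtype=float)
    # axis passes through (0,0,Z_int); extend from vertex to z=-d_s
    return p * (1.0 + array.sensor_distance / array.intersection_distance)


def _stop_crossing(array: ArraySpec, p: np.ndarray, q: np.ndarray, z: float) -> np.ndarray:
    """Lateral position where the chief ray object(q,z)->vertex(p) crosses the stop."""
    h = array.stop.height_above_lenslets
    return p - (h / z) * (p - q)


def project_point(
    array: ArraySpec, lens_id: int, point
) -> np.ndarray | None:
    """Chief-ray projection of an object point onto the sensor plane.

    ``point`` is (x, y, z) in μm with z > 0.  Returns the sensor-plane
    (x, y) in μm, or ``None`` when the chief ray misses the field stop
    (the point is occluded for this lenslet).  The ray passes straight
    through the lenslet vertex (pinhole), so the image is inverted and
    scaled by d_s/z about the vertex.
    """
    lens = array.lenslet(lens_id)
    q = np.asarray(point, dtype=float)
    if q[2] <= 0:
        raise InvalidParameterError("object point must lie above the lenslet plane")
    p = np.asarray(lens.center, dtype=float)
    z = float(q[2])
    xy = _stop_crossing(array, p, q[:2], z)
    if np.hypot(xy[0], xy[1]) > array.stop.diameter / 2.0:
        return None
    return p + (array.sensor_distance / z) * (p - q[:2])


def fov_window(array: ArraySpec, lens_id: int, z: float) -> tuple[np.ndarray, float]:
    """Object-plane visibility disk of one lenslet at depth z.

    The set of object positions whose chief ray to the vertex passes the
    stop is a disk of diameter a·z/h centred at p·(1 − z/h), where a and h
    are the stop diameter and height and p the lenslet position — a pure
    similar-triangle consequence, affine in z.
    Returns (center_xy [μm], diameter [μm]).
    """
    if z <= 0:
        raise InvalidParameterError("depth must be > 0")
    lens = array.lenslet(lens_id)
    h = array.stop.height_above_lenslets
    p = np.asarray(lens.center, dtype=float)
    if h == 0:
        # stop in the lenslet plane: window is the stop itself, depth-free
        return np.zeros(2), array.stop.diameter
    center = p * (1.0 - z / h)
    diameter = array.stop.diameter * z / h
    return center, diameter


def fov_windows_at_depth(array: ArraySpec, z: float) -> dict:
    """Per-lenslet windows plus union / full-intersection extents at depth z.

    Returns a dict with ``windows`` (lens_id -> (center, diameter)),
    ``union_diameter`` (outer extent seen by at least one lenslet) and
    ``intersection_diameter`` (equivalent-area diameter of the region seen
    by all seven — the geometric fovea).
    """
    windows = {lens.id: fov_window(array, lens.id, z) for lens in array.lenslets}
    radii = {k: d / 2.0 for k, (c, d) in windows.items()}
    union_diameter = 2.0 * max(
        float(np.hypot(*c)) + radii[k] for k, (c, d) in windows.items()
    )
    counts, pitch = coverage_count_grid(array, z, pixel=union_diameter / 800.0)
    full = counts >= len(array.lenslets)
    inter_diam = 2.0 * math.sqrt(full.sum() * pitch**2 / math.pi)
    return {
        "windows": windows,
        "union_diameter": union_diameter,
        "intersection_diameter": inter_diam,
    }


def coverage_count_grid(
    array: ArraySpec, z: float, pixel: float = 5.0
) -> tuple[np.ndarray, float]:
    """Rasterized lenslet-coverage count over the object plane at depth z.

    Returns (counts, pixel) where counts[i, j] is the number of lenslet
    windows containing that object-plane position.  The grid spans the
    union of all windows.
    """
    windows = [fov_window(array, lens.id, z) for lens in array.lenslets]
    extent = max(float(np.hypot(*c)) + d / 2.0 for c, d in windows) + 2 * pixel
    n = int(math.ceil(2 * extent / pixel))
    ax = (np.arange(n) - (n - 1) / 2.0) * pixel
    xx, yy = np.meshgrid(ax, ax)
    counts = np.zeros((n, n), dtype=np.int16)
    for c, d in windows:
        counts += ((xx - c[0]) ** 2 + (yy - c[1]) ** 2) <= (d / 2.0) ** 2
    return counts, pixel


def zone_extents(array: ArraySpec, zrange: DepthRange, pixel: float = 5.0):
    """Foveated / blend / peripheral diameters versus depth.

    Zones are cumulative coverage-count regions — foveated: covered by ≥6
    lenslets, blend: ≥3, peripheral: ≥1 — reported as equivalent-area
    diameters (2·sqrt(area/π)) so the nesting foveated ⊆ blend ⊆ peripheral
    holds by construction.  Returns a pandas DataFrame with columns
    ``z, foveated, blend, peripheral`` [μm] and a dict of depth means.
    """
    import pandas as pd

    rows = []
    n_lens = len(array.lenslets)
    for z in zrange.samples():
        counts, pitch = coverage_count_grid(array, z, pixel=pixel)
        diam = {}
        for name, thresh in (("foveated", min(6, n_lens)), ("blend", min(3, n_lens)),
                             ("peripheral", 1)):
            area = float((counts >= thresh).sum()) * pitch**2
            diam[name] = 2.0 * math.sqrt(area / math.pi)
        rows.append({"z": z, **diam})
    table = pd.DataFrame(rows)
    means = {k: float(table[k].mean()) for k in ("foveated", "blend", "peripheral")}
    return table, means


def with_stop(array: ArraySpec, *, diameter: float | None = None,
              height_mm: float | None = None) -> ArraySpec:
    """Convenience copy-with-modified-stop (stop height is a free design knob)."""
    stop = ApertureSpec(
        diameter=array.stop.diameter if diameter is None else diameter,
        height_above_lenslets=(
            array.stop.height_above_lenslets if height_mm is None else height_mm * MM
        ),
    )
    return replace(array, stop=stop)
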