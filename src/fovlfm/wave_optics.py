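"""Scalar-diffraction model of logarithmic-axicon and spherical lenslets.

A logarithmic axicon maps aperture radius to focal length quadratically,

    f(r) = f_min + (f_max - f_min) * r^2 / R^2,

so successive annular zones focus onto a continuous axial segment
[f_min, f_max] instead of a single point.  Integrating the local focusing
condition dφ/dr = -k r / f(r) gives the logarithmic phase

    φ(r) = -(k / 2α) * ln(1 + α r^2 / f_min),   α = (f_max - f_min) / R^2,

the uniform-axial-intensity axicon design; for α → 0 it reduces to the
paraxial spherical phase -k r^2 / (2 f).  This extended depth of focus is
what lets one fixed sensor plane stay "in focus" over the imager's ~2 mm
object-side detection range.

Propagation is the band-limited angular-spectrum method (exact scalar
free-space transfer, evanescent components dropped, transfer function
clipped at the Matsushima sampling limit), which conserves power within
the propagating band.  Object-side point sources are modelled as diverging
spherical waves sampled at the lens plane, so the imaging chain is
point -> (spherical wave x aperture x lens phase) -> sensor plane.

All lengths in μm except wavelengths, which follow the field convention
of nanometres at the interface.
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass, field

import numpy as np
from scipy import ndimage
from scipy.fft import fft2, fftfreq, ifft2

from .array_model import ArraySpec, InvalidParameterError, LensletSpec

__all__ = [
    "PhaseProfile",
    "FieldGrid",
    "AxialResponse",
    "log_axicon_phase",
    "spherical_phase",
    "plane_wave_field",
    "point_source_field",
    "propagate_angular_spectrum",
    "axial_response",
    "object_space_response",
    "edof_range",
    "edof_ratio",
    "psf_kernel_at_depth",
    "approx_fwhm_at_depth",
    "variance_of_laplacian",
    "fwhm_1d",
]

DEFAULT_WAVELENGTH_NM = 635.0


class SamplingError(ValueError):
    """Grid pitch too coarse for the field's maximum phase gradient."""


# ---------------------------------------------------------------------------
# phase profiles
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class PhaseProfile:
    """Rotationally symmetric thin-element phase, φ(0) = 0.

    ``samples`` holds an (n, 2) radial lookup table (r [μm], φ [rad]) for
    export; the analytic form is used everywhere internally.
    """

    kind: str                       # "log_axicon" | "spherical"
    aperture_radius: float          # μm
    focal_min: float                # μm
    focal_max: float                # μm
    wavelength: float = DEFAULT_WAVELENGTH_NM   # nm
    n_samples: int = 2048

    @property
    def k(self) -> float:
        return 2.0 * math.pi / (self.wavelength * 1e-3)  # rad/μm

    @property
    def alpha(self) -> float:
        return (self.focal_max - self.focal_min) / self.aperture_radius**2

    def focal_at_radius(self, r):
        """Local focal length f(r) of the annular zone at radius r."""
        return self.focal_min + self.alpha * np.asarray(r, dtype=float) ** 2

    def phase(self, r):
        """φ(r) [rad]; defined for r <= aperture_radius (not masked here)."""
        r = np.asarray(r, dtype=float)
        if self.kind == "spherical":
            f = self.focal_min
            return -self.k * (np.sqrt(r**2 + f**2) - f)
        a = self.alpha
        if a == 0.0:
            return -self.k * r**2 / (2.0 * self.focal_min)
        return -(self.k / (2.0 * a)) * np.log1p(a * r**2 / self.focal_min)

    def max_phase_gradient(self) -> float:
        """sup |dφ/dr| over the aperture [rad/μm] (attained at the rim)."""
        r = self.aperture_radius
        if self.kind == "spherical":
            f = self.focal_min
            return self.k * r / math.sqrt(r**2 + f**2)
        return self.k * r / float(self.focal_at_radius(r))

    @property
    def samples(self) -> np.ndarray:
        r = np.linspace(0.0, self.aperture_radius, self.n_samples)
        return np.column_stack([r, self.phase(r)])

    def sag(self, r, refractive_index: float = 1.51):
        """Equivalent surface height [μm] for a resist of the given index."""
        return self.phase(r) * (self.wavelength * 1e-3) / (
            2.0 * math.pi * (refractive_index - 1.0)
        )


def log_axicon_phase(
    aperture_radius: float,
    focal_min: float,
    focal_max: float,
    wavelength: float = DEFAULT_WAVELENGTH_NM,
) -> PhaseProfile:
    """Logarithmic-axicon profile with quadratic radius-to-focus mapping."""
    if focal_min <= 0 or not (focal_min <= focal_max):
        raise InvalidParameterError("need 0 < focal_min <= focal_max")
    if aperture_radius <= 0:
        raise InvalidParameterError("aperture_radius must be > 0")
    return PhaseProfile("log_axicon", aperture_radius, focal_min, focal_max, wavelength)


def spherical_phase(
    aperture_radius: float, focal: float, wavelength: float = DEFAULT_WAVELENGTH_NM
) -> PhaseProfile:
    """Exact spherical converging phase φ(r) = -k(sqrt(r²+f²) - f)."""
    if focal <= 0:
        raise InvalidParameterError("focal must be > 0")
    if aperture_radius <= 0:
        raise InvalidParameterError("aperture_radius must be > 0")
    return PhaseProfile("spherical", aperture_radius, focal, focal, wavelength)


# ---------------------------------------------------------------------------
# fields
# ---------------------------------------------------------------------------

@dataclass
class FieldGrid:
    """Complex scalar field on a square grid of physical ``pitch`` [μm]."""

    values: np.ndarray
    pitch: float
    wavelength: float = DEFAULT_WAVELENGTH_NM   # nm

    def __post_init__(self) -> None:
        if self.values.ndim != 2:
            raise InvalidParameterError("field must be 2D")
        if self.pitch <= 0:
            raise InvalidParameterError("pitch must be > 0")
        if not np.isfinite(self.power):
            raise InvalidParameterError("field power must be finite")

    @property
    def power(self) -> float:
        return float(np.sum(np.abs(self.values) ** 2))

    @property
    def intensity(self) -> np.ndarray:
        return np.abs(self.values) ** 2

    def radial_axes(self) -> tuple[np.ndarray, np.ndarray]:
        n = self.values.shape[0]
        ax = (np.arange(n) - n // 2) * self.pitch
        return np.meshgrid(ax, ax, indexing="xy")


def _grid_r2(n: int, pitch: float) -> np.ndarray:
    ax = (np.arange(n) - n // 2) * pitch
    xx, yy = np.meshgrid(ax, ax)
    return xx**2 + yy**2


def _check_sampling(max_gradient: float, pitch: float) -> None:
    # Nyquist: at least two samples per phase fringe of the product field
    if max_gradient * pitch > math.pi:
        raise SamplingError(
            f"pitch {pitch:.3f} μm undersamples phase gradient "
            f"{max_gradient:.3f} rad/μm (Nyquist limit "
            f"{math.pi / max_gradient:.3f} μm)"
        )


def plane_wave_field(
    profile: PhaseProfile, grid_n: int = 2048, guard: float = 2.0
) -> FieldGrid:
    """Unit plane wave through the aperture-masked phase profile.

    The grid spans ``guard`` times the aperture diameter; pitch follows.
    Sampling is validated against the profile's maximum phase gradient.
    """
    pitch = guard * 2.0 * profile.aperture_radius / grid_n
    _check_sampling(profile.max_phase_gradient(), pitch)
    r2 = _grid_r2(grid_n, pitch)
    mask = r2 <= profile.aperture_radius**2
    u = np.zeros((grid_n, grid_n), dtype=np.complex64)
    u[mask] = np.exp(1j * profile.phase(np.sqrt(r2[mask])))
    return FieldGrid(u, pitch, profile.wavelength)


def point_source_field(
    profile: PhaseProfile, z_obj: float, grid_n: int = 2048, guard: float = 2.0
) -> FieldGrid:
    """Field just after the lens for an on-axis point emitter at depth z_obj.

    The incident diverging spherical wave exp(i k sqrt(r²+z²)) is multiplied
    by the aperture mask and lens phase analytically per pixel, so only the
    *transmitted* (nearly converging) field needs to satisfy the sampling
    bound.
    """
    if z_obj <= 0:
        raise InvalidParameterError("z_obj must be > 0")
    pitch = guard * 2.0 * profile.aperture_radius / grid_n
    k = profile.k
    rim = profile.aperture_radius
    inc_grad = k * rim / math.hypot(rim, z_obj)
    # gradients of incident (diverging, +) and lens (converging, -) partly cancel
    net = abs(inc_grad - profile.max_phase_gradient())
    _check_sampling(max(net, 0.25 * profile.max_phase_gradient()), pitch)
    r2 = _grid_r2(grid_n, pitch)
    mask = r2 <= rim**2
    u = np.zeros((grid_n, grid_n), dtype=np.complex64)
    rm = np.sqrt(r2[mask])
    u[mask] = np.exp(1j * (k * np.sqrt(r2[mask] + z_obj**2) + profile.phase(rm)))
    return FieldGrid(u, pitch, profile.wavelength)


# ---------------------------------------------------------------------------
# propagation
# ---------------------------------------------------------------------------

def _transfer(shape, pitch, wavelength_nm, distance):
    """Band-limited angular-spectrum transfer function."""
    lam = wavelength_nm * 1e-3
    fy = fftfreq(shape[0], d=pitch)
    fx = fftfreq(shape[1], d=pitch)
    fxx, fyy = np.meshgrid(fx, fy)
    f2 = fxx**2 + fyy**2
    arg = 1.0 - (lam**2) * f2
    prop = arg > 0.0
    h = np.zeros(shape, dtype=np.complex64)
    h[prop] = np.exp(1j * 2.0 * np.pi / lam * abs(distance) * np.sqrt(arg[prop]))
    if distance < 0:
        h = np.conj(h)
    # Matsushima band limit: keep H where its phase is adequately sampled
    if distance != 0:
        dfx = 1.0 / (shape[1] * pitch)
        dfy = 1.0 / (shape[0] * pitch)
        fx_lim = 1.0 / (lam * math.sqrt((2.0 * dfx * abs(distance)) ** 2 + 1.0))
        fy_lim = 1.0 / (lam * math.sqrt((2.0 * dfy * abs(distance)) ** 2 + 1.0))
        h[(np.abs(fxx) > fx_lim) | (np.abs(fyy) > fy_lim)] = 0.0
    return h


def propagate_angular_spectrum(fieldgrid: FieldGrid, distance: float) -> FieldGrid:
    """Free-space propagation by ``distance`` [μm] (sign = direction).

    Power is conserved to numerical precision within the propagating,
    band-limited spectrum; a warning is raised when the band limit clips a
    non-negligible fraction of the field's power (aliasing risk).
    """
    if distance == 0:
        return FieldGrid(fieldgrid.values.copy(), fieldgrid.pitch, fieldgrid.wavelength)
    spec = fft2(fieldgrid.values)
    h = _transfer(fieldgrid.values.shape, fieldgrid.pitch, fieldgrid.wavelength, distance)
    p_in = float(np.sum(np.abs(spec) ** 2))
    out_spec = spec * h
    p_kept = float(np.sum(np.abs(out_spec) ** 2))
    if p_in > 0 and (p_in - p_kept) / p_in > 1e-3:
        warnings.warn(
            "angular-spectrum band limit clipped "
            f"{(p_in - p_kept) / p_in:.2%} of the field power; "
            "increase the grid or guard band",
            RuntimeWarning,
            stacklevel=2,
        )
    return FieldGrid(
        np.asarray(ifft2(out_spec), dtype=np.complex64),
        fieldgrid.pitch,
        fieldgrid.wavelength,
    )


# ---------------------------------------------------------------------------
# axial metrics
# ---------------------------------------------------------------------------

@dataclass
class AxialResponse:
    """Normalized focus metric sampled along the axis (max = 1)."""

    z: np.ndarray                   # μm
    values: np.ndarray
    criterion: str = "on_axis_intensity"

    def __post_init__(self) -> None:
        self.z = np.asarray(self.z, dtype=float)
        self.values = np.asarray(self.values, dtype=float)
        if self.z.size != self.values.size or self.z.size == 0:
            raise InvalidParameterError("z and values must be same nonzero length")
        if np.any(self.values < 0):
            raise InvalidParameterError("response must be nonnegative")
        peak = self.values.max()
        if peak > 0:
            self.values = self.values / peak


def variance_of_laplacian(image: np.ndarray) -> float:
    """Classic degree-of-focus score: Var(∇² I)."""
    return float(np.var(ndimage.laplace(np.asarray(image, dtype=np.float32))))


def _criterion_value(intensity: np.ndarray, criterion: str) -> float:
    if criterion == "on_axis_intensity":
        n = intensity.shape[0]
        return float(intensity[n // 2, intensity.shape[1] // 2])
    if criterion == "focus_score":
        return variance_of_laplacian(intensity)
    raise InvalidParameterError(f"unknown criterion {criterion!r}")


def axial_response(
    profile: PhaseProfile,
    zs,
    criterion: str = "on_axis_intensity",
    grid_n: int = 1024,
    guard: float = 2.0,
) -> AxialResponse:
    """Image-space response: plane wave through the profile, probed at each z."""
    zs = np.asarray(zs, dtype=float)
    if zs.size == 0:
        raise InvalidParameterError("empty z range")
    u0 = plane_wave_field(profile, grid_n=grid_n, guard=guard)
    spec = fft2(u0.values)
    vals = np.empty(zs.size)
    for i, z in enumerate(zs):
        h = _transfer(u0.values.shape, u0.pitch, u0.wavelength, float(z))
        intensity = np.abs(ifft2(spec * h)) ** 2
        vals[i] = _criterion_value(intensity, criterion)
    return AxialResponse(zs, vals, criterion)


def object_space_response(
    profile: PhaseProfile,
    sensor_distance: float,
    zs,
    criterion: str = "focus_score",
    grid_n: int = 2048,
    guard: float = 2.0,
) -> AxialResponse:
    """Object-space response with the sensor plane fixed.

    For each object depth z the on-axis point-source PSF on the sensor is
    simulated and scored; this is the quantity behind the imager's
    extended-depth-of-focus claim.
    """
    zs = np.asarray(zs, dtype=float)
    if zs.size == 0:
        raise InvalidParameterError("empty z range")
    vals = np.empty(zs.size)
    for i, z in enumerate(zs):
        u = point_source_field(profile, float(z), grid_n=grid_n, guard=guard)
        with warnings.catch_warnings():
            warnings.simplefilter("ignore", RuntimeWarning)
            us = propagate_angular_spectrum(u, sensor_distance)
        vals[i] = _criterion_value(us.intensity, criterion)
    return AxialResponse(zs, vals, criterion)


def edof_range(resp: AxialResponse, threshold: float = 0.5) -> float:
    """Length [μm] of the contiguous above-threshold interval around the peak.

    Crossing positions are linearly interpolated between samples.  Returns 0
    (with a warning) when the response never reaches the threshold.
    """
    v, z = resp.values, resp.z
    imax = int(np.argmax(v))
    if v[imax] < threshold:
        warnings.warn("response never reaches threshold", RuntimeWarning, stacklevel=2)
        return 0.0
    # walk left
    lo = z[0]
    for i in range(imax, 0, -1):
        if v[i - 1] < threshold:
            frac = (v[i] - threshold) / (v[i] - v[i - 1])
            lo = z[i] - frac * (z[i] - z[i - 1])
            break
    hi = z[-1]
    for i in range(imax, len(v) - 1):
        if v[i + 1] < threshold:
            frac = (v[i] - threshold) / (v[i] - v[i + 1])
            hi = z[i] + frac * (z[i + 1] - z[i])
            break
    return float(hi - lo)


def edof_ratio(
    array: ArraySpec,
    wavelength: float = DEFAULT_WAVELENGTH_NM,
    grid_n: int = 2048,
    z_span: tuple[float, float] = (1800.0, 4500.0),
    z_step: float = 25.0,
    threshold: float = 0.5,
    criterion: str = "focus_score",
) -> float:
    """Object-space in-focus range of the log-axicon central lenslet divided
    by that of an equal-aperture spherical lenslet at the midpoint focal.

    Both optics image onto the fixed sensor plane; the in-focus range is the
    half-maximum width of the focus-score curve.  The design target is a
    ratio exceeding ~6.
    """
    lens = array.lenslet(array.center_lenslet_id)
    radius = lens.diameter / 2.0
    zs = np.arange(z_span[0], z_span[1] + z_step / 2, z_step)
    log_p = log_axicon_phase(radius, lens.focal_min, lens.focal_max, wavelength)
    sph_p = spherical_phase(radius, lens.focal_mid, wavelength)
    r_log = edof_range(
        object_space_response(log_p, array.sensor_distance, zs, criterion, grid_n),
        threshold,
    )
    r_sph = edof_range(
        object_space_response(sph_p, array.sensor_distance, zs, criterion, grid_n),
        threshold,
    )
    if r_sph == 0:
        raise RuntimeError("spherical reference response below threshold everywhere")
    return r_log / r_sph


# ---------------------------------------------------------------------------
# PSF kernels
# ---------------------------------------------------------------------------

def fwhm_1d(x: np.ndarray, y: np.ndarray) -> float:
    """Full width at half maximum of a sampled single-peaked curve."""
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    imax = int(np.argmax(y))
    half = y[imax] / 2.0
    lo = x[0]
    for i in range(imax, 0, -1):
        if y[i - 1] < half:
            frac = (y[i] - half) / (y[i] - y[i - 1])
            lo = x[i] - frac * (x[i] - x[i - 1])
            break
    hi = x[-1]
    for i in range(imax, len(y) - 1):
        if y[i + 1] < half:
            frac = (y[i] - half) / (y[i] - y[i + 1])
            hi = x[i] + frac * (x[i + 1] - x[i])
            break
    return float(hi - lo)


def _point_psf(
    profile: PhaseProfile, z_obj: float, sensor_distance: float,
    grid_n: int = 1024, guard: float = 2.0
) -> FieldGrid:
    """Sensor-plane field for an on-axis point emitter at depth ``z_obj``."""
    u = point_source_field(profile, z_obj, grid_n=grid_n, guard=guard)
    with warnings.catch_warnings():
        warnings.simplefilter("ignore", RuntimeWarning)
        return propagate_angular_spectrum(u, sensor_distance)


_FWHM_CACHE: dict[tuple, float] = {}


def psf_fwhm_at_depth(
    profile: PhaseProfile,
    sensor_distance: float,
    z_obj: float,
    grid_n: int = 768,
) -> float:
    """Lateral PSF core FWHM [μm] from scalar diffraction, cached per depth.

    The full wave-optics PSF is evaluated exactly at each requested depth
    (memoized at 0.1 μm granularity), so the fast rendering path gets
    diffraction-accurate spot widths for the handful of depths a scene
    actually uses.  Interpolating between precomputed depths is *not* safe
    here: the width changes by factors of several across the thin-lens
    conjugate boundaries of the focal range.  Note this is the width of
    the central core only; the out-of-range halo carries energy the
    Gaussian approximation ignores.
    """
    key = (
        profile.kind, profile.aperture_radius, profile.focal_min,
        profile.focal_max, profile.wavelength, sensor_distance,
        round(float(z_obj), 1), grid_n,
    )
    if key not in _FWHM_CACHE:
        field = _point_psf(profile, float(z_obj), sensor_distance, grid_n)
        intensity = field.intensity
        n = intensity.shape[0]
        xs = (np.arange(n) - n // 2) * field.pitch
        _FWHM_CACHE[key] = fwhm_1d(xs, intensity[n // 2])
    return _FWHM_CACHE[key]


def psf_kernel_at_depth(
    profile: PhaseProfile,
    z_obj: float,
    array: ArraySpec,
    grid_n: int = 1024,
    guard: float = 2.0,
    clip: float = 1e-4,
) -> tuple[np.ndarray, float]:
    """Sensor-plane intensity PSF of a point emitter at depth z_obj.

    Returns a small unit-sum kernel resampled to the sensor pixel pitch and
    its lateral FWHM in sensor-plane μm.  Depths outside the thin-lens
    conjugate span of the focal range raise an extrapolation warning.
    """
    lens = array.lenslet(array.center_lenslet_id)
    try:
        from .array_model import conjugate_object_range

        z_near, z_far = conjugate_object_range(lens, array.sensor_distance)
        if not (z_near <= z_obj <= z_far):
            warnings.warn(
                f"z_obj={z_obj:.0f} μm outside conjugate validity "
                f"[{z_near:.0f}, {z_far:.0f}]",
                RuntimeWarning,
                stacklevel=2,
            )
    except Exception:
        pass
    us = _point_psf(profile, z_obj, array.sensor_distance, grid_n, guard)
    intensity = us.intensity
    n = intensity.shape[0]
    prof = intensity[n // 2]
    xs = (np.arange(n) - n // 2) * us.pitch
    fwhm = fwhm_1d(xs, prof)
    # resample to sensor pitch and crop to the significant support
    factor = us.pitch / array.sensor.pixel_pitch
    kernel = ndimage.zoom(intensity, factor, order=1)
    kernel = np.clip(kernel, 0.0, None)
    keep = kernel > clip * kernel.max()
    rows = np.where(keep.any(axis=1))[0]
    cols = np.where(keep.any(axis=0))[0]
    kernel = kernel[rows[0]: rows[-1] + 1, cols[0]: cols[-1] + 1]
    s = kernel.sum()
    if s <= 0:
        raise RuntimeError("degenerate PSF kernel")
    return kernel / s, fwhm


def approx_fwhm_at_depth(
    lens: LensletSpec,
    array: ArraySpec,
    z_obj: float,
    fwhm_focus: float = 6.0,
) -> float:
    """Cheap geometric PSF-width model for the fast rendering path.

    Inside the thin-lens conjugate span of the lenslet's focal range some
    annular zone focuses exactly on the sensor, so the width is the
    (near-constant) in-focus value ``fwhm_focus`` [μm] — the extended
    depth of focus.  Outside, the width grows continuously with the
    ray-blur of the energy-median annulus (radius R/√2) against the
    nearest in-range focal power:
    b = (R/√2)·d_s·dist(1/f_req, [1/f_max, 1/f_min]),
    FWHM = hypot(fwhm_focus, 2b).
    """
    if z_obj <= 0:
        raise InvalidParameterError("z_obj must be > 0")
    d_s = array.sensor_distance
    inv_req = 1.0 / z_obj + 1.0 / d_s          # = 1/f_req
    dist = max(0.0, inv_req - 1.0 / lens.focal_min,
               1.0 / lens.focal_max - inv_req)
    if dist == 0.0:
        return fwhm_focus
    r_med = lens.diameter / 2.0 / math.sqrt(2.0)
    blur = r_med * d_s * dist
    return math.hypot(fwhm_focus, 2.0 * blur)
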