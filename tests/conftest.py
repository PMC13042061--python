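"""Shared fixtures: the default imager geometry and one calibration session.

The expensive artefacts (rendered aperture frame, 21-step PSF calibration
stack, fitted translation curves) are session-scoped so every test module
reuses one forward-model run.
"""

from __future__ import annotations

import warnings

import numpy as np
import pytest
from hypothesis import settings

import fovlfm
from fovlfm import array_model, calibration, phantoms

settings.register_profile("ci", deadline=None, max_examples=25, derandomize=True)
settings.load_profile("ci")


@pytest.fixture(scope="session")
def array():
    return fovlfm.default_array()


@pytest.fixture(scope="session")
def aperture_frame(array):
    return phantoms.render_aperture_frame(array)


@pytest.fixture(scope="session")
def aperture_mask(array, aperture_frame):
    return calibration.segment_apertures(aperture_frame)


@pytest.fixture(scope="session")
def depth_range():
    return array_model.DepthRange(2000.0, 4000.0, 100.0)


@pytest.fixture(scope="session")
def psf_stack(array, depth_range):
    scenes = phantoms.psf_calibration_stack_scene(depth_range)
    return [(z, phantoms.render_capture(scene, array)) for z, scene in scenes]


@pytest.fixture(scope="session")
def localizations(psf_stack, aperture_mask):
    return calibration.localize_psfs(psf_stack, aperture_mask)


@pytest.fixture(scope="session")
def tmodel_linear(localizations):
    return calibration.fit_translation_model(localizations, model="linear")


@pytest.fixture(scope="session")
def tmodel_piecewise(localizations):
    return calibration.fit_translation_model(localizations, model="piecewise")


@pytest.fixture(scope="session")
def tmodel_inverse(localizations):
    return calibration.fit_translation_model(localizations, model="inverse")


@pytest.fixture(scope="session")
def mag_model(array):
    return calibration.fit_magnification("parametric", array=array)


@pytest.fixture(scope="session")
def center_roi(array):
    h, w = array.sensor.height_px, array.sensor.width_px
    return (h // 2 - 250, h // 2 + 250, w // 2 - 250, w // 2 + 250)


@pytest.fixture()
def quiet_warnings():
    with warnings.catch_warnings():
        warnings.simplefilter("ignore", RuntimeWarning)
        yield


def true_registration_shift(array, lens_id: int, z: float) -> tuple[float, float]:
    """Pinhole-oracle registration shift (centre − edge) in pixels."""
    lens = array.lenslet(lens_id)
    p = np.asarray(lens.center)
    shift_um = -p * (1.0 + array.sensor_distance / z)
    # (d_row, d_col) = (y, x) / pitch
    return (shift_um[1] / array.sensor.pixel_pitch,
            shift_um[0] / array.sensor.pixel_pitch)
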