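"""Reconstruction pipeline: refocusing, zones, masking, rescaling, autofocus."""

import numpy as np
import pytest
from scipy import ndimage
from skimage import measure, restoration

from fovlfm import array_model as am
from fovlfm import calibration as cal
from fovlfm import phantoms as ph
from fovlfm import reconstruction as rec


def identity_translation(n_lenslets: int = 7) -> cal.TranslationModel:
    """All-zero translation curves (elements already registered)."""
    curves = {i: {"row": (0.0, 0.0), "col": (0.0, 0.0)}
              for i in range(1, n_lenslets + 1)}
    return cal.TranslationModel(
        center_lenslet=1, curves=curves,
        residual_rms={i: 0.0 for i in curves},
        z_min=0.0, z_max=1e9, model="linear",
    )


def toy_elements(n: int = 96) -> tuple[rec.ElementalSet, cal.ApertureMask]:
    """Seven tiny fully-overlapping elements with one spot in the centre view."""
    masks = {i: np.ones((n, n), dtype=bool) for i in range(1, 8)}
    images = {i: np.zeros((n, n), dtype=np.float32) for i in range(1, 8)}
    images[1][30, 30] = 1.0
    labels = np.ones((n, n), dtype=np.uint8)
    mask = cal.ApertureMask(labels, {1: (n / 2, n / 2)},
                            {1: (0, 0, n, n)})
    elements = rec.ElementalSet(images, masks, 1.4)
    return elements, mask


class TestBackgroundSubtraction:
    def test_constant_image_maps_to_zero(self):
        frame = ph.CaptureFrame(np.full((64, 64), 9.0, np.float32), 1.4)
        out = rec.subtract_background(frame, radius=10, downscale=1)
        assert np.allclose(out.image, 0.0, atol=1e-6)

    def test_impulse_preserved_on_flat_background(self):
        img = np.full((64, 64), 5.0, np.float32)
        img[32, 32] = 50.0
        out = rec.subtract_background(ph.CaptureFrame(img, 1.4), radius=10,
                                      downscale=1)
        assert out.image[32, 32] > 40.0
        assert out.image[5, 5] < 1e-6

    def test_matches_reference_rolling_ball(self):
        rng = np.random.default_rng(3)
        img = ndimage.gaussian_filter(rng.uniform(0, 100, (80, 80)), 2.0)
        frame = ph.CaptureFrame(img.astype(np.float32), 1.4)
        exact = rec.subtract_background(frame, radius=8, downscale=1)
        reference = np.clip(img - restoration.rolling_ball(img, radius=8), 0, None)
        assert np.max(np.abs(exact.image - reference)) < 1e-4
        fast = rec.subtract_background(frame, radius=8, downscale=2)
        assert np.max(np.abs(fast.image - reference)) < 0.10 * img.max()

    def test_degenerate_radius_rejected(self):
        frame = ph.CaptureFrame(np.zeros((32, 32), np.float32), 1.4)
        with pytest.raises(am.InvalidParameterError):
            rec.subtract_background(frame, radius=40)
        with pytest.raises(am.InvalidParameterError):
            rec.subtract_background(frame, radius=0)


class TestExtraction:
    def test_partition_property(self, array, aperture_mask, psf_stack):
        _, frame = psf_stack[10]
        elements = rec.extract_elementals(frame, aperture_mask)
        total = sum(elements.images.values())
        masked_original = np.where(aperture_mask.labels > 0,
                                   np.asarray(frame.image, np.float32), 0.0)
        assert np.allclose(total, masked_original, atol=1e-6)

    def test_each_element_holds_one_spot(self, aperture_mask, psf_stack):
        _, frame = psf_stack[10]
        elements = rec.extract_elementals(frame, aperture_mask)
        for label, img in elements.images.items():
            comps = measure.label(img > 0.05 * img.max())
            assert comps.max() == 1

    def test_dimension_mismatch_rejected(self, aperture_mask):
        bad = ph.CaptureFrame(np.zeros((10, 10), np.float32), 1.4)
        with pytest.raises(am.InvalidParameterError):
            rec.extract_elementals(bad, aperture_mask)


class TestTranslateImage:
    def test_integer_shift_moves_content_exactly(self):
        img = np.zeros((16, 16), np.float32)
        img[4, 6] = 2.0
        out = rec.translate_image(img, 3.0, -2.0)
        assert out[7, 4] == 2.0 and out.sum() == 2.0

    def test_bilinear_weights_conserve_interior_energy(self):
        rng = np.random.default_rng(0)
        img = np.zeros((40, 40), np.float32)
        img[15:25, 15:25] = rng.uniform(1, 2, (10, 10))
        out = rec.translate_image(img, 2.3, -1.7)
        assert out.sum() == pytest.approx(img.sum(), rel=1e-6)

    def test_roi_equals_cropped_full_translation(self):
        rng = np.random.default_rng(1)
        img = rng.uniform(0, 1, (64, 64)).astype(np.float32)
        full = rec.translate_image(img, -5.4, 8.2)
        roi = (10, 50, 12, 44)
        window = rec.translate_image(img, -5.4, 8.2, roi=roi)
        assert np.allclose(window, full[roi[0]:roi[1], roi[2]:roi[3]],
                           atol=1e-6)


class TestRefocus:
    def test_peak_at_true_depth_within_one_step(self, array, aperture_mask,
                                                tmodel_piecewise, center_roi,
                                                quiet_warnings):
        scene = ph.Scene((ph.Emitter((0.0, 0.0, 3200.0), 2.5),),
                         extent=(1000, 1000, 4500))
        frame = ph.render_capture(scene, array)
        elements = rec.extract_elementals(frame, aperture_mask)
        zs = np.arange(2800.0, 3601.0, 100.0)
        stack = rec.focal_stack(elements, tmodel_piecewise, zs, roi=center_roi)
        peaks = stack.data.max(axis=(1, 2))
        assert abs(stack.zs[np.argmax(peaks)] - 3200.0) <= 100.0

    def test_defocused_point_spreads_into_subspots(self, array, aperture_mask,
                                                   tmodel_piecewise, center_roi,
                                                   quiet_warnings):
        scene = ph.Scene((ph.Emitter((0.0, 0.0, 3000.0), 2.5),),
                         extent=(1000, 1000, 4500))
        frame = ph.render_capture(scene, array)
        elements = rec.extract_elementals(frame, aperture_mask)
        sharp = rec.refocus(elements, tmodel_piecewise, 3000.0, roi=center_roi)
        blurred = rec.refocus(elements, tmodel_piecewise, 3500.0, roi=center_roi)
        assert sharp.max() > 2.5 * blurred.max()
        comps = measure.label(blurred > 0.3 * blurred.max())
        assert 2 <= comps.max() <= 7

    def test_refocus_equals_sum_of_translated_elements(self, aperture_mask,
                                                       psf_stack,
                                                       tmodel_piecewise,
                                                       quiet_warnings):
        _, frame = psf_stack[5]
        elements = rec.extract_elementals(frame, aperture_mask)
        z = 2750.0
        out = rec.refocus(elements, tmodel_piecewise, z)
        manual = sum(
            rec.translate_image(img,
                                *cal.shift_at_depth(tmodel_piecewise, label, z))
            for label, img in elements.images.items()
        )
        assert np.array_equal(out, manual)

    def test_all_zero_elements_give_zero(self, aperture_mask, array,
                                         tmodel_piecewise, quiet_warnings):
        shape = aperture_mask.labels.shape
        blank = ph.CaptureFrame(np.zeros(shape, np.float32), 1.4)
        elements = rec.extract_elementals(blank, aperture_mask)
        out = rec.refocus(elements, tmodel_piecewise, 3000.0)
        assert not out.any()


class TestShadingAndZones:
    def test_counts_bounded_and_peak_at_convergence(self, aperture_mask,
                                                    tmodel_piecewise,
                                                    center_roi,
                                                    quiet_warnings):
        shading = rec.build_shading_map(aperture_mask, tmodel_piecewise,
                                        3000.0, roi=center_roi)
        assert shading.counts.max() == 7
        n = shading.counts.shape[0]
        assert shading.counts[n // 2, n // 2] == 7

    def test_zone_areas_nested_across_depth(self, aperture_mask,
                                            tmodel_piecewise, center_roi,
                                            quiet_warnings):
        for z in (2400.0, 3000.0, 3600.0):
            shading = rec.build_shading_map(aperture_mask, tmodel_piecewise, z,
                                            roi=center_roi)
            c = shading.counts
            assert (c >= 6).sum() <= (c >= 3).sum() <= (c >= 1).sum()

    def test_zone_classification_partition(self, aperture_mask,
                                           tmodel_piecewise, quiet_warnings):
        shading = rec.build_shading_map(aperture_mask, tmodel_piecewise, 2900.0)
        zones = rec.classify_zones(shading)
        c = shading.counts
        assert np.array_equal(zones == rec.ZONE_OUTSIDE, c == 0)
        assert np.array_equal(zones == rec.ZONE_PERIPHERAL, (c >= 1) & (c < 3))
        assert np.array_equal(zones == rec.ZONE_BLEND, (c >= 3) & (c < 6))
        assert np.array_equal(zones == rec.ZONE_FOVEATED, c >= 6)
        # every pixel carries exactly one label
        assert set(np.unique(zones)) <= {0, 1, 2, 3}

    def test_uniform_maps(self):
        all7 = rec.classify_zones(rec.ShadingMap(np.full((8, 8), 7, np.uint8)))
        assert (all7 == rec.ZONE_FOVEATED).all()
        all1 = rec.classify_zones(rec.ShadingMap(np.ones((8, 8), np.uint8)))
        assert (all1 == rec.ZONE_PERIPHERAL).all()

    def test_concentric_zones_on_default_geometry(self, aperture_mask,
                                                  tmodel_piecewise,
                                                  quiet_warnings):
        shading = rec.build_shading_map(aperture_mask, tmodel_piecewise, 3000.0)
        zones = rec.classify_zones(shading)
        h, w = zones.shape
        yy, xx = np.mgrid[0:h, 0:w]
        r = np.hypot(yy - (h - 1) / 2, xx - (w - 1) / 2)
        # mean radius ordering: foveated < blend < peripheral
        radii = [r[zones == code].mean()
                 for code in (rec.ZONE_FOVEATED, rec.ZONE_BLEND,
                              rec.ZONE_PERIPHERAL)]
        assert radii[0] < radii[1] < radii[2]


class TestFeatureMaskAndGhosts:
    def test_blank_central_element_gives_empty_mask(self):
        mask = rec.build_feature_mask(np.zeros((64, 64), np.float32))
        assert not mask.mask.any()

    def test_three_bead_frame_gives_three_components(self, array,
                                                     aperture_mask):
        scene = ph.Scene(
            tuple(ph.Emitter(p, 15.4) for p in
                  [(-120.0, 0.0, 3000.0), (0.0, 90.0, 3000.0),
                   (130.0, -110.0, 3000.0)]),
            extent=(1000, 1000, 4000),
        )
        frame = ph.render_capture(scene, array)
        elements = rec.extract_elementals(frame, aperture_mask)
        fm = rec.build_feature_mask(elements.images[1], window=31,
                                    opening_radius=2)
        comps = measure.label(fm.mask)
        assert comps.max() == 3

    def test_window_validation(self):
        with pytest.raises(am.InvalidParameterError):
            rec.build_feature_mask(np.zeros((32, 32)), window=4)

    def test_ghost_removed_real_feature_kept(self):
        elements, mask = toy_elements()
        model = identity_translation()
        elements.images[2][70, 70] = 1.0      # ghost: absent from central view
        stack = rec.focal_stack(elements, model, [3000.0])
        feature = rec.build_feature_mask(
            ndimage.gaussian_filter(elements.images[1], 1.0), window=15,
            opening_radius=0,
        )
        n = elements.shape[0]
        shading = [rec.ShadingMap(np.full((n, n), 7, np.uint8))]
        out = rec.apply_masks(stack, feature, shading, mode="feature")
        assert out.data[0][70, 70] == 0.0          # ghost suppressed
        assert out.data[0][30, 30] > 0.0           # true feature survives

    def test_full_feature_mask_keeps_stack(self):
        elements, mask = toy_elements()
        model = identity_translation()
        stack = rec.focal_stack(elements, model, [3000.0])
        feature = rec.FeatureMask(np.ones_like(elements.images[1], dtype=bool))
        n = elements.shape[0]
        shading = [rec.ShadingMap(np.full((n, n), 7, np.uint8))]
        out = rec.apply_masks(stack, feature, shading, mode="feature")
        assert np.array_equal(out.data, stack.data)

    def test_peripheral_zone_never_feature_masked(self, aperture_mask,
                                                  psf_stack, tmodel_piecewise,
                                                  quiet_warnings):
        # put energy in a peripheral position by using a real edge element
        _, frame = psf_stack[0]       # z = 2000: edge spots far out
        elements = rec.extract_elementals(frame, aperture_mask)
        stack = rec.focal_stack(elements, tmodel_piecewise, [2000.0])
        shading = [rec.build_shading_map(aperture_mask, tmodel_piecewise,
                                         2000.0)]
        empty = rec.FeatureMask(np.zeros(stack.data.shape[1:], dtype=bool))
        out = rec.apply_masks(stack, empty, shading, mode="feature")
        peripheral = shading[0].counts < shading[0].blend_min
        # inside blend+fovea everything is zeroed; peripheral survives
        assert not out.data[0][~peripheral & (shading[0].counts > 0)].any()
        assert np.array_equal(out.data[0][peripheral],
                              stack.data[0][peripheral])


class TestRescaling:
    def test_unit_magnification_is_identity(self):
        data = np.random.default_rng(0).uniform(0, 1, (2, 32, 32)).astype(
            np.float32)
        stack = rec.FocalStack(data, [2999.0, 3001.0], 1.4)
        mag = cal.MagnificationModel("tabulated",
                                     table=((1000.0, 1.0), (5000.0, 1.0)))
        vol = rec.rescale_stack(stack, mag, reference_z=3000.0)
        assert np.allclose(vol.volume, data, atol=1e-5)

    def test_grid_pitch_recovered_after_rescale(self, array, aperture_mask,
                                                tmodel_piecewise, mag_model,
                                                center_roi, quiet_warnings):
        z = 2400.0
        scene = ph.grid_target_scene(100.0, 400.0, z)
        frame = ph.render_capture(scene, array)
        vol = rec.reconstruct(frame, aperture_mask, tmodel_piecewise,
                              mag_model, [z - 25.0, z, z + 25.0],
                              background_radius=None, mask_mode="none",
                              roi=center_roi)
        layer = vol.volume[1]
        n = layer.shape[0]
        # centroid spacing of the two spots bracketing the centre column
        def centroid(r, c, half=10):
            win = layer[r - half: r + half + 1, c - half: c + half + 1]
            yy, xx = np.mgrid[0: 2 * half + 1, 0: 2 * half + 1]
            return ((yy * win).sum() / win.sum() + r - half,
                    (xx * win).sum() / win.sum() + c - half)
        pitch_px = 100.0 / vol.object_pixel
        c0 = centroid(n // 2, n // 2)
        c1 = centroid(n // 2, n // 2 + int(round(pitch_px)))
        measured = np.hypot(c1[0] - c0[0], c1[1] - c0[1])
        assert measured * vol.object_pixel == pytest.approx(100.0, rel=0.02)

    def test_equal_true_separation_equal_after_rescale(self, array,
                                                       aperture_mask,
                                                       tmodel_piecewise,
                                                       mag_model, center_roi,
                                                       quiet_warnings):
        sep = 140.0
        pairs = {}
        for z in (2500.0, 3500.0):
            scene = ph.Scene(
                (ph.Emitter((-sep / 2, 0.0, z), 2.5),
                 ph.Emitter((sep / 2, 0.0, z), 2.5)),
                extent=(1000, 1000, 4500),
            )
            frame = ph.render_capture(scene, array)
            vol = rec.reconstruct(frame, aperture_mask, tmodel_piecewise,
                                  mag_model, [z], background_radius=None,
                                  mask_mode="none", roi=center_roi)
            layer = vol.volume[0]
            n = layer.shape[0]
            half_px = sep / 2 / vol.object_pixel
            def centroid(c):
                win = layer[n // 2 - 8: n // 2 + 9, c - 8: c + 9]
                xx = np.mgrid[0:17, 0:17][1]
                return (xx * win).sum() / win.sum() + c - 8
            left = centroid(int(round(n / 2 - half_px)))
            right = centroid(int(round(n / 2 + half_px)))
            pairs[z] = (right - left) * vol.object_pixel
        assert abs(pairs[2500.0] - pairs[3500.0]) <= vol.object_pixel

    def test_nonpositive_magnification_rejected(self):
        stack = rec.FocalStack(np.zeros((1, 8, 8), np.float32), [3000.0], 1.4)
        bad = cal.MagnificationModel("parametric", sensor_distance=-3000.0)
        with pytest.raises(am.InvalidParameterError):
            rec.rescale_stack(stack, bad)


class TestPipeline:
    def test_empty_frame_gives_empty_volume_with_metadata(self, array,
                                                          aperture_mask,
                                                          tmodel_piecewise,
                                                          mag_model,
                                                          quiet_warnings):
        shape = aperture_mask.labels.shape
        blank = ph.CaptureFrame(np.zeros(shape, np.float32), 1.4)
        vol = rec.reconstruct(blank, aperture_mask, tmodel_piecewise,
                              mag_model, [2900.0, 3000.0, 3100.0],
                              background_radius=None,
                              roi=(800, 1100, 1100, 1500))
        assert not vol.volume.any()
        assert vol.provenance["n_layers"] == 3
        assert vol.zones is not None

    def test_stage_errors_name_the_stage(self, array, aperture_mask,
                                         tmodel_piecewise, mag_model):
        shape = aperture_mask.labels.shape
        blank = ph.CaptureFrame(np.zeros(shape, np.float32), 1.4)
        with pytest.raises(RuntimeError, match="background"):
            rec.reconstruct(blank, aperture_mask, tmodel_piecewise, mag_model,
                            [3000.0], background_radius=1e9)


class TestDepthEstimation:
    def test_point_stack_peak_within_one_step(self, array, aperture_mask,
                                              tmodel_piecewise, center_roi,
                                              quiet_warnings):
        scene = ph.Scene((ph.Emitter((0.0, 0.0, 3150.0), 2.5),),
                         extent=(1000, 1000, 4500))
        frame = ph.render_capture(scene, array)
        elements = rec.extract_elementals(frame, aperture_mask)
        zs = np.arange(2750.0, 3551.0, 100.0)
        stack = rec.focal_stack(elements, tmodel_piecewise, zs, roi=center_roi)
        # score a tight window around the reconstructed spot so parallax
        # sub-spots leave the window as defocus grows
        z_hat, scores = rec.estimate_depth(stack, roi=(220, 280, 220, 280))
        assert abs(z_hat - 3150.0) <= 100.0
        # the focus peak dominates the background of misfocused layers
        # (the ever-sharp central element keeps the off-focus score finite)
        i = int(np.argmax(scores))
        others = np.delete(scores, i)
        assert scores[i] > 1.3 * others.max()

    def test_flat_curve_warns(self):
        stack = rec.FocalStack(np.ones((4, 16, 16), np.float32),
                               [1.0, 2.0, 3.0, 4.0], 1.4)
        with pytest.warns(RuntimeWarning):
            z_hat, _ = rec.estimate_depth(stack)
        assert z_hat == 1.0

    def test_too_few_layers_rejected(self):
        stack = rec.FocalStack(np.ones((2, 8, 8), np.float32), [1.0, 2.0], 1.4)
        with pytest.raises(am.InvalidParameterError):
            rec.estimate_depth(stack)

    def test_autofocus_grid_recovers_known_depth(self, array, aperture_mask,
                                                 tmodel_piecewise, center_roi,
                                                 quiet_warnings):
        z_true = 3300.0
        scene = ph.grid_target_scene(100.0, 600.0, z_true, intensity=1.0)
        frame = ph.render_capture(scene, array)
        elements = rec.extract_elementals(frame, aperture_mask)
        zs = np.arange(2900.0, 3701.0, 50.0)
        z_hat, _ = rec.autofocus(elements, aperture_mask, tmodel_piecewise,
                                 zs, roi=center_roi)
        assert abs(z_hat - z_true) <= 50.0


class TestFlatField:
    def test_unit_reference_identity(self):
        img = np.random.default_rng(0).uniform(1, 2, (16, 16))
        assert np.allclose(rec.flat_field(img, np.ones_like(img)), img)

    def test_vignette_inverse_flattens(self):
        yy, xx = np.mgrid[0:32, 0:32]
        vignette = 1.0 - 0.5 * ((xx - 15.5) ** 2 + (yy - 15.5) ** 2) / 500.0
        scene = 4.0 * vignette
        out = rec.flat_field(scene, vignette)
        assert np.max(np.abs(out - out.mean())) < 1e-6

    def test_zone_boundary_step_reduced(self, quiet_warnings):
        # uniform scene summed over a 3-vs-7 overlap boundary shows a step;
        # dividing by the overlap-count reference removes it
        counts = np.concatenate([np.full((16, 32), 3.0),
                                 np.full((16, 32), 7.0)])
        image = counts.copy()      # uniform scene -> intensity tracks counts
        corrected = rec.flat_field(image, counts)
        step_before = abs(image[:16].mean() - image[16:].mean())
        step_after = abs(corrected[:16].mean() - corrected[16:].mean())
        assert step_after < 0.01 * step_before

    def test_guard_on_nonpositive_reference(self):
        ref = np.ones((8, 8))
        ref[0, 0] = 0.0
        with pytest.warns(RuntimeWarning):
            out = rec.flat_field(np.ones((8, 8)), ref)
        assert np.isfinite(out).all()
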