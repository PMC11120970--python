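import dataclasses

import numpy as np
import pytest

from axoplast import (
    FiberSpec,
    ParameterError,
    SceneParams,
    make_ankg_profile,
    make_axon_scene,
    make_ring_profile,
    random_fiber_specs,
    save_scene,
)
from axoplast.profiles import read_image
from axoplast.synthgen import load_ground_truth


def replace(p, **kw):
    return dataclasses.replace(p, **kw)


class TestSceneParams:
    def test_rejects_bad_ais_ordering(self):
        with pytest.raises(ParameterError):
            SceneParams(ankg_start_um=10.0, ankg_max_um=5.0, ankg_end_um=20.0)

    def test_rejects_bad_probability(self):
        with pytest.raises(ParameterError):
            SceneParams(puncta_end_prob=1.5)

    def test_rejects_nonpositive_fiber_length(self):
        with pytest.raises(ParameterError):
            SceneParams(fiber_specs=((1.0, 0.0, 10.0, 1.0),))


class TestAnkgProfile:
    def test_noiseless_crossing_at_requested_start(self):
        # construction constraint: normalized value crosses 0.33 at start
        p = SceneParams(
            ankg_start_um=5.0, ankg_max_um=14.0, ankg_end_um=27.0,
            profile_length_um=35.0, noise_sigma=0.0,
        )
        prof, _ = make_ankg_profile(p)
        v = prof.intensities
        norm = (v - v.min()) / (v.max() - v.min())
        # crossing is bracketed by one pixel step around 5.0 um
        i = int(np.searchsorted(prof.positions_um, 5.0))
        assert norm[i - 1] <= 0.33 <= norm[i + 1]

    def test_control_truth_length(self, control_params):
        # control-condition bounds give a 22.4 um AIS
        _, truth = make_ankg_profile(control_params)
        assert truth.true_ais.length_um == pytest.approx(22.4)

    def test_same_seed_same_samples(self):
        p = SceneParams(profile_length_um=35.0, noise_sigma=150.0, seed=42)
        a, _ = make_ankg_profile(p)
        b, _ = make_ankg_profile(p)
        np.testing.assert_array_equal(a.intensities, b.intensities)

    def test_profile_must_reach_past_ais_end(self):
        with pytest.raises(ParameterError, match="profile_length"):
            make_ankg_profile(SceneParams(profile_length_um=20.0))


class TestRingProfile:
    def test_grid_aligned_spacing_peaks_every_fifth_pixel(self, ring_params):
        p, _ = make_ring_profile(replace(ring_params, ring_spacing_nm=200.0))
        v = p.intensities
        interior_maxima = [
            i for i in range(1, len(v) - 1) if v[i] > v[i - 1] and v[i] > v[i + 1]
        ]
        assert interior_maxima == [i for i in interior_maxima if i % 5 == 0]
        assert len(interior_maxima) >= 8

    def test_off_grid_spacing_matches_brute_force_oracle(self, ring_params):
        # independent oracle: evaluate the Gaussian sum with plain loops
        p, _ = make_ring_profile(ring_params)
        x_nm = p.positions_um * 1000.0
        oracle = np.array(
            [
                sum(
                    np.exp(-((x - k * 190.0) ** 2) / (2 * 40.0**2))
                    for k in range(0, 12)
                )
                for x in x_nm
            ]
        )
        expected = ring_params.background + ring_params.ring_amplitude * oracle
        np.testing.assert_allclose(p.intensities, expected, rtol=1e-10)

    def test_sub_nyquist_spacing_rejected(self, ring_params):
        with pytest.raises(ParameterError, match="Nyquist|twice"):
            make_ring_profile(replace(ring_params, ring_spacing_nm=75.0))

    def test_overwhelming_noise_destroys_significance(self):
        # noise_sigma >> ring_amplitude: the acf peak should usually vanish
        from axoplast import autocorrelate, local_normalize

        n_insig = 0
        trials = 60
        for s in range(trials):
            p, _ = make_ring_profile(
                SceneParams(profile_length_um=2.0, ring_amplitude=1.0, noise_sigma=20.0, seed=s)
            )
            r = autocorrelate(local_normalize(p), 800.0)
            n_insig += r.first_peak_lag_nm is None or r.first_peak_lag_nm != 200.0
        assert n_insig >= trials // 2


class TestAxonScene:
    def test_fixed_seed_byte_identical(self):
        p = SceneParams(fiber_specs=((3.0, 2.0, 5.0, 1.2),), seed=9)
        a, _ = make_axon_scene(p)
        b, _ = make_axon_scene(p)
        np.testing.assert_array_equal(a, b)

    def test_puncta_count_bounds_at_prob_one(self):
        p = SceneParams(
            fiber_specs=((2.0, 2.0, 0.0, 1.2), (8.0, 2.0, 3.0, 1.2), (14.0, 2.0, -3.0, 1.2)),
            puncta_end_prob=1.0,
            seed=3,
        )
        _, truth = make_axon_scene(p)
        assert 3 <= len(truth.puncta_um) <= 6
        ends = {tuple(np.round(e, 6)) for t in truth.fibers for e in t.ends}
        for punct in truth.puncta_um:
            assert tuple(np.round(punct, 6)) in ends

    def test_axial_mean_is_periodic_without_fibers(self):
        # FFT oracle on the noiseless raster
        p = SceneParams(noise_sigma=0.0, ring_spacing_nm=200.0)
        scene, _ = make_axon_scene(p)
        axial = scene[0].mean(axis=0)
        axial = axial - axial.mean()
        freqs = np.fft.rfftfreq(axial.size, d=p.pixel_size_nm)
        peak_freq = freqs[np.argmax(np.abs(np.fft.rfft(axial)))]
        assert 1.0 / peak_freq == pytest.approx(200.0, rel=0.05)

    def test_out_of_raster_fiber_truncated_with_flag(self):
        p = SceneParams(fiber_specs=((18.0, 6.0, 0.0, 1.2),), seed=1)
        _, truth = make_axon_scene(p)
        assert any("truncated" in f for f in truth.flags)
        assert truth.fibers[0].polyline_um[:, 0].max() <= 20.0 + 1e-9

    def test_truth_coordinates_inside_scene(self, rng):
        specs = random_fiber_specs(rng, 5)
        p = SceneParams(fiber_specs=specs, puncta_end_prob=1.0, seed=8)
        scene, truth = make_axon_scene(p)
        h, w = scene.shape[1:]
        xmax, ymax = (w - 1) * p.step_um, (h - 1) * p.step_um
        for t in truth.fibers:
            assert t.polyline_um[:, 0].min() >= -1e-9
            assert t.polyline_um[:, 0].max() <= xmax + 1e-9
            assert t.polyline_um[:, 1].min() >= -1e-9
            assert t.polyline_um[:, 1].max() <= ymax + 1e-9
        for x, y in truth.puncta_um:
            assert 0 <= x <= xmax and 0 <= y <= ymax

    def test_stripe_artifact_adds_background(self):
        base = SceneParams(noise_sigma=0.0)
        a, _ = make_axon_scene(base)
        b, _ = make_axon_scene(replace(base, stripe_artifact=True))
        # stripes raise off-shaft background where the plain scene is ~0
        assert b[0][0, :].mean() > a[0][0, :].mean()

    def test_scene_tiff_json_roundtrip(self, tmp_path):
        p = SceneParams(fiber_specs=((3.0, 2.0, 5.0, 1.2),), seed=4)
        scene, truth = make_axon_scene(p)
        path = tmp_path / "scene.tif"
        save_scene(scene, truth, path, p.pixel_size_nm)
        img = read_image(path)
        np.testing.assert_allclose(img, scene.astype(np.float32))
        meta = load_ground_truth(path)
        assert meta["pixel_size_nm"] == p.pixel_size_nm
        assert len(meta["fibers"]) == len(truth.fibers)


class TestRandomFiberSpecs:
    def test_lengths_in_countable_range(self, rng):
        specs = random_fiber_specs(rng, 30)
        assert all(1.0 <= s.length_um <= 6.0 for s in specs)
        assert all(abs(s.angle_deg) <= 45.0 for s in specs)

    def test_overlapping_fibers_laterally_separated(self, rng):
        for _ in range(10):
            specs = random_fiber_specs(rng, 4)
            boxes = []
            for s in specs:
                y1 = s.y_offset_um + s.length_um * np.sin(np.deg2rad(s.angle_deg))
                boxes.append(
                    (s.start_um, s.start_um + s.length_um * np.cos(np.deg2rad(s.angle_deg)),
                     min(s.y_offset_um, y1), max(s.y_offset_um, y1))
                )
            for i in range(len(boxes)):
                for j in range(i + 1, len(boxes)):
                    x_overlap = min(boxes[i][1], boxes[j][1]) - max(boxes[i][0], boxes[j][0])
                    y_gap = max(boxes[i][2] - boxes[j][3], boxes[j][2] - boxes[i][3])
                    if x_overlap > 0.25:
                        assert y_gap >= 0.15
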