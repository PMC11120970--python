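import numpy as np
import pytest
from hypothesis import given
from hypothesis import strategies as st

from axoplast import (
    AISMeasure,
    FlatProfileError,
    Profile,
    SceneParams,
    adr,
    axon_width,
    detect_ais,
    make_ankg_profile,
    smooth_profile,
)


def make_profile(values, px=40.0, start_um=0.0):
    values = np.asarray(values, float)
    x = start_um + np.arange(len(values)) * px / 1000.0
    return Profile(positions_um=x, intensities=values, pixel_size_nm=px)


def ramp_profile(n=501, px=40.0):
    x = np.arange(n) * px / 1000.0
    return Profile(positions_um=x, intensities=100.0 * x / x[-1], pixel_size_nm=px)


class TestSmoothing:
    def test_constant_profile_unchanged(self):
        p = make_profile(np.full(200, 5.0))
        assert np.allclose(smooth_profile(p).intensities, 5.0)

    def test_linear_ramp_unchanged_everywhere(self):
        # centered symmetric averaging preserves linear trends, edges included
        p = ramp_profile()
        np.testing.assert_allclose(smooth_profile(p).intensities, p.intensities, atol=1e-9)

    def test_unit_impulse_becomes_box(self):
        v = np.zeros(101)
        v[50] = 1.0
        p = make_profile(v)
        sm = smooth_profile(p, window_um=0.12).intensities  # 3 px window
        assert sm[49] == sm[50] == sm[51] == pytest.approx(1.0 / 3.0)
        assert sm[48] == 0.0 and sm[52] == 0.0

    def test_window_larger_than_profile_rejected(self):
        with pytest.raises(ValueError, match="window"):
            smooth_profile(make_profile(np.ones(10)), window_um=3.0)


class TestDetectAIS:
    def test_linear_ramp_start_at_third_and_truncated_end(self):
        m = detect_ais(ramp_profile())
        assert m.start_um == pytest.approx(0.33 * 20.0, abs=0.04)
        assert m.end_um == pytest.approx(20.0)
        assert "end_truncated" in m.flags and m.truncated

    def test_noiseless_synthetic_start_within_one_pixel(self, control_params):
        prof, truth = make_ankg_profile(control_params)
        m = detect_ais(prof)
        assert m.start_um == pytest.approx(truth.true_ais.start_um, abs=0.04)
        assert m.end_um == pytest.approx(truth.true_ais.end_um, abs=0.04)
        assert m.max_um == pytest.approx(truth.true_ais.max_um, abs=0.04)

    @given(a=st.floats(0.1, 50.0), b=st.floats(0.0, 100.0))
    def test_affine_intensity_invariance(self, a, b):
        prof, _ = make_ankg_profile(SceneParams(profile_length_um=35.0, noise_sigma=120.0, seed=5))
        m1 = detect_ais(prof)
        scaled = Profile(
            prof.positions_um, a * prof.intensities + b, prof.pixel_size_nm
        )
        m2 = detect_ais(scaled)
        assert m1 == m2

    def test_position_shift_shifts_bounds_not_length(self, control_params):
        prof, _ = make_ankg_profile(control_params)
        shifted = Profile(
            prof.positions_um + 2.0, prof.intensities, prof.pixel_size_nm
        )
        m1, m2 = detect_ais(prof), detect_ais(shifted)
        assert m2.start_um == pytest.approx(m1.start_um + 2.0)
        assert m2.end_um == pytest.approx(m1.end_um + 2.0)
        assert m2.length_um == pytest.approx(m1.length_um)

    def test_boundary_is_first_crossing_despite_recrossing(self):
        # dips below 0.33 then rises again: the FIRST outward crossing wins
        x = np.arange(500) * 0.04
        v = np.full(500, 0.1)
        v[150:300] = 1.0  # plateau = AIS
        v[50:80] = 0.6  # proximal bump that re-exceeds the cutoff
        p = Profile(x, v, 40.0)
        m = detect_ais(p, smooth=False)
        assert 80 * 0.04 <= m.start_um <= 150 * 0.04

    def test_flat_profile_rejected(self):
        with pytest.raises(FlatProfileError):
            detect_ais(make_profile(np.full(300, 2.0)))

    def test_leftmost_maximum_on_plateau(self):
        v = np.concatenate(
            [np.linspace(0, 1, 100, endpoint=False), np.ones(100), np.linspace(1, 0, 100)]
        )
        p = make_profile(v)
        m = detect_ais(p, smooth=False)
        assert m.max_um == pytest.approx(100 * 0.04, abs=0.001)

    def test_measure_invariants_enforced(self):
        with pytest.raises(ValueError):
            AISMeasure(start_um=5.0, max_um=4.0, end_um=10.0, length_um=5.0)
        with pytest.raises(ValueError):
            AISMeasure(start_um=1.0, max_um=2.0, end_um=3.0, length_um=1.0)


class TestAxonWidth:
    def test_rectangular_pulse_width(self):
        v = np.zeros(100)
        v[40:60] = 1.0  # 20 px = 0.8 um
        w, flags = axon_width(make_profile(v))
        assert w == pytest.approx(0.8, abs=0.08)
        assert flags == ()

    def test_gaussian_closed_form(self):
        x = np.arange(101) * 0.04
        sigma = 0.32
        v = np.exp(-((x - 2.0) ** 2) / (2 * sigma**2))
        w, _ = axon_width(Profile(x, v, 40.0))
        expected = 2 * sigma * np.sqrt(2 * np.log(1 / 0.33))
        assert w == pytest.approx(expected, abs=0.08)

    def test_no_crossing_side_flagged(self):
        v = np.linspace(0.5, 1.0, 50)  # never falls to 33% on the left
        w, flags = axon_width(make_profile(v))
        assert "left_truncated" in flags


class TestADR:
    def make_ais(self):
        return AISMeasure(start_um=4.5, max_um=13.6, end_um=26.9, length_um=22.4)

    def test_uniform_marker_gives_exactly_one(self):
        ais_p = make_profile(np.full(876, 7.0))
        dend = [make_profile(np.full(1400, 7.0)) for _ in range(3)]
        val = adr(ais_p, dend, self.make_ais())
        assert val.ratio == pytest.approx(1.0)
        assert val.n_dendrites == 3

    def test_double_intensity_in_ais_gives_two(self):
        x = np.arange(876) * 0.04
        v = np.where((x >= 4.5) & (x <= 26.9), 2.0, 0.5)
        ais_p = Profile(x, v, 40.0)
        dend = [make_profile(np.full(1400, 1.0)) for _ in range(2)]
        assert adr(ais_p, dend, self.make_ais()).ratio == pytest.approx(2.0)

    def test_short_dendrite_rejected(self):
        ais_p = make_profile(np.full(876, 1.0))
        with pytest.raises(ValueError, match="shorter"):
            adr(ais_p, [make_profile(np.full(100, 1.0))], self.make_ais())

    def test_no_dendrites_rejected(self):
        with pytest.raises(ValueError, match="dendrite"):
            adr(make_profile(np.full(876, 1.0)), [], self.make_ais())

    def test_zero_dendrite_mean_rejected(self):
        ais_p = make_profile(np.full(876, 1.0))
        with pytest.raises(ValueError, match="zero"):
            adr(ais_p, [make_profile(np.zeros(1400))], self.make_ais())


class TestRecovery:
    def test_start_bias_vanishes_as_noise_vanishes(self):
        biases = []
        for sigma in (100.0, 10.0, 0.0):
            errs = []
            for s in range(10):
                params = SceneParams(profile_length_um=35.0, noise_sigma=sigma, seed=s)
                prof, truth = make_ankg_profile(params)
                m = detect_ais(prof)
                errs.append(m.start_um - truth.true_ais.start_um)
            biases.append(abs(np.mean(errs)))
        assert biases[-1] <= 0.04
        assert biases[-1] <= biases[0] + 1e-9

    def test_shaft_width_in_study_band(self):
        # transverse cut through synthetic scenes: mean width 0.9-1.0 um
        from axoplast import Polyline, extract_line_profile, make_axon_scene

        widths = []
        for s in range(30):
            params = SceneParams(noise_sigma=0.1, shaft_width_um=1.0, seed=s)
            scene, _ = make_axon_scene(params)
            path = Polyline(((10.0, 0.2), (10.0, 2.8)), width_px=1)
            t = extract_line_profile(scene[1], path, params.pixel_size_nm)
            w, flags = axon_width(t)
            if not flags:
                widths.append(w)
        assert 0.9 <= np.mean(widths) <= 1.0
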