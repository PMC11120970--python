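import numpy as np
import pytest


from axoplast import (
    PeakSet,
    Profile,
    SceneParams,
    SegmentRecord,
    acf_amplitude,
    autocorrelate,
    detect_intensity_peaks,
    interpeak_distribution,
    local_normalize,
    make_ring_profile,
    spatial_periodicity,
)


def make_profile(values, px=40.0, flags=()):
    x = np.arange(len(values)) * px / 1000.0
    return Profile(x, np.asarray(values, float), px, flags=flags)


def cosine_profile(period_nm=200.0, n=400, px=40.0, amp=1.0, trend=0.0, offset=5.0):
    x_nm = np.arange(n) * px
    v = offset + amp * np.cos(2 * np.pi * x_nm / period_nm) + trend * x_nm / 1000.0
    return make_profile(v, px)


class TestLocalNormalize:
    def test_recovers_cosine_under_linear_trend(self):
        p = cosine_profile(trend=3.0)
        res = local_normalize(p)
        x_nm = np.arange(p.n) * 40.0
        pure = np.cos(2 * np.pi * x_nm / 200.0)
        interior = slice(10, -10)
        r = np.corrcoef(res.intensities[interior], pure[interior])[0, 1]
        assert r >= 0.99

    def test_constant_profile_flagged_zeros(self):
        res = local_normalize(make_profile(np.full(100, 3.0)))
        assert np.all(res.intensities == 0.0)
        assert "constant" in res.flags

    def test_residual_mean_near_zero(self, rng):
        p = make_profile(rng.random(300) + 1.0)
        res = local_normalize(p)
        assert abs(res.intensities.mean()) < 0.05

    def test_unit_variance(self, rng):
        p = make_profile(rng.random(300) + 1.0)
        assert local_normalize(p).intensities.std() == pytest.approx(1.0)


class TestAutocorrelate:
    def test_acf_zero_lag_is_one_and_bounded(self, rng):
        p = local_normalize(make_profile(rng.random(200) + 0.5))
        r = autocorrelate(p, 800.0)
        assert r.acf[0] == 1.0
        assert np.all(np.abs(r.acf) <= 1.0 + 1e-12)
        assert np.allclose(r.lags_nm % 40.0, 0.0)

    def test_iid_noise_mostly_inside_bound(self):
        # raw i.i.d. noise: ~95% of nonzero-lag acf values inside the
        # 1.96/sqrt(n) white-noise band (local normalization would induce
        # short-lag anticorrelation, so it is skipped here)
        frac_inside = []
        for s in range(50):
            rng = np.random.default_rng(s)
            p = make_profile(rng.normal(10, 1, 400))
            r = autocorrelate(p, 2000.0)
            inside = np.abs(r.acf[1:]) < r.significance_bound
            frac_inside.append(inside.mean())
        assert np.mean(frac_inside) >= 0.93

    def test_noiseless_cosine_peaks_at_its_period(self):
        r = autocorrelate(local_normalize(cosine_profile(200.0)), 800.0)
        assert r.first_peak_lag_nm == 200.0

    def test_ring_spacing_190_reports_grid_lag_200(self, ring_params):
        # brute-force acf oracle on the noiseless quantized signal
        p, _ = make_ring_profile(ring_params)
        norm = local_normalize(p)
        x = norm.intensities - norm.intensities.mean()
        denom = np.dot(x, x)
        oracle = [1.0] + [float(np.dot(x[:-k], x[k:])) / denom for k in range(1, 21)]
        lag_of_first_max = next(
            k for k in range(1, 20) if oracle[k] > oracle[k - 1] and oracle[k] >= oracle[k + 1]
        )
        assert lag_of_first_max * 40.0 == 200.0
        r = autocorrelate(norm, 800.0)
        assert r.first_peak_lag_nm == 200.0

    def test_affine_invariance(self):
        p = cosine_profile()
        r1 = autocorrelate(local_normalize(p), 800.0)
        q = Profile(p.positions_um, 7.0 * p.intensities + 3.0, p.pixel_size_nm)
        r2 = autocorrelate(local_normalize(q), 800.0)
        np.testing.assert_allclose(r1.acf, r2.acf, atol=1e-10)

    def test_short_profile_rejected(self):
        with pytest.raises(ValueError, match="shorter"):
            autocorrelate(local_normalize(make_profile(np.arange(30.0))), 800.0)

    @pytest.mark.parametrize("spacing", [160.0, 200.0, 240.0])
    def test_grid_aligned_spacing_recovery_under_noise(self, spacing):
        hits = 0
        n = 40
        for i in range(n):
            p, _ = make_ring_profile(
                SceneParams(
                    profile_length_um=2.0,
                    ring_spacing_nm=spacing,
                    noise_sigma=0.2,
                    ring_phase_nm=float((13 * i) % spacing),
                    seed=900 + i,
                )
            )
            r = autocorrelate(local_normalize(p), 800.0)
            hits += r.first_peak_lag_nm == spacing
        assert hits >= 0.95 * n


class TestAmplitude:
    def test_long_cosine_amplitude_matches_grid_closed_form(self):
        # closed form for a sampled cosine of period P: acf(k) = cos(2*pi*
        # k*px/P) as n -> inf, so peak and valleys are read off the lag grid.
        # 200 nm on a 40 nm grid: peak cos(0) = 1; the continuous valleys at
        # +-100 nm fall OFF the grid, the grid valleys are cos(2pi*2/5) =
        # cos(2pi*3/5) = -0.809, hence amplitude 1.809.
        r = acf_amplitude(autocorrelate(local_normalize(cosine_profile(n=4000)), 800.0))
        assert not r.omitted
        expected = 1.0 - 0.5 * (np.cos(2 * np.pi * 2 / 5) + np.cos(2 * np.pi * 3 / 5))
        assert r.amplitude == pytest.approx(expected, abs=0.05)

    def test_long_cosine_amplitude_two_when_valley_on_grid(self):
        # 160 nm period: the true valley lag 80 nm IS a grid lag, so the
        # continuous limit (peak 1, valleys -1, amplitude 2) is attained
        r = acf_amplitude(
            autocorrelate(local_normalize(cosine_profile(period_nm=160.0, n=4000)), 800.0)
        )
        assert r.amplitude == pytest.approx(2.0, abs=0.05)

    def test_white_noise_usually_omitted(self):
        omitted = 0
        trials = 40
        for s in range(trials):
            rng = np.random.default_rng(1000 + s)
            p = local_normalize(make_profile(rng.normal(10, 1, 50)))
            r = acf_amplitude(autocorrelate(p, 800.0))
            # no peak in band, or an insignificant bump
            omitted += r.omitted or (r.amplitude is not None and r.amplitude < 0.5)
        assert omitted > trials // 2

    def test_omitted_curves_carry_no_amplitude(self):
        v = np.exp(-np.arange(60) / 3.0) + 1.0  # monotone decay, no 200 nm peak
        r = acf_amplitude(autocorrelate(local_normalize(make_profile(v)), 800.0))
        if r.omitted:
            assert r.amplitude is None

    def test_requires_sufficient_lag_range(self):
        r = autocorrelate(local_normalize(cosine_profile()), 240.0)
        with pytest.raises(ValueError, match="search band"):
            acf_amplitude(r)


class TestPeaks:
    def test_exact_comb_gives_all_200(self):
        v = np.zeros(100)
        v[::5] = 1.0
        ps = detect_intensity_peaks(local_normalize(make_profile(v)))
        assert np.all(ps.interpeak_nm == 200.0)
        d = interpeak_distribution([ps])
        assert d.proportion_at_200 == 1.0

    def test_monotone_profile_has_no_peaks(self):
        ps = detect_intensity_peaks(local_normalize(make_profile(np.linspace(1, 2, 80))))
        assert ps.n_peaks == 0
        assert "too_few_peaks" in ps.flags

    def test_190_spacing_quantizes_to_grid_multiples(self, ring_params):
        ps = detect_intensity_peaks(local_normalize(make_ring_profile(ring_params)[0]))
        dist = set(np.round(ps.interpeak_nm).astype(int))
        assert dist <= {160, 200, 240}
        assert np.gcd.reduce(np.round(ps.interpeak_nm).astype(int)) % 40 == 0

    def test_peakset_rejects_off_grid_distances(self):
        with pytest.raises(ValueError):
            PeakSet(
                peak_positions_nm=np.array([0.0, 190.0]),
                interpeak_nm=np.array([190.0]),
                pixel_size_nm=40.0,
            )


class TestInterpeakDistribution:
    def test_mixed_distances_proportion(self):
        ps = PeakSet(
            peak_positions_nm=np.array([0.0, 160.0, 360.0, 560.0, 800.0]),
            interpeak_nm=np.array([160.0, 200.0, 200.0, 240.0]),
            pixel_size_nm=40.0,
        )
        d = interpeak_distribution([ps])
        assert d.proportion_at_200 == 0.5
        assert d.n_distances == 4

    def test_empty_input_rejected(self):
        empty = PeakSet(np.empty(0), np.empty(0), 40.0)
        with pytest.raises(ValueError, match="no inter-peak"):
            interpeak_distribution([empty])


class TestSpatialBins:
    def test_midpoint_assignment(self):
        recs = [SegmentRecord(2.4), SegmentRecord(7.0), SegmentRecord(12.0), SegmentRecord(17.0)]
        bins = spatial_periodicity(recs)
        assert bins.n_segments == (1, 1, 1, 1)

    def test_boundary_midpoint_goes_to_upper_bin(self):
        bins = spatial_periodicity([SegmentRecord(5.0)])
        assert bins.n_segments == (0, 1, 0, 0)

    def test_midpoints_beyond_20_excluded_and_counted(self):
        bins = spatial_periodicity([SegmentRecord(21.0), SegmentRecord(3.0)])
        assert bins.n_excluded == 1
        assert sum(bins.n_segments) == 1

    def test_per_bin_payloads(self):
        ps = PeakSet(
            peak_positions_nm=np.array([0.0, 200.0, 400.0]),
            interpeak_nm=np.array([200.0, 200.0]),
            pixel_size_nm=40.0,
        )
        bins = spatial_periodicity([SegmentRecord(2.0, ps, 1.2), SegmentRecord(8.0, None, 0.8)])
        assert bins.proportion_at_200[0] == 1.0
        assert bins.amplitudes[0].tolist() == [1.2]
        assert bins.amplitudes[1].tolist() == [0.8]
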