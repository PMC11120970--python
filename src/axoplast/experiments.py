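"""Canonical in-silico validation experiments.

Each function runs one self-contained synthetic experiment — generate data
with known ground truth, run the corresponding detector, measure the
result — at the study conditions (40 nm pixels, 190 nm ring spacing,
signal-to-noise ratio 5, control AIS bounds).  They are used both by the
test suite and by the reproduction script, so the measured quantities are
defined in exactly one place.
"""
from __future__ import annotations

import dataclasses

import numpy as np

from .fibers import detect_fibers, filter_and_count, merge_collinear, puncta_at_ends
from .morphometry import adr, detect_ais
from .periodicity import (
    acf_amplitude,
    autocorrelate,
    average_acf,
    detect_intensity_peaks,
    interpeak_distribution,
    local_normalize,
)
from .profiles import Polyline, Profile, extract_line_profile
from .synthgen import (
    SceneParams,
    make_adr_profiles,
    make_ankg_profile,
    make_axon_scene,
    make_ring_profile,
    random_fiber_specs,
)

__all__ = [
    "ring_params",
    "averaged_acf_first_peak",
    "interpeak_gcd",
    "ramp_boundary_value",
    "uniform_adr",
    "ais_start_recovery",
    "adr_recovery",
    "fiber_count_recovery",
    "fiber_false_positive_rate",
    "puncta_recovery",
    "occlusion_comparison",
    "amplitude_noise_trend",
]

SNR = 5.0


def ring_params(seed: int, **overrides) -> SceneParams:
    """~2 um ring-profile parameters at the study conditions (SNR 5)."""
    defaults = dict(
        profile_length_um=2.0,
        ring_spacing_nm=190.0,
        ring_amplitude=1.0,
        noise_sigma=1.0 / SNR,
        seed=seed,
    )
    defaults.update(overrides)
    return SceneParams(**defaults)


def _spawn(seed: int, n: int) -> list[int]:
    """Derive n child seeds (< 2**31) from one base seed."""
    ss = np.random.SeedSequence(seed)
    return [int(s) % (2**31 - 1) for s in ss.generate_state(n)]


def averaged_acf_first_peak(
    seed: int, n_profiles: int = 30, spacing_nm: float = 190.0
) -> float | None:
    """Lag (nm) of the first significant peak of the averaged acf.

    Thirty ~2 um ring profiles at SNR 5 with random ring phase, each
    locally normalized and autocorrelated to 800 nm; curves averaged and
    the first local maximum above the 1.96/sqrt(n) bound reported.
    """
    seeds = _spawn(seed, n_profiles)
    acfs = []
    for s in seeds:
        phase = float(np.random.default_rng(s).uniform(0.0, spacing_nm))
        p, _ = make_ring_profile(ring_params(s, ring_spacing_nm=spacing_nm, ring_phase_nm=phase))
        acfs.append(autocorrelate(local_normalize(p), 800.0))
    return average_acf(acfs).first_peak_lag_nm


def interpeak_gcd(seed: int, n_profiles: int = 50) -> int:
    """GCD (nm) of all pooled adjacent inter-peak distances.

    Ring spacing 190 nm is not a multiple of the 40 nm pixel, so detected
    peak positions quantize to the grid and all distances share the pixel
    size as greatest common divisor.
    """
    seeds = _spawn(seed + 1, n_profiles)
    peaksets = []
    for s in seeds:
        phase = float(np.random.default_rng(s).uniform(0.0, 190.0))
        p, _ = make_ring_profile(ring_params(s, ring_phase_nm=phase))
        peaksets.append(detect_intensity_peaks(local_normalize(p)))
    pooled = np.concatenate([ps.interpeak_nm for ps in peaksets if ps.interpeak_nm.size])
    return int(np.gcd.reduce(np.round(pooled).astype(int)))


def ramp_boundary_value(pixel_size_nm: float = 40.0, length_um: float = 20.0) -> float:
    """Normalized smoothed value at the detected AIS start of a linear ramp.

    A noiseless profile rising linearly from 0 to its maximum over 20 um is
    the cleanest probe of the boundary rule: smoothing preserves the ramp,
    normalization maps it to [0, 1], and the detected start must sit at the
    0.33 level.  Deterministic.
    """
    step = pixel_size_nm / 1000.0
    n = int(round(length_um / step)) + 1
    x = np.arange(n) * step
    p = Profile(positions_um=x, intensities=1000.0 * x / x[-1], pixel_size_nm=pixel_size_nm)
    m = detect_ais(p)
    from .morphometry import smooth_profile

    sm = smooth_profile(p, 3.0).intensities
    norm = (sm - sm.min()) / (sm.max() - sm.min())
    idx = int(round(m.start_um / step))
    return float(norm[idx])


def uniform_adr(n_dendrites: int = 3) -> float:
    """ADR of a neuron with spatially uniform marker intensity (exactly 1)."""
    params = SceneParams(noise_sigma=0.0, profile_length_um=35.0)
    _, truth = make_ankg_profile(params)
    marker, dendrites, _ = make_adr_profiles(
        dataclasses.replace(params, noise_sigma=0.0),
        contrast=1.0,
        n_dendrites=n_dendrites,
    )
    return adr(marker, dendrites, truth.true_ais).ratio


def ais_start_recovery(seed: int, n_profiles: int = 100) -> float:
    """Median |detected - true| AIS start (um) over noisy profiles at SNR 5."""
    errs = []
    for s in _spawn(seed + 2, n_profiles):
        params = SceneParams(
            profile_length_um=35.0, noise_sigma=0.95 * 1000.0 / SNR, seed=s
        )
        prof, truth = make_ankg_profile(params)
        m = detect_ais(prof)
        errs.append(abs(m.start_um - truth.true_ais.start_um))
    return float(np.median(errs))


def adr_recovery(seed: int, contrast: float = 0.44, n_cells: int = 20) -> float:
    """Mean recovered ADR over noisy synthetic neurons with known contrast."""
    vals = []
    for s in _spawn(seed + 3, n_cells):
        params = SceneParams(profile_length_um=35.0, noise_sigma=1.0 / SNR, seed=s)
        _, truth = make_ankg_profile(dataclasses.replace(params, noise_sigma=0.0))
        marker, dendrites, _ = make_adr_profiles(params, contrast=contrast)
        vals.append(adr(marker, dendrites, truth.true_ais).ratio)
    return float(np.mean(vals))


def _analyze_scene_fibers(scene: np.ndarray, pixel_size_nm: float = 40.0):
    traces = merge_collinear(detect_fibers(scene[0], pixel_size_nm))
    return filter_and_count(traces)


def fiber_count_recovery(seed: int, n_scenes: int = 100) -> float:
    """Fraction of scenes (0-6 true fibers, SNR 5) counted within +-1."""
    rng = np.random.default_rng(seed + 4)
    seeds = _spawn(seed + 5, n_scenes)
    ok = 0
    for s in seeds:
        k = int(rng.integers(0, 7))
        specs = random_fiber_specs(rng, k)
        scene, truth = make_axon_scene(
            dataclasses.replace(SceneParams(), fiber_specs=specs, seed=s)
        )
        count, _ = _analyze_scene_fibers(scene)
        truth_n = sum(1 for t in truth.fibers if t.length_um >= 1.0 and t.angle_deg <= 45.0)
        ok += abs(count.n_fibers - truth_n) <= 1
    return ok / n_scenes


def fiber_false_positive_rate(seed: int, n_scenes: int = 40) -> float:
    """Mean spurious fibers per fiber-free 20 um scene at SNR 5."""
    total = 0
    for s in _spawn(seed + 6, n_scenes):
        scene, _ = make_axon_scene(dataclasses.replace(SceneParams(), seed=s))
        count, _ = _analyze_scene_fibers(scene)
        total += count.n_fibers
    return total / n_scenes


def puncta_recovery(seed: int, min_fibers: int = 200) -> tuple[float, float]:
    """(truth per-fiber punctum rate, detected fraction) at prob 0.6."""
    rng = np.random.default_rng(seed + 7)
    hits_det = n_det = hits_true = n_true = 0
    s = 0
    seeds = _spawn(seed + 8, 400)
    while n_det < min_fibers and s < len(seeds):
        specs = random_fiber_specs(rng, 3)
        scene, truth = make_axon_scene(
            dataclasses.replace(
                SceneParams(puncta_end_prob=0.6), fiber_specs=specs, seed=seeds[s]
            )
        )
        s += 1
        _, kept = _analyze_scene_fibers(scene)
        res = puncta_at_ends(kept, truth.puncta_um, 160.0)
        if res.fraction is not None:
            hits_det += sum(res.per_fiber)
            n_det += res.n_fibers
        hits_true += sum(truth.fiber_has_punctum)
        n_true += len(truth.fibers)
    return hits_true / max(n_true, 1), hits_det / max(n_det, 1)


def occlusion_comparison(seed: int, n_scenes: int = 15) -> tuple[float, float]:
    """Proportion of 200 nm inter-peak distances: clean vs fiber-occluded.

    Both arms are imaged identically (photon-limited: Poisson noise at 25
    counts per intensity unit plus weak Gaussian read noise); the occluded
    arm carries five bright longitudinal fibers per scene.  Four ~2 um
    profiles per scene are drawn at random lateral positions within the
    shaft.  Returns (proportion_clean, proportion_occluded).
    """

    def arm(with_fibers: bool) -> float:
        rng = np.random.default_rng(seed + (11 if with_fibers else 10))
        seeds = _spawn(seed + (13 if with_fibers else 12), n_scenes)
        sets = []
        base = SceneParams(noise_sigma=0.1, poisson_scale=25.0)
        for s in seeds:
            specs = random_fiber_specs(rng, 5, intensity=2.5) if with_fibers else ()
            scene, _ = make_axon_scene(
                dataclasses.replace(base, fiber_specs=specs, seed=s)
            )
            for seg in range(4):
                x0 = 5.0 * seg + float(rng.uniform(0.2, 2.8))
                y = 1.5 + float(rng.uniform(-0.28, 0.28))
                path = Polyline(((x0, y), (x0 + 2.0, y)), width_px=3)
                prof = extract_line_profile(scene[0], path, 40.0)
                sets.append(detect_intensity_peaks(local_normalize(prof)))
        return interpeak_distribution(sets).proportion_at_200

    return arm(False), arm(True)


def amplitude_noise_trend(
    seed: int,
    noise_sigmas: tuple[float, ...] = (0.05, 0.1, 0.2, 0.4, 0.8),
    n_profiles: int = 40,
) -> list[float]:
    """Averaged-acf amplitude at each noise level (should decrease)."""
    amps = []
    for j, sig in enumerate(noise_sigmas):
        seeds = _spawn(seed + 20 + j, n_profiles)
        acfs = []
        for s in seeds:
            phase = float(np.random.default_rng(s).uniform(0.0, 190.0))
            p, _ = make_ring_profile(
                ring_params(s, noise_sigma=sig, ring_phase_nm=phase)
            )
            acfs.append(autocorrelate(local_normalize(p), 800.0))
        r = acf_amplitude(average_acf(acfs))
        amps.append(float(r.amplitude) if r.amplitude is not None else float("nan"))
    return amps
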