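"""Synthetic SIM-like profiles and scenes with ground truth.

Emulates the structured-illumination imagery this pipeline targets: 40 nm
camera pixels, an axon shaft ~1 um wide carrying transverse actin rings
spaced ~190 nm, longitudinal actin fibers (bright line segments 1-6 um
long, within 45 degrees of the shaft axis), an axial ankyrinG gradient
defining the AIS, punctate marker channels at fiber ends, and additive
Gaussian (optionally Poisson) noise with an optional periodic stripe
reconstruction artifact.  Every stochastic placement is recorded in a
:class:`SceneGroundTruth` so detectors can be scored against truth.

Coordinates are 0-based pixel indices; physical position = index *
pixel_size_nm, with position 0 at the path origin ("soma" end).
"""
from __future__ import annotations

import json
from dataclasses import asdict, dataclass
from pathlib import Path as _Path

import numpy as np
import tifffile

from .fibers import FiberTrace
from .morphometry import AISMeasure
from .profiles import Profile

__all__ = [
    "ParameterError",
    "FiberSpec",
    "SceneParams",
    "SceneGroundTruth",
    "make_ankg_profile",
    "make_ring_profile",
    "make_axon_scene",
    "make_adr_profiles",
    "random_fiber_specs",
    "save_scene",
    "load_ground_truth",
]

# Relative level of the plateau shoulders flanking the apex.  Kept close to
# the apex so that smoothing the apex tent barely lowers the profile maximum:
# a lower maximum rescales the min-max normalization and would drag the 0.33
# crossing off the requested position.  At 0.98 the residual shift is ~0.2 px.
_SHOULDER = 0.98
_EDGE_MARGIN_UM = 1.6  # linear run kept on each side of a 0.33 crossing


class ParameterError(ValueError):
    """Invalid generator parameters."""


@dataclass(frozen=True)
class FiberSpec:
    """One longitudinal fiber: axial start, length, signed angle, intensity.

    ``y_offset_um`` places the fiber start relative to the shaft center;
    None lets the scene builder draw a small random offset.
    """

    start_um: float
    length_um: float
    angle_deg: float
    intensity: float = 1.2
    y_offset_um: float | None = None

    def __post_init__(self) -> None:
        if self.length_um <= 0:
            raise ParameterError("fiber length must be positive")
        if self.intensity <= 0:
            raise ParameterError("fiber intensity must be positive")


@dataclass(frozen=True)
class SceneParams:
    """Generator parameters; defaults reproduce the study's control setup.

    Pixel size 40 nm (SIM camera), ring spacing 190 nm, AIS bounds at the
    control condition means (start 4.5, max 13.6, end 26.9 um), axon width
    0.95 um (33%-of-max width), and Gaussian noise at one fifth of the
    signal amplitude (SNR 5).
    """

    pixel_size_nm: float = 40.0
    profile_length_um: float = 20.0
    ring_spacing_nm: float = 190.0
    ring_sigma_nm: float = 40.0
    ring_amplitude: float = 1.0
    ring_phase_nm: float = 0.0
    background: float = 0.5
    fiber_specs: tuple[FiberSpec, ...] = ()
    ankg_start_um: float = 4.5
    ankg_max_um: float = 13.6
    ankg_end_um: float = 26.9
    ankg_amplitude: float = 1000.0
    ankg_baseline_frac: float = 0.05
    boundary_fraction: float = 0.33
    noise_sigma: float = 0.2
    poisson_scale: float | None = None
    puncta_end_prob: float = 0.6
    stripe_artifact: bool = False
    shaft_width_um: float = 0.95
    scene_height_um: float = 3.0
    seed: int = 0

    def __post_init__(self) -> None:
        if self.pixel_size_nm <= 0:
            raise ParameterError("pixel_size_nm must be positive")
        if self.profile_length_um <= 0:
            raise ParameterError("profile_length_um must be positive")
        if not (0 <= self.ankg_start_um < self.ankg_max_um < self.ankg_end_um):
            raise ParameterError("require 0 <= ankg_start < ankg_max < ankg_end")
        if not 0.0 <= self.puncta_end_prob <= 1.0:
            raise ParameterError("puncta_end_prob must lie in [0, 1]")
        if not 0.0 < self.boundary_fraction < 1.0:
            raise ParameterError("boundary_fraction must lie in (0, 1)")
        if not 0.0 <= self.ankg_baseline_frac < self.boundary_fraction:
            raise ParameterError("ankg baseline must sit below the boundary level")
        if self.noise_sigma < 0:
            raise ParameterError("noise_sigma must be >= 0")
        specs = tuple(
            f if isinstance(f, FiberSpec) else FiberSpec(*f) for f in self.fiber_specs
        )
        object.__setattr__(self, "fiber_specs", specs)

    @property
    def step_um(self) -> float:
        return self.pixel_size_nm / 1000.0

    def rng(self) -> np.random.Generator:
        return np.random.default_rng(self.seed)


@dataclass(frozen=True)
class SceneGroundTruth:
    """Generator-side truth against which detectors are scored."""

    true_ais: AISMeasure | None = None
    ring_spacing_nm: float | None = None
    fibers: tuple[FiberTrace, ...] = ()
    puncta_um: tuple[tuple[float, float], ...] = ()
    fiber_has_punctum: tuple[bool, ...] = ()
    channel_labels: tuple[str, ...] = ()
    shaft_width_um: float | None = None
    adr_truth: float | None = None
    flags: tuple[str, ...] = ()


# ---------------------------------------------------------------------------
# AnkyrinG axial profile


def _ankg_breakpoints(
    start: float, maxp: float, end: float, baseline: float, cutoff: float
) -> tuple[np.ndarray, np.ndarray]:
    """Breakpoints of the piecewise-linear rise-shoulder-apex-fall shape.

    The rise and fall are single linear segments crossing the normalized
    ``cutoff`` level exactly at ``start`` and ``end``; the segments extend
    at least ``_EDGE_MARGIN_UM`` beyond the crossing on each side wherever
    geometry permits, so a centered moving average (which preserves linear
    trends exactly) leaves the crossing position unchanged.  The apex at
    ``maxp`` is a symmetric tent between equal shoulders, keeping the
    smoothed argmax at the apex.
    """
    vstar = baseline + cutoff * (1.0 - baseline)
    frac = (vstar - baseline) / (_SHOULDER - baseline)  # crossing position on the edge

    def edge_len(avail_lo: float, avail_hi: float) -> float:
        ideal = max(_EDGE_MARGIN_UM / frac, _EDGE_MARGIN_UM / (1.0 - frac))
        return max(min(ideal, avail_lo / frac, avail_hi / (1.0 - frac)), 1e-6)

    lr = edge_len(start, max(maxp - start - 0.1, 1e-6))
    r0, r1 = start - frac * lr, start + (1.0 - frac) * lr
    # fall mirrors the rise: value drops SHOULDER -> baseline over lf,
    # crossing vstar at `end`; only the portion proximal of `end` is
    # constrained (the tail may run past the sampled profile)
    lf = edge_len(np.inf, max(end - maxp - 0.1, 1e-6))
    f0, f1 = end - (1.0 - frac) * lf, end + frac * lf
    if not (r1 < maxp and f0 > maxp):
        raise ParameterError("ankg_start/max/end too close together for the profile shape")
    d = min(_EDGE_MARGIN_UM, maxp - r1, f0 - maxp)
    xs = [r0, r1, maxp - d, maxp, maxp + d, f0, f1]
    vs = [baseline, _SHOULDER, _SHOULDER, 1.0, _SHOULDER, _SHOULDER, baseline]
    # drop duplicate breakpoints (when d hits a shoulder end exactly)
    keep_x, keep_v = [xs[0]], [vs[0]]
    for x, v in zip(xs[1:], vs[1:]):
        if x > keep_x[-1] + 1e-9:
            keep_x.append(x)
            keep_v.append(v)
    return np.asarray(keep_x), np.asarray(keep_v)


def ankg_shape(x_um: np.ndarray, params: SceneParams) -> np.ndarray:
    """Noiseless relative ankyrinG intensity (baseline..1) along the axon."""
    xs, vs = _ankg_breakpoints(
        params.ankg_start_um,
        params.ankg_max_um,
        params.ankg_end_um,
        params.ankg_baseline_frac,
        params.boundary_fraction,
    )
    return np.interp(x_um, xs, vs, left=vs[0], right=vs[-1])


def _apply_noise(
    vals: np.ndarray, params: SceneParams, rng: np.random.Generator
) -> np.ndarray:
    out = vals
    if params.poisson_scale:
        out = rng.poisson(np.clip(out, 0, None) * params.poisson_scale) / params.poisson_scale
    if params.noise_sigma > 0:
        out = out + rng.normal(0.0, params.noise_sigma, size=out.shape)
    return np.clip(out, 0.0, None)


def make_ankg_profile(params: SceneParams) -> tuple[Profile, SceneGroundTruth]:
    """Axial ankyrinG profile with known 0.33-crossing positions.

    The noiseless normalized trace crosses ``boundary_fraction`` exactly at
    ``ankg_start_um`` and ``ankg_end_um`` and peaks at ``ankg_max_um``; the
    recorded ground truth is those construction positions.  Noise per
    ``noise_sigma`` / ``poisson_scale`` (the ankyrinG signal amplitude is
    ``ankg_amplitude``, so SNR = (1 - baseline) * amplitude / sigma).
    """
    if params.ankg_end_um > params.profile_length_um:
        raise ParameterError(
            "profile_length_um must reach beyond ankg_end_um "
            f"({params.ankg_end_um:g} > {params.profile_length_um:g})"
        )
    n = int(round(params.profile_length_um / params.step_um)) + 1
    x = np.arange(n) * params.step_um
    shape = ankg_shape(x, params)
    rng = params.rng()
    inten = _apply_noise(shape * params.ankg_amplitude, params, rng)
    profile = Profile(
        positions_um=x,
        intensities=inten,
        pixel_size_nm=params.pixel_size_nm,
        channel="ankyrinG",
        source=f"synthgen.make_ankg_profile(seed={params.seed})",
    )
    truth = SceneGroundTruth(
        true_ais=AISMeasure(
            start_um=params.ankg_start_um,
            max_um=params.ankg_max_um,
            end_um=params.ankg_end_um,
            length_um=params.ankg_end_um - params.ankg_start_um,
        ),
        channel_labels=("ankyrinG",),
    )
    return profile, truth


# ---------------------------------------------------------------------------
# Ring profiles


def _ring_comb(x_nm: np.ndarray, spacing: float, sigma: float, phase: float) -> np.ndarray:
    """Sum of unit Gaussian bumps centered at phase + k*spacing, k = 0, 1, ..."""
    kmax = int(np.ceil((x_nm[-1] - phase) / spacing)) + 1
    centers = phase + np.arange(max(kmax, 1) + 1) * spacing
    return np.exp(-((x_nm[:, None] - centers[None, :]) ** 2) / (2.0 * sigma**2)).sum(axis=1)


def make_ring_profile(params: SceneParams) -> tuple[Profile, SceneGroundTruth]:
    """Periodic actin-ring intensity trace sampled on the pixel grid.

    Gaussian bumps at integer multiples of ``ring_spacing_nm`` (offset by
    ``ring_phase_nm``) on a constant background, plus noise.  Requires the
    spacing to exceed twice the pixel size (Nyquist).
    """
    if params.ring_spacing_nm <= 2 * params.pixel_size_nm:
        raise ParameterError(
            f"ring spacing ({params.ring_spacing_nm:g} nm) must exceed twice "
            f"the pixel size ({params.pixel_size_nm:g} nm)"
        )
    n = int(round(params.profile_length_um / params.step_um)) + 1
    x_nm = np.arange(n) * params.pixel_size_nm
    signal = params.background + params.ring_amplitude * _ring_comb(
        x_nm, params.ring_spacing_nm, params.ring_sigma_nm, params.ring_phase_nm
    )
    rng = params.rng()
    inten = _apply_noise(signal, params, rng)
    profile = Profile(
        positions_um=x_nm / 1000.0,
        intensities=inten,
        pixel_size_nm=params.pixel_size_nm,
        channel="actin",
        source=f"synthgen.make_ring_profile(seed={params.seed})",
    )
    truth = SceneGroundTruth(
        ring_spacing_nm=params.ring_spacing_nm, channel_labels=("actin",)
    )
    return profile, truth


# ---------------------------------------------------------------------------
# 2D scenes


def _clip_segment(
    p0: np.ndarray, p1: np.ndarray, xmax: float, ymax: float
) -> tuple[np.ndarray, np.ndarray, bool]:
    """Clip a segment to [0, xmax] x [0, ymax] (Liang-Barsky)."""
    d = p1 - p0
    t0, t1 = 0.0, 1.0
    clipped = False
    for axis, bound in ((0, xmax), (1, ymax)):
        for sign, edge in ((-1.0, 0.0), (1.0, bound)):
            denom = sign * d[axis]
            num = sign * (edge - p0[axis])
            if denom == 0:
                if num < 0:
                    return p0, p0, True  # fully outside
                continue
            t = num / denom
            if denom < 0:
                if t > t0:
                    t0, clipped = t, True
            else:
                if t < t1:
                    t1, clipped = t, True
    if t0 > t1:
        return p0, p0, True
    return p0 + t0 * d, p0 + t1 * d, clipped


def _render_segment(
    img: np.ndarray,
    p0_um: np.ndarray,
    p1_um: np.ndarray,
    sigma_um: float,
    amplitude: float,
    step_um: float,
) -> None:
    """Add a Gaussian-cross-section line segment to ``img`` in place."""
    ny, nx = img.shape
    yy, xx = np.mgrid[0:ny, 0:nx]
    pts = np.stack([xx * step_um, yy * step_um], axis=-1)
    d = p1_um - p0_um
    L2 = float(d @ d)
    if L2 == 0:
        dist = np.linalg.norm(pts - p0_um, axis=-1)
    else:
        t = np.clip(((pts - p0_um) @ d) / L2, 0.0, 1.0)
        proj = p0_um + t[..., None] * d
        dist = np.linalg.norm(pts - proj, axis=-1)
    img += amplitude * np.exp(-(dist**2) / (2.0 * sigma_um**2))


def make_axon_scene(params: SceneParams) -> tuple[np.ndarray, SceneGroundTruth]:
    """Multi-channel 2D raster {actin, ankyrinG, puncta} with ground truth.

    The axon shaft runs along x with a Gaussian cross-section whose
    33%-of-max width equals ``shaft_width_um``.  The actin channel carries
    transverse ring bands and the configured longitudinal fibers (Gaussian
    cross-section, FWHM 120 nm); the ankyrinG channel carries the axial AIS
    gradient; the puncta channel holds marker spots placed at each fiber
    end with probability ``puncta_end_prob``.  Fibers extending outside the
    raster are truncated with a warning flag in the ground truth.
    """
    step = params.step_um
    nx = int(round(params.profile_length_um / step)) + 1
    ny = int(round(params.scene_height_um / step)) + 1
    xmax, ymax = (nx - 1) * step, (ny - 1) * step
    yc = ymax / 2.0
    rng = params.rng()

    y_um = np.arange(ny) * step
    x_um = np.arange(nx) * step
    # Gaussian shaft: width at the 33% level equals shaft_width_um
    sigma_y = params.shaft_width_um / (2.0 * np.sqrt(2.0 * np.log(1.0 / 0.33)))
    shaft = np.exp(-((y_um - yc) ** 2) / (2.0 * sigma_y**2))

    comb = _ring_comb(
        x_um * 1000.0, params.ring_spacing_nm, params.ring_sigma_nm, params.ring_phase_nm
    )
    actin = shaft[:, None] * (params.background + params.ring_amplitude * comb[None, :])

    flags: list[str] = []
    fiber_truth: list[FiberTrace] = []
    sigma_fiber_um = 0.120 / 2.355  # FWHM 120 nm, SIM-like
    for i, spec in enumerate(params.fiber_specs):
        theta = np.deg2rad(spec.angle_deg)
        dy = rng.uniform(-0.25, 0.25) * params.shaft_width_um
        y0 = yc + (spec.y_offset_um if spec.y_offset_um is not None else dy)
        p0 = np.array([spec.start_um, y0])
        p1 = p0 + spec.length_um * np.array([np.cos(theta), np.sin(theta)])
        q0, q1, clipped = _clip_segment(p0, p1, xmax, ymax)
        if clipped:
            flags.append(f"fiber_{i}_truncated")
        length = float(np.linalg.norm(q1 - q0))
        if length < step:
            flags.append(f"fiber_{i}_outside_raster")
            continue
        _render_segment(actin, q0, q1, sigma_fiber_um, spec.intensity, step)
        fiber_truth.append(
            FiberTrace(
                polyline_um=np.stack([q0, q1]),
                length_um=length,
                angle_deg=abs(spec.angle_deg),
            )
        )

    ankg = shaft[:, None] * ankg_shape(x_um, params)[None, :]

    puncta_img = np.zeros_like(actin)
    puncta: list[tuple[float, float]] = []
    has_punctum: list[bool] = []
    sigma_punct_um = 0.080
    for tr in fiber_truth:
        hit = False
        for end in tr.ends:
            if rng.random() < params.puncta_end_prob:
                hit = True
                puncta.append((float(end[0]), float(end[1])))
                _render_segment(
                    puncta_img, np.asarray(end), np.asarray(end), sigma_punct_um, 1.0, step
                )
        has_punctum.append(hit)

    if params.ankg_end_um > xmax:
        flags.append("ais_extends_beyond_raster")

    if params.stripe_artifact:
        phi = np.deg2rad(30.0)
        u = x_um[None, :] * np.cos(phi) + y_um[:, None] * np.sin(phi)
        stripes = 0.15 * params.background * 0.5 * (1.0 + np.sin(2.0 * np.pi * u / 0.4))
        actin = actin + stripes

    channels = []
    for ch in (actin, ankg, puncta_img):
        channels.append(_apply_noise(ch, params, rng))
    image = np.stack(channels)

    truth = SceneGroundTruth(
        true_ais=AISMeasure(
            start_um=params.ankg_start_um,
            max_um=params.ankg_max_um,
            end_um=params.ankg_end_um,
            length_um=params.ankg_end_um - params.ankg_start_um,
        ),
        ring_spacing_nm=params.ring_spacing_nm,
        fibers=tuple(fiber_truth),
        puncta_um=tuple(puncta),
        fiber_has_punctum=tuple(has_punctum),
        channel_labels=("actin", "ankyrinG", "puncta"),
        shaft_width_um=params.shaft_width_um,
        flags=tuple(flags),
    )
    return image, truth


# ---------------------------------------------------------------------------
# Helpers for study-like datasets


def random_fiber_specs(
    rng: np.random.Generator,
    n: int,
    mean_length_um: float = 3.0,
    sd_length_um: float = 1.0,
    max_angle_deg: float = 25.0,
    scene_length_um: float = 20.0,
    intensity: float = 1.2,
) -> tuple[FiberSpec, ...]:
    """Draw fiber specs with lengths clipped to the countable 1-6 um range.

    The default mean length matches the control AIS condition.  Angles are
    uniform within ``max_angle_deg`` of the shaft axis (counted fibers were
    always within 45 degrees, usually far less), additionally capped so the
    fiber's transverse excursion stays inside a ~1 um shaft: a long fiber
    inside a thin axon is necessarily near-parallel.

    Fibers that overlap axially are placed in laterally separated lanes
    (>= 0.16 um apart): distinct countable fibers must be resolvable at
    SIM resolution, so the generator does not superpose them.
    """
    min_lateral_um = 0.16
    band_um = 0.3  # fibers live within +-band of the shaft center line
    placed: list[tuple[float, float, float, float]] = []  # x0, x1, ylo, yhi
    specs = []
    for _ in range(n):
        length = float(np.clip(rng.normal(mean_length_um, sd_length_um), 1.0, 6.0))
        start = y0 = angle = 0.0
        box = (0.0, 0.0, 0.0, 0.0)
        for _attempt in range(80):
            y0 = float(rng.uniform(-band_um, band_um))
            # the whole fiber stays inside the shaft band, so long fibers
            # are necessarily near-parallel
            sin_cap = max((band_um - abs(y0)) / length, 0.02)
            amax = min(max_angle_deg, float(np.degrees(np.arcsin(min(1.0, sin_cap)))))
            angle = float(rng.uniform(-amax, amax))
            span = length * np.cos(np.deg2rad(angle))
            hi = max(scene_length_um - span - 0.5, 0.6)
            start = float(rng.uniform(0.5, hi))
            y1 = y0 + length * np.sin(np.deg2rad(angle))
            ylo, yhi = min(y0, y1), max(y0, y1)
            box = (start, start + span, ylo, yhi)
            clash = any(
                min(box[1], x1) - max(box[0], x0) > 0.2
                and max(ylo - b_yhi, b_ylo - yhi) < min_lateral_um
                for x0, x1, b_ylo, b_yhi in placed
            )
            if not clash:
                break
        placed.append(box)
        specs.append(FiberSpec(start, length, angle, intensity, y_offset_um=y0))
    return tuple(specs)


def make_adr_profiles(
    params: SceneParams,
    contrast: float = 0.44,
    base_intensity: float = 100.0,
    n_dendrites: int = 3,
    dendrite_length_um: float = 60.0,
) -> tuple[Profile, list[Profile], SceneGroundTruth]:
    """Marker (Daam1-like) profiles for an AIS and several dendrites.

    The noiseless marker level is ``contrast * base_intensity`` along the
    axon and ``base_intensity`` along dendrites, so the true AIS-to-dendrite
    ratio is ``contrast``.  Noise follows ``params.noise_sigma`` scaled by
    the base intensity (SNR = base / (base * noise_sigma) in the dendrites).
    """
    if contrast <= 0:
        raise ParameterError("contrast must be positive")
    rng = params.rng()
    step = params.step_um

    n_ax = int(round(params.profile_length_um / step)) + 1
    x_ax = np.arange(n_ax) * step
    ais_vals = np.full(n_ax, contrast * base_intensity)
    sigma = params.noise_sigma * base_intensity
    if sigma > 0:
        ais_vals = ais_vals + rng.normal(0.0, sigma, n_ax)
    marker_ais = Profile(
        positions_um=x_ax,
        intensities=np.clip(ais_vals, 0.0, None),
        pixel_size_nm=params.pixel_size_nm,
        channel="marker",
        source=f"synthgen.make_adr_profiles(seed={params.seed})",
    )

    dendrites = []
    n_d = int(round(dendrite_length_um / step)) + 1
    x_d = np.arange(n_d) * step
    for _ in range(n_dendrites):
        vals = np.full(n_d, base_intensity)
        if sigma > 0:
            vals = vals + rng.normal(0.0, sigma, n_d)
        dendrites.append(
            Profile(
                positions_um=x_d,
                intensities=np.clip(vals, 0.0, None),
                pixel_size_nm=params.pixel_size_nm,
                channel="marker",
                source="synthgen.make_adr_profiles(dendrite)",
            )
        )
    truth = SceneGroundTruth(adr_truth=contrast, channel_labels=("marker",))
    return marker_ais, dendrites, truth


# ---------------------------------------------------------------------------
# Scene I/O: multi-page TIFF + JSON ground-truth sidecar


def _truth_to_jsonable(truth: SceneGroundTruth) -> dict:
    def conv(obj):
        if isinstance(obj, np.ndarray):
            return obj.tolist()
        if isinstance(obj, (np.floating, np.integer)):
            return obj.item()
        if isinstance(obj, (list, tuple)):
            return [conv(o) for o in obj]
        if isinstance(obj, dict):
            return {k: conv(v) for k, v in obj.items()}
        return obj

    d = asdict(truth)
    d["fibers"] = [
        {
            "polyline_um": tr.polyline_um.tolist(),
            "length_um": tr.length_um,
            "angle_deg": tr.angle_deg,
            "bins": list(tr.bins),
        }
        for tr in truth.fibers
    ]
    return conv(d)


def save_scene(
    image: np.ndarray,
    truth: SceneGroundTruth,
    path: str | _Path,
    pixel_size_nm: float,
) -> None:
    """Write a scene as multi-page TIFF with a JSON ground-truth sidecar."""
    path = _Path(path)
    tifffile.imwrite(
        str(path), np.asarray(image, dtype=np.float32), photometric="minisblack"
    )
    sidecar = path.with_suffix(".json")
    payload = _truth_to_jsonable(truth)
    payload["pixel_size_nm"] = pixel_size_nm
    with open(sidecar, "w") as fh:
        json.dump(payload, fh, indent=1)


def load_ground_truth(path: str | _Path) -> dict:
    """Read a scene's JSON ground-truth sidecar as a plain dict."""
    path = _Path(path)
    if path.suffix != ".json":
        path = path.with_suffix(".json")
    with open(path) as fh:
        return json.load(fh)
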