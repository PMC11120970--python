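"""AIS morphometry from ankyrinG line profiles.

The axon initial segment (AIS) is located operationally from the axial
ankyrinG fluorescence profile: the profile is smoothed with a 3 um rolling
average, min-max normalized to [0, 1], and the AIS start/end are the first
samples on either side of the intensity maximum where the normalized value
falls to 0.33.  Axon width uses the same 33% rule on a raw (unsmoothed)
transverse profile, relative to the profile maximum only.  The AIS-to-
dendrite ratio (ADR) compares mean marker intensity inside the AIS with the
mean over the first 50 um of all dendrites of the same neuron.
"""
from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .profiles import Profile

__all__ = [
    "AISMeasure",
    "ADRValue",
    "FlatProfileError",
    "smooth_profile",
    "detect_ais",
    "axon_width",
    "adr",
]


class FlatProfileError(ValueError):
    """Raised when a profile has no intensity contrast (max == min)."""


@dataclass(frozen=True)
class AISMeasure:
    """AIS boundary positions in micrometres from the path origin.

    ``length_um`` is exactly ``end_um - start_um``.  Flags record boundary
    truncation at the profile ends ("start_truncated", "end_truncated");
    truncated AISes should be excluded from length statistics.
    """

    start_um: float
    max_um: float
    end_um: float
    length_um: float
    flags: tuple[str, ...] = ()

    def __post_init__(self) -> None:
        if not (self.start_um <= self.max_um <= self.end_um):
            raise ValueError("AIS bounds must satisfy start <= max <= end")
        if self.length_um != self.end_um - self.start_um:
            raise ValueError("length_um must equal end_um - start_um")

    @property
    def truncated(self) -> bool:
        return any(f.endswith("truncated") for f in self.flags)


@dataclass(frozen=True)
class ADRValue:
    """AIS-to-dendrite marker ratio; 1.0 means equal distribution."""

    ratio: float
    ais_mean: float
    dendrite_mean: float
    n_dendrites: int

    def __post_init__(self) -> None:
        if self.dendrite_mean <= 0:
            raise ValueError("dendrite_mean must be positive")
        if self.n_dendrites < 1:
            raise ValueError("at least one dendrite is required")


def _movmean(x: np.ndarray, window_px: int) -> np.ndarray:
    """Centered moving average; at edges the window shrinks symmetrically.

    Keeping the window symmetric (half-width ``min(h, i, n-1-i)``) preserves
    linear trends exactly everywhere, including the edges.
    """
    x = np.asarray(x, dtype=float)
    n = x.size
    h = window_px // 2
    idx = np.arange(n)
    hw = np.minimum(h, np.minimum(idx, n - 1 - idx))
    csum = np.concatenate([[0.0], np.cumsum(x)])
    lo = idx - hw
    hi = idx + hw + 1
    return (csum[hi] - csum[lo]) / (hi - lo)


def smoothing_window_px(window_um: float, pixel_size_nm: float) -> int:
    """Window length in pixels for a rolling average of ``window_um``, forced odd."""
    w = int(round(window_um * 1000.0 / pixel_size_nm))
    if w % 2 == 0:
        w += 1
    return max(w, 1)


def smooth_profile(p: Profile, window_um: float = 3.0) -> Profile:
    """Rolling average around each pixel (default 3 um window)."""
    if window_um <= 0:
        raise ValueError("window_um must be positive")
    w = smoothing_window_px(window_um, p.pixel_size_nm)
    if w > p.n:
        raise ValueError(f"smoothing window ({w} px) larger than profile ({p.n} px)")
    sm = _movmean(p.intensities, w)
    return Profile(
        positions_um=p.positions_um,
        intensities=sm,
        pixel_size_nm=p.pixel_size_nm,
        channel=p.channel,
        source=p.source,
        flags=p.flags + (f"smoothed:{window_um}um",),
    )


def detect_ais(
    p: Profile,
    cutoff: float = 0.33,
    smooth_window_um: float = 3.0,
    smooth: bool = True,
) -> AISMeasure:
    """Locate AIS start/max/end from an axial ankyrinG profile.

    The (smoothed) trace is min-max normalized; the maximum position is the
    leftmost global maximum.  Scanning outward from the maximum toward each
    profile end, the boundary is the FIRST sample whose normalized value is
    <= ``cutoff`` — regardless of later re-crossings.  If no sample falls to
    the cutoff before the profile end, the boundary is set to that end and a
    truncation flag is raised.

    Invariant to affine intensity transforms a*I + b (a > 0).
    """
    if not 0 < cutoff < 1:
        raise ValueError("cutoff must be in (0, 1)")
    if smooth:
        w = smoothing_window_px(smooth_window_um, p.pixel_size_nm)
        if p.n < 2 * w:
            raise ValueError(
                f"profile too short ({p.n} px) for boundary detection with a "
                f"{w} px smoothing window"
            )
        sm = smooth_profile(p, smooth_window_um)
    else:
        sm = p
    vals = sm.intensities
    vmin, vmax = float(vals.min()), float(vals.max())
    if vmax <= vmin:
        raise FlatProfileError("flat profile: no AIS detectable")
    norm = (vals - vmin) / (vmax - vmin)
    imax = int(np.argmax(norm))  # leftmost (most proximal) global maximum

    flags: list[str] = []
    below = norm <= cutoff

    i_start = 0
    left = np.nonzero(below[: imax + 1])[0]
    if left.size:
        i_start = int(left[-1])  # first crossing scanning outward from imax
    else:
        flags.append("start_truncated")

    i_end = sm.n - 1
    right = np.nonzero(below[imax:])[0]
    if right.size:
        i_end = imax + int(right[0])
    else:
        flags.append("end_truncated")

    pos = sm.positions_um
    start, end = float(pos[i_start]), float(pos[i_end])
    return AISMeasure(
        start_um=start,
        max_um=float(pos[imax]),
        end_um=end,
        length_um=end - start,
        flags=tuple(flags),
    )


def axon_width(transverse: Profile, cutoff_fraction: float = 0.33) -> tuple[float, tuple[str, ...]]:
    """Axon width from a raw transverse profile at 33% of its maximum.

    No smoothing and no baseline subtraction: the cutoff is relative to the
    profile maximum alone, distinguishing the axon from the background.
    Returns ``(width_um, flags)``; a side that never falls to the cutoff is
    truncated at the profile end and flagged.
    """
    vals = transverse.intensities
    vmax = float(vals.max())
    if vmax <= 0:
        raise FlatProfileError("flat transverse profile")
    imax = int(np.argmax(vals))
    below = vals <= cutoff_fraction * vmax

    flags: list[str] = []
    i_left = 0
    left = np.nonzero(below[: imax + 1])[0]
    if left.size:
        i_left = int(left[-1])
    else:
        flags.append("left_truncated")
    i_right = vals.size - 1
    right = np.nonzero(below[imax:])[0]
    if right.size:
        i_right = imax + int(right[0])
    else:
        flags.append("right_truncated")

    pos = transverse.positions_um
    return float(pos[i_right] - pos[i_left]), tuple(flags)


def adr(
    marker_ais: Profile,
    marker_dendrites: list[Profile],
    ais: AISMeasure,
    dendrite_extent_um: float = 50.0,
) -> ADRValue:
    """AIS-to-dendrite ratio of a marker channel.

    Mean marker intensity over AIS samples (``start_um <= position <=
    end_um``) divided by the mean over the pooled first
    ``dendrite_extent_um`` of all dendrite profiles.
    """
    if not marker_dendrites:
        raise ValueError("at least one dendrite profile is required")
    pos = marker_ais.positions_um
    sel = (pos >= ais.start_um) & (pos <= ais.end_um)
    if not sel.any():
        raise ValueError("AIS bounds lie outside the marker profile")
    ais_mean = float(marker_ais.intensities[sel].mean())

    pooled: list[np.ndarray] = []
    for i, d in enumerate(marker_dendrites):
        rel = d.positions_um - d.positions_um[0]
        if rel[-1] < dendrite_extent_um:
            raise ValueError(
                f"dendrite profile {i} is shorter ({rel[-1]:.1f} um) than the "
                f"required {dendrite_extent_um:g} um extent"
            )
        pooled.append(d.intensities[rel <= dendrite_extent_um])
    dend = np.concatenate(pooled)
    dendrite_mean = float(dend.mean())
    if dendrite_mean <= 0:
        raise ValueError("dendrite mean intensity is zero")
    return ADRValue(
        ratio=ais_mean / dendrite_mean,
        ais_mean=ais_mean,
        dendrite_mean=dendrite_mean,
        n_dendrites=len(marker_dendrites),
    )
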