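"""Fluorescence line profiles: containers, extraction from rasters, and I/O.

A :class:`Profile` is a 1D fluorescence trace sampled at the camera pixel
size along a path drawn from the soma outward.  Positions are in micrometres
from the path origin, intensities in arbitrary units.  Profiles are the
common currency between the synthetic generator, the morphometry module
(AIS boundaries) and the periodicity module (actin rings).
"""
from __future__ import annotations

import json
from dataclasses import dataclass, replace
from pathlib import Path as _Path

import numpy as np
import pandas as pd
import tifffile
from scipy import ndimage as ndi

__all__ = [
    "Profile",
    "Polyline",
    "extract_line_profile",
    "read_profile_csv",
    "write_profile_csv",
    "read_image",
    "write_image",
    "read_polyline_json",
    "write_polyline_json",
]

_SPACING_RTOL = 1e-6


@dataclass(frozen=True)
class Profile:
    """A uniformly sampled 1D fluorescence trace.

    Attributes
    ----------
    positions_um:
        Sample positions in micrometres from the path origin, strictly
        increasing with uniform spacing equal to ``pixel_size_nm / 1000``.
    intensities:
        Fluorescence in arbitrary units, same length as ``positions_um``.
        Raw profiles are non-negative; locally-normalized residual profiles
        carry the ``"normalized"`` flag and may be signed.
    pixel_size_nm:
        Physical pixel size of the camera, nanometres.
    channel:
        Fluorescence channel label (e.g. ``"ankyrinG"``, ``"actin"``).
    source:
        Free-form provenance string.
    flags:
        Quality/processing flags accumulated by operations.
    """

    positions_um: np.ndarray
    intensities: np.ndarray
    pixel_size_nm: float
    channel: str = ""
    source: str = ""
    flags: tuple[str, ...] = ()

    def __post_init__(self) -> None:
        pos = np.asarray(self.positions_um, dtype=float)
        inten = np.asarray(self.intensities, dtype=float)
        object.__setattr__(self, "positions_um", pos)
        object.__setattr__(self, "intensities", inten)
        if pos.ndim != 1 or inten.ndim != 1 or pos.size != inten.size:
            raise ValueError("positions and intensities must be 1D of equal length")
        if pos.size < 2:
            raise ValueError("a profile needs at least 2 samples")
        if self.pixel_size_nm <= 0:
            raise ValueError("pixel_size_nm must be positive")
        if not np.all(np.isfinite(pos)) or not np.all(np.isfinite(inten)):
            raise ValueError("profile contains non-finite values")
        step = self.pixel_size_nm / 1000.0
        diffs = np.diff(pos)
        bad = np.nonzero(~np.isclose(diffs, step, rtol=_SPACING_RTOL, atol=step * _SPACING_RTOL))[0]
        if bad.size:
            i = int(bad[0])
            raise ValueError(
                f"non-uniform spacing at sample {i + 1}: step {diffs[i]:.6g} um, "
                f"expected {step:.6g} um"
            )
        if "normalized" not in self.flags and np.any(inten < 0):
            raise ValueError("raw profile intensities must be >= 0")

    @property
    def n(self) -> int:
        return int(self.positions_um.size)

    @property
    def step_um(self) -> float:
        return self.pixel_size_nm / 1000.0

    @property
    def length_um(self) -> float:
        """Distance spanned from first to last sample."""
        return float(self.positions_um[-1] - self.positions_um[0])

    def with_flags(self, *flags: str) -> "Profile":
        return replace(self, flags=self.flags + tuple(f for f in flags if f not in self.flags))


@dataclass(frozen=True)
class Polyline:
    """A path along an axon or dendrite, in image coordinates (x, y) um.

    ``width_px`` is the number of perpendicular samples averaged at each
    point along the path (forced odd, centered on the path).
    """

    vertices_um: tuple[tuple[float, float], ...]
    width_px: int = 3

    def __post_init__(self) -> None:
        verts = tuple((float(x), float(y)) for x, y in self.vertices_um)
        object.__setattr__(self, "vertices_um", verts)
        if len(verts) < 2:
            raise ValueError("a polyline needs at least 2 vertices")
        for a, b in zip(verts[:-1], verts[1:]):
            if a == b:
                raise ValueError("consecutive polyline vertices must be distinct")
        if self.width_px < 1:
            raise ValueError("width_px must be >= 1")

    @property
    def length_um(self) -> float:
        v = np.asarray(self.vertices_um)
        return float(np.sum(np.hypot(*np.diff(v, axis=0).T)))


def _arc_samples(verts: np.ndarray, step_um: float) -> tuple[np.ndarray, np.ndarray]:
    """Sample points and unit tangents at ``step_um`` intervals of arc length."""
    seg = np.diff(verts, axis=0)
    seg_len = np.hypot(seg[:, 0], seg[:, 1])
    cum = np.concatenate([[0.0], np.cumsum(seg_len)])
    total = cum[-1]
    if total <= 0:
        raise ValueError("zero-length path")
    s = np.arange(0.0, total + step_um / 2, step_um)
    s = s[s <= total + 1e-12]
    idx = np.clip(np.searchsorted(cum, s, side="right") - 1, 0, len(seg_len) - 1)
    frac = (s - cum[idx]) / seg_len[idx]
    pts = verts[idx] + seg[idx] * frac[:, None]
    tangents = seg[idx] / seg_len[idx, None]
    return pts, tangents


def extract_line_profile(
    image: np.ndarray,
    path: Polyline,
    pixel_size_nm: float,
    channel: str = "",
    max_project: bool = True,
    z_slice: int | None = None,
) -> Profile:
    """Sample image intensity along a polyline at pixel-size steps.

    Intensity at each arc-length position is the mean over ``path.width_px``
    bilinearly interpolated samples spaced one pixel apart perpendicular to
    the local path direction.  3D stacks are maximum-intensity projected
    along the first axis unless ``z_slice`` selects a single plane.

    Positions of the returned profile start at 0 (the first vertex).
    """
    img = np.asarray(image, dtype=float)
    if img.ndim == 3:
        img = img[z_slice] if z_slice is not None else img.max(axis=0)
    elif not max_project and img.ndim != 2:
        raise ValueError("expected a 2D image or 3D stack")
    if img.ndim != 2:
        raise ValueError("expected a 2D image or 3D stack")

    step_um = pixel_size_nm / 1000.0
    verts = np.asarray(path.vertices_um, dtype=float)
    # vertex (x, y) um -> pixel (col, row)
    verts_px = verts * 1000.0 / pixel_size_nm
    ny, nx = img.shape
    if (
        verts_px[:, 0].min() < -0.5
        or verts_px[:, 1].min() < -0.5
        or verts_px[:, 0].max() > nx - 0.5
        or verts_px[:, 1].max() > ny - 0.5
    ):
        raise ValueError("path lies outside the image bounds")

    pts, tangents = _arc_samples(verts, step_um)
    pts_px = pts * 1000.0 / pixel_size_nm
    normals = np.stack([-tangents[:, 1], tangents[:, 0]], axis=1)

    w = int(path.width_px)
    if w % 2 == 0:
        w += 1
    offsets = np.arange(w) - w // 2  # in pixels
    # sample coords: (n_samples, w, 2) in pixel units, order (col=x, row=y)
    coords = pts_px[:, None, :] + offsets[None, :, None] * normals[:, None, :]
    rows = coords[..., 1].ravel()
    cols = coords[..., 0].ravel()
    vals = ndi.map_coordinates(img, np.stack([rows, cols]), order=1, mode="nearest")
    inten = vals.reshape(len(pts), w).mean(axis=1)
    positions = np.arange(len(pts)) * step_um
    return Profile(
        positions_um=positions,
        intensities=np.clip(inten, 0.0, None),
        pixel_size_nm=pixel_size_nm,
        channel=channel,
        source="extract_line_profile",
    )


# ---------------------------------------------------------------------------
# CSV / TIFF / JSON I/O


def write_profile_csv(profile: Profile, path: str | _Path) -> None:
    """Write a profile as 2-column CSV (position_um, intensity)."""
    df = pd.DataFrame(
        {"position_um": profile.positions_um, "intensity": profile.intensities}
    )
    # repr is the shortest exact round-trip representation of a float
    df.to_csv(path, index=False, float_format=lambda v: repr(float(v)))


def read_profile_csv(
    path: str | _Path, channel: str = "", pixel_size_nm: float | None = None
) -> Profile:
    """Read a 2-column CSV profile; spacing must be uniform.

    The pixel size is inferred from the position spacing unless given.
    """
    try:
        df = pd.read_csv(path, float_precision="round_trip")
    except pd.errors.EmptyDataError as exc:
        raise ValueError(f"{path}: empty or unreadable profile CSV") from exc
    missing = {"position_um", "intensity"} - set(df.columns)
    if missing:
        raise ValueError(f"{path}: missing column(s) {sorted(missing)}")
    if len(df) < 2:
        raise ValueError(f"{path}: a profile needs at least 2 rows")
    pos = df["position_um"].to_numpy(dtype=float)
    diffs = np.diff(pos)
    step = diffs[0]
    if step <= 0:
        raise ValueError(f"{path}: positions must increase (row 1)")
    bad = np.nonzero(~np.isclose(diffs, step, rtol=_SPACING_RTOL, atol=abs(step) * _SPACING_RTOL))[0]
    if bad.size:
        raise ValueError(f"{path}: non-uniform spacing at row {int(bad[0]) + 2}")
    px = pixel_size_nm if pixel_size_nm is not None else step * 1000.0
    return Profile(
        positions_um=pos,
        intensities=df["intensity"].to_numpy(dtype=float),
        pixel_size_nm=px,
        channel=channel,
        source=str(path),
    )


def read_image(path: str | _Path) -> np.ndarray:
    """Read a (multi-page) TIFF as an array (pages become the first axis)."""
    return tifffile.imread(str(path))


def write_image(image: np.ndarray, path: str | _Path) -> None:
    tifffile.imwrite(
        str(path), np.asarray(image, dtype=np.float32), photometric="minisblack"
    )


def write_polyline_json(path_obj: Polyline, path: str | _Path) -> None:
    with open(path, "w") as fh:
        json.dump(
            {"vertices_um": [list(v) for v in path_obj.vertices_um], "width_px": path_obj.width_px},
            fh,
        )


def read_polyline_json(path: str | _Path) -> Polyline:
    with open(path) as fh:
        data = json.load(fh)
    return Polyline(
        vertices_um=tuple(tuple(v) for v in data["vertices_um"]),
        width_px=int(data.get("width_px", 3)),
    )
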