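"""Needle-referenced (M-mode) maps and Doppler-driven surface-referenced maps.

The needle-referenced map is the raw concatenation of per-pair profiles with
time horizontal and probe-relative depth vertical.  The surface-referenced
canvas re-anchors every profile at the Doppler-tracked absolute tip depth:
rows above the current tip carry their last-written values (the record of
traversed tissue), rows at and below the tip are refreshed from the live
A-line, and dwell time at a position widens its band along the time axis —
an implicit confidence indicator.  Rendered frames mirror the image about
the needle axis purely for presentation.
"""

from __future__ import annotations

import os
from dataclasses import dataclass

import imageio.v3 as iio
import matplotlib

matplotlib.use("Agg")
from matplotlib import colormaps

import numpy as np

from .doppler import TipTrack
from .recon import PolarimetryProfiles

__all__ = [
    "NeedleReferencedMap",
    "SurfaceCanvas",
    "RenderStyle",
    "needle_referenced_map",
    "build_surface_canvas",
    "render_frame",
    "export_frames",
]

CONTRASTS = ("intensity_db", "retardation", "axis_deg")


@dataclass
class NeedleReferencedMap:
    """Depth x time image per contrast; column j is profile j verbatim."""

    intensity_db: np.ndarray
    retardation: np.ndarray
    axis_deg: np.ndarray
    mask: np.ndarray
    time_s: np.ndarray
    depth_offset_px: int
    pitch_um: float

    @property
    def n_columns(self) -> int:
        return self.intensity_db.shape[1]


def needle_referenced_map(profiles: PolarimetryProfiles) -> NeedleReferencedMap:
    """Pure concatenation of A-line profiles, no resampling."""
    return NeedleReferencedMap(
        intensity_db=np.ascontiguousarray(profiles.intensity_db.T),
        retardation=np.ascontiguousarray(profiles.retardation.T),
        axis_deg=np.ascontiguousarray(profiles.axis_deg.T),
        mask=np.ascontiguousarray(profiles.mask.T),
        time_s=profiles.time_s,
        depth_offset_px=profiles.depth_offset_px,
        pitch_um=profiles.pitch_um,
    )


@dataclass
class SurfaceCanvas:
    """Absolute-depth x time store per contrast, with the tip-row trace.

    Row 0 is the tissue surface; row r spans depths [r*pitch, (r+1)*pitch).
    ``frozen`` marks, per column, rows that lay above the tip (the traversed
    record) when that column was written.
    """

    data: dict[str, np.ndarray]
    tip_row: np.ndarray
    frozen: np.ndarray           # bool (rows, cols)
    time_s: np.ndarray
    pitch_um: float


def build_surface_canvas(
    profiles: PolarimetryProfiles,
    track: TipTrack,
    surface_pixel: int,
    pitch_um: float | None = None,
    extent_px: int | None = None,
    mask_polarimetry: bool = True,
) -> SurfaceCanvas:
    """Convert needle-referenced profiles into a surface-referenced canvas.

    For each time column the tip row is round(p(t)/pitch); rows tip..tip+extent
    are written from the current profile (needle-relative depth shifted by the
    tracked tip depth), shallower rows keep their previous values.
    """
    pitch = pitch_um or profiles.pitch_um
    pt, tt = profiles.time_s, track.time_s
    if pt[0] < tt[0] - 0.05 or pt[-1] > tt[-1] + 0.05:
        raise ValueError("profile and track time bases do not overlap")
    p = np.interp(pt, tt, track.tip_depth_um)
    r = np.rint(np.maximum(p, 0.0) / pitch).astype(int)

    j0 = surface_pixel - profiles.depth_offset_px
    if j0 < 0:
        raise ValueError("profiles do not cover the tissue surface pixel")
    n_z = profiles.intensity_db.shape[1] - j0
    extent = n_z if extent_px is None else min(extent_px, n_z)
    n_rows = int(r.max()) + extent
    n_cols = len(pt)

    data = {c: np.full((n_rows, n_cols), np.nan, dtype=np.float32) for c in CONTRASTS}
    frozen = np.zeros((n_rows, n_cols), dtype=bool)
    cols = {
        "intensity_db": profiles.intensity_db,
        "retardation": np.where(profiles.mask, profiles.retardation, np.nan)
        if mask_polarimetry else profiles.retardation,
        "axis_deg": np.where(profiles.mask, profiles.axis_deg, np.nan)
        if mask_polarimetry else profiles.axis_deg,
    }
    for t in range(n_cols):
        rt = r[t]
        for c in CONTRASTS:
            col = data[c][:, t]
            if t > 0:
                col[:] = data[c][:, t - 1]        # carry the record forward
            stop = min(rt + extent, n_rows)
            col[rt:stop] = cols[c][t, j0: j0 + (stop - rt)]
        frozen[:rt, t] = True
    return SurfaceCanvas(data=data, tip_row=r, frozen=frozen, time_s=pt, pitch_um=pitch)


@dataclass(frozen=True)
class RenderStyle:
    """Fixed color scales per contrast plus tip-boundary cosmetics."""

    intensity_cmap: str = "gray"
    intensity_range_db: tuple[float, float] = (-50.0, 0.0)
    retardation_cmap: str = "viridis"
    axis_cmap: str = "hsv"       # cyclic, period 180 deg
    tip_line_px: int = 3
    background: tuple[int, int, int] = (0, 0, 0)


def _colorize(arr: np.ndarray, contrast: str, style: RenderStyle) -> np.ndarray:
    if contrast == "intensity_db":
        lo, hi = style.intensity_range_db
        norm = (arr - lo) / (hi - lo)
        cmap = colormaps[style.intensity_cmap]
    elif contrast == "retardation":
        norm = arr / np.pi
        cmap = colormaps[style.retardation_cmap]
    elif contrast == "axis_deg":
        norm = (arr + 90.0) / 180.0
        cmap = colormaps[style.axis_cmap]
    else:
        raise KeyError(f"unknown contrast {contrast!r}")
    bad = ~np.isfinite(norm)
    rgb = (cmap(np.clip(np.nan_to_num(norm), 0.0, 1.0))[..., :3] * 255).astype(np.uint8)
    rgb[bad] = np.array(style.background, dtype=np.uint8)
    return rgb


def render_frame(
    canvas: SurfaceCanvas,
    t_index: int,
    contrast: str = "retardation",
    style: RenderStyle | None = None,
) -> np.ndarray:
    """Render the canvas history up to column ``t_index`` as an RGB raster.

    The image is mirrored about the needle's centre line (a one-pixel
    separator column), and the traversed/untraversed boundary is drawn as a
    thick dark line along the tip-row trace.  Frame width is
    2 * (columns so far) + 1.
    """
    style = style or RenderStyle()
    if not (0 <= t_index < len(canvas.time_s)):
        raise IndexError("t_index outside the canvas")
    half = canvas.data[contrast][:, : t_index + 1]
    rgb = _colorize(half, contrast, style)
    n_rows = rgb.shape[0]
    # tip boundary trace
    for t in range(t_index + 1):
        r = canvas.tip_row[t]
        rgb[r: min(r + style.tip_line_px, n_rows), t] = (20, 20, 20)
    sep = np.full((n_rows, 1, 3), 60, dtype=np.uint8)
    return np.concatenate([rgb[:, ::-1], sep, rgb], axis=1)


def export_frames(frames: list[np.ndarray], directory: str | os.PathLike,
                  prefix: str = "frame") -> list[str]:
    """Write numbered lossless PNG frames plus a manifest; returns the paths."""
    os.makedirs(directory, exist_ok=True)
    paths = []
    for i, frame in enumerate(frames):
        name = f"{prefix}_{i:05d}.png"
        iio.imwrite(os.path.join(directory, name), frame)
        paths.append(name)
    with open(os.path.join(directory, "manifest.txt"), "w") as fh:
        fh.write("\n".join(paths) + ("\n" if paths else ""))
    return [os.path.join(str(directory), p) for p in paths]
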