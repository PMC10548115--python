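"""Layer-identification metrics on reconstructed needle runs.

These are the automated readouts of the three guidance archetypes:

* retardation alternation — muscle/connective alternation shows up as a
  high/low square wave in the cumulative retardation a fixed distance below
  the tip while the needle traverses the stack;
* optic-axis changepoints — equally retarding layers with distinct fiber
  orientations produce a piecewise-constant apparent axis just below the tip
  (the cumulative measurement is referenced to the tip, so it only spans the
  layer currently ahead of the needle), with jumps at boundary crossings;
* void crossing — entering a low-scattering space is flagged by the
  co-occurrence of an intensity spike at the tip reflection and the loss of
  polarimetric signal below it.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .doppler import TipTrack
from .recon import PolarimetryProfiles, circular_mean_halfturn

__all__ = [
    "insertion_window",
    "retardation_alternation",
    "axis_changepoints",
    "void_crossing_time",
]


def insertion_window(track: TipTrack) -> tuple[float, float]:
    """(t_start, t_peak): the insertion half of a traverse, by tracked depth."""
    i = int(np.argmax(track.tip_depth_um))
    return float(track.time_s[0]), float(track.time_s[i])


def _probe_series(profiles: PolarimetryProfiles, surface_pixel: int,
                  probe_depth_um: float, band_um: float) -> tuple[np.ndarray, np.ndarray]:
    """Per-pair circular summaries of (retardation, axis) in a shallow band
    [probe_depth - band/2, probe_depth + band/2] below the contact surface."""
    j0 = surface_pixel - profiles.depth_offset_px
    pitch = profiles.pitch_um
    lo = j0 + max(1, int(round((probe_depth_um - band_um / 2) / pitch)))
    hi = j0 + int(round((probe_depth_um + band_um / 2) / pitch)) + 1
    ret = circular_mean_halfturn(profiles.retardation[:, lo:hi], axis=1)
    ax = np.rad2deg(circular_mean_halfturn(
        np.deg2rad(profiles.axis_deg[:, lo:hi]), axis=1))
    ax = (ax + 90.0) % 180.0 - 90.0
    return ret, ax


def _runs(binary: np.ndarray, times: np.ndarray, min_duration_s: float):
    """Contiguous runs of a boolean series, short blips merged into their
    predecessor.  Run duration counts whole samples (span plus one period)."""
    dt = float(np.median(np.diff(times))) if len(times) > 1 else 0.0
    runs: list[tuple[bool, float, float]] = []
    start = 0
    for i in range(1, len(binary) + 1):
        if i == len(binary) or binary[i] != binary[start]:
            runs.append((bool(binary[start]), float(times[start]), float(times[i - 1])))
            start = i
    merged: list[list] = []
    for val, t0, t1 in runs:
        if merged and (t1 - t0 + dt) < min_duration_s:
            merged[-1][2] = t1            # absorb the blip
        elif merged and merged[-1][0] == val:
            merged[-1][2] = t1
        else:
            merged.append([val, t0, t1])
    return [(v, t0, t1) for v, t0, t1 in merged]


def retardation_alternation(
    profiles: PolarimetryProfiles,
    track: TipTrack,
    surface_pixel: int,
    probe_depth_um: float = 150.0,
    threshold_rad: float = 0.7,
    min_duration_s: float = 0.08,
) -> tuple[int, int]:
    """Count (birefringent, non-birefringent) layer runs during insertion.

    Thresholds the cumulative retardation ``probe_depth_um`` below the tip
    over the insertion half of the traverse and counts high/low runs.
    """
    t0, t1 = insertion_window(track)
    sel = (profiles.time_s >= t0) & (profiles.time_s <= t1)
    ret, _ = _probe_series(profiles, surface_pixel, probe_depth_um, band_um=40.0)
    runs = _runs(ret[sel] > threshold_rad, profiles.time_s[sel], min_duration_s)
    n_high = sum(1 for v, *_ in runs if v)
    n_low = sum(1 for v, *_ in runs if not v)
    return n_high, n_low


def axis_changepoints(
    profiles: PolarimetryProfiles,
    track: TipTrack,
    surface_pixel: int,
    probe_depth_um: float = 100.0,
    min_jump_deg: float = 20.0,
    min_separation_s: float = 0.15,
    smooth_pairs: int = 15,
    lag_s: float = 0.06,
) -> list[float]:
    """Times of sustained optic-axis orientation jumps during insertion.

    Differences of the (circularly smoothed) axis series just below the tip,
    taken ``lag_s`` apart so the comparison straddles the gradual band
    crossing, are clustered into boundary-crossing events above
    ``min_jump_deg``.
    """
    t0, t1 = insertion_window(track)
    sel = (profiles.time_s >= t0) & (profiles.time_s <= t1)
    _, ax = _probe_series(profiles, surface_pixel, probe_depth_um, band_um=80.0)
    ax, times = ax[sel], profiles.time_s[sel]
    if len(ax) < 3 * smooth_pairs:
        return []
    # circular moving average over doubled angles
    z = np.exp(2j * np.deg2rad(ax))
    kern = np.ones(smooth_pairs) / smooth_pairs
    zs = np.convolve(z, kern, mode="same")
    sm = np.rad2deg(np.angle(zs)) / 2.0
    dt = float(np.median(np.diff(times))) if len(times) > 1 else 1.0
    lag = max(2, int(round(lag_s / dt)))
    if lag >= len(sm):
        return []
    diff = np.abs(np.angle(np.exp(2j * np.deg2rad(sm[lag:] - sm[:-lag])))) / 2.0
    diff_deg = np.rad2deg(diff)
    hits = np.nonzero(diff_deg > min_jump_deg)[0]
    events: list[float] = []
    for h in hits:
        t = float(times[h + lag // 2])
        if not events or t - events[-1] > min_separation_s:
            events.append(t)
    return events


def void_crossing_time(
    profiles: PolarimetryProfiles,
    track: TipTrack,
    tip_pixel: int,
    surface_pixel: int,
    spike_db: float = 5.0,
    max_valid_fraction: float = 0.3,
    window_um: float = 120.0,
) -> float | None:
    """First time the tip intensity spikes while sub-tip polarimetry is lost.

    Returns None when no such co-occurrence exists.  The intensity baseline
    is the median tip-pixel intensity over the run.
    """
    j_tip = tip_pixel - profiles.depth_offset_px
    j0 = surface_pixel - profiles.depth_offset_px + 1
    j1 = j0 + int(round(window_um / profiles.pitch_um))
    tip_db = profiles.intensity_db[:, j_tip]
    baseline = np.median(tip_db)
    spike = tip_db > baseline + spike_db
    valid_frac = profiles.mask[:, j0:j1].mean(axis=1)
    lost = valid_frac < max_valid_fraction
    both = np.nonzero(spike & lost)[0]
    if both.size == 0:
        return None
    return float(profiles.time_s[both[0]])
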