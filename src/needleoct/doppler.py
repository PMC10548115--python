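"""Doppler phase-shift odometry of the needle tip.

One launch state's consecutive complex A-lines (40 us apart) yield a wrapped
per-depth phase-difference series.  The processing chain, in order:

1. jitter gate    — |dphi| > 2.5 rad is physically implausible needle motion
                    (> ~4.7 mm/s) and is classified as laser phase jitter,
                    set to exactly zero;
2. causal median  — per depth pixel, a sliding median over the past 72
                    same-state intervals (2.88 ms) absorbs the gated zeros
                    and speckle re-configuration glitches;
3. tip reference  — the phase difference at the static needle-tip reflection
                    is subtracted from every depth below it, cancelling slow
                    common-mode phase drift;
4. depth mean     — arithmetic mean over 46 pixels (86 um) of tissue below
                    the contact surface, where tissue moves rigidly relative
                    to the needle;
5. conversion     — v = lambda_c dphi / (4 pi n T) and d = lambda_c dphi /
                    (4 pi n), integrated into tip depth p(t).
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy import ndimage

from .phantom import SystemSpec
from .recon import BinnedTomogram

__all__ = [
    "DopplerParams",
    "PhaseDifferenceSeries",
    "TipTrack",
    "phase_difference",
    "jitter_gate",
    "temporal_median",
    "tip_reference_correct",
    "depth_average",
    "to_velocity",
    "to_displacement",
    "integrate_position",
    "track",
    "index_mismatch_error",
    "ADIPOSE_INDEX",
]


@dataclass(frozen=True)
class DopplerParams:
    """Constants of the velocity/displacement conversion and filtering."""

    center_wavelength_um: float = 1.310
    tissue_index: float = 1.37
    state_period_s: float = 40e-6
    gate_rad: float = 2.5
    median_window: int = 72
    depth_span_px: int = 46
    tip_pixel: int = 30
    surface_offset_px: int = 8   # tissue contact surface below the reflection
    state: int = 0               # which launch state feeds the Doppler phase

    def __post_init__(self) -> None:
        if not (0.0 < self.gate_rad < np.pi):
            raise ValueError("gate_rad must be in (0, pi): no unwrapping is done")
        if self.median_window < 1 or self.depth_span_px < 1:
            raise ValueError("median_window and depth_span_px must be >= 1")

    @classmethod
    def from_system(cls, system: SystemSpec, **overrides) -> "DopplerParams":
        kw = dict(
            center_wavelength_um=system.center_wavelength_um,
            tissue_index=system.tissue_index,
            state_period_s=system.state_period_s,
            tip_pixel=system.tip_pixel,
            surface_offset_px=system.tip_standoff_px,
        )
        kw.update(overrides)
        return cls(**kw)

    @property
    def gate_velocity_mm_s(self) -> float:
        """Axial speed corresponding to the gate threshold (Doppler limit)."""
        return to_velocity(self.gate_rad, self)

    @property
    def median_span_s(self) -> float:
        return self.median_window * self.state_period_s


@dataclass
class PhaseDifferenceSeries:
    """Wrapped phase differences dphi in (-pi, pi]: (intervals, depth)."""

    dphi: np.ndarray
    time_s: np.ndarray
    depth_offset_px: int = 0

    def copy_with(self, dphi: np.ndarray) -> "PhaseDifferenceSeries":
        return PhaseDifferenceSeries(dphi, self.time_s, self.depth_offset_px)


@dataclass
class TipTrack:
    """Gated/filtered tip odometry per same-state interval."""

    time_s: np.ndarray
    dphi_tip: np.ndarray          # rad, post gate/median/reference/depth-mean
    velocity_mm_s: np.ndarray
    displacement_um: np.ndarray
    tip_depth_um: np.ndarray      # integrated position, insertion positive
    gate_hit_rate: float = 0.0    # fraction of samples zeroed by the gate
    params: DopplerParams | None = None


def phase_difference(tom: BinnedTomogram, state: int = 0) -> PhaseDifferenceSeries:
    """Per-depth wrapped phase of consecutive same-state A-line products.

    The two detection channels are combined power-weighted and phase-
    coherently: dphi = arg(sum_c z_t z*_{t-1}).
    """
    if tom.full is None:
        raise ValueError("tomogram carries no full-spectrum profiles")
    idx = np.nonzero(tom.state == state)[0]
    if idx.size < 2:
        raise ValueError(f"need >= 2 A-lines of state {state} for phase differences")
    z = tom.full[idx].astype(np.complex64)
    prod = np.sum(z[1:] * np.conj(z[:-1]), axis=1)   # channel sum
    dphi = np.angle(prod).astype(np.float32)
    return PhaseDifferenceSeries(
        dphi=dphi,
        time_s=tom.time_s[idx[1:]],
        depth_offset_px=tom.depth_offset_px,
    )


def jitter_gate(series: PhaseDifferenceSeries, gate_rad: float = 2.5) -> PhaseDifferenceSeries:
    """Zero every sample with |dphi| strictly above the gate threshold."""
    d = series.dphi
    return series.copy_with(np.where(np.abs(d) > gate_rad, 0.0, d).astype(d.dtype))


def temporal_median(series: PhaseDifferenceSeries, window: int = 72) -> PhaseDifferenceSeries:
    """Causal sliding median over the most recent ``window`` intervals.

    Each depth pixel is filtered independently; output at interval i uses
    samples i-window+1 .. i.  Start-up rows use all available past samples.
    """
    if window < 1:
        raise ValueError("window must be >= 1")
    d = series.dphi
    if window == 1 or d.shape[0] == 1:
        return series.copy_with(d.copy())
    w = min(window, d.shape[0])
    origin = ((w - 1) // 2, 0)    # shifts the window onto the past w samples
    if w % 2:
        out = ndimage.median_filter(d, size=(w, 1), mode="nearest", origin=origin)
    else:                         # true median: mean of the two central ranks
        lo_r = ndimage.rank_filter(d, w // 2 - 1, size=(w, 1), mode="nearest",
                                   origin=origin)
        hi_r = ndimage.rank_filter(d, w // 2, size=(w, 1), mode="nearest",
                                   origin=origin)
        out = 0.5 * (lo_r + hi_r)
    for i in range(w - 1):        # growing prefix windows
        out[i] = np.median(d[: i + 1], axis=0)
    return series.copy_with(out.astype(d.dtype))


def tip_reference_correct(series: PhaseDifferenceSeries, tip_pixel: int) -> PhaseDifferenceSeries:
    """Subtract the needle-tip phase difference from every depth, re-wrapped.

    The tip reflection sits at constant delay, so its apparent phase
    difference is pure common-mode drift; output at the tip pixel is exactly
    zero.
    """
    j = tip_pixel - series.depth_offset_px
    if not (0 <= j < series.dphi.shape[1]):
        raise ValueError("tip pixel outside the stored depth range")
    diff = series.dphi - series.dphi[:, j][:, None]
    wrapped = np.mod(diff + np.pi, 2.0 * np.pi) - np.pi
    wrapped[:, j] = 0.0
    return series.copy_with(wrapped.astype(series.dphi.dtype))


def depth_average(series: PhaseDifferenceSeries, below_pixel: int,
                  depth_span: int = 46) -> np.ndarray:
    """Arithmetic mean over pixels (below_pixel+1 .. below_pixel+depth_span)."""
    j0 = below_pixel - series.depth_offset_px + 1
    j1 = j0 + depth_span
    if j0 < 0 or j1 > series.dphi.shape[1]:
        raise ValueError("averaging span exceeds the stored depth range")
    return series.dphi[:, j0:j1].mean(axis=1)


def to_velocity(dphi_rad, params: DopplerParams):
    """Axial velocity in mm/s: v = lambda_c dphi / (4 pi n T)."""
    um_per_s = (params.center_wavelength_um * np.asarray(dphi_rad, dtype=np.float64)
                / (4.0 * np.pi * params.tissue_index * params.state_period_s))
    return um_per_s * 1e-3


def to_displacement(dphi_rad, params: DopplerParams):
    """Per-interval displacement in um: d = lambda_c dphi / (4 pi n)."""
    return (params.center_wavelength_um * np.asarray(dphi_rad, dtype=np.float64)
            / (4.0 * np.pi * params.tissue_index))


#: Refractive index of adipose tissue near 1300 nm; the conversion assumes
#: muscle-like n = 1.37 everywhere, so displacements measured inside fat are
#: overestimated by n_fat / 1.37 - 1 (the error cancels on retraction).
ADIPOSE_INDEX = 1.46


def index_mismatch_error(n_true: float, params: DopplerParams | None = None) -> float:
    """Relative displacement error from assuming ``params.tissue_index``
    in a medium whose true index is ``n_true``."""
    n_assumed = (params or DopplerParams()).tissue_index
    return abs(n_true / n_assumed - 1.0)


def integrate_position(displacement_um: np.ndarray) -> np.ndarray:
    """Cumulative tip depth after each interval (start position is zero)."""
    return np.cumsum(np.asarray(displacement_um, dtype=np.float64))


def track(tom: BinnedTomogram, params: DopplerParams) -> TipTrack:
    """Full odometry chain: gate -> causal median -> tip reference -> depth
    mean -> velocity/displacement/position."""
    series = phase_difference(tom, state=params.state)
    gated = jitter_gate(series, params.gate_rad)

    surface = params.tip_pixel + params.surface_offset_px
    j0 = params.tip_pixel - series.depth_offset_px
    j1 = surface - series.depth_offset_px + 1 + params.depth_span_px
    if j0 < 0 or j1 > series.dphi.shape[1]:
        raise ValueError("tomogram depth slice does not cover tip + averaging span")
    span = series.dphi[:, surface - series.depth_offset_px + 1: j1]
    hit_rate = float(np.mean(np.abs(span) > params.gate_rad)) if span.size else 0.0

    filt = temporal_median(gated, params.median_window)
    corr = tip_reference_correct(filt, params.tip_pixel)
    dphi_tip = depth_average(corr, surface, params.depth_span_px)

    v = to_velocity(dphi_tip, params)
    d = to_displacement(dphi_tip, params)
    p = integrate_position(d)
    return TipTrack(
        time_s=series.time_s,
        dphi_tip=dphi_tip.astype(np.float64),
        velocity_mm_s=np.asarray(v, dtype=np.float64),
        displacement_um=np.asarray(d, dtype=np.float64),
        tip_depth_um=p,
        gate_hit_rate=hit_rate,
        params=params,
    )
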