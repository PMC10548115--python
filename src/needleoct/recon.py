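"""Spectral-fringe reconstruction and spectrally binned PS-OCT polarimetry.

Fringes are apodized, Fourier transformed from wavenumber to depth, and the
positive-delay half retained.  Five half-overlapping sub-band windows laid
over the occupied source spectrum yield per-bin complex tomograms whose
polarimetric estimates are recombined by circular averaging, mitigating
polarization-mode dispersion.

Polarimetry follows the two-input-state Stokes formulation: for each
consecutive launch-state pair the pair of measured Stokes vectors at the
reference depth (the needle-tip reflection) and at depth z determine a
rotation on the Poincare sphere; its rotation angle is the cumulative
round-trip retardation (wrapped to [0, pi]) and the azimuth of its rotation
axis in the Q-U plane, halved, is the apparent optic-axis orientation in
[-90, 90) degrees.  Retardation is invariant under the static fiber-lead
unitary; the axis is reported relative to an unknown global offset.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy import ndimage

from .phantom import SystemSpec
from .simulate import SpectralSequence, _source_envelope

__all__ = [
    "BinnedTomogram",
    "PolarimetryProfiles",
    "reconstruct_tomogram",
    "compute_intensity",
    "compute_polarimetry",
    "combine_bins",
    "circular_mean_halfturn",
]

_BAND_FLOOR = 0.05    # bin layout spans envelope >= 5% of peak
_EPS = 1e-20


@dataclass
class BinnedTomogram:
    """Complex depth profiles, full-spectrum and per spectral bin.

    ``full``  (T, 2 channels, Z) for every A-line — intensity and Doppler.
    ``bins``  (n_bins, P, 2 states, 2 channels, Z) for a (possibly strided)
    subset of consecutive state pairs — polarimetry.
    """

    full: np.ndarray | None
    bins: np.ndarray | None
    state: np.ndarray
    time_s: np.ndarray
    pair_time_s: np.ndarray | None
    depth_offset_px: int
    system: SystemSpec

    @property
    def n_depth(self) -> int:
        arr = self.full if self.full is not None else self.bins
        return arr.shape[-1]


def bin_windows(system: SystemSpec, n_bins: int, window: str = "hann") -> np.ndarray:
    """Sub-band apodization windows (n_bins, K) over the occupied spectrum.

    Equal-width windows with 50% overlap spanning the band where the source
    envelope exceeds 5% of its peak; a single bin degenerates to one window
    covering that band.
    """
    K = system.k_samples
    env = _source_envelope(system)
    occ = np.nonzero(env >= _BAND_FLOOR)[0]
    lo, hi = int(occ[0]), int(occ[-1]) + 1
    band = hi - lo
    if n_bins == 1:
        centers = [lo + band / 2.0]
        width = band
    else:
        width = 2.0 * band / (n_bins + 1)
        centers = [lo + width / 2.0 + i * width / 2.0 for i in range(n_bins)]
    j = np.arange(K)
    out = np.zeros((n_bins, K))
    for i, c in enumerate(centers):
        x = (j - c) / width
        if window == "hann":
            w = np.where(np.abs(x) < 0.5, 0.5 * (1.0 + np.cos(2.0 * np.pi * x)), 0.0)
        elif window == "rect":
            w = (np.abs(x) < 0.5).astype(float)
        else:
            raise KeyError(f"unknown window {window!r}")
        out[i] = w
    return out


def reconstruct_tomogram(
    seq: SpectralSequence,
    bins: int = 5,
    window: str = "hann",
    depth_slice: tuple[int, int] | None = None,
    pair_stride: int = 1,
    keep_full: bool = True,
    chunk: int = 8192,
) -> BinnedTomogram:
    """Turn spectral fringes into complex depth profiles.

    ``depth_slice`` restricts the stored depth pixels (half-open, in depth
    bins) and ``pair_stride`` subsamples the state pairs kept for the binned
    (polarimetry) tomogram; the full-spectrum tomogram keeps every A-line.
    """
    if bins < 1:
        raise ValueError("need at least one spectral bin")
    sysspec = seq.system
    K = sysspec.k_samples
    T = seq.n_alines
    state = np.asarray(seq.state)
    if state.ndim != 1 or state.size != T:
        raise ValueError("sequence state labels missing or malformed")
    lo, hi = depth_slice if depth_slice is not None else (0, K // 2)
    if not (0 <= lo < hi <= K // 2):
        raise ValueError("bad depth_slice")
    Z = hi - lo

    full = np.empty((T, 2, Z), dtype=np.complex64) if keep_full else None

    n_pairs = T // 2
    pair_idx = np.arange(0, n_pairs, pair_stride)
    bin_w = bin_windows(sysspec, bins, window)
    bdat = np.empty((bins, pair_idx.size, 2, 2, Z), dtype=np.complex64)

    for c0 in range(0, T, chunk):
        c1 = min(c0 + chunk, T)
        fr = seq.fringes[c0:c1].astype(np.float64)
        if keep_full:
            full[c0:c1] = np.fft.fft(fr, axis=-1)[..., lo:hi].astype(np.complex64)
        # which selected pair A-lines fall in this chunk
        a_sel = np.stack([2 * pair_idx, 2 * pair_idx + 1], axis=1).ravel()
        in_chunk = (a_sel >= c0) & (a_sel < c1)
        if np.any(in_chunk):
            rows = a_sel[in_chunk] - c0
            flat_pos = np.nonzero(in_chunk)[0]
            sub = fr[rows]                       # (R, 2, K)
            p_arr, s_arr = np.divmod(flat_pos, 2)
            for b in range(bins):
                spec = np.fft.fft(sub * bin_w[b], axis=-1)[..., lo:hi]
                bdat[b, p_arr, s_arr] = spec.astype(np.complex64)

    pair_time = seq.time_s[2 * pair_idx]
    return BinnedTomogram(
        full=full,
        bins=bdat,
        state=state,
        time_s=seq.time_s,
        pair_time_s=pair_time,
        depth_offset_px=lo,
        system=sysspec,
    )


def compute_intensity(
    tom: BinnedTomogram,
    dynamic_range_db: float = 60.0,
) -> np.ndarray:
    """dB intensity image (time x depth): channel-summed squared magnitude,
    referenced to the image maximum and floored at ``-dynamic_range_db``."""
    if tom.full is None:
        raise ValueError("tomogram was built without the full-spectrum profile")
    power = np.sum(np.abs(tom.full.astype(np.complex128)) ** 2, axis=1)
    ref = float(power.max())
    if ref <= 0.0:
        return np.full(power.shape, -dynamic_range_db, dtype=np.float32)
    db = 10.0 * np.log10(np.maximum(power / ref, 10.0 ** (-dynamic_range_db / 10.0)))
    return db.astype(np.float32)


# ---------------------------------------------------------------------------
# polarimetry


def _stokes(E: np.ndarray, smooth_px: int = 0) -> np.ndarray:
    """(..., 2 channels, Z) complex fields -> (..., Z, 3) unit Stokes (Q,U,V).

    Optional axial boxcar smoothing is applied to the unnormalized Stokes
    components (intensity-weighted averaging), the standard way to beat
    polarization speckle before extracting rotations.
    """
    e1 = E[..., 0, :]
    e2 = E[..., 1, :]
    I = np.abs(e1) ** 2 + np.abs(e2) ** 2
    Q = np.abs(e1) ** 2 - np.abs(e2) ** 2
    cross = e1 * np.conj(e2)
    U = 2.0 * cross.real
    V = -2.0 * cross.imag
    s = np.stack([Q, U, V], axis=-1)
    if smooth_px and smooth_px > 1:
        s = ndimage.uniform_filter1d(s, size=smooth_px, axis=-2, mode="nearest")
        I = ndimage.uniform_filter1d(I, size=smooth_px, axis=-1, mode="nearest")
    return s / np.maximum(I, _EPS)[..., None]


def _orthonormal_triad(a: np.ndarray, b: np.ndarray) -> np.ndarray:
    """Right-handed orthonormal triad (..., 3, 3) whose columns span (a, b)."""
    u1 = a / np.maximum(np.linalg.norm(a, axis=-1, keepdims=True), _EPS)
    b_perp = b - np.sum(b * u1, axis=-1, keepdims=True) * u1
    u2 = b_perp / np.maximum(np.linalg.norm(b_perp, axis=-1, keepdims=True), _EPS)
    u3 = np.cross(u1, u2)
    return np.stack([u1, u2, u3], axis=-1)


def _observation_triad(a: np.ndarray, b: np.ndarray) -> np.ndarray:
    """Columns (a, b, a x b), unit-normalized but NOT orthogonalized.

    Keeping both measured states as-is (rather than Gram-Schmidting one
    against the other) lets the subsequent SO(3) projection distribute
    measurement inconsistency symmetrically between the launch states.
    """
    u1 = a / np.maximum(np.linalg.norm(a, axis=-1, keepdims=True), _EPS)
    u2 = b / np.maximum(np.linalg.norm(b, axis=-1, keepdims=True), _EPS)
    u3 = np.cross(u1, u2)
    u3 = u3 / np.maximum(np.linalg.norm(u3, axis=-1, keepdims=True), _EPS)
    return np.stack([u1, u2, u3], axis=-1)


def circular_mean_halfturn(angles: np.ndarray, axis: int = 0,
                           weights: np.ndarray | None = None) -> np.ndarray:
    """Circular mean of angles with period pi (doubled-angle average).

    Works for round-trip retardation in [0, pi] (radians) and for optic-axis
    orientations expressed in radians in [-pi/2, pi/2).  Returns values in
    [0, pi).
    """
    z = np.exp(2j * angles)
    if weights is not None:
        z = z * weights
    m = np.mean(z, axis=axis)
    return (np.angle(m) % (2.0 * np.pi)) / 2.0


@dataclass
class PolarimetryProfiles:
    """Per state-pair intensity / cumulative retardation / optic axis."""

    time_s: np.ndarray
    intensity_db: np.ndarray     # (P, Z)
    retardation: np.ndarray      # (P, Z) rad in [0, pi]
    axis_deg: np.ndarray         # (P, Z) deg in [-90, 90)
    mask: np.ndarray             # (P, Z) True where ret/axis are meaningful
    depth_offset_px: int
    pitch_um: float
    per_bin_retardation: np.ndarray | None = None   # (B, P, Z)
    per_bin_axis_deg: np.ndarray | None = None

    @property
    def n_pairs(self) -> int:
        return self.intensity_db.shape[0]


def combine_bins(
    per_bin_retardation: np.ndarray | None = None,
    per_bin_axis_deg: np.ndarray | None = None,
    bin_axis: int = 0,
) -> tuple[np.ndarray | None, np.ndarray | None]:
    """Combine per-bin estimates by circular mean on doubled angles.

    Single-bin input returns itself.  Retardation keeps [0, pi]; axis keeps
    [-90, 90) degrees.
    """
    ret = ax = None
    if per_bin_retardation is not None:
        r = np.asarray(per_bin_retardation)
        ret = r.take(0, axis=bin_axis) if r.shape[bin_axis] == 1 else \
            circular_mean_halfturn(r, axis=bin_axis)
    if per_bin_axis_deg is not None:
        a = np.asarray(per_bin_axis_deg)
        if a.shape[bin_axis] == 1:
            ax = a.take(0, axis=bin_axis)
        else:
            mean = circular_mean_halfturn(np.deg2rad(a), axis=bin_axis)
            ax = (np.rad2deg(mean) + 90.0) % 180.0 - 90.0
    return ret, ax


def compute_polarimetry(
    tom: BinnedTomogram,
    reference_pixel: int | None = None,
    smooth_px: int = 3,
    noise_floor_db: float = -55.0,
    mask_margin_db: float = 5.0,
    retardation_floor_rad: float = 0.05,
    keep_per_bin: bool = False,
) -> PolarimetryProfiles:
    """Stokes-rotation polarimetry referenced to the needle-tip pixel.

    Degenerate reference pairs (parallel launch states at the reference) are
    flagged in the mask rather than raised.
    """
    if tom.bins is None:
        raise ValueError("tomogram carries no spectral bins")
    sysspec = tom.system
    ref_abs = sysspec.tip_pixel if reference_pixel is None else reference_pixel
    ref = ref_abs - tom.depth_offset_px
    B, P, _, _, Z = tom.bins.shape
    if not (0 <= ref < Z):
        raise ValueError("reference pixel outside the stored depth slice")

    E = tom.bins.astype(np.complex128)
    s = _stokes(E, smooth_px=smooth_px)              # (B, P, 2, Z, 3)

    a_ref = s[:, :, 0, ref, :][:, :, None, :]         # (B, P, 1, 3)
    b_ref = s[:, :, 1, ref, :][:, :, None, :]
    degenerate = np.abs(np.sum(a_ref * b_ref, axis=-1))[..., 0] > 0.999   # (B, P)

    # balanced two-observation rotation fit: pair up (a, b, a x b) at the
    # reference and at depth, form B = sum_i t_i r_i^T, and project B onto
    # SO(3) by Lowdin symmetric orthogonalization (Newton-Schulz iterations)
    U = _orthonormal_triad(a_ref, b_ref)              # (B, P, 1, 3, 3)
    W = _observation_triad(s[:, :, 0, :, :], s[:, :, 1, :, :])   # (B, P, Z, 3, 3)
    R = W @ np.swapaxes(U, -1, -2)
    for _ in range(3):
        R = 1.5 * R - 0.5 * R @ np.swapaxes(R, -1, -2) @ R

    tr = np.trace(R, axis1=-2, axis2=-1)
    delta = np.arccos(np.clip((tr - 1.0) / 2.0, -1.0, 1.0))       # [0, pi]
    vq = R[..., 2, 1] - R[..., 1, 2]
    vu = R[..., 0, 2] - R[..., 2, 0]
    # (vq, vu) = 2 sin(delta) * rotation-axis (Q, U); azimuth needs no norm
    small = np.hypot(vq, vu) < 1e-9
    axis_deg = np.rad2deg(0.5 * np.arctan2(vu, np.where(small, 1.0, vq)))
    axis_deg = (axis_deg + 90.0) % 180.0 - 90.0

    ret, ax = combine_bins(delta, axis_deg, bin_axis=0)
    ret[:, ref] = 0.0       # retardation is defined as zero at the reference

    power = np.sum(np.abs(E) ** 2, axis=(0, 2, 3))     # (P, Z)
    pmax = max(float(power.max()), _EPS)
    intensity_db = (10.0 * np.log10(np.maximum(power / pmax,
                                               10.0 ** (noise_floor_db / 10.0)))).astype(np.float32)
    mask = (
        (intensity_db > noise_floor_db + mask_margin_db)
        & (ret > retardation_floor_rad)
        & ~np.any(degenerate, axis=0)[:, None]
    )
    return PolarimetryProfiles(
        time_s=tom.pair_time_s,
        intensity_db=intensity_db,
        retardation=ret.astype(np.float32),
        axis_deg=ax.astype(np.float32),
        mask=mask,
        depth_offset_px=tom.depth_offset_px,
        pitch_um=sysspec.axial_pitch_um,
        per_bin_retardation=delta.astype(np.float32) if keep_per_bin else None,
        per_bin_axis_deg=axis_deg.astype(np.float32) if keep_per_bin else None,
    )
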