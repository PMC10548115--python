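"""Fringe-level synthesis of swept-source PS-OCT sequences.

The phantom is a set of discrete scatterers on a layered birefringent stack.
For every A-line the simulator

* evaluates the true tip position p(t) and the optical delay of each visible
  scatterer relative to the needle tip,
* transports the alternating launch polarization through the static fiber
  lead and the round-trip tissue Jones matrix between the tip and the
  scatterer,
* imprints the exact round-trip carrier phase 4*pi*n*d / lambda_c (so the
  Doppler phase oracle is analytic), common-mode laser drift/jitter, and the
  static needle-tip reflection at a constant delay,
* and renders the two detection-channel spectral fringes over K linear-in-k
  samples under a Gaussian source envelope whose width reproduces the
  configured axial resolution.

Sign convention: insertion (p increasing, tissue approaching the probe)
advances the phase of every tissue scatterer by +4*pi*n*dp/lambda_c per
interval, so downstream Doppler processing reports insertion as positive
displacement.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .phantom import (
    MotionProfile,
    NoiseSpec,
    Phantom,
    SystemSpec,
    jones_oneway,
    jones_retarder,
    truth_polarimetry_profile,
)

__all__ = ["SpectralSequence", "GroundTruth", "synthesize_sequence", "random_fiber_jones"]

#: Launch Jones vectors: horizontal and +45 deg linear, 90 deg apart on the
#: Poincare sphere, as produced by an electro-optic modulator alternating
#: between successive sweeps.
LAUNCH_STATES = (
    np.array([1.0, 0.0], dtype=complex),
    np.array([1.0, 1.0], dtype=complex) / np.sqrt(2.0),
)

_VOID_TIP_BOOST = 5.0   # tip-reflection amplitude gain inside a void layer
_EDGE_GUARD_PX = 4      # keep scatterers clear of the aliasing edge


@dataclass
class SpectralSequence:
    """Time-ordered raw fringes: (A-lines, 2 channels, K samples)."""

    fringes: np.ndarray      # float32 (T, 2, K)
    state: np.ndarray        # uint8 (T,), launch state per A-line
    time_s: np.ndarray       # float64 (T,)
    system: SystemSpec

    @property
    def n_alines(self) -> int:
        return self.fringes.shape[0]


@dataclass
class GroundTruth:
    """Everything the simulator knows that the pipeline must recover."""

    time_s: np.ndarray           # per A-line
    tip_depth_um: np.ndarray     # true p(t) per A-line
    boundaries_um: np.ndarray    # layer tops + bottom
    depth_grid_um: np.ndarray    # depths (from surface) of the truth profiles
    retardation: np.ndarray      # ideal cumulative round-trip retardation
    axis_deg: np.ndarray         # ideal optic-axis orientation
    phantom: Phantom
    motion: MotionProfile
    system: SystemSpec


def random_fiber_jones(seed: int) -> np.ndarray:
    """Haar-ish random static unitary modeling the fiber lead birefringence."""
    rng = np.random.default_rng(seed)
    z = rng.normal(size=(2, 2)) + 1j * rng.normal(size=(2, 2))
    q, r = np.linalg.qr(z)
    return q * (np.diagonal(r) / np.abs(np.diagonal(r)))


def _source_envelope(sys: SystemSpec) -> np.ndarray:
    """Gaussian spectral envelope reproducing the configured axial resolution."""
    K = sys.k_samples
    fwhm_px = sys.resolution_air_um / (sys.tissue_index * sys.axial_pitch_um)
    a = (np.pi * fwhm_px / K) ** 2 / (2.0 * np.log(2.0))
    j = np.arange(K) - K / 2.0
    return np.exp(-a * j * j)


def _draw_scatterers(phantom: Phantom, rng: np.random.Generator):
    """Random axial reflector positions, amplitudes and phases."""
    spacing = phantom.scatterer_spacing_um
    n_est = int(phantom.total_depth_um / spacing * 2) + 16
    gaps = spacing * rng.uniform(0.5, 1.5, size=n_est)
    depth = np.cumsum(gaps)
    depth = depth[depth < phantom.total_depth_um]
    amp = rng.lognormal(mean=-0.125, sigma=0.5, size=depth.size)
    psi = rng.uniform(0.0, 2.0 * np.pi, size=depth.size)
    # layer-dependent reflectivity
    tops = phantom.boundaries_um
    layer_idx = np.clip(np.searchsorted(tops, depth, side="right") - 1, 0, len(phantom.layers) - 1)
    refl = np.array([l.reflectivity_mean for l in phantom.layers])
    amp = amp * refl[layer_idx]
    return depth, amp, psi


def _attenuation_integral(phantom: Phantom) -> tuple[np.ndarray, np.ndarray]:
    """Cumulative single-pass attenuation C(z) at layer tops (amplitude log)."""
    mu_per_um = np.array([l.attenuation_mm for l in phantom.layers]) * 1e-3
    t = np.array([l.thickness_um for l in phantom.layers])
    tops = phantom.boundaries_um
    c_tops = np.concatenate([[0.0], np.cumsum(mu_per_um * t)])
    return tops, c_tops


def _cum_attenuation(z: np.ndarray, tops: np.ndarray, c_tops: np.ndarray,
                     mu_per_um: np.ndarray) -> np.ndarray:
    idx = np.clip(np.searchsorted(tops, z, side="right") - 1, 0, len(mu_per_um) - 1)
    return c_tops[idx] + mu_per_um[idx] * (z - tops[idx])


def _oneway_at(phantom: Phantom, p: np.ndarray, wavelength_um: float) -> np.ndarray:
    """Vectorized one-way Jones matrices from the surface to depths ``p``."""
    tops = phantom.boundaries_um
    J_tops = np.empty((len(tops), 2, 2), dtype=complex)
    J_tops[0] = np.eye(2)
    for i in range(len(phantom.layers)):
        J_tops[i + 1] = jones_oneway(phantom, tops[i + 1], 0.0, wavelength_um)
    idx = np.clip(np.searchsorted(tops, p, side="right") - 1, 0, len(phantom.layers) - 1)
    dn = np.array([l.dn for l in phantom.layers])[idx]
    th = np.deg2rad(np.array([l.axis_deg for l in phantom.layers]))[idx]
    delta = 2.0 * np.pi * dn * (p - tops[idx]) / wavelength_um
    partial = jones_retarder(delta, th)                  # (T, 2, 2)
    return np.einsum("tij,tjk->tik", partial, J_tops[idx])


def synthesize_sequence(
    phantom: Phantom,
    motion: MotionProfile,
    system: SystemSpec,
    noise: NoiseSpec | None = None,
    fiber_jones: np.ndarray | None = None,
    scatterers: tuple[np.ndarray, np.ndarray] | None = None,
    chunk: int = 8192,
) -> tuple[SpectralSequence, GroundTruth]:
    """Render the full spectral fringe sequence plus its ground truth.

    Parameters
    ----------
    fiber_jones : optional static unitary applied on launch (J) and return
        (J^T); identity when omitted.
    scatterers : optional (depths_um, amplitudes) override replacing the
        random reflector draw — used for controlled single-reflector tests.
    """
    noise = noise or NoiseSpec.silent()
    lam = system.center_wavelength_um
    K = system.k_samples
    pitch = system.axial_pitch_um
    kappa = system.carrier_rad_per_um
    surf = system.surface_pixel
    vis_max_um = (system.n_depth - surf - _EDGE_GUARD_PX) * pitch
    if vis_max_um <= 0:
        raise ValueError("no tissue pixels below the surface: k_samples too small")

    n_alines = int(round(motion.total_time_s * system.sweep_rate_hz)) + 1
    time = np.arange(n_alines) / system.sweep_rate_hz
    state = (np.arange(n_alines) % 2).astype(np.uint8)
    p_t = motion.position(time)
    if p_t.max() > phantom.total_depth_um:
        raise ValueError("motion drives the tip beyond the phantom")

    rng_ph = np.random.default_rng(phantom.seed)
    if scatterers is None:
        D, amp0, psi = _draw_scatterers(phantom, rng_ph)
    else:
        D = np.asarray(scatterers[0], dtype=float)
        amp0 = np.asarray(scatterers[1], dtype=float)
        psi = np.zeros_like(D)
    order = np.argsort(D)
    D, amp0, psi = D[order], amp0[order], psi[order]

    # per-scatterer one-way Jones from the surface, and attenuation integral
    J_D = _oneway_at(phantom, D, lam)
    mu_per_um = np.array([l.attenuation_mm for l in phantom.layers]) * 1e-3
    tops, c_tops = _attenuation_integral(phantom)
    C_D = _cum_attenuation(D, tops, c_tops, mu_per_um)

    Jf = np.eye(2, dtype=complex) if fiber_jones is None else np.asarray(fiber_jones, complex)
    launch = [Jf @ e for e in LAUNCH_STATES]                # at the sample
    tip_field = [Jf.T @ Jf @ e for e in LAUNCH_STATES]      # mirror at the tip

    # common-mode laser phase
    rng_n = np.random.default_rng(noise.seed)
    phi_c = noise.drift_rad_per_s * time
    if noise.jitter_prob > 0.0:
        hit = rng_n.random(n_alines) < noise.jitter_prob
        sign = np.where(rng_n.random(n_alines) < 0.5, -1.0, 1.0)
        phi_c = phi_c + hit * sign * noise.jitter_magnitude_rad

    # void occupancy of the tip (boosted interface reflection)
    layer_is_void = np.array([l.is_void for l in phantom.layers])
    tip_layer = np.clip(np.searchsorted(phantom.boundaries_um, p_t, side="right") - 1,
                        0, len(phantom.layers) - 1)
    tip_amp_t = system.tip_reflect_amp * np.where(layer_is_void[tip_layer], _VOID_TIP_BOOST, 1.0)

    env = _source_envelope(system)
    alt_sign = np.where(np.arange(K) % 2 == 0, 1.0, -1.0)   # centers k index on K/2
    fringes = np.empty((n_alines, 2, K), dtype=np.float32)
    noise_scale = None

    def build_B(p: np.ndarray, st: np.ndarray, phi: np.ndarray,
                tip_amp: np.ndarray) -> np.ndarray:
        """Complex depth-domain spectra (len(p), 2 channels, K) for given tip
        positions, launch states, and common-mode phases."""
        T = len(p)
        # scatterers that can be visible anywhere in this block
        s_lo = np.searchsorted(D, p.min() - 1.0)
        s_hi = np.searchsorted(D, p.max() + vis_max_um + 1.0)
        B = np.zeros((T, 2, K), dtype=complex)

        if s_hi > s_lo:
            Ds, amps, psis = D[s_lo:s_hi], amp0[s_lo:s_hi], psi[s_lo:s_hi]
            JDs, CDs = J_D[s_lo:s_hi], C_D[s_lo:s_hi]
            d = Ds[None, :] - p[:, None]                     # depth below tip
            visible = (d >= 0.0) & (d <= vis_max_um)
            m_pix = surf + np.rint(d / pitch).astype(np.int64)

            Jp = _oneway_at(phantom, p, lam)                 # (T, 2, 2)
            Jp_inv = np.conj(np.swapaxes(Jp, -1, -2))        # unitary inverse
            Jseg = np.einsum("sij,tjk->tsik", JDs, Jp_inv)
            M = np.einsum("tsji,tsjk->tsik", Jseg, Jseg)     # J^T J round trip

            C_p = _cum_attenuation(p, tops, c_tops, mu_per_um)
            att = np.exp(-(CDs[None, :] - C_p[:, None]))
            roll = 1.0 / np.sqrt(1.0 + (d / system.rolloff_um) ** 2)
            theta = psis[None, :] - kappa * d + phi[:, None]
            contrib = np.where(visible, amps[None, :] * att * roll, 0.0) * np.exp(1j * theta)

            for launch_state in (0, 1):
                rows = np.nonzero(st == launch_state)[0]
                if rows.size == 0:
                    continue
                v = np.einsum("ac,tsab,b->tsc", Jf, M[rows], launch[launch_state])
                vals = contrib[rows][:, :, None] * v          # (t, s, channel)
                t_i = np.broadcast_to(rows[:, None, None], vals.shape)
                c_i = np.broadcast_to(np.arange(2)[None, None, :], vals.shape)
                m_i = np.broadcast_to(m_pix[rows][:, :, None], vals.shape)
                ok = np.broadcast_to(visible[rows][:, :, None], vals.shape)
                flat = ((t_i * 2 + c_i) * K + m_i)[ok]
                vv = vals[ok]
                acc = (np.bincount(flat, weights=vv.real, minlength=T * 2 * K)
                       + 1j * np.bincount(flat, weights=vv.imag, minlength=T * 2 * K))
                B += acc.reshape(T, 2, K)

        # static needle-tip reflection (common-mode phase only)
        tip_phase = np.exp(1j * phi)
        for launch_state in (0, 1):
            rows = st == launch_state
            for c in (0, 1):
                B[rows, c, system.tip_pixel] += (
                    tip_amp[rows] * tip_phase[rows] * tip_field[launch_state][c]
                )
        return B

    for lo in range(0, n_alines, chunk):
        hi = min(lo + chunk, n_alines)
        p = p_t[lo:hi]
        if np.ptp(p) == 0.0:
            # stationary block: the tissue/tip spectrum is static, only the
            # common-mode phase rotates it
            base = build_B(p[:1].repeat(2), np.array([0, 1], dtype=np.uint8),
                           np.zeros(2), tip_amp_t[lo:hi][:1].repeat(2))
            B = np.exp(1j * phi_c[lo:hi])[:, None, None] * base[state[lo:hi]]
        else:
            B = build_B(p, state[lo:hi], phi_c[lo:hi], tip_amp_t[lo:hi])

        analytic = np.fft.ifft(B * alt_sign, axis=-1) * K
        fr = env * analytic.real
        if noise_scale is None:
            # detector noise is scaled to the tissue signal (the static tip
            # reflection dominates the raw fringe and must not set the SNR)
            Bt = B.copy()
            Bt[:, :, system.tip_pixel] = 0.0
            tissue_power = float(np.mean(np.sum(np.abs(Bt) ** 2, axis=-1)))
            noise_scale = max(
                np.sqrt(0.5 * tissue_power * float(np.mean(env**2))), 1e-12
            )
        if noise.detector_noise_rel > 0.0:
            fr = fr + rng_n.normal(scale=noise.detector_noise_rel * noise_scale,
                                   size=fr.shape)
        fringes[lo:hi] = fr.astype(np.float32)

    seq = SpectralSequence(fringes=fringes, state=state, time_s=time, system=system)

    grid = np.arange(surf, system.n_depth) * pitch - surf * pitch
    ret, ax = truth_polarimetry_profile(phantom, grid, lam)
    truth = GroundTruth(
        time_s=time,
        tip_depth_um=p_t,
        boundaries_um=phantom.boundaries_um,
        depth_grid_um=grid,
        retardation=ret,
        axis_deg=ax,
        phantom=phantom,
        motion=motion,
        system=system,
    )
    return seq, truth
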