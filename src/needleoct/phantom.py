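"""Ground-truth phantoms, probe/system description, and needle motion traces.

The simulator works on layered birefringent phantoms built from discrete
scatterers.  Each layer is a homogeneous linear retarder characterised by a
birefringence ``dn`` and an in-plane optic-axis orientation; polarization
transport through a stack of layers is described by 2x2 Jones matrices, which
double as the exact oracle for the polarimetric reconstruction stage.

Length unit is micrometres throughout unless a name says otherwise; times are
seconds; angles are radians unless a name carries ``_deg``.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from typing import Sequence

import numpy as np

__all__ = [
    "LayerSpec",
    "Phantom",
    "SystemSpec",
    "MotionProfile",
    "NoiseSpec",
    "build_phantom",
    "make_motion",
    "jones_retarder",
    "jones_oneway",
    "jones_roundtrip",
    "retardation_axis_from_roundtrip",
    "GATE_SPEED_UM_S",
]

#: Axial speed (um/s) corresponding to the 2.5 rad phase-jitter gate at the
#: default system parameters; true phantom motion must stay below it so that
#: real motion is never classified as laser jitter.
GATE_SPEED_UM_S = 4.7e3


@dataclass(frozen=True)
class LayerSpec:
    """One homogeneous tissue layer.

    Parameters
    ----------
    thickness_um : float
        Axial extent of the layer (> 0).
    reflectivity_mean : float
        Mean scatterer amplitude (arbitrary units, >= 0).  Near zero for
        optically empty spaces.
    attenuation_mm : float
        Intensity attenuation coefficient (mm^-1, >= 0); applied as a
        single-pass amplitude factor exp(-mu * z), i.e. round-trip intensity
        exp(-2 mu z).
    dn : float
        Birefringence (refractive-index split between slow and fast axis).
    axis_deg : float
        Optic-axis orientation in [-90, 90); ignored when ``dn`` is 0.
    is_void : bool
        Low-scattering space with a strong entry-interface reflection at the
        probe tip (models an epidural space).
    """

    thickness_um: float
    reflectivity_mean: float = 1.0
    attenuation_mm: float = 1.0
    dn: float = 0.0
    axis_deg: float = 0.0
    is_void: bool = False

    def __post_init__(self) -> None:
        if self.thickness_um <= 0:
            raise ValueError("layer thickness must be > 0")
        if self.reflectivity_mean < 0 or self.attenuation_mm < 0 or self.dn < 0:
            raise ValueError("reflectivity, attenuation and dn must be >= 0")
        if not (-90.0 <= self.axis_deg < 90.0):
            raise ValueError("axis_deg must lie in [-90, 90)")


@dataclass(frozen=True)
class Phantom:
    """Ordered layer stack (surface first) plus scatterer statistics."""

    layers: tuple[LayerSpec, ...]
    scatterer_spacing_um: float = 10.0
    seed: int = 0
    name: str = "custom"

    def __post_init__(self) -> None:
        if not self.layers:
            raise ValueError("phantom needs at least one layer")
        if self.scatterer_spacing_um <= 0:
            raise ValueError("scatterer spacing must be > 0")

    @property
    def total_depth_um(self) -> float:
        return float(sum(l.thickness_um for l in self.layers))

    @property
    def boundaries_um(self) -> np.ndarray:
        """Depths of layer tops, surface (0) included, plus the bottom."""
        t = np.array([l.thickness_um for l in self.layers])
        return np.concatenate([[0.0], np.cumsum(t)])

    def layer_at(self, depth_um: float) -> LayerSpec:
        b = self.boundaries_um
        if depth_um < 0 or depth_um > b[-1]:
            raise ValueError(f"depth {depth_um} outside phantom [0, {b[-1]}]")
        idx = int(np.searchsorted(b, depth_um, side="right")) - 1
        idx = min(idx, len(self.layers) - 1)
        return self.layers[idx]


@dataclass(frozen=True)
class SystemSpec:
    """Swept-source PS-OCT system and probe geometry.

    The probe is forward-viewing and unscanned: a single depth axis, with the
    static fiber-end (needle tip) reflection at ``tip_pixel`` and the tissue
    contact surface ``tip_standoff_px`` pixels deeper (the fiber end sits
    slightly recessed behind a thin epoxy window).
    """

    center_wavelength_um: float = 1.310
    k_samples: int = 1024
    sweep_rate_hz: float = 50e3
    state_period_s: float = 40e-6        # between same-launch-state A-lines
    tissue_range_um: float = 4700.0
    axial_pitch_um: float = 1.87         # depth pixel pitch in tissue
    tissue_index: float = 1.37
    tip_pixel: int = 30
    tip_standoff_px: int = 8
    resolution_air_um: float = 10.6      # axial resolution (intensity FWHM, air)
    tip_reflect_amp: float = 30.0        # fiber-end reflection amplitude
    rolloff_um: float = 1500.0           # diverging-beam amplitude roll-off scale

    def __post_init__(self) -> None:
        if self.k_samples < 8 or self.k_samples % 2:
            raise ValueError("k_samples must be even and >= 8")
        if abs(self.state_period_s * self.sweep_rate_hz - 2.0) > 1e-9:
            raise ValueError(
                "state_period_s must equal 2 / sweep_rate_hz for strictly "
                "alternating launch states"
            )
        if not (0 <= self.tip_pixel < self.n_depth):
            raise ValueError("tip_pixel outside the depth axis")
        if self.tip_standoff_px < 0:
            raise ValueError("tip_standoff_px must be >= 0")

    @property
    def n_depth(self) -> int:
        return self.k_samples // 2

    @property
    def surface_pixel(self) -> int:
        """Depth pixel of the tissue contact surface at the needle tip."""
        return self.tip_pixel + self.tip_standoff_px

    @property
    def visible_tissue_um(self) -> float:
        """Tissue depth span imaged below the contact surface."""
        return (self.n_depth - self.surface_pixel) * self.axial_pitch_um

    @property
    def aline_period_s(self) -> float:
        return 1.0 / self.sweep_rate_hz

    @property
    def carrier_rad_per_um(self) -> float:
        """Round-trip phase per unit physical depth: 4 pi n / lambda_c."""
        return 4.0 * np.pi * self.tissue_index / self.center_wavelength_um


@dataclass(frozen=True)
class MotionProfile:
    """Piecewise-linear true tip position p(t) relative to the tissue surface."""

    times_s: np.ndarray
    depths_um: np.ndarray
    max_speed_um_s: float = GATE_SPEED_UM_S

    def __post_init__(self) -> None:
        t = np.asarray(self.times_s, dtype=float)
        p = np.asarray(self.depths_um, dtype=float)
        if t.ndim != 1 or t.shape != p.shape or t.size < 2:
            raise ValueError("need matching 1-d arrays of >= 2 breakpoints")
        if np.any(np.diff(t) <= 0):
            raise ValueError("breakpoint times must be strictly increasing")
        speeds = np.abs(np.diff(p) / np.diff(t))
        if np.any(speeds >= self.max_speed_um_s):
            raise ValueError(
                f"peak speed {speeds.max():.1f} um/s reaches the "
                f"{self.max_speed_um_s:.0f} um/s jitter-gate limit; true "
                "motion must stay below it"
            )
        object.__setattr__(self, "times_s", t)
        object.__setattr__(self, "depths_um", p)

    @property
    def total_time_s(self) -> float:
        return float(self.times_s[-1])

    def position(self, t: np.ndarray | float) -> np.ndarray:
        """Tip depth p(t) in um (clamped to the end values outside range)."""
        return np.interp(t, self.times_s, self.depths_um)


@dataclass(frozen=True)
class NoiseSpec:
    """Detector noise plus common-mode laser phase defects."""

    detector_noise_rel: float = 0.02
    jitter_prob: float = 0.01
    jitter_magnitude_rad: float = 3.0
    drift_rad_per_s: float = 0.5
    seed: int = 0

    def __post_init__(self) -> None:
        if min(self.detector_noise_rel, self.jitter_magnitude_rad) < 0:
            raise ValueError("noise magnitudes must be >= 0")
        if not 0.0 <= self.jitter_prob <= 1.0:
            raise ValueError("jitter_prob must be a probability")
        if self.drift_rad_per_s < 0:
            raise ValueError("drift rate must be >= 0")

    @classmethod
    def silent(cls) -> "NoiseSpec":
        return cls(detector_noise_rel=0.0, jitter_prob=0.0, drift_rad_per_s=0.0)


# ---------------------------------------------------------------------------
# Phantom presets


def build_phantom(
    preset_name: str,
    seed: int = 0,
    layers: Sequence[LayerSpec] | None = None,
    scatterer_spacing_um: float = 10.0,
) -> Phantom:
    """Build one of the experimental archetype phantoms.

    ``salmon``  alternating birefringent muscle / non-birefringent connective
                tissue, five muscle + four connective layers;
    ``shrimp``  three equally birefringent muscle layers whose optic-axis
                orientations differ;
    ``spine``   skin / subcutaneous fat / three ligament layers terminating in
                a low-scattering void with a strong tip-interface reflection;
    ``custom``  caller-supplied ``layers``.
    """
    if preset_name == "salmon":
        muscle = LayerSpec(700.0, 1.0, 1.2, dn=1.0e-3, axis_deg=30.0)
        fat = LayerSpec(450.0, 0.7, 2.0, dn=0.0)
        stack: list[LayerSpec] = []
        for i in range(9):
            stack.append(muscle if i % 2 == 0 else fat)
    elif preset_name == "shrimp":
        stack = [
            LayerSpec(1600.0, 1.0, 1.2, dn=1.0e-3, axis_deg=-50.0),
            LayerSpec(1600.0, 1.0, 1.2, dn=1.0e-3, axis_deg=0.0),
            LayerSpec(1600.0, 1.0, 1.2, dn=1.0e-3, axis_deg=50.0),
        ]
    elif preset_name == "spine":
        stack = [
            LayerSpec(800.0, 1.0, 1.5, dn=3.0e-4, axis_deg=10.0),      # skin
            LayerSpec(1200.0, 0.6, 2.5, dn=0.0),                        # fat
            LayerSpec(600.0, 1.0, 1.2, dn=1.5e-3, axis_deg=40.0),       # ligament
            LayerSpec(600.0, 1.0, 1.2, dn=1.5e-3, axis_deg=40.0),
            LayerSpec(700.0, 1.0, 1.2, dn=1.5e-3, axis_deg=40.0),
            LayerSpec(1100.0, 0.02, 0.1, dn=0.0, is_void=True),         # epidural
        ]
    elif preset_name == "custom":
        if layers is None:
            raise ValueError("preset 'custom' requires explicit layers")
        stack = list(layers)
    else:
        raise KeyError(f"unknown phantom preset {preset_name!r}")
    return Phantom(
        layers=tuple(stack),
        scatterer_spacing_um=scatterer_spacing_um,
        seed=seed,
        name=preset_name,
    )


# ---------------------------------------------------------------------------
# Motion


def make_motion(
    style: str,
    total_time_s: float,
    max_depth_um: float,
    breakpoints: Sequence[tuple[float, float]] | None = None,
    max_speed_um_s: float = GATE_SPEED_UM_S,
) -> MotionProfile:
    """Build a needle motion trace.

    ``triangle``: symmetric insertion to ``max_depth_um`` at half time, then
    retraction back to the surface.  ``custom``: explicit (time, depth)
    breakpoints.
    """
    if total_time_s <= 0:
        raise ValueError("total_time_s must be > 0")
    if max_depth_um < 0:
        raise ValueError("max_depth_um must be >= 0")
    if style == "triangle":
        t = np.array([0.0, total_time_s / 2.0, total_time_s])
        p = np.array([0.0, float(max_depth_um), 0.0])
    elif style == "custom":
        if not breakpoints:
            raise ValueError("style 'custom' requires breakpoints")
        arr = np.asarray(breakpoints, dtype=float)
        t, p = arr[:, 0], arr[:, 1]
    else:
        raise KeyError(f"unknown motion style {style!r}")
    return MotionProfile(t, p, max_speed_um_s=max_speed_um_s)


# ---------------------------------------------------------------------------
# Jones-matrix transport (the polarimetry oracle)


def jones_retarder(delta_rad: float | np.ndarray, axis_rad: float | np.ndarray) -> np.ndarray:
    """Jones matrix of a linear retarder: retardance ``delta``, axis ``theta``.

    J = R(theta) diag(e^{-i d/2}, e^{+i d/2}) R(-theta).  Broadcasts over
    array inputs; returns shape (..., 2, 2).
    """
    d = np.asarray(delta_rad, dtype=float)
    th = np.asarray(axis_rad, dtype=float)
    c, s = np.cos(d / 2.0), np.sin(d / 2.0)
    c2, s2 = np.cos(2.0 * th), np.sin(2.0 * th)
    out = np.empty(np.broadcast_shapes(d.shape, th.shape) + (2, 2), dtype=complex)
    out[..., 0, 0] = c - 1j * s * c2
    out[..., 0, 1] = -1j * s * s2
    out[..., 1, 0] = -1j * s * s2
    out[..., 1, 1] = c + 1j * s * c2
    return out


def _segments(phantom: Phantom, z0: float, z1: float) -> list[tuple[float, LayerSpec]]:
    """Layer segments (length, layer) crossed between depths z0 < z1."""
    segs: list[tuple[float, LayerSpec]] = []
    tops = phantom.boundaries_um
    for i, layer in enumerate(phantom.layers):
        lo = max(z0, tops[i])
        hi = min(z1, tops[i + 1])
        if hi > lo:
            segs.append((hi - lo, layer))
    return segs


def jones_oneway(
    phantom: Phantom, z1_um: float, z0_um: float = 0.0,
    wavelength_um: float = 1.310,
) -> np.ndarray:
    """Single-pass Jones matrix for propagation from depth z0 to z1.

    One-way matrices compose multiplicatively along the path, so the segment
    between two depths is ``jones_oneway(0, z1) @ inv(jones_oneway(0, z0))``
    — used by the simulator to move the reference plane with the needle tip.
    """
    if z0_um > z1_um:
        raise ValueError("need z0 <= z1")
    if z0_um < 0 or z1_um > phantom.total_depth_um:
        raise ValueError("depth outside phantom")
    J = np.eye(2, dtype=complex)
    for length, layer in _segments(phantom, z0_um, z1_um):
        if layer.dn == 0.0:
            continue
        delta = 2.0 * np.pi * layer.dn * length / wavelength_um
        J = jones_retarder(delta, np.deg2rad(layer.axis_deg)) @ J
    return J


def jones_roundtrip(
    phantom: Phantom, depth_um: float, wavelength_um: float = 1.310,
    from_um: float = 0.0,
) -> np.ndarray:
    """Cumulative round-trip Jones matrix from ``from_um`` down to ``depth_um``.

    Reciprocity of the double pass makes the result transpose-symmetric:
    M = J^T J for the one-way matrix J.
    """
    J = jones_oneway(phantom, depth_um, from_um, wavelength_um)
    return J.T @ J


def retardation_axis_from_roundtrip(M: np.ndarray) -> tuple[float, float]:
    """Extract (round-trip retardance in [0, pi], axis angle in [-90, 90) deg).

    Writes the unitary as exp(-i d/2 n.sigma); the retardance is the SU(2)
    rotation angle wrapped to [0, pi], the axis is the azimuth of the
    rotation axis in the Q-U plane, halved to a physical orientation.
    """
    U = np.asarray(M, dtype=complex)
    det = np.linalg.det(U)
    U = U / np.sqrt(det)
    # U = c I - i s (n1 sz' + n2 sx'), linear retarder has no circular part
    c = np.real(U[0, 0] + U[1, 1]) / 2.0
    n1s = -np.imag(U[0, 0] - U[1, 1]) / 2.0   # s * cos(2 theta)
    n2s = -np.imag(U[0, 1] + U[1, 0]) / 2.0   # s * sin(2 theta)
    s = np.hypot(n1s, n2s)
    delta = 2.0 * np.arctan2(s, c)
    if delta > np.pi:  # wrap rotation angle into [0, pi]
        delta = 2.0 * np.pi - delta
        n1s, n2s = -n1s, -n2s
    if s < 1e-12:
        return float(delta), 0.0
    axis_deg = np.rad2deg(0.5 * np.arctan2(n2s, n1s))
    axis_deg = (axis_deg + 90.0) % 180.0 - 90.0
    return float(delta), float(axis_deg)


def truth_polarimetry_profile(
    phantom: Phantom,
    depths_um: np.ndarray,
    wavelength_um: float = 1.310,
    from_um: float = 0.0,
) -> tuple[np.ndarray, np.ndarray]:
    """Ideal cumulative (retardation, axis_deg) at the given depths."""
    ret = np.empty(len(depths_um))
    ax = np.empty(len(depths_um))
    for i, z in enumerate(depths_um):
        M = jones_roundtrip(phantom, float(z), wavelength_um, from_um)
        ret[i], ax[i] = retardation_axis_from_roundtrip(M)
    return ret, ax
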