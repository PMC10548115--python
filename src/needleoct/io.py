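"""HDF5 containers, TOML run configuration, and CSV export.

One HDF5 file carries a raw sequence: ``/fringes`` (A-lines x channels x k
samples), ``/state``, ``/time``, the ground truth under ``/truth`` when the
sequence came from the simulator, and the system parameters as root
attributes.  Profiles and tracks get their own small files.
"""

from __future__ import annotations

import csv
import dataclasses
import os
import tomllib
from dataclasses import dataclass, field
from typing import Any

import h5py
import numpy as np

from .doppler import DopplerParams, TipTrack
from .phantom import (
    LayerSpec,
    MotionProfile,
    NoiseSpec,
    Phantom,
    SystemSpec,
    build_phantom,
    make_motion,
)
from .recon import PolarimetryProfiles
from .simulate import GroundTruth, SpectralSequence

__all__ = [
    "write_sequence",
    "read_sequence",
    "write_profiles",
    "read_profiles",
    "write_track",
    "read_track",
    "write_track_csv",
    "RunConfig",
    "load_config",
]


def _system_to_attrs(sys: SystemSpec, attrs) -> None:
    for f in dataclasses.fields(sys):
        attrs[f.name] = getattr(sys, f.name)


def _system_from_attrs(attrs) -> SystemSpec:
    names = {f.name for f in dataclasses.fields(SystemSpec)}
    kw = {k: (int(v) if isinstance(v, np.integer) else float(v))
          for k, v in attrs.items() if k in names}
    for int_field in ("k_samples", "tip_pixel", "tip_standoff_px"):
        if int_field in kw:
            kw[int_field] = int(kw[int_field])
    return SystemSpec(**kw)


def write_sequence(path: str | os.PathLike, seq: SpectralSequence,
                   truth: GroundTruth | None = None) -> None:
    with h5py.File(path, "w") as h5:
        h5.create_dataset("fringes", data=seq.fringes, compression="gzip", shuffle=True)
        h5.create_dataset("state", data=seq.state)
        h5.create_dataset("time", data=seq.time_s)
        _system_to_attrs(seq.system, h5.attrs)
        if truth is not None:
            g = h5.create_group("truth")
            g.create_dataset("tip_depth", data=truth.tip_depth_um)
            g.create_dataset("retardation", data=truth.retardation)
            g.create_dataset("axis", data=truth.axis_deg)
            g.create_dataset("depth_grid", data=truth.depth_grid_um)
            g.create_dataset("boundaries", data=truth.boundaries_um)
            g.create_dataset("motion_breakpoints",
                             data=np.stack([truth.motion.times_s,
                                            truth.motion.depths_um], axis=1))
            layers = np.array(
                [(l.thickness_um, l.reflectivity_mean, l.attenuation_mm,
                  l.dn, l.axis_deg, float(l.is_void))
                 for l in truth.phantom.layers])
            g.create_dataset("layers", data=layers)
            g.attrs["phantom_name"] = truth.phantom.name
            g.attrs["phantom_seed"] = truth.phantom.seed
            g.attrs["scatterer_spacing_um"] = truth.phantom.scatterer_spacing_um


def read_sequence(path: str | os.PathLike) -> tuple[SpectralSequence, GroundTruth | None]:
    with h5py.File(path, "r") as h5:
        system = _system_from_attrs(h5.attrs)
        seq = SpectralSequence(
            fringes=h5["fringes"][...],
            state=h5["state"][...].astype(np.uint8),
            time_s=h5["time"][...],
            system=system,
        )
        truth = None
        if "truth" in h5:
            g = h5["truth"]
            layers = tuple(
                LayerSpec(row[0], row[1], row[2], row[3], row[4], bool(row[5]))
                for row in g["layers"][...]
            )
            phantom = Phantom(
                layers=layers,
                scatterer_spacing_um=float(g.attrs["scatterer_spacing_um"]),
                seed=int(g.attrs["phantom_seed"]),
                name=str(g.attrs["phantom_name"]),
            )
            bp = g["motion_breakpoints"][...]
            motion = MotionProfile(bp[:, 0], bp[:, 1])
            truth = GroundTruth(
                time_s=seq.time_s,
                tip_depth_um=g["tip_depth"][...],
                boundaries_um=g["boundaries"][...],
                depth_grid_um=g["depth_grid"][...],
                retardation=g["retardation"][...],
                axis_deg=g["axis"][...],
                phantom=phantom,
                motion=motion,
                system=system,
            )
    return seq, truth


def write_profiles(path: str | os.PathLike, profiles: PolarimetryProfiles) -> None:
    with h5py.File(path, "w") as h5:
        h5.create_dataset("intensity_db", data=profiles.intensity_db)
        h5.create_dataset("retardation", data=profiles.retardation)
        h5.create_dataset("axis_deg", data=profiles.axis_deg)
        h5.create_dataset("mask", data=profiles.mask)
        h5.create_dataset("time", data=profiles.time_s)
        h5.attrs["depth_offset_px"] = profiles.depth_offset_px
        h5.attrs["pitch_um"] = profiles.pitch_um


def read_profiles(path: str | os.PathLike) -> PolarimetryProfiles:
    with h5py.File(path, "r") as h5:
        return PolarimetryProfiles(
            time_s=h5["time"][...],
            intensity_db=h5["intensity_db"][...],
            retardation=h5["retardation"][...],
            axis_deg=h5["axis_deg"][...],
            mask=h5["mask"][...].astype(bool),
            depth_offset_px=int(h5.attrs["depth_offset_px"]),
            pitch_um=float(h5.attrs["pitch_um"]),
        )


def write_track(path: str | os.PathLike, track: TipTrack) -> None:
    with h5py.File(path, "w") as h5:
        h5.create_dataset("dphi_tip", data=track.dphi_tip)
        h5.create_dataset("velocity_mm_s", data=track.velocity_mm_s)
        h5.create_dataset("displacement_um", data=track.displacement_um)
        h5.create_dataset("tip_depth_um", data=track.tip_depth_um)
        h5.create_dataset("time_s", data=track.time_s)
        h5.attrs["gate_hit_rate"] = track.gate_hit_rate


def read_track(path: str | os.PathLike) -> TipTrack:
    with h5py.File(path, "r") as h5:
        return TipTrack(
            time_s=h5["time_s"][...],
            dphi_tip=h5["dphi_tip"][...],
            velocity_mm_s=h5["velocity_mm_s"][...],
            displacement_um=h5["displacement_um"][...],
            tip_depth_um=h5["tip_depth_um"][...],
            gate_hit_rate=float(h5.attrs.get("gate_hit_rate", 0.0)),
        )


def write_track_csv(path: str | os.PathLike, track: TipTrack) -> None:
    with open(path, "w", newline="") as fh:
        w = csv.writer(fh)
        w.writerow(["time_s", "dphi_tip_rad", "velocity_mm_s",
                    "displacement_um", "tip_depth_um"])
        for row in zip(track.time_s, track.dphi_tip, track.velocity_mm_s,
                       track.displacement_um, track.tip_depth_um):
            w.writerow([f"{x:.9g}" for x in row])


# ---------------------------------------------------------------------------
# Run configuration


@dataclass
class RunConfig:
    """Everything one simulated guidance run needs, TOML-expressible."""

    preset: str = "salmon"
    seed: int = 0
    total_time_s: float = 4.0
    max_depth_um: float = 4800.0
    motion_style: str = "triangle"
    motion_breakpoints: list | None = None
    bins: int = 5
    pair_stride: int = 8
    frame_stride: int = 50
    render_contrast: str = "retardation"
    system: dict = field(default_factory=dict)
    noise: dict = field(default_factory=dict)
    fiber_seed: int | None = None
    sequence_path: str = "sequence.h5"
    profiles_path: str = "profiles.h5"
    track_path: str = "track.h5"
    frames_dir: str = "frames"
    verbosity: int = 1

    def build_system(self) -> SystemSpec:
        return SystemSpec(**self.system)

    def build_noise(self) -> NoiseSpec:
        kw = dict(self.noise)
        kw.setdefault("seed", self.seed + 1)
        return NoiseSpec(**kw)

    def build_phantom(self) -> Phantom:
        return build_phantom(self.preset, seed=self.seed)

    def build_motion(self) -> MotionProfile:
        return make_motion(self.motion_style, self.total_time_s,
                           self.max_depth_um, breakpoints=self.motion_breakpoints)

    def build_doppler(self) -> DopplerParams:
        return DopplerParams.from_system(self.build_system())


def load_config(path: str | os.PathLike, **overrides: Any) -> RunConfig:
    with open(path, "rb") as fh:
        raw = tomllib.load(fh)
    raw.update(overrides)
    names = {f.name for f in dataclasses.fields(RunConfig)}
    unknown = set(raw) - names
    if unknown:
        raise ValueError(f"unknown config fields: {sorted(unknown)}")
    return RunConfig(**raw)
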