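"""End-to-end orchestration: simulate -> reconstruct -> track -> map -> render.

Each stage consumes the previous stage's in-memory product; the CLI persists
the intermediate artifacts between subcommands, the examples and tests call
these functions directly.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .analysis import insertion_window
from .doppler import DopplerParams, TipTrack, track as run_track
from .mapping import (
    NeedleReferencedMap,
    RenderStyle,
    SurfaceCanvas,
    build_surface_canvas,
    needle_referenced_map,
    render_frame,
)
from .recon import (
    BinnedTomogram,
    PolarimetryProfiles,
    compute_polarimetry,
    reconstruct_tomogram,
)
from .io import RunConfig
from .simulate import GroundTruth, SpectralSequence, random_fiber_jones, synthesize_sequence

__all__ = ["RunResult", "simulate_stage", "reconstruct_stage", "track_stage",
           "render_stage", "run_pipeline", "compare_with_truth"]


@dataclass
class RunResult:
    sequence: SpectralSequence | None = None
    truth: GroundTruth | None = None
    tomogram: BinnedTomogram | None = None
    profiles: PolarimetryProfiles | None = None
    track: TipTrack | None = None
    needle_map: NeedleReferencedMap | None = None
    canvas: SurfaceCanvas | None = None
    frames: list | None = None
    metrics: dict | None = None


def simulate_stage(config: RunConfig) -> tuple[SpectralSequence, GroundTruth]:
    system = config.build_system()
    phantom = config.build_phantom()
    motion = config.build_motion()
    noise = config.build_noise()
    fiber = None if config.fiber_seed is None else random_fiber_jones(config.fiber_seed)
    return synthesize_sequence(phantom, motion, system, noise, fiber_jones=fiber)


def reconstruct_stage(seq: SpectralSequence, config: RunConfig) -> tuple[BinnedTomogram, PolarimetryProfiles]:
    tom = reconstruct_tomogram(seq, bins=config.bins, pair_stride=config.pair_stride)
    profiles = compute_polarimetry(tom)
    return tom, profiles


def track_stage(tom: BinnedTomogram, config: RunConfig) -> TipTrack:
    return run_track(tom, config.build_doppler())


def render_stage(profiles: PolarimetryProfiles, tip: TipTrack, config: RunConfig) -> tuple[SurfaceCanvas, list]:
    system = config.build_system()
    canvas = build_surface_canvas(profiles, tip, surface_pixel=system.surface_pixel)
    idx = list(range(0, len(canvas.time_s), max(1, config.frame_stride)))
    if idx and idx[-1] != len(canvas.time_s) - 1:
        idx.append(len(canvas.time_s) - 1)
    style = RenderStyle()
    frames = [render_frame(canvas, i, config.render_contrast, style) for i in idx]
    return canvas, frames


def run_pipeline(config: RunConfig, stop_after: str | None = None) -> RunResult:
    """Run all stages (or up to ``stop_after`` in
    {'simulate','reconstruct','track','render'})."""
    res = RunResult()
    res.sequence, res.truth = simulate_stage(config)
    if stop_after == "simulate":
        return res
    res.tomogram, res.profiles = reconstruct_stage(res.sequence, config)
    res.needle_map = needle_referenced_map(res.profiles)
    if stop_after == "reconstruct":
        return res
    res.track = track_stage(res.tomogram, config)
    res.metrics = compare_with_truth(res.track, res.truth)
    if stop_after == "track":
        return res
    res.canvas, res.frames = render_stage(res.profiles, res.track, config)
    return res


def compare_with_truth(tip: TipTrack, truth: GroundTruth | None) -> dict:
    """Tracking-quality metrics against simulator ground truth.

    RMSE and final-position error of the integrated tip depth, the recovered
    depth at each true layer-boundary crossing, and the peak depth.
    """
    out: dict = {
        "peak_depth_um": float(np.max(tip.tip_depth_um)),
        "final_position_um": float(tip.tip_depth_um[-1]),
        "gate_hit_rate": tip.gate_hit_rate,
    }
    if truth is None:
        return out
    p_true = np.interp(tip.time_s, truth.time_s, truth.tip_depth_um)
    err = tip.tip_depth_um - p_true
    out["rmse_um"] = float(np.sqrt(np.mean(err**2)))
    out["final_error_um"] = float(err[-1])
    out["true_peak_depth_um"] = float(p_true.max())
    # recovered depth when the tip truly crosses each internal boundary
    t0 = tip.time_s[0]
    i_peak = int(np.argmax(p_true))
    crossings = {}
    for b in truth.boundaries_um[1:-1]:
        idx = np.nonzero(p_true[: i_peak + 1] >= b)[0]
        if idx.size:
            crossings[float(b)] = float(tip.tip_depth_um[idx[0]])
    out["boundary_depths_recovered_um"] = crossings
    return out
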