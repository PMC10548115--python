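"""Shared fixtures: small reusable simulated runs.

The expensive end-to-end simulations are session-scoped and shared between
module tests and the acceptance suite; raw fringes are dropped as soon as
the derived products exist.
"""

from __future__ import annotations

import numpy as np
import pytest

import needleoct as no


def _run_archetype(preset: str, total_time_s: float, max_depth_um: float,
                   seed: int) -> dict:
    """Simulate + reconstruct + track one archetype traverse."""
    system = no.SystemSpec(k_samples=384, tissue_range_um=280.0)
    phantom = no.build_phantom(preset, seed=seed)
    motion = no.make_motion("triangle", total_time_s, max_depth_um)
    noise = no.NoiseSpec(seed=seed + 1)
    seq, truth = no.synthesize_sequence(phantom, motion, system, noise)
    tom_d = no.reconstruct_tomogram(
        seq, bins=1, depth_slice=(system.tip_pixel, system.surface_pixel + 48),
        pair_stride=10**9)
    tip = no.track(tom_d, no.DopplerParams.from_system(system))
    del tom_d
    tom_p = no.reconstruct_tomogram(seq, bins=5, pair_stride=16, keep_full=False)
    del seq
    profiles = no.compute_polarimetry(tom_p)
    del tom_p
    return {"system": system, "phantom": phantom, "motion": motion,
            "truth": truth, "track": tip, "profiles": profiles}


SYNTH_PITCH_UM = 2.0
SYNTH_SURFACE_PX = 5


def synthetic_profiles(p_of_t, n_pairs=60, n_z=50, boundary_um=60.0):
    """Idealised profiles of a two-layer medium seen from a moving needle:
    retardation steps at a fixed absolute depth; intensity encodes the
    column index (so freezing can be traced)."""
    from needleoct.recon import PolarimetryProfiles

    times = np.arange(n_pairs) * 0.01
    depth_below = (np.arange(n_z) - SYNTH_SURFACE_PX) * SYNTH_PITCH_UM
    ret = np.empty((n_pairs, n_z), np.float32)
    inten = np.empty((n_pairs, n_z), np.float32)
    for t in range(n_pairs):
        absolute = depth_below + p_of_t[t]
        ret[t] = np.where(absolute > boundary_um, 2.0, 0.5)
        inten[t] = t
    return PolarimetryProfiles(
        time_s=times, intensity_db=inten, retardation=ret,
        axis_deg=np.zeros((n_pairs, n_z), np.float32),
        mask=np.ones((n_pairs, n_z), bool), depth_offset_px=0,
        pitch_um=SYNTH_PITCH_UM)


def make_synthetic_track(p_of_t, times):
    from needleoct.doppler import TipTrack

    z = np.zeros_like(np.asarray(p_of_t, float))
    return TipTrack(time_s=times, dphi_tip=z, velocity_mm_s=z,
                    displacement_um=z, tip_depth_um=np.asarray(p_of_t, float))


@pytest.fixture(scope="session")
def small_system() -> no.SystemSpec:
    return no.SystemSpec(k_samples=512, tip_pixel=10, tip_standoff_px=8,
                         tissue_range_um=400.0)


@pytest.fixture(scope="session")
def single_layer_phantom() -> no.Phantom:
    return no.build_phantom(
        "custom", seed=1,
        layers=[no.LayerSpec(2000.0, dn=5e-4, axis_deg=30.0, attenuation_mm=0.5)])


@pytest.fixture(scope="session")
def single_layer_run(small_system, single_layer_phantom) -> dict:
    """Constant-speed insertion (0.6 mm/s, 0.2 s) through one birefringent
    layer, noise-free: the polarimetry / Doppler oracle workhorse."""
    motion = no.make_motion("custom", 0.2, 120.0,
                            breakpoints=[(0.0, 0.0), (0.2, 120.0)])
    seq, truth = no.synthesize_sequence(
        single_layer_phantom, motion, small_system, no.NoiseSpec.silent())
    tom = no.reconstruct_tomogram(seq, bins=5, pair_stride=4)
    profiles = no.compute_polarimetry(tom)
    tip = no.track(tom, no.DopplerParams.from_system(small_system, tip_pixel=10))
    return {"seq": seq, "truth": truth, "tom": tom, "profiles": profiles,
            "track": tip, "system": small_system, "phantom": single_layer_phantom,
            "speed_um_s": 600.0}


@pytest.fixture(scope="session")
def fiber_oracle_run(small_system, single_layer_phantom) -> dict:
    """Insertion under a random static fiber unitary; speckle decorrelates
    along the traverse so time averages isolate the polarimetric truth."""
    motion = no.make_motion("custom", 0.5, 600.0,
                            breakpoints=[(0.0, 0.0), (0.5, 600.0)])
    fiber = no.random_fiber_jones(3)
    seq, truth = no.synthesize_sequence(
        single_layer_phantom, motion, small_system, no.NoiseSpec.silent(),
        fiber_jones=fiber)
    tom = no.reconstruct_tomogram(seq, bins=5, pair_stride=16, keep_full=False)
    del seq
    profiles = no.compute_polarimetry(tom)
    del tom
    return {"truth": truth, "profiles": profiles, "system": small_system,
            "phantom": single_layer_phantom}


@pytest.fixture(scope="session")
def decimated_triangle_run() -> dict:
    """Insertion/retraction triangle at the full experimental speed but a
    tenth of the duration and depth (0.4 mm peak, 0.65 s each way)."""
    system = no.SystemSpec(k_samples=256, tissue_range_um=200.0)
    phantom = no.build_phantom("spine", seed=2)
    motion = no.make_motion("triangle", 1.3, 400.0)
    seq, truth = no.synthesize_sequence(phantom, motion, system,
                                        no.NoiseSpec.silent())
    tom = no.reconstruct_tomogram(seq, bins=1, pair_stride=10**9)
    del seq
    tip = no.track(tom, no.DopplerParams.from_system(system))
    del tom
    return {"truth": truth, "track": tip, "system": system}


@pytest.fixture(scope="session")
def jitter_run() -> dict:
    """Stationary needle, 10 s, with laser jitter, slow drift, and detector
    noise: the tracking output should stay put."""
    system = no.SystemSpec(k_samples=128, tip_pixel=6, tip_standoff_px=8,
                           tissue_range_um=100.0)
    phantom = no.build_phantom(
        "custom", seed=1,
        layers=[no.LayerSpec(2000.0, dn=5e-4, axis_deg=30.0, attenuation_mm=0.5)])
    motion = no.make_motion("custom", 10.0, 0.0,
                            breakpoints=[(0.0, 0.0), (10.0, 0.0)])
    noise = no.NoiseSpec(detector_noise_rel=0.02, jitter_prob=0.05,
                         jitter_magnitude_rad=3.0, drift_rad_per_s=0.5, seed=5)
    seq, truth = no.synthesize_sequence(phantom, motion, system, noise)
    tom = no.reconstruct_tomogram(seq, bins=1, pair_stride=10**9)
    del seq
    tip = no.track(tom, no.DopplerParams.from_system(system, tip_pixel=6))
    del tom
    return {"truth": truth, "track": tip, "system": system}


@pytest.fixture(scope="session")
def salmon_run() -> dict:
    return _run_archetype("salmon", 2.95, 5150.0, seed=3)


@pytest.fixture(scope="session")
def shrimp_run() -> dict:
    return _run_archetype("shrimp", 2.8, 4500.0, seed=3)


@pytest.fixture(scope="session")
def spine_run() -> dict:
    return _run_archetype("spine", 2.8, 4150.0, seed=3)
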