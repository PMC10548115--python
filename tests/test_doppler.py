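"""Doppler odometry: gating, causal median, drift correction, conversion."""

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

import needleoct as no
from needleoct.doppler import (
    DopplerParams,
    PhaseDifferenceSeries,
    depth_average,
    integrate_position,
    jitter_gate,
    phase_difference,
    temporal_median,
    tip_reference_correct,
    to_displacement,
    to_velocity,
)


def _series(arr):
    arr = np.asarray(arr, dtype=np.float32)
    return PhaseDifferenceSeries(arr, np.arange(arr.shape[0], dtype=float), 0)


class TestJitterGate:
    @pytest.mark.parametrize("value,expected", [
        (2.6, 0.0),        # above the gate: classified as laser jitter
        (2.5, 2.5),        # boundary kept: the rule is strictly 'greater'
        (-2.6, 0.0),       # gating is on magnitude
        (-2.4, -2.4),
        (0.0, 0.0),
    ])
    def test_gate_rule(self, value, expected):
        out = jitter_gate(_series([[value]]), 2.5)
        assert out.dphi[0, 0] == np.float32(expected)

    @given(st.lists(st.floats(-np.pi, np.pi), min_size=1, max_size=50))
    @settings(max_examples=50, deadline=None, derandomize=True)
    def test_gate_idempotent(self, values):
        s = _series([[v] for v in values])
        once = jitter_gate(s, 2.5)
        twice = jitter_gate(once, 2.5)
        assert np.array_equal(once.dphi, twice.dphi)


class TestTemporalMedian:
    def test_constant_series_unchanged(self):
        s = _series(np.full((200, 3), 0.7))
        assert np.allclose(temporal_median(s, 72).dphi, 0.7)

    def test_zeros_from_gate_are_removed(self):
        """10 zeroed samples inside a 72-sample window leave the median at
        the underlying constant (brute-force sorted-window check)."""
        x = np.full((100, 1), 0.9, dtype=np.float32)
        zero_idx = np.arange(80, 90)
        x[zero_idx] = 0.0
        out = temporal_median(_series(x), 72).dphi
        window = x[99 - 71: 100, 0]
        assert np.median(np.sort(window)) == pytest.approx(0.9)
        assert out[99, 0] == pytest.approx(0.9)

    def test_causality(self):
        """Modifying a future sample never changes past outputs."""
        rng = np.random.default_rng(0)
        x = rng.normal(size=(150, 2)).astype(np.float32)
        base = temporal_median(_series(x), 20).dphi.copy()
        x2 = x.copy()
        x2[120] += 5.0
        out = temporal_median(_series(x2), 20).dphi
        assert np.array_equal(out[:120], base[:120])

    def test_matches_brute_force(self):
        rng = np.random.default_rng(3)
        x = rng.normal(size=(300, 4)).astype(np.float32)
        out = temporal_median(_series(x), 72).dphi
        brute = np.stack([np.median(x[max(0, i - 71): i + 1], axis=0)
                          for i in range(300)])
        assert np.allclose(out, brute, atol=1e-6)

    @given(st.floats(-2.0, 2.0))
    @settings(max_examples=20, deadline=None, derandomize=True)
    def test_shift_equivariance(self, c):
        rng = np.random.default_rng(7)
        x = rng.normal(size=(120, 2)).astype(np.float32)
        a = temporal_median(_series(x + np.float32(c)), 30).dphi
        b = temporal_median(_series(x), 30).dphi + np.float32(c)
        assert np.allclose(a, b, atol=1e-5)


class TestTipReference:
    def test_common_offset_cancels(self):
        rng = np.random.default_rng(1)
        x = rng.uniform(-1, 1, size=(50, 8)).astype(np.float32)
        plain = tip_reference_correct(_series(x), 2).dphi
        offset = tip_reference_correct(_series(x + 0.4), 2).dphi
        assert np.allclose(plain, offset, atol=1e-5)

    def test_output_zero_at_tip(self):
        rng = np.random.default_rng(2)
        x = rng.uniform(-3, 3, size=(50, 8)).astype(np.float32)
        out = tip_reference_correct(_series(x), 5).dphi
        assert np.all(out[:, 5] == 0.0)

    def test_simulated_drift_cancels_with_stationary_needle(self):
        """0.5 rad/s common-mode drift is removed to numerical precision."""
        sys = no.SystemSpec(k_samples=256, tip_pixel=10, tissue_range_um=150.0)
        ph = no.build_phantom("custom", seed=3,
                              layers=[no.LayerSpec(2000.0, dn=5e-4, axis_deg=10.0)])
        mo = no.make_motion("custom", 0.05, 1.0,
                            breakpoints=[(0.0, 0.0), (0.05, 0.0)])
        seq, _ = no.synthesize_sequence(
            ph, mo, sys, no.NoiseSpec(detector_noise_rel=0.0, jitter_prob=0.0,
                                      drift_rad_per_s=0.5, seed=0))
        tom = no.reconstruct_tomogram(seq, bins=1)
        ser = phase_difference(tom, 0)
        corr = tip_reference_correct(ser, sys.tip_pixel)
        span = corr.dphi[:, sys.surface_pixel + 1: sys.surface_pixel + 47]
        assert np.abs(np.mean(span)) < 1e-3


class TestDepthAverage:
    def test_constant_profile(self):
        x = np.full((10, 60), 0.3, dtype=np.float32)
        assert depth_average(_series(x), 5, 46) == pytest.approx(0.3)

    def test_linear_profile_closed_form(self):
        """Mean of a+b*j over pixels 1..46 below the anchor is a + b*23.5."""
        a, b = 0.2, 0.01
        x = (a + b * np.arange(60, dtype=np.float32))[None, :].repeat(3, axis=0)
        out = depth_average(_series(x), 0, 46)
        assert out == pytest.approx(a + b * 23.5)

    def test_span_one_is_single_pixel(self):
        x = np.arange(20, dtype=np.float32)[None, :]
        assert depth_average(_series(x), 7, 1)[0] == 8.0

    def test_span_beyond_range_raises(self):
        x = np.zeros((5, 30), dtype=np.float32)
        with pytest.raises(ValueError):
            depth_average(_series(x), 10, 46)


class TestConversion:
    def test_gate_phase_maps_to_printed_velocity(self):
        p = DopplerParams()
        v = to_velocity(2.5, p)
        assert np.floor(v * 10) / 10 == pytest.approx(4.7)

    @pytest.mark.parametrize("dphi,expected_mm_s", [(0.0, 0.0), (1.0, 1.9026)])
    def test_velocity_formula(self, dphi, expected_mm_s):
        assert to_velocity(dphi, DopplerParams()) == pytest.approx(
            expected_mm_s, abs=1e-3)

    def test_displacement_at_gate(self):
        assert to_displacement(2.5, DopplerParams()) == pytest.approx(0.1902, abs=2e-4)

    @given(st.floats(-np.pi, np.pi))
    @settings(max_examples=50, deadline=None, derandomize=True)
    def test_velocity_times_period_is_displacement(self, dphi):
        p = DopplerParams()
        v_um_s = to_velocity(dphi, p) * 1e3
        assert v_um_s * p.state_period_s == pytest.approx(
            to_displacement(dphi, p), rel=1e-12, abs=1e-15)

    def test_integrate_position(self):
        assert np.all(integrate_position(np.zeros(10)) == 0.0)
        assert integrate_position(np.full(40, 0.5))[-1] == pytest.approx(20.0)
        d = np.concatenate([np.full(25, 0.3), np.full(25, -0.3)])
        assert integrate_position(d)[-1] == pytest.approx(0.0, abs=1e-12)


class TestTrack:
    def test_constant_speed_recovery_within_2pct(self, single_layer_run):
        """Noise-free constant-speed insertion is recovered to < 2%."""
        tr = single_layer_run["track"]
        true_v = single_layer_run["speed_um_s"] * 1e-3
        est = np.mean(tr.velocity_mm_s[200:])
        assert est == pytest.approx(true_v, rel=0.02)

    def test_track_invariants(self, single_layer_run):
        tr = single_layer_run["track"]
        p = tr.params
        assert np.allclose(tr.velocity_mm_s * 1e3 * p.state_period_s,
                           tr.displacement_um, rtol=1e-12, atol=1e-12)
        assert np.allclose(np.cumsum(tr.displacement_um), tr.tip_depth_um)

    def test_insufficient_alines_raises(self, single_layer_run):
        tom = single_layer_run["tom"]
        sub = no.BinnedTomogram(
            full=tom.full[:1], bins=None, state=tom.state[:1],
            time_s=tom.time_s[:1], pair_time_s=None, depth_offset_px=0,
            system=tom.system)
        with pytest.raises(ValueError, match="state"):
            phase_difference(sub, 0)

    def test_uniform_phase_rotation_reads_as_alpha(self, single_layer_run):
        """Multiplying one A-line by e^{i alpha} shifts its phase difference
        by alpha at every depth."""
        tom = single_layer_run["tom"]
        alpha = 0.8
        full = tom.full[:8].copy()
        full[6] *= np.exp(1j * alpha).astype(np.complex64)
        sub = no.BinnedTomogram(full=full, bins=None, state=tom.state[:8],
                                time_s=tom.time_s[:8], pair_time_s=None,
                                depth_offset_px=0, system=tom.system)
        base = phase_difference(
            no.BinnedTomogram(full=tom.full[:8], bins=None, state=tom.state[:8],
                              time_s=tom.time_s[:8], pair_time_s=None,
                              depth_offset_px=0, system=tom.system), 0)
        mod = phase_difference(sub, 0)
        delta = mod.dphi[2] - base.dphi[2]      # A-line 6 is state 0, pair 2
        wrapped = np.angle(np.exp(1j * delta.astype(np.float64)))
        assert np.allclose(wrapped, alpha, atol=1e-3)
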