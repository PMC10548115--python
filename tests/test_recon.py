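"""Tomogram reconstruction, intensity scaling, and Stokes polarimetry."""

import numpy as np
import pytest

import needleoct as no
from needleoct.recon import (
    bin_windows,
    circular_mean_halfturn,
    combine_bins,
    compute_intensity,
    compute_polarimetry,
    reconstruct_tomogram,
)
from needleoct.simulate import SpectralSequence


def _manual_sequence(system, alines):
    """SpectralSequence from explicit per-A-line fringes (both channels)."""
    f = np.stack([np.stack([a, a]) for a in alines]).astype(np.float32)
    n = len(alines)
    return SpectralSequence(
        fringes=f, state=(np.arange(n) % 2).astype(np.uint8),
        time_s=np.arange(n) / system.sweep_rate_hz, system=system)


@pytest.fixture(scope="module")
def sys256():
    return no.SystemSpec(k_samples=256, tip_pixel=10, tissue_range_um=150.0)


class TestTransform:
    @pytest.mark.parametrize("z0", [23, 57, 90])
    def test_single_cosine_peaks_at_its_delay_in_every_bin(self, sys256, z0):
        """A pure cosine of fringe frequency z0 transforms to a peak at
        depth pixel z0, bin by bin (brute-force DFT cross-check)."""
        K = sys256.k_samples
        j = np.arange(K)
        fringe = np.cos(2 * np.pi * z0 * j / K)
        seq = _manual_sequence(sys256, [fringe] * 4)
        tom = reconstruct_tomogram(seq, bins=5)
        for b in range(5):
            prof = np.abs(tom.bins[b, 0, 0, 0])
            assert int(np.argmax(prof)) == z0
        # independent oracle: brute-force DFT magnitude at z0 vs elsewhere
        w = bin_windows(sys256, 5)[2]
        dft = np.array([np.abs(np.sum(w * fringe * np.exp(-2j * np.pi * m * j / K)))
                        for m in range(K // 2)])
        assert int(np.argmax(dft)) == z0

    def test_zero_fringe_gives_zero_profile(self, sys256):
        seq = _manual_sequence(sys256, [np.zeros(256)] * 4)
        tom = reconstruct_tomogram(seq, bins=3)
        assert np.abs(tom.full).max() == 0.0
        assert np.abs(tom.bins).max() == 0.0

    def test_missing_state_labels_rejected(self, sys256):
        seq = _manual_sequence(sys256, [np.zeros(256)] * 4)
        seq.state = np.zeros((2, 2))
        with pytest.raises(ValueError, match="state"):
            reconstruct_tomogram(seq)

    def test_two_reflector_linearity(self, sys256):
        """Intensity of well-separated reflectors adds within cross-term
        tolerance."""
        ph = no.build_phantom("custom", seed=0,
                              layers=[no.LayerSpec(3000.0, attenuation_mm=0.0)])
        mo = no.make_motion("custom", 0.002, 1.0,
                            breakpoints=[(0.0, 0.0), (0.002, 0.0)])
        tissue = slice(sys256.surface_pixel + 1, None)   # exclude the tip echo
        single_peaks = []
        for depths in ([80.0], [160.0], [80.0, 160.0]):
            seq, _ = no.synthesize_sequence(
                ph, mo, sys256, no.NoiseSpec.silent(),
                scatterers=(np.array(depths), np.ones(len(depths))))
            tom = reconstruct_tomogram(seq, bins=1)
            power = np.sum(np.abs(tom.full[0]) ** 2, axis=0)[tissue]
            single_peaks.append(power)
        combined = single_peaks[2]
        summed = single_peaks[0] + single_peaks[1]
        assert np.sum(combined) == pytest.approx(np.sum(summed), rel=0.02)


class TestIntensity:
    def test_all_zero_profile_sits_at_the_floor(self, sys256):
        seq = _manual_sequence(sys256, [np.zeros(256)] * 4)
        tom = reconstruct_tomogram(seq, bins=1)
        img = compute_intensity(tom, dynamic_range_db=50.0)
        assert np.all(img == -50.0)

    def test_doubling_amplitude_adds_6dB(self, sys256):
        K = 256
        j = np.arange(K)
        base = np.cos(2 * np.pi * 40 * j / K)
        seq = _manual_sequence(sys256, [base, base, 2 * base, 2 * base])
        tom = reconstruct_tomogram(seq, bins=1)
        img = compute_intensity(tom)
        assert img[2, 40] - img[0, 40] == pytest.approx(20 * np.log10(2), abs=1e-3)


class TestCombineBins:
    def test_identical_bins_are_idempotent(self):
        ret = np.full((4, 10), 1.2)
        ax = np.full((4, 10), 25.0)
        r, a = combine_bins(ret, ax)
        assert np.allclose(r, 1.2) and np.allclose(a, 25.0)

    def test_symmetric_axes_average_to_zero(self):
        ax = np.array([[30.0], [-30.0]])
        _, a = combine_bins(per_bin_axis_deg=ax)
        assert a[0] == pytest.approx(0.0, abs=1e-9)

    def test_single_bin_returns_itself(self):
        ret = np.array([[0.7, 2.9]])
        r, _ = combine_bins(ret)
        assert np.array_equal(r, ret[0])

    def test_combination_reduces_circular_variance(self):
        """Monte-Carlo: the 5-bin circular mean is tighter than any single
        bin's estimates."""
        rng = np.random.default_rng(42)
        true = 1.0
        perturbed = true + rng.normal(0, 0.15, size=(5, 2000))
        combined = circular_mean_halfturn(perturbed, axis=0)

        def circ_var(x):
            return 1.0 - np.abs(np.mean(np.exp(2j * x)))

        assert circ_var(combined) < min(circ_var(perturbed[b]) for b in range(5))


class TestPolarimetry:
    def test_nonbirefringent_phantom_has_near_zero_retardation(self, sys256):
        ph = no.build_phantom("custom", seed=2,
                              layers=[no.LayerSpec(3000.0, dn=0.0,
                                                   attenuation_mm=0.0)])
        mo = no.make_motion("custom", 0.02, 60.0,
                            breakpoints=[(0.0, 0.0), (0.02, 60.0)])
        seq, _ = no.synthesize_sequence(ph, mo, sys256, no.NoiseSpec.silent())
        tom = reconstruct_tomogram(seq, bins=5, pair_stride=2)
        prof = compute_polarimetry(tom)
        band = prof.retardation[:, sys256.surface_pixel + 5: sys256.surface_pixel + 50]
        assert circular_mean_halfturn(band.ravel()) < 0.1

    def test_single_layer_matches_jones_oracle(self, single_layer_run):
        """Cumulative retardation and axis at mid-depth agree with the
        round-trip Jones transport (identity fiber)."""
        sys = single_layer_run["system"]
        prof = single_layer_run["profiles"]
        z_um = 300.0
        j = sys.surface_pixel + int(round(z_um / sys.axial_pitch_um))
        ret_true, ax_true = no.retardation_axis_from_roundtrip(
            no.jones_roundtrip(single_layer_run["phantom"], z_um))
        ret_est = circular_mean_halfturn(prof.retardation[:, j - 3: j + 4].ravel())
        assert abs(ret_est - ret_true) < 0.01 * np.pi
        ax_est = np.rad2deg(circular_mean_halfturn(
            np.deg2rad(prof.axis_deg[:, j - 3: j + 4]).ravel()))
        ax_est = (ax_est + 90) % 180 - 90
        assert abs(ax_est - ax_true) < 3.0

    def test_output_ranges(self, single_layer_run):
        prof = single_layer_run["profiles"]
        assert np.all(prof.retardation >= 0) and np.all(prof.retardation <= np.pi)
        assert np.all(prof.axis_deg >= -90) and np.all(prof.axis_deg < 90)

    def test_retardation_at_reference_is_zero(self, single_layer_run):
        sys = single_layer_run["system"]
        prof = single_layer_run["profiles"]
        ref_col = prof.retardation[:, sys.tip_pixel - prof.depth_offset_px]
        assert np.abs(ref_col).max() < 1e-6

    def test_per_bin_estimates_agree_without_dispersion(self, single_layer_run):
        """No polarization-mode dispersion is simulated, so the five bins
        must agree on the retardation."""
        tom = single_layer_run["tom"]
        sys = single_layer_run["system"]
        prof = compute_polarimetry(tom, keep_per_bin=True)
        j = sys.surface_pixel + int(round(300.0 / sys.axial_pitch_um))
        per_bin = [circular_mean_halfturn(
            prof.per_bin_retardation[b][:, j - 3: j + 4].ravel()) for b in range(5)]
        assert max(per_bin) - min(per_bin) < 0.1

    def test_degenerate_reference_flags_not_raises(self, sys256):
        """Parallel launch states at the reference flag the mask instead of
        raising."""
        K = sys256.k_samples
        tom = reconstruct_tomogram(
            _manual_sequence(sys256, [np.zeros(K)] * 4), bins=2)
        # identical fields for both states everywhere -> degenerate reference
        tom.bins[...] = 1.0 + 0.5j
        prof = compute_polarimetry(tom)
        assert not prof.mask.any()

    def test_retardation_invariant_under_fiber_unitary(self, fiber_oracle_run,
                                                       single_layer_run):
        """A static fiber lead must not change the measured retardation."""
        sys = single_layer_run["system"]
        z_um = 300.0
        j = sys.surface_pixel + int(round(z_um / sys.axial_pitch_um))
        a = circular_mean_halfturn(
            single_layer_run["profiles"].retardation[:, j - 3: j + 4].ravel())
        b = circular_mean_halfturn(
            fiber_oracle_run["profiles"].retardation[:, j - 3: j + 4].ravel())
        assert abs(a - b) < 0.02
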