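"""Layer identification by retardation contrast: the salmon archetype.

The phantom alternates five birefringent muscle layers with four
non-birefringent connective-tissue layers.  As the needle traverses the
stack, the cumulative retardation measured ~150 um below the tip switches
between high (muscle) and low (connective) values; thresholding that series
recovers the layer sequence.
"""

import needleoct as no

system = no.SystemSpec(k_samples=384, tissue_range_um=280.0)
phantom = no.build_phantom("salmon", seed=3)
motion = no.make_motion("triangle", 2.95, 5150.0)
seq, truth = no.synthesize_sequence(phantom, motion, system,
                                    no.NoiseSpec(seed=4))

tom_d = no.reconstruct_tomogram(
    seq, bins=1, depth_slice=(system.tip_pixel, system.surface_pixel + 48),
    pair_stride=10**9)
tip = no.track(tom_d, no.DopplerParams.from_system(system))
tom_p = no.reconstruct_tomogram(seq, bins=5, pair_stride=16, keep_full=False)
profiles = no.compute_polarimetry(tom_p)

n_muscle, n_connective = no.retardation_alternation(
    profiles, tip, system.surface_pixel)
print(f"layers recovered during insertion: {n_muscle} birefringent (muscle), "
      f"{n_connective} non-birefringent (connective)")
print(f"phantom truth: 5 muscle / 4 connective, "
      f"{phantom.total_depth_um:.0f} um total depth")

m = no.needle_referenced_map(profiles)
j = system.surface_pixel + int(round(150.0 / system.axial_pitch_um))
series = m.retardation[j]
print(f"retardation 150 um below tip: min {series.min():.2f} rad (fat), "
      f"max {series.max():.2f} rad (muscle)")
print("\nHigh/low alternation of the sub-tip retardation reproduces the "
      "muscle/connective layering without any structural-image contrast.")
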