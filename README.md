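# needleoct

Doppler-tracked polarization-sensitive OCT (PS-OCT) needle guidance, as a
tested simulation and processing toolkit.

## The problem

Optical coherence tomography can be built into a bare "smart needle": a
single-mode fiber glued into the bore gives a forward-viewing, unscanned
probe that reports one depth profile (A-line) per laser sweep. Structural
OCT alone is hard to interpret in such probes — there is no lateral
dimension, and many soft tissues look alike in backscatter. Two additions
make the signal interpretable:

* **Polarization sensitivity.** Alternating the launch polarization between
  successive sweeps and detecting two orthogonal channels yields, per depth,
  the cumulative round-trip *phase retardation* and apparent *optic-axis
  orientation* of the tissue ahead of the needle. Oriented tissue (muscle,
  ligament) is birefringent; fat and empty spaces are not — so layers that
  are invisible in intensity separate cleanly in retardation or axis.
* **Doppler odometry.** The phase change between consecutive same-state
  A-lines measures the needle's axial motion relative to the tissue,
  turning the time axis of the M-mode record into an absolute depth axis
  referenced to the tissue surface.

This is directly useful for epidural needle placement: the epidural space
announces itself as a spike in tip-reflection intensity coinciding with the
loss of polarimetric signal.

The package is aimed at researchers developing or evaluating such probes.
Because the method lives in hardware, every stage here is driven by a
**fringe-level simulator** with an exact per-scatterer ground truth, so the
whole pipeline is testable on a desk.

## The method

For one launch state, with consecutive same-state A-lines separated by
T = 40 µs, the per-depth wrapped phase difference Δφ is processed as:

1. **Jitter gate** — |Δφ| > 2.5 rad corresponds to axial motion faster than
   v = λc·Δφ/(4π·n·T) ≈ 4.7 mm/s, implausible for a hand-held needle; such
   samples are laser phase jitter and are set to zero.
2. **Causal median** — per depth pixel, a sliding median over the past 72
   intervals (2.88 ms) absorbs the gated zeros and speckle glitches.
3. **Tip reference** — the needle-tip reflection sits at constant delay, so
   its phase difference is pure common-mode drift; it is subtracted from
   every depth below.
4. **Depth mean** — arithmetic mean over 46 pixels (86 µm at 1.87 µm/pixel)
   of tissue below the tip, which moves rigidly relative to the needle.
5. **Conversion** — velocity v = λc·Δφ/(4π·n·T) and displacement
   d = λc·Δφ/(4π·n) with n = 1.37, integrated into tip depth p(t).

Polarimetry uses spectral binning (five half-overlapping sub-bands) and the
two-input-state Stokes formulation: the rotation on the Poincaré sphere
carrying the tip-referenced Stokes pair to the pair at depth z gives the
retardation (rotation angle, wrapped to [0, π]) and the axis (azimuth of the
rotation axis in the Q–U plane, halved, in [−90°, 90°)). Retardation is
invariant under the static fiber-lead unitary; the axis carries an unknown
constant offset.

The Doppler-tracked p(t) then converts needle-referenced M-mode maps into
**surface-referenced maps**: each A-line is written at its absolute depth,
rows above the tip are frozen as the traversed-tissue record, and dwell time
widens a band along the time axis (an implicit confidence cue).

## Worked example

```bash
python examples/tip_tracking.py
```

```
peak depth: tracked 400.6 um, true 400.0 um
RMSE vs truth:        1.16 um
closure error at end: 1.75 um (0.44% of peak)
gate hit rate:        0.0001
```

A noise-free 0.4 mm insertion/retraction at 0.62 mm/s is tracked to ~1 µm;
the 1.75 µm closure error is the causal median filter's lag at the
turnaround (36 intervals × 2 × 0.025 µm), inherent to the causal chain.

```bash
python examples/jones_oracle_polarimetry.py
```

```
depth   150 um: retardation 0.721 rad (oracle 0.719), axis  -43.4 deg (true +30 deg + fiber offset)
depth   250 um: retardation 1.202 rad (oracle 1.199), axis  -43.3 deg (true +30 deg + fiber offset)
depth   350 um: retardation 1.677 rad (oracle 1.679), axis  -43.3 deg (true +30 deg + fiber offset)
```

The recovered retardation matches the Jones-matrix transport oracle to a
few mrad behind a random fiber unitary; the axis is constant across depth,
offset by the fiber rotation. `examples/salmon_layers.py` and
`examples/epidural_guidance.py` demonstrate the layer-identification
archetypes (5/4 muscle–connective alternation; epidural-void detection to
0.2 ms).

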