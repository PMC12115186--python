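# membkit

Analysis toolkit for studies of membrane-modifying small molecules:
bilayer structural observables from molecular trajectories, probe-particle
transport and permeability, and DSC thermogram parameterization — together
with synthetic-data generators that provide exact ground truth for all
three, so every estimator in the package is validated by parameter
recovery, closed forms, or an independent brute-force oracle.

It is aimed at membrane biophysicists who need the quantitative pipeline
of a drug–bilayer interaction study (calorimetry deltas, interdigitation
ratios, solubility–diffusion permeability) as tested, reusable code rather
than one-off scripts.

## What it computes

**Structure** (from a role-annotated multi-frame trajectory)

- area per lipid, projected convention: APL = 2·Lx·Ly/N
- bilayer thickness δ: distance between the leaflets' phosphate
  (or head-reference) planes
- mass-density profiles ρ(z) per selection, midplane-centred
- deuterium order parameter |S_CD| = |⟨(3cos²θ − 1)/2⟩| per tail carbon,
  θ the C–H angle to the membrane normal
- leaflet interdigitation as a fraction of mass overlap,
  f_ov = ∫min(ρ_U, ρ_L)dz / (½∫(ρ_U + ρ_L)dz), and the
  treated-vs-control ratio D_int = f_ov,treated / f_ov,control
- geometric hydrogen-bond counts (D–A ≤ 3.5 Å, H–D–A ≤ 30°)

**Transport** (from probe-particle trajectories)

- hydrophobic-core boundaries from the head/tail density crossover
- partition coefficient K_p = occupancy(core)/occupancy(outside)
- multiple-time-origin MSD per component (z, xy, 3-D) and diffusion
  coefficients D = slope/(2d) from OLS on a configurable lag window
- membrane permeability by the solubility–diffusion estimate
  **P_m = D_m·K_p/δ**, with D_m = D_z by default and the anisotropy
  D_z/D_xy reported alongside

**Calorimetry** (from heating/cooling Cp(T) traces)

- T_m (parabolic apex), ΔT_b (FWHM), ΔH (peak area), ΔT_h (heating −
  cooling hysteresis), drug-minus-control delta tables and dose series
  with biphasic-trend detection

**Generators** with exact ground truth: an idealized bead-chain bilayer
builder (controllable APL, thickness, tilt, leaflet interpenetration),
an overdamped Langevin simulator for probes on a smoothed square-well,
region-dependent diffusivity field, and a two-state van't Hoff thermogram
generator (separate calorimetric and van't Hoff enthalpies, optional
pre-transition, scan hysteresis, noise).

## Worked example

```python
import membkit as mk

# a 120-lipid gel-phase bilayer, 10 jittered frames
traj = mk.build_bilayer(mk.BilayerSpec(n_frames=10, thermal_jitter_sd=0.4, seed=1))
s = mk.structure_summary(traj)
print(f"APL       {s.apl.mean:.2f} ± {s.apl.sd:.2f} Å²")
print(f"thickness {s.thickness.mean:.2f} ± {s.thickness.sd:.2f} Å")

# 500 probes in a 1-kT hydrophobic well, 50 ns of Langevin dynamics
pt = mk.simulate_probes(mk.ProbeFieldSpec(
    well_depth_kt=1.0, core_halfwidth=20.0, box_z=80.0,
    n_particles=500, dt=0.5, n_steps=100_000, record_every=50, seed=1))
t = mk.transport_summary(pt, delta_angstrom=s.thickness.mean,
                         config=mk.TransportConfig(fit_window=(25.0, 2000.0)))
print(f"K_p {t.k_p:.2f}  D_z {t.d_z:.2e} cm²/s  P_m {t.p_m:.1f} cm/s")

# control-DPPC thermogram pair, analysed back
h, c = mk.generate_thermogram(mk.ThermogramSpec())
ph, pc = mk.transition_params(h), mk.transition_params(c)
print(f"T_m {ph.t_m:.1f} °C  ΔT_b {ph.delta_t_b:.1f} °C  "
      f"ΔH {ph.delta_h:.1f} kcal/mol  ΔT_h {mk.hysteresis(ph, pc):.1f} °C")
```

prints

```
APL       47.00 ± 0.00 Å²
thickness 46.07 ± 0.06 Å
K_p 2.65  D_z 7.18e-06 cm²/s  P_m 41.3 cm/s
T_m 41.5 °C  ΔT_b 1.7 °C  ΔH 24.9 kcal/mol  ΔT_h 0.4 °C
```

Reading the numbers: the builder's ground truth (APL 47 Å², jitter-level
sd) is recovered exactly; the probe occupancy ratio K_p ≈ 2.65 sits near
the Boltzmann ratio e¹ ≈ 2.72 for a 1-kT well occupying half the box; D_z
is below the input 1e-5 cm²/s because z is confined between reflecting
walls (fit window and r² are in the record); and the DSC stage recovers
the generator's transition temperature, width, enthalpy and hysteresis at
the precision of the sampling grid.

A `memb` CLI wraps the same stages
(`memb synth bilayer|probes|dsc`, `memb structure`, `memb transport`,
`memb dsc`, `memb run --config pipeline.yaml`).

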