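# Methods

This note documents the models and numerical conventions behind membkit:
what each stage computes, what the synthetic generators do and do not
emulate, and the choices made where the underlying conventions were
genuinely open.

## Scope and design

membkit analyses three kinds of input: role-annotated bilayer
trajectories (structural observables), probe-particle trajectories
(partitioning, diffusion, permeability), and DSC thermograms (thermotropic
transition parameters). Because studies of membrane-modifying small
molecules frequently deposit no raw trajectories or thermograms, the
package ships generators that produce all three kinds of data with exact,
parameterized ground truth; every analysis operator is validated by
round-tripping against those parameters, by closed forms, or by an
independent brute-force oracle.

One unit system holds at every in-memory interface: Å, ps, amu, kcal/mol,
°C. Files use their conventional units (GRO stores nm; diffusion
coefficients are reported in cm²/s; permeability in cm/s); conversion
happens only at those boundaries, which is itself covered by a
dimensional-consistency test on P_m.

## Synthetic bilayer (builder)

Lipids are idealized bead-chains: one lumped headgroup bead above a single
all-trans acyl chain whose carbons each carry two geometric hydrogens
perpendicular to the local chain axis. The default system is a 120-lipid
(60 per leaflet) DPPC-like membrane in the gel state: area per lipid
47 Å², C–C z-projection 1.27 Å, 16 tail carbons, head bead 4 Å above the
chain start. The generator is geometric, not physical — no forces, no
electrostatics, no chemistry beyond role tags. What it guarantees instead:

- lateral box area is exactly `N_per_leaflet × target_apl`, so the
  projected area per lipid is recovered exactly at zero jitter;
- total lipid mass equals `Σ head_mass + n_C·(m_C + 2 m_H)` exactly;
- leaflet interpenetration is a single parameter, the distance
  `interdigitation_offset` that each leaflet's tail termini reach past the
  midplane (≤ 0 keeps the leaflets apart). The mapping onto the
  mass-overlap fraction is monotone; this is asserted by test, not assumed;
- untilted chains have every C–H bond perpendicular to the normal, so
  |S_CD| = 0.5 identically — the order-parameter closed form.

Thermal disorder is Gaussian per-coordinate jitter. Note that at zero
jitter the mass density is a set of delta planes, on which the overlap
statistic is degenerate (two interpenetrating combs of planes can overlap
nowhere); interdigitation tests therefore use jitter ≥ ~1 Å, which is also
the physically sensible regime — real densities are thermally smeared.
Probe and drug particles are placed in the head region; the drug insertion
depth below the head plane is a free parameter (default 2 Å) because no
deeper convention exists for "inserted in the headgroup region".

What passing tests on this generator do *not* show: force-field realism,
undulations, protrusions, per-lipid tilt disorder, or finite-size effects
of real membranes. They show that the analysis operators compute their
definitions correctly.

## Probe Langevin simulator

Overdamped (position) Langevin dynamics on a piecewise-constant
diffusivity field with a smoothed square well of depth `well_depth_kt`
(in kT) centred on the hydrophobic core: Euler–Maruyama with per-axis step
sd `sqrt(2 D_axis dt)`. Steps in D(z) and U(z) are smoothed with 1 Å tanh
ramps, and the z-update includes the Itô spurious-drift term `dD_z/dz`;
without it a space-dependent diffusivity does not sample `exp(-U)`, and
the Boltzmann partition-coefficient oracle would be biased. The core may
be anisotropic (`anisotropy_core` scales D_z relative to D_xy inside the
core), emulating the hindered normal diffusion of a probe inside an
ordered acyl region. xy is periodic (positions stored wrapped), z bounded
by reflecting walls (periodic optional).

Default scales mirror a small-molecule probe in water/membrane: D of
1e-5 cm²/s, ~10 probes, dt 0.5–1 ps. The integrator refuses time steps
whose rms displacement exceeds a quarter of the core halfwidth. The
recovery tests run at 500 particles and 1e5 steps — large enough that the
MSD slope recovers D within 10% and the occupancy ratio recovers the
Boltzmann prediction within 15%, which are the resolutions the stochastic
tests assert. For D recovery the box height is set large (400 Å) and the
fit window short relative to the confinement time, because z is bounded:
the z-MSD of a particle in a slab saturates at `L²/6`, and fitting into
the saturating regime biases D low. This confinement bias is physical, not
an artifact, and is the reason the analysis reports the fit window and r².

## Thermogram generator

Two-state van't Hoff excess heat capacity

    Cp_ex(T) = (ΔH_vH·ΔH_cal / (R T_K²)) · K/(1+K)²,
    K = exp[(ΔH_vH/R)(1/T_m,K − 1/T_K)],

whose temperature integral is ΔH_cal exactly (verified to 0.1% by
trapezoid on the sampled grid, and invariant under grid refinement to
0.01%). ΔH_vH sets the peak sharpness; callers may instead request a
target full width at half maximum and the corresponding ΔH_vH is solved by
1-D root finding on the numerically measured FWHM (the analytic
approximation FWHM ≈ 3.5255·R·T_m²/ΔH_vH seeds the bracket). Separating
ΔH_vH from ΔH_cal makes narrow cooperative peaks reachable: a 1.7 °C-wide
peak at 41.5 °C requires ΔH_vH ≈ 410 kcal/mol against ΔH_cal 25 kcal/mol,
i.e. a cooperative melting unit of roughly 16 lipids — the DPPC regime.
An optional pre-transition peak of the same form, a linear baseline,
Gaussian noise, and a cooling scan whose main peak is shifted down by the
hysteresis complete the trace. Defaults are the untreated-DPPC control:
T_m 41.5 °C, FWHM 1.7 °C, ΔH 25 kcal/mol, hysteresis 0.4 °C, heating at
0.2 and cooling at 0.3 °C/min as scan metadata.

## Structural observables

- **Leaflets.** A lipid is upper iff its head-reference z exceeds the
  midplane (mean head-reference z), per frame; a head exactly at the
  midplane goes to the lower leaflet — determinism over elegance — with a
  warning, and leaflet flips between frames are reported.
- **Density profiles.** Each frame is re-centred so the midplane sits at
  z = 0 (removing box drift), masses are binned (default 0.5 Å — fine
  enough to resolve ~1.4 Å thickness changes) and divided by the bin
  volume. The grid covers the full atom extent, so the profile integral
  conserves the selected mass exactly; the suite asserts 0.1%.
- **Area per lipid** is the projected-area convention 2·Lx·Ly/N — exact
  for ensemble means, oracle-checkable against the builder, and free of
  the tessellation ambiguity of Voronoi APL (out of scope). Asymmetric
  leaflet populations switch to the per-leaflet formula with both values
  reported.
- **Thickness** is the distance between the mean z of the two leaflets'
  phosphate reference atoms (head-reference fallback) — translation
  invariant by construction.
- **Interdigitation** is the fraction of leaflet tail-density mass
  overlap, `f_ov = ∫min(ρ_U,ρ_L)dz / (½∫(ρ_U+ρ_L)dz) ∈ [0,1]`, trapezoidal
  on the shared grid. Absolute f_ov values are convention-dependent (bin
  width, overlap functional); the treated/control ratio D_int cancels the
  convention to first order and is the comparison statistic. The estimator
  is checked against a 10× finer Riemann refinement and for monotonicity
  in the builder's interpenetration offset.
- **|S_CD|** per tail carbon: |⟨(3cos²θ−1)/2⟩| of the C→H bond against
  +z, averaged over frames, lipids and hydrogens, per chain label.
  Invariant under rotation about z and xy translation (property-tested).
- **Hydrogen bonds** use the de facto geometric criterion, D–A ≤ 3.5 Å
  and H–D–A ≤ 30°, minimum image laterally; both thresholds configurable.
- **Averaging.** All per-frame metrics are mean ± sd over frames after
  discarding the first 20% (mirroring a 20-ns discard of a 100-ns run);
  the fraction is configurable in [0, 0.9]. Block averaging is not the
  default because plain frame statistics are what mean ± sd conventionally
  denotes here.

## Transport observables

- **Region classification.** The hydrophobic core is the contiguous
  interval around the midplane where tail density exceeds head density,
  bounded by the two linearly interpolated crossovers of the
  discard-window-averaged profile (per-frame mode would add noise for no
  benefit at these statistics).
- **K_p** is the ratio of time-summed probe counts inside vs outside the
  core, frame-instantaneous, over the post-discard window. It equals the
  ratio of mean indicator occupancies (algebraic identity, property-
  tested) and converges to the Boltzmann ratio on generator output.
- **MSD** uses every time origin (FFT autocorrelation formulation, exactly
  equal to the O(N²) double loop — asserted on ≤ 20-frame inputs), per
  component, with xy unwrapped by minimum-image displacement accumulation
  and z left bounded, lags to half the trajectory.
- **Diffusion** is OLS on MSD vs lag; D = slope/(2d), d ∈ {1, 2, 3}. The
  2–10 ns window is the default when the lags reach it and its fit clears
  r² ≥ 0.99; otherwise the longest candidate window clearing the floor is
  auto-selected and rejections are flagged. Non-positive slopes report
  D = 0 with a degenerate-fit flag rather than a negative coefficient.
- **Permeability** is the homogeneous solubility–diffusion estimate
  P_m = D_m·K_p/δ with δ in Å converted to cm. The inhomogeneous integral
  over local free-energy/diffusivity profiles is deliberately out of
  scope; the simplified formula is the contract. A "ratio of D_z to D_xy"
  has the wrong dimensions for a diffusion coefficient, so D_m defaults to
  D_z (membrane-normal transport governs crossing) and the anisotropy
  D_z/D_xy is reported alongside; the estimator is configurable ("dz",
  "xy", "3d").

## DSC parameterization

Baseline: linear through the median Cp of the first and last 10% of the
temperature range; ranges under 5 °C are refused, and edge medians
differing by more than 20% of the peak are flagged (sigmoidal baselines
are out of scope). Peaks: local maxima with prominence ≥ 5% of the global
maximum (plus an optional absolute floor for noise rejection); the
largest-area peak is the main transition, lower-temperature peaks are
pre-transitions; bounds extend to 1% of apex or a clear local minimum.
T_m: 3-point parabolic interpolation through the apex, so resolution beats
the sampling step (needed to resolve 0.1 °C shifts on 0.02 °C grids).
ΔT_b: full width at half maximum, interpolated linearly at the crossings —
FWHM is the convention that ties peak width to van't Hoff cooperativity;
widths measured at the baseline would not be comparable across
cooperativities. ΔH: trapezoid over the peak bounds; the 1%-of-apex bound
truncates ≈ 0.5% of a two-state peak's tails, which is within the 1%
recovery tolerance the tests assert and disappears for narrower windows of
interest (deltas between traces). ΔT_h = T_m(heating) − T_m(cooling),
sign preserved. Delta reports (ΔT_m, ΔΔT_b, ΔΔT_h, ΔΔH) use the heating
scan as reference; dose series are ordered by drug fraction and flagged
"biphasic" when the ΔT_m slope changes sign exactly once (≥ 3 ratios;
plateau extrema report the flat interval).

## Problem sizes

Defaults keep every stage desk-scale: 120-lipid single-type bilayers with
tens of frames for structure tests; 200–500 probes for 2·10⁴–10⁵ Langevin
steps for transport recovery; 1251-point thermograms (0.02 °C over
30–55 °C). These sizes give the stochastic assertions (10% on D, 15% on
K_p, 0.1 °C on noisy T_m) comfortable margins while the full suite runs in
well under a minute of simulation time.

## Known limitations

- The builder's single-chain lipids mean sn-1/sn-2 differences are label
  conventions, not geometry; two-chain lipids enter only via role tables.
- Reflecting-wall z confinement biases long-lag z-MSD; users must fit
  short lags or enlarge the box (the auto-window r² floor usually rejects
  the saturating regime on its own).
- Absolute f_ov depends on bin width and jitter; only ratios (D_int) are
  comparable across conventions.
- The DSC stage fits no multi-state deconvolution and applies no
  scan-rate correction; heating/cooling traces are analysed as given.
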