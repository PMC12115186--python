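"""Overdamped Langevin simulator for membrane-permeating probe particles.

Emulates small hydrophobic probes (nitric oxide in the study system)
partitioning between a hydrophobic slab ("core") and the hydrophilic
remainder of a periodic box, with region-dependent and optionally
anisotropic diffusivity. The generator's role is parameter recovery: the
partition coefficient of the analysis stage must converge to the Boltzmann
ratio implied by ``well_depth_kt``, and MSD regression must recover the
input diffusivities.

Scheme: Euler–Maruyama with per-axis step sd ``sqrt(2 D_axis dt)``.
Diffusivity and potential steps are smoothed over ~1 Å with tanh ramps, and
the Itô spurious-drift term ``dD_z/dz`` is included so that the stationary
z-distribution is exactly ``exp(-U(z)/kT)`` despite the space-dependent
diffusivity.
"""
from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .core import CM2_PER_S_TO_A2_PER_PS, ProbeTrajectory

__all__ = ["ProbeFieldSpec", "simulate_probes"]


@dataclass
class ProbeFieldSpec:
    """Parameters of the probe field and its Langevin integration.

    Diffusivities are given in cm²/s (the field's reporting unit) and
    converted to Å²/ps internally. ``well_depth_kt`` > 0 makes the core
    energetically favourable. ``anisotropy_core`` scales the z-diffusivity
    relative to the lateral one inside the core.
    """

    d_core: float = 1.0e-5        # cm²/s
    d_out: float = 1.0e-5         # cm²/s
    anisotropy_core: float = 1.0
    well_depth_kt: float = 0.0
    core_halfwidth: float = 15.0  # Å
    box_z: float = 80.0           # Å
    box_xy: float = 50.0          # Å lateral periodic box
    n_particles: int = 10
    dt: float = 1.0               # ps
    n_steps: int = 10_000
    record_every: int = 10        # output stride in steps
    z_boundary: str = "reflecting"  # or "periodic"
    smoothing_width: float = 1.0  # Å tanh ramp half-scale
    seed: int = 20240563

    def validate(self) -> None:
        if self.d_core <= 0 or self.d_out <= 0:
            raise ValueError("diffusivities must be positive")
        if not 0 < self.core_halfwidth < self.box_z / 2:
            raise ValueError("core_halfwidth must lie in (0, box_z/2)")
        if self.n_particles < 1:
            raise ValueError("n_particles must be >= 1")
        if self.dt <= 0 or self.n_steps < 1 or self.record_every < 1:
            raise ValueError("dt, n_steps and record_every must be positive")
        if self.z_boundary not in ("reflecting", "periodic"):
            raise ValueError("z_boundary must be 'reflecting' or 'periodic'")
        d_max = max(self.d_core * max(self.anisotropy_core, 1.0), self.d_out)
        step_sd = np.sqrt(2.0 * d_max * CM2_PER_S_TO_A2_PER_PS * self.dt)
        if step_sd > self.core_halfwidth / 4.0:
            raise ValueError(
                f"dt too large: rms step {step_sd:.2f} Å exceeds a quarter of "
                f"the core halfwidth ({self.core_halfwidth / 4:.2f} Å)"
            )


def _field(z: np.ndarray, spec: ProbeFieldSpec):
    """Smoothed core indicator s(z) and its derivative."""
    h, w = spec.core_halfwidth, spec.smoothing_width
    up = (z + h) / w
    dn = (z - h) / w
    s = 0.5 * (np.tanh(up) - np.tanh(dn))
    ds = 0.5 / w * (1.0 / np.cosh(up) ** 2 - 1.0 / np.cosh(dn) ** 2)
    return s, ds


def simulate_probes(spec: ProbeFieldSpec) -> ProbeTrajectory:
    """Run the Langevin dynamics and return recorded positions.

    z spans ``[-box_z/2, +box_z/2]`` with the core centred on 0; xy are
    periodic on ``[0, box_xy)`` and stored wrapped (the MSD stage unwraps
    by minimum image). The returned trajectory carries the ground-truth
    core boundaries ``(-core_halfwidth, +core_halfwidth)``.
    """
    spec.validate()
    rng = np.random.default_rng(spec.seed)

    d_core = spec.d_core * CM2_PER_S_TO_A2_PER_PS
    d_out = spec.d_out * CM2_PER_S_TO_A2_PER_PS
    dz_amp = spec.anisotropy_core * d_core - d_out  # z-diffusivity contrast
    dxy_amp = d_core - d_out

    n = spec.n_particles
    xy = rng.uniform(0.0, spec.box_xy, size=(n, 2))
    z = rng.uniform(-spec.box_z / 2, spec.box_z / 2, size=n)

    n_rec = spec.n_steps // spec.record_every + 1
    out = np.empty((n_rec, n, 3))
    out[0, :, :2] = xy
    out[0, :, 2] = z

    dt = spec.dt
    half_lz = spec.box_z / 2.0
    rec = 1
    for step in range(1, spec.n_steps + 1):
        s, ds = _field(z, spec)
        d_z = d_out + dz_amp * s
        d_xy = d_out + dxy_amp * s
        # U(z)/kT = -well * s(z)  =>  -D_z U' = D_z * well * ds
        drift = (d_z * spec.well_depth_kt + dz_amp) * ds
        noise = rng.standard_normal(size=(n, 3))
        xy += np.sqrt(2.0 * d_xy * dt)[:, None] * noise[:, :2]
        z = z + drift * dt + np.sqrt(2.0 * d_z * dt) * noise[:, 2]

        xy %= spec.box_xy
        if spec.z_boundary == "reflecting":
            # fold into [-L/2, L/2] by triangle-wave reflection
            z = spec.box_z - np.abs((z + half_lz) % (2.0 * spec.box_z) - spec.box_z) - half_lz
        else:
            z = (z + half_lz) % spec.box_z - half_lz

        if step % spec.record_every == 0:
            out[rec, :, :2] = xy
            out[rec, :, 2] = z
            rec += 1

    times = dt * spec.record_every * np.arange(n_rec, dtype=float)
    boxes = np.tile(np.array([spec.box_xy, spec.box_xy, spec.box_z]), (n_rec, 1))
    return ProbeTrajectory(
        times=times, positions=out, boxes=boxes,
        region_boundaries=(-spec.core_halfwidth, spec.core_halfwidth),
    )


def boltzmann_partition(spec: ProbeFieldSpec) -> float:
    """Predicted K_p for the smoothed well: ∫_core e^{-U} / ∫_out e^{-U}.

    Independent of the dynamics — the oracle for partition-coefficient
    recovery tests.
    """
    zg = np.linspace(-spec.box_z / 2, spec.box_z / 2, 20001)
    s, _ = _field(zg, spec)
    w = np.exp(spec.well_depth_kt * s)
    inside = np.abs(zg) <= spec.core_halfwidth
    num = np.trapezoid(np.where(inside, w, 0.0), zg)
    den = np.trapezoid(np.where(~inside, w, 0.0), zg)
    return float(num / den)
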