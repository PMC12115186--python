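"""Geometric bilayer generator with fully known ground truth.

Lipids are idealized bead-chains: one lumped headgroup bead (the head
reference / thickness plane atom) above a single all-trans acyl chain of
``n_tail_carbons`` carbons, each carrying two geometric hydrogens
perpendicular to the local chain axis. The construction is geometric, not
physical — the point is that every structural observable of the analysis
stages (area per lipid, thickness, |SCD|, leaflet mass overlap) has an
exact, spec-level ground truth to recover.

Leaflet interpenetration is parameterized directly: ``interdigitation_offset``
is the distance the tail termini of each leaflet reach past the bilayer
midplane (≤ 0 keeps the leaflets separated). The mapping from this offset to
the mass-overlap fraction is monotone; the analysis stage, not the builder,
owns the overlap convention.
"""
from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .core import Trajectory

__all__ = ["LipidType", "BilayerSpec", "build_bilayer"]

#: time between generated frames, ps (trajectory-recording cadence).
FRAME_SPACING_PS = 10.0
CH_BOND_LENGTH = 1.09  # Å


@dataclass
class LipidType:
    """One lipid species of the idealized bilayer.

    ``head_mass`` lumps the whole headgroup (phosphocholine + glycerol)
    into the single head bead; the chain carries ``n_tail_carbons`` CH₂
    beads split into an explicit carbon and two hydrogens.
    """

    name: str = "DPPC"
    count_per_leaflet: int = 60
    n_tail_carbons: int = 16
    head_mass: float = 224.0
    carbon_mass: float = 12.011
    hydrogen_mass: float = 1.008


@dataclass
class BilayerSpec:
    """Parameters of the synthetic bilayer.

    Defaults emulate the study system: a 120-lipid (60 per leaflet) DPPC
    membrane in the gel state — small area per lipid, modest collective
    chain tilt, leaflets meeting near the midplane.
    """

    lipid_types: list[LipidType] = field(default_factory=lambda: [LipidType()])
    target_apl: float = 47.0            # Å², gel-phase DPPC scale
    head_region_halfwidth: float = 4.0  # Å, head bead height above chain start
    tail_tilt_deg: float = 0.0          # collective tilt from the normal
    interdigitation_offset: float = 0.0  # Å past the midplane (≤0 = separated)
    carbon_spacing: float = 1.27        # Å C–C z-projection before tilt
    n_frames: int = 1
    thermal_jitter_sd: float = 0.0      # Å, per-coordinate Gaussian
    probe_count: int = 0
    drug_count: int = 0
    probe_mass: float = 30.006          # NO
    drug_mass: float = 488.6            # vardenafil-scale small molecule
    drug_insertion_depth: float = 2.0   # Å below the head plane (free parameter)
    water_margin: float = 15.0          # Å of empty "solvent" space per side
    seed: int = 20240563

    def validate(self) -> None:
        if not self.lipid_types:
            raise ValueError("at least one lipid type is required")
        if self.target_apl <= 0:
            raise ValueError("target_apl must be positive")
        for lt in self.lipid_types:
            if lt.n_tail_carbons < 2:
                raise ValueError("n_tail_carbons must be >= 2")
            if lt.count_per_leaflet < 1:
                raise ValueError("count_per_leaflet must be >= 1")
        if self.n_frames < 1:
            raise ValueError("n_frames must be >= 1")
        if self.thermal_jitter_sd < 0:
            raise ValueError("thermal_jitter_sd must be >= 0")
        if not 0.0 <= self.tail_tilt_deg < 90.0:
            raise ValueError("tail_tilt_deg must be in [0, 90)")


def _chain_extent(lt: LipidType, spec: BilayerSpec) -> float:
    cos_t = math.cos(math.radians(spec.tail_tilt_deg))
    return (lt.n_tail_carbons - 1) * spec.carbon_spacing * cos_t


def _perpendicular_pair(u: np.ndarray, phi: float) -> tuple[np.ndarray, np.ndarray]:
    """Two orthonormal vectors perpendicular to the chain axis ``u``."""
    zhat = np.array([0.0, 0.0, 1.0])
    a = np.cross(u, zhat)
    norm = np.linalg.norm(a)
    if norm < 1e-9:  # untilted chain: any lateral direction works
        a = np.array([math.cos(phi), math.sin(phi), 0.0])
    else:
        a = a / norm
    b = np.cross(u, a)
    b = b / np.linalg.norm(b)
    return a, b


def build_bilayer(spec: BilayerSpec) -> Trajectory:
    """Construct the bilayer and return it as a :class:`Trajectory`.

    The lateral box area is exactly ``N_per_leaflet × target_apl``; head
    beads sit on the smallest enclosing square grid (vacancies allowed when
    the count is not a perfect square). The z origin of the stored
    coordinates puts the bilayer midplane at ``Lz/2``. Reproducible: the
    same spec and seed give bit-identical output.
    """
    spec.validate()
    rng = np.random.default_rng(spec.seed)

    n_leaflet = sum(lt.count_per_leaflet for lt in spec.lipid_types)
    lx = ly = math.sqrt(n_leaflet * spec.target_apl)
    n_side = math.ceil(math.sqrt(n_leaflet))
    spacing = lx / n_side

    tilt = math.radians(spec.tail_tilt_deg)
    # head height above the midplane, per type
    head_z = {}
    for lt in spec.lipid_types:
        hz = -spec.interdigitation_offset + _chain_extent(lt, spec) + spec.head_region_halfwidth
        if hz <= 0:
            raise ValueError(
                f"negative geometry for {lt.name}: head plane at z={hz:.2f} Å "
                "is at or below the midplane (offset too large for the chain length)"
            )
        head_z[lt.name] = hz
    z_top = max(head_z.values()) + spec.water_margin
    lz = 2.0 * z_top
    mid = lz / 2.0

    rows: list[dict] = []
    xyz: list[np.ndarray] = []
    atom_id = 0
    residue_id = 0

    def add_atom(name, element, mass, resname, mclass, role, chain, k, pos):
        nonlocal atom_id
        atom_id += 1
        rows.append(dict(
            atom_id=atom_id, atom_name=name, element=element, mass=mass,
            residue_id=residue_id, residue_name=resname, molecule_class=mclass,
            role=role, chain=chain, carbon_index=k,
        ))
        xyz.append(np.asarray(pos, dtype=float))

    # lateral grid sites, identical layout in both leaflets
    sites = [((i + 0.5) * spacing, (j + 0.5) * spacing)
             for j in range(n_side) for i in range(n_side)][:n_leaflet]

    lipid_seq: list[LipidType] = []
    for lt in spec.lipid_types:
        lipid_seq.extend([lt] * lt.count_per_leaflet)

    lipid_counter = 0
    for sign in (+1, -1):  # upper, then lower leaflet
        for (x0, y0), lt in zip(sites, lipid_seq):
            residue_id += 1
            chain_label = "sn-1" if lipid_counter % 2 == 0 else "sn-2"
            lipid_counter += 1
            phi = float(rng.uniform(0.0, 2.0 * math.pi))
            # chain axis points from head side toward (and possibly past) the midplane
            u = np.array([
                math.sin(tilt) * math.cos(phi),
                math.sin(tilt) * math.sin(phi),
                -sign * math.cos(tilt),
            ])
            z1 = sign * (head_z[lt.name] - spec.head_region_halfwidth)  # first carbon
            c1 = np.array([x0, y0, mid + z1])
            add_atom("HED", "P", lt.head_mass, lt.name, "lipid", "head_ref",
                     "", -1, c1 + np.array([0.0, 0.0, sign * spec.head_region_halfwidth]))
            a, b = _perpendicular_pair(u, phi)
            for k in range(1, lt.n_tail_carbons + 1):
                c = c1 + (k - 1) * spec.carbon_spacing * u
                add_atom(f"C{k}", "C", lt.carbon_mass, lt.name, "lipid",
                         "tail_carbon", chain_label, k, c)
                add_atom(f"H{k}A", "H", lt.hydrogen_mass, lt.name, "lipid",
                         "tail_hydrogen", chain_label, k, c + CH_BOND_LENGTH * a)
                add_atom(f"H{k}B", "H", lt.hydrogen_mass, lt.name, "lipid",
                         "tail_hydrogen", chain_label, k, c + CH_BOND_LENGTH * b)

    head_plane = max(head_z.values())
    for i in range(spec.probe_count):
        residue_id += 1
        sign = +1 if i % 2 == 0 else -1
        pos = np.array([rng.uniform(0, lx), rng.uniform(0, ly),
                        mid + sign * head_plane])
        add_atom("NO", "N", spec.probe_mass, "NO", "probe", "other", "", -1, pos)
    for i in range(spec.drug_count):
        residue_id += 1
        sign = +1 if i % 2 == 0 else -1
        pos = np.array([rng.uniform(0, lx), rng.uniform(0, ly),
                        mid + sign * (head_plane - spec.drug_insertion_depth)])
        add_atom("DRG", "C", spec.drug_mass, "DRG", "drug", "other", "", -1, pos)

    atoms = pd.DataFrame(rows)
    base = np.stack(xyz)
    coords = np.repeat(base[None, :, :], spec.n_frames, axis=0)
    if spec.thermal_jitter_sd > 0:
        coords = coords + rng.normal(0.0, spec.thermal_jitter_sd, size=coords.shape)
    times = FRAME_SPACING_PS * np.arange(spec.n_frames, dtype=float)
    boxes = np.tile(np.array([lx, ly, lz]), (spec.n_frames, 1))
    return Trajectory(atoms=atoms, times=times, coords=coords, boxes=boxes)


def lipid_mass(spec: BilayerSpec) -> float:
    """Exact total lipid mass implied by the spec (both leaflets)."""
    total = 0.0
    for lt in spec.lipid_types:
        per_lipid = lt.head_mass + lt.n_tail_carbons * (lt.carbon_mass + 2 * lt.hydrogen_mass)
        total += 2 * lt.count_per_leaflet * per_lipid
    return total
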