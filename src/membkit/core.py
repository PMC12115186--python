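"""Shared domain containers and unit conventions.

One unit system holds at every in-memory interface: lengths in Å, times in
ps, masses in amu, energies in kcal/mol, temperatures in °C. Conversions
(nm in GRO files, cm²/s for diffusion coefficients, K inside van't Hoff
formulas) happen only at the boundaries where those units are conventional.
"""
from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

# Boundary conversion factors.
ANGSTROM_PER_NM = 10.0
CM2_PER_S_TO_A2_PER_PS = 1.0e4   # 1 cm²/s = 1e16 Å² / 1e12 ps
A2_PER_PS_TO_CM2_PER_S = 1.0e-4
CM_PER_ANGSTROM = 1.0e-8

# Gas constant in kcal/(mol·K) and the Celsius offset.
R_KCAL = 1.987204259e-3
ZERO_CELSIUS_K = 273.15

#: Columns every atom table must carry. ``chain`` and ``carbon_index`` are
#: meaningful only for tail_carbon / tail_hydrogen roles (empty string / -1
#: otherwise).
ATOM_COLUMNS = (
    "atom_id", "atom_name", "element", "mass",
    "residue_id", "residue_name", "molecule_class",
    "role", "chain", "carbon_index",
)

MOLECULE_CLASSES = ("lipid", "probe", "drug", "solvent")
ROLES = ("head_ref", "phosphate", "tail_carbon", "tail_hydrogen", "other")


@dataclass
class MeanSd:
    """A mean ± standard deviation pair (sd over frames)."""

    mean: float
    sd: float

    def __iter__(self):
        yield self.mean
        yield self.sd

    def __repr__(self) -> str:  # pragma: no cover - cosmetic
        return f"{self.mean:g} ± {self.sd:g}"


def validate_atoms(atoms: pd.DataFrame) -> pd.DataFrame:
    """Check an atom table against the schema and return it.

    Raises ``ValueError`` on missing columns, non-positive masses, or a
    tail hydrogen whose (residue, chain, carbon) has no matching carbon.
    """
    missing = [c for c in ATOM_COLUMNS if c not in atoms.columns]
    if missing:
        raise ValueError(f"atom table missing columns: {missing}")
    if (atoms["mass"] <= 0).any():
        bad = atoms.loc[atoms["mass"] <= 0, "atom_id"].tolist()
        raise ValueError(f"non-positive mass for atom ids {bad[:5]}")
    hyd = atoms[atoms["role"] == "tail_hydrogen"]
    if len(hyd):
        carb = atoms[atoms["role"] == "tail_carbon"]
        ckeys = set(zip(carb["residue_id"], carb["chain"], carb["carbon_index"]))
        hkeys = set(zip(hyd["residue_id"], hyd["chain"], hyd["carbon_index"]))
        orphans = hkeys - ckeys
        if orphans:
            raise ValueError(
                f"tail hydrogens without a matching tail carbon: {sorted(orphans)[:5]}"
            )
    return atoms


@dataclass
class Trajectory:
    """Time-ordered coordinates of a role-annotated atom set.

    Attributes
    ----------
    atoms : pandas.DataFrame
        One row per atom with :data:`ATOM_COLUMNS`.
    times : (n_frames,) ndarray, ps.
    coords : (n_frames, n_atoms, 3) ndarray, Å.
    boxes : (n_frames, 3) ndarray, Å — orthorhombic (Lx, Ly, Lz) per frame.
    """

    atoms: pd.DataFrame
    times: np.ndarray
    coords: np.ndarray
    boxes: np.ndarray

    def __post_init__(self) -> None:
        self.times = np.asarray(self.times, dtype=float)
        self.coords = np.asarray(self.coords, dtype=float)
        self.boxes = np.asarray(self.boxes, dtype=float)
        if self.coords.ndim != 3 or self.coords.shape[2] != 3:
            raise ValueError("coords must have shape (n_frames, n_atoms, 3)")
        if self.coords.shape[1] != len(self.atoms):
            raise ValueError(
                f"coordinate count ({self.coords.shape[1]}) differs from "
                f"atom-table length ({len(self.atoms)})"
            )
        if self.boxes.shape != (self.coords.shape[0], 3):
            raise ValueError("boxes must have shape (n_frames, 3)")
        if (self.boxes <= 0).any():
            raise ValueError("box lengths must be positive")
        validate_atoms(self.atoms)

    @property
    def n_frames(self) -> int:
        return self.coords.shape[0]

    @property
    def n_atoms(self) -> int:
        return self.coords.shape[1]

    def frame_slice(self, start: int, stop: int | None = None) -> "Trajectory":
        """A view-style sub-trajectory over frames ``start:stop``."""
        sl = slice(start, stop)
        return Trajectory(self.atoms, self.times[sl], self.coords[sl], self.boxes[sl])


@dataclass
class DensityProfile:
    """Mass density along the membrane normal for one or more selections.

    ``densities`` maps a selection label to a (n_bins,) array in amu/Å³,
    averaged over ``frame_count`` frames on a common z grid centred on the
    per-frame midplane.
    """

    bin_centers: np.ndarray
    bin_width: float
    densities: dict[str, np.ndarray]
    frame_count: int
    lateral_area: float  # mean Lx·Ly over included frames, Å²

    def integral(self, label: str) -> float:
        """∫ρ(z)dz for one selection, amu/Å² (a rectangle-rule sum, which is
        exact for histogram densities)."""
        return float(np.sum(self.densities[label]) * self.bin_width)


@dataclass
class ProbeTrajectory:
    """Positions of probe particles through time.

    positions : (n_frames, n_particles, 3) ndarray, Å; xy wrapped into the
    periodic box, z bounded.
    """

    times: np.ndarray
    positions: np.ndarray
    boxes: np.ndarray
    region_boundaries: tuple[float, float] | None = None

    def __post_init__(self) -> None:
        self.times = np.asarray(self.times, dtype=float)
        self.positions = np.asarray(self.positions, dtype=float)
        self.boxes = np.asarray(self.boxes, dtype=float)
        dt = np.diff(self.times)
        if len(dt) and (dt <= 0).any():
            raise ValueError("times must be strictly increasing")
        if len(dt) > 1 and not np.allclose(dt, dt[0], rtol=1e-8):
            raise ValueError("times must be uniformly spaced")
        if self.region_boundaries is not None:
            lo, hi = self.region_boundaries
            if not lo < hi:
                raise ValueError("region boundaries require z_low < z_high")

    @property
    def n_frames(self) -> int:
        return self.positions.shape[0]

    @property
    def n_particles(self) -> int:
        return self.positions.shape[1]

    @property
    def dt(self) -> float:
        return float(self.times[1] - self.times[0])


def celsius_to_kelvin(t_c):
    return np.asarray(t_c, dtype=float) + ZERO_CELSIUS_K


def warn(msg: str) -> None:
    warnings.warn(msg, stacklevel=3)
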