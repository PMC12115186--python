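"""Shared fixtures: hand-built micro-trajectories and builder systems."""
from __future__ import annotations

import numpy as np
import pandas as pd
import pytest

from membkit import BilayerSpec, Trajectory, build_bilayer


def make_atoms(rows: list[dict]) -> pd.DataFrame:
    """Atom table from partial dicts; missing schema columns get defaults."""
    defaults = dict(atom_name="X", element="C", mass=12.011,
                    residue_name="MOL", molecule_class="lipid",
                    role="other", chain="", carbon_index=-1)
    full = []
    for i, r in enumerate(rows, start=1):
        d = dict(defaults, atom_id=i, residue_id=r.get("residue_id", i))
        d.update(r)
        full.append(d)
    return pd.DataFrame(full)


def make_traj(rows: list[dict], coords, box=(60.0, 60.0, 100.0), times=None):
    """Trajectory from partial atom dicts and (n_frames, n_atoms, 3) coords."""
    coords = np.asarray(coords, dtype=float)
    if coords.ndim == 2:
        coords = coords[None]
    n_frames = coords.shape[0]
    if times is None:
        times = 10.0 * np.arange(n_frames)
    boxes = np.tile(np.asarray(box, dtype=float), (n_frames, 1))
    return Trajectory(atoms=make_atoms(rows), times=np.asarray(times, float),
                      coords=coords, boxes=boxes)


def two_lipid_rows(z_upper=20.0, z_lower=-20.0, box=(60.0, 60.0, 100.0)):
    """Minimal two-lipid system: one head_ref per lipid at ±z."""
    rows = [
        dict(residue_id=1, residue_name="DPPC", role="head_ref", atom_name="HED",
             element="P", mass=224.0),
        dict(residue_id=2, residue_name="DPPC", role="head_ref", atom_name="HED",
             element="P", mass=224.0),
    ]
    coords = [[10.0, 10.0, 50.0 + z_upper], [30.0, 30.0, 50.0 + z_lower]]
    return make_traj(rows, coords, box=box)


@pytest.fixture(scope="session")
def gel_bilayer():
    """Jitter-free single-frame default bilayer (exact ground truth)."""
    return build_bilayer(BilayerSpec(n_frames=1, thermal_jitter_sd=0.0))


@pytest.fixture(scope="session")
def noisy_bilayer():
    """Small jittered multi-frame bilayer for statistics-path tests."""
    spec = BilayerSpec(
        lipid_types=[__import__("membkit").LipidType(count_per_leaflet=16)],
        n_frames=10, thermal_jitter_sd=0.4, seed=7,
    )
    return build_bilayer(spec)


def tail_masks(traj: Trajectory):
    atoms = traj.atoms
    heads = (atoms["role"] == "head_ref").to_numpy()
    tails = atoms["role"].isin(["tail_carbon", "tail_hydrogen"]).to_numpy()
    return heads, tails
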