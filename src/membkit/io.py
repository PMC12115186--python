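"""Readers and writers for trajectory, role-table and thermogram files.

Supported trajectory dialects: multi-frame (concatenated) GRO with the box
on the final line of each frame, multi-MODEL PDB with a CRYST1 box (read
through MDAnalysis), and an extended-XYZ subset with a ``Lattice="..."``
comment. In-file GRO units are nm; everything in memory is Å — the
conversion happens here and nowhere else.

Atom roles (head reference, phosphate, tail carbons/hydrogens) come from a
role-annotation CSV keyed on (residue_name, atom_name); unmatched atoms
fall back to role ``other`` with a logged count.
"""
from __future__ import annotations

import logging
from pathlib import Path

import numpy as np
import pandas as pd

from .core import ANGSTROM_PER_NM, Trajectory, warn
from .dsc import Thermogram

__all__ = [
    "read_trajectory", "write_gro", "read_role_table", "apply_roles",
    "write_thermogram_csv", "read_thermogram_csv",
    "write_probe_csv", "read_probe_csv",
]

log = logging.getLogger("membkit.io")

_ELEMENT_MASS = {"H": 1.008, "C": 12.011, "N": 14.007, "O": 15.999,
                 "P": 30.974, "S": 32.06}


def _guess_element(atom_name: str) -> str:
    for ch in atom_name:
        if ch.isalpha():
            return ch.upper()
    return "C"


# ------------------------------------------------------------------ roles

def read_role_table(path: str | Path) -> pd.DataFrame:
    """Role-annotation CSV with columns residue_name, atom_name, role, mass,
    element (optional: molecule_class).

    ``role`` accepts the parenthesized tail syntax ``tail_carbon(sn-1,4)``
    / ``tail_hydrogen(sn-2,7)``; chain and carbon index are split out.
    Duplicate (residue_name, atom_name) keys with conflicting entries are
    an error.
    """
    df = pd.read_csv(path, comment="#", skipinitialspace=True,
                     dtype={"residue_name": str, "atom_name": str})
    if df.empty:
        warn(f"role table {path} is empty; all atoms default to role=other")
        return pd.DataFrame(columns=["residue_name", "atom_name", "role",
                                     "mass", "element", "molecule_class",
                                     "chain", "carbon_index"])
    required = {"residue_name", "atom_name", "role"}
    missing = required - set(df.columns)
    if missing:
        raise ValueError(f"role table missing columns: {sorted(missing)}")
    dup = df.duplicated(subset=["residue_name", "atom_name"], keep=False)
    if dup.any():
        conflicting = df[dup].drop_duplicates()
        if len(conflicting) != len(df[dup].drop_duplicates(
                subset=["residue_name", "atom_name"])):
            keys = df[dup][["residue_name", "atom_name"]].drop_duplicates()
            raise ValueError(
                f"conflicting duplicate role rows for keys: {keys.values.tolist()[:5]}")
        df = df.drop_duplicates(subset=["residue_name", "atom_name"])

    chains, ks, bare = [], [], []
    for r in df["role"]:
        r = str(r).strip()
        if "(" in r:
            name, args = r.split("(", 1)
            chain, k = args.rstrip(")").split(",")
            bare.append(name.strip())
            chains.append(chain.strip())
            ks.append(int(k))
        else:
            bare.append(r)
            chains.append("")
            ks.append(-1)
    df = df.assign(role=bare, chain=chains, carbon_index=ks)
    if "molecule_class" not in df.columns:
        df["molecule_class"] = np.where(df["role"] == "other", "solvent", "lipid")
    if "element" not in df.columns:
        df["element"] = [_guess_element(a) for a in df["atom_name"]]
    if "mass" not in df.columns:
        df["mass"] = [_ELEMENT_MASS.get(e, 12.0) for e in df["element"]]
    return df


def apply_roles(atoms: pd.DataFrame, roles: pd.DataFrame | None) -> pd.DataFrame:
    """Annotate a bare atom table (names/residues only) with roles.

    Matching is exact on (residue_name, atom_name); unmatched atoms get
    role ``other`` / class ``solvent`` with element-guessed masses, and
    their count is logged.
    """
    out = atoms.copy()
    out["element"] = [_guess_element(a) for a in out["atom_name"]]
    out["mass"] = [_ELEMENT_MASS.get(e, 12.0) for e in out["element"]]
    out["molecule_class"] = "solvent"
    out["role"] = "other"
    out["chain"] = ""
    out["carbon_index"] = -1
    if roles is not None and len(roles):
        key = ["residue_name", "atom_name"]
        idx = roles.set_index(key)
        matched = 0
        for i, row in out.iterrows():
            k = (row["residue_name"], row["atom_name"])
            if k in idx.index:
                r = idx.loc[k]
                out.at[i, "role"] = r["role"]
                out.at[i, "chain"] = r.get("chain", "")
                out.at[i, "carbon_index"] = int(r.get("carbon_index", -1))
                out.at[i, "molecule_class"] = r.get(
                    "molecule_class",
                    "solvent" if r["role"] == "other" else "lipid")
                if not pd.isna(r.get("mass")):
                    out.at[i, "mass"] = float(r["mass"])
                if isinstance(r.get("element"), str):
                    out.at[i, "element"] = r["element"]
                matched += 1
        unmatched = len(out) - matched
        if unmatched:
            log.info("%d/%d atoms unmatched by the role table (role=other)",
                     unmatched, len(out))
    return out


def roles_from_trajectory(traj: Trajectory) -> pd.DataFrame:
    """Role table equivalent to a (synthetic) trajectory's annotation."""
    cols = ["residue_name", "atom_name", "role", "mass", "element",
            "molecule_class", "chain", "carbon_index"]
    df = traj.atoms[["residue_name", "atom_name", "role", "mass", "element",
                     "molecule_class", "chain", "carbon_index"]].copy()
    df = df.drop_duplicates(subset=["residue_name", "atom_name"])
    # re-join parenthesized syntax for the tail roles
    role = []
    for _, r in df.iterrows():
        if r["role"] in ("tail_carbon", "tail_hydrogen"):
            role.append(f"{r['role']}({r['chain']},{r['carbon_index']})")
        else:
            role.append(r["role"])
    df = df.assign(role=role)
    return df[cols]


# -------------------------------------------------------------------- GRO

def write_gro(traj: Trajectory, path: str | Path) -> None:
    """Write all frames as concatenated GRO (nm in file, box per frame)."""
    atoms = traj.atoms
    with open(path, "w") as fh:
        for f in range(traj.n_frames):
            fh.write(f"membkit t= {traj.times[f]:.5f}\n")
            fh.write(f"{traj.n_atoms:5d}\n")
            xyz_nm = traj.coords[f] / ANGSTROM_PER_NM
            for i in range(traj.n_atoms):
                a = atoms.iloc[i]
                fh.write("%5d%-5s%5s%5d%8.3f%8.3f%8.3f\n" % (
                    int(a["residue_id"]) % 100000, str(a["residue_name"])[:5],
                    str(a["atom_name"])[:5], int(a["atom_id"]) % 100000,
                    xyz_nm[i, 0], xyz_nm[i, 1], xyz_nm[i, 2]))
            box_nm = traj.boxes[f] / ANGSTROM_PER_NM
            fh.write("%10.5f%10.5f%10.5f\n" % tuple(box_nm))


def _read_gro(path: Path) -> tuple[pd.DataFrame, list, list, list]:
    frames, boxes, times = [], [], []
    atom_rows = None
    with open(path) as fh:
        lines = fh.read().splitlines()
    pos = 0
    frame_no = 0
    while pos < len(lines):
        if not lines[pos].strip():
            pos += 1
            continue
        title = lines[pos]
        try:
            n = int(lines[pos + 1])
        except (IndexError, ValueError) as exc:
            raise ValueError(f"malformed GRO frame header at line {pos + 1}") from exc
        t = None
        if " t=" in title:
            try:
                t = float(title.split(" t=")[1].split()[0])
            except (IndexError, ValueError):
                t = None
        rows, xyz = [], []
        for j in range(n):
            ln = lines[pos + 2 + j]
            rows.append((int(ln[0:5]), ln[5:10].strip(), ln[10:15].strip(),
                         int(ln[15:20])))
            xyz.append((float(ln[20:28]), float(ln[28:36]), float(ln[36:44])))
        box = [float(v) for v in lines[pos + 2 + n].split()[:3]]
        if atom_rows is None:
            atom_rows = rows
        elif len(rows) != len(atom_rows):
            raise ValueError(
                f"inconsistent atom count in GRO frame {frame_no}: "
                f"{len(rows)} vs {len(atom_rows)}")
        frames.append(np.array(xyz) * ANGSTROM_PER_NM)
        boxes.append(np.array(box) * ANGSTROM_PER_NM)
        times.append(t)
        pos += n + 3
        frame_no += 1
    if atom_rows is None:
        raise ValueError(f"no frames found in {path}")
    atoms = pd.DataFrame(atom_rows,
                         columns=["residue_id", "residue_name", "atom_name",
                                  "atom_id"])
    return atoms, frames, boxes, times


def _read_pdb(path: Path) -> tuple[pd.DataFrame, list, list, list]:
    import MDAnalysis as mda
    cryst_box = None
    with open(path) as fh:
        for line in fh:
            if line.startswith("CRYST1"):
                cryst_box = np.array([float(line[6:15]), float(line[15:24]),
                                      float(line[24:33])])
                break
    if cryst_box is None:
        raise ValueError("PDB lacks a CRYST1 record; box dimensions are required")
    u = mda.Universe(str(path))
    atoms = pd.DataFrame({
        "residue_id": u.atoms.resids.astype(int),
        "residue_name": u.atoms.resnames,
        "atom_name": u.atoms.names,
        "atom_id": np.arange(1, len(u.atoms) + 1),
    })
    frames, boxes, times = [], [], []
    for ts in u.trajectory:
        frames.append(ts.positions.copy().astype(float))
        if ts.dimensions is not None:  # per-MODEL CRYST1 takes precedence
            boxes.append(np.asarray(ts.dimensions[:3], dtype=float))
        else:
            boxes.append(cryst_box.copy())
        times.append(float(ts.time) if ts.time is not None else None)
    return atoms, frames, boxes, times


def _read_xyz(path: Path) -> tuple[pd.DataFrame, list, list, list]:
    frames, boxes, times = [], [], []
    atom_rows = None
    with open(path) as fh:
        lines = fh.read().splitlines()
    pos = 0
    frame_no = 0
    while pos < len(lines):
        if not lines[pos].strip():
            pos += 1
            continue
        n = int(lines[pos])
        comment = lines[pos + 1]
        if 'Lattice="' not in comment:
            raise ValueError("extended XYZ requires a Lattice=\"...\" comment")
        lat = [float(v) for v in
               comment.split('Lattice="')[1].split('"')[0].split()]
        box = np.array([lat[0], lat[4], lat[8]])
        t = None
        for tok in comment.split():
            if tok.startswith("Time="):
                t = float(tok.split("=")[1])
        rows, xyz = [], []
        for j in range(n):
            parts = lines[pos + 2 + j].split()
            rows.append((1, "MOL", parts[0], j + 1))
            xyz.append([float(v) for v in parts[1:4]])
        if atom_rows is None:
            atom_rows = rows
        elif len(rows) != len(atom_rows):
            raise ValueError(f"inconsistent atom count in XYZ frame {frame_no}")
        frames.append(np.asarray(xyz, dtype=float))
        boxes.append(box)
        times.append(t)
        pos += n + 2
        frame_no += 1
    if atom_rows is None:
        raise ValueError(f"no frames found in {path}")
    atoms = pd.DataFrame(atom_rows, columns=["residue_id", "residue_name",
                                             "atom_name", "atom_id"])
    return atoms, frames, boxes, times


_READERS = {"gro": _read_gro, "pdb": _read_pdb, "xyz": _read_xyz}


def read_trajectory(path: str | Path, fmt: str | None = None,
                    roles: pd.DataFrame | str | Path | None = None) -> Trajectory:
    """Read a multi-frame trajectory and annotate it with roles.

    ``fmt`` defaults to the file extension. Missing frame times fall back
    to uniform 1-ps spacing with a warning.
    """
    path = Path(path)
    fmt = (fmt or path.suffix.lstrip(".")).lower()
    if fmt not in _READERS:
        raise ValueError(f"unknown trajectory format '{fmt}'; "
                         f"supported: {sorted(_READERS)}")
    atoms, frames, boxes, times = _READERS[fmt](path)
    if isinstance(roles, (str, Path)):
        roles = read_role_table(roles)
    atoms = apply_roles(atoms, roles)
    if any(t is None for t in times):
        warn("frame times missing; assuming uniform 1 ps spacing")
        times = [float(i) for i in range(len(frames))]
    return Trajectory(atoms=atoms, times=np.asarray(times, dtype=float),
                      coords=np.stack(frames), boxes=np.stack(boxes))


# ------------------------------------------------------------ thermograms

def write_thermogram_csv(trace: Thermogram, path: str | Path) -> None:
    with open(path, "w") as fh:
        fh.write(f"# direction={trace.direction}\n")
        fh.write(f"# scan_rate_C_per_min={trace.scan_rate}\n")
        fh.write("temperature_C,cp_kcal_per_mol_C\n")
        for t, c in zip(trace.temperature, trace.cp_excess):
            fh.write(f"{t:.6g},{c:.10g}\n")


def read_thermogram_csv(path: str | Path) -> Thermogram:
    direction, rate = "heating", 0.2
    with open(path) as fh:
        for line in fh:
            if not line.startswith("#"):
                break
            body = line[1:].strip()
            if body.startswith("direction="):
                direction = body.split("=", 1)[1]
            elif body.startswith("scan_rate_C_per_min="):
                rate = float(body.split("=", 1)[1])
    df = pd.read_csv(path, comment="#")
    return Thermogram(temperature=df["temperature_C"].to_numpy(),
                      cp_excess=df["cp_kcal_per_mol_C"].to_numpy(),
                      direction=direction, scan_rate=rate,
                      label=str(Path(path).stem))


# ------------------------------------------------------- probe trajectories

def write_probe_csv(ptraj, path: str | Path) -> None:
    """Probe trajectory as long-format CSV (time_ps, particle, x, y, z)."""
    with open(path, "w") as fh:
        bx, by, bz = ptraj.boxes[0]
        fh.write(f"# box_xy={bx:.6g} box_z={bz:.6g}\n")
        if ptraj.region_boundaries is not None:
            lo, hi = ptraj.region_boundaries
            fh.write(f"# core_z_low={lo:.6g} core_z_high={hi:.6g}\n")
        fh.write("time_ps,particle,x,y,z\n")
        for f in range(ptraj.n_frames):
            t = ptraj.times[f]
            for p in range(ptraj.n_particles):
                x, y, z = ptraj.positions[f, p]
                fh.write(f"{t:.6g},{p},{x:.6g},{y:.6g},{z:.6g}\n")


def read_probe_csv(path: str | Path):
    from .core import ProbeTrajectory
    box_xy = box_z = None
    bounds = None
    with open(path) as fh:
        for line in fh:
            if not line.startswith("#"):
                break
            toks = dict(t.split("=") for t in line[1:].split())
            if "box_xy" in toks:
                box_xy, box_z = float(toks["box_xy"]), float(toks["box_z"])
            if "core_z_low" in toks:
                bounds = (float(toks["core_z_low"]), float(toks["core_z_high"]))
    df = pd.read_csv(path, comment="#")
    times = np.sort(df["time_ps"].unique())
    n_p = df["particle"].nunique()
    pos = (df.sort_values(["time_ps", "particle"])[["x", "y", "z"]]
           .to_numpy().reshape(len(times), n_p, 3))
    if box_xy is None:
        raise ValueError("probe CSV lacks the box header line")
    boxes = np.tile([box_xy, box_xy, box_z], (len(times), 1))
    return ProbeTrajectory(times=times, positions=pos, boxes=boxes,
                           region_boundaries=bounds)
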