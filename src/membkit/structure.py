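"""Bilayer structural observables.

Implements the structural analysis battery for role-annotated bilayer
trajectories: leaflet assignment, mass-density profiles along the membrane
normal, area per lipid (projected-area convention, 2·Lx·Ly/N), bilayer
thickness (distance between the leaflets' phosphate/head reference planes),
the deuterium order parameter |S_CD| per tail carbon, geometric hydrogen-
bond counting, and leaflet interdigitation quantified as a fraction of
mass-density overlap,

    f_ov = ∫ min(ρ_U, ρ_L) dz / (½ ∫ (ρ_U + ρ_L) dz) ∈ [0, 1],

with D_int = f_ov(treated)/f_ov(control) as the treated-vs-control ratio.
All per-frame quantities are reported as mean ± standard deviation over the
included frames after an initial equilibration discard (default: the first
20% of frames).
"""
from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .core import DensityProfile, MeanSd, Trajectory, warn

__all__ = [
    "StructureConfig", "StructureSummary", "InterdigitationRatio", "ScdProfile",
    "assign_leaflets", "density_profile", "area_per_lipid", "bilayer_thickness",
    "interdigitation_fraction", "interdigitation_ratio", "leaflet_tail_profiles",
    "order_parameters", "count_hydrogen_bonds", "structure_summary",
    "structure_delta",
]


# ---------------------------------------------------------------- leaflets

def _head_ref_info(atoms: pd.DataFrame) -> pd.DataFrame:
    lipids = atoms[atoms["molecule_class"] == "lipid"]
    heads = lipids[lipids["role"] == "head_ref"]
    counts = heads.groupby("residue_id").size()
    all_lipids = lipids["residue_id"].unique()
    missing = sorted(set(all_lipids) - set(counts.index))
    if missing:
        names = lipids.set_index("residue_id")["residue_name"]
        raise ValueError(
            f"lipid residue(s) without a head_ref atom: "
            f"{[(m, names.get(m)) for m in missing[:5]]}"
        )
    multi = counts[counts > 1]
    if len(multi):
        raise ValueError(f"residues with more than one head_ref: {list(multi.index[:5])}")
    return heads


def _leaflet_masks(traj: Trajectory) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    """Per-frame upper-leaflet membership of each lipid.

    Returns (upper[n_frames, n_lipids] bool, residue_ids, head_rows).
    Midplane = mean head_ref z over all lipids, per frame. A head exactly
    at the midplane goes to the lower leaflet (deterministic tie rule) with
    a warning.
    """
    heads = _head_ref_info(traj.atoms)
    rows = heads.index.to_numpy()
    z = traj.coords[:, rows, 2]                       # (n_frames, n_lipids)
    midplane = z.mean(axis=1, keepdims=True)
    upper = z > midplane
    if np.any(z == midplane):
        warn("head_ref exactly at the midplane: assigned to the lower leaflet")
    return upper, heads["residue_id"].to_numpy(), rows


def assign_leaflets(traj: Trajectory, frame: int = 0) -> pd.Series:
    """Leaflet label per lipid residue for one frame.

    A warning is emitted when any lipid's label differs between frames of
    the trajectory (leaflet flip — suspicious for a bilayer).
    """
    upper, resids, _ = _leaflet_masks(traj)
    flips = np.any(upper != upper[0], axis=0)
    if flips.any():
        warn(f"{int(flips.sum())} lipid(s) change leaflet between frames")
    labels = np.where(upper[frame], "upper", "lower")
    return pd.Series(labels, index=pd.Index(resids, name="residue_id"), name="leaflet")


# ---------------------------------------------------------- density profile

def _resolve_selection(atoms: pd.DataFrame, sel) -> np.ndarray:
    if callable(sel):
        mask = np.asarray(sel(atoms), dtype=bool)
    else:
        mask = np.asarray(sel, dtype=bool)
    if mask.shape != (len(atoms),):
        raise ValueError("selection mask length must equal the atom count")
    return mask


def _midplane_z(traj: Trajectory) -> np.ndarray:
    heads = _head_ref_info(traj.atoms)
    return traj.coords[:, heads.index.to_numpy(), 2].mean(axis=1)


def density_profile(traj: Trajectory, selections: dict, bin_width: float = 0.5,
                    frames: slice | None = None) -> DensityProfile:
    """Mass density along z for each selection, midplane-centred.

    Each frame is re-centred so the bilayer midplane (mean head_ref z) sits
    at z = 0 before binning; the common grid covers the full z extent of
    all atoms in all included frames, so the profile integral conserves the
    selected mass exactly. Selections map labels to boolean masks over the
    atom table (or callables producing them).
    """
    if bin_width <= 0:
        raise ValueError("bin_width must be positive")
    sub = traj if frames is None else traj.frame_slice(frames.start or 0, frames.stop)
    mid = _midplane_z(sub)
    z_rel = sub.coords[:, :, 2] - mid[:, None]
    half = float(np.max(np.abs(z_rel))) + bin_width
    n_half = int(np.ceil(half / bin_width))
    edges = bin_width * np.arange(-n_half, n_half + 1)
    centers = 0.5 * (edges[:-1] + edges[1:])
    area = float(np.mean(sub.boxes[:, 0] * sub.boxes[:, 1]))

    densities: dict[str, np.ndarray] = {}
    masses = sub.atoms["mass"].to_numpy()
    for label, sel in selections.items():
        mask = _resolve_selection(sub.atoms, sel)
        if not mask.any():
            warn(f"selection '{label}' is empty; profile of zeros")
            densities[label] = np.zeros(len(centers))
            continue
        acc = np.zeros(len(centers))
        w = masses[mask]
        for f in range(sub.n_frames):
            hist, _ = np.histogram(z_rel[f, mask], bins=edges, weights=w)
            acc += hist
        densities[label] = acc / (sub.n_frames * area * bin_width)
    return DensityProfile(bin_centers=centers, bin_width=bin_width,
                          densities=densities, frame_count=sub.n_frames,
                          lateral_area=area)


def leaflet_tail_profiles(traj: Trajectory, bin_width: float = 0.5,
                          frames: slice | None = None
                          ) -> tuple[DensityProfile, DensityProfile]:
    """Lipid-tail mass-density profiles split by leaflet (upper, lower)."""
    upper, resids, _ = _leaflet_masks(traj)
    up_res = set(resids[upper[0]])
    atoms = traj.atoms
    tail = atoms["role"].isin(["tail_carbon", "tail_hydrogen"]).to_numpy()
    in_upper = atoms["residue_id"].isin(up_res).to_numpy()
    p_up = density_profile(traj, {"tails": tail & in_upper}, bin_width, frames)
    p_lo = density_profile(traj, {"tails": tail & ~in_upper}, bin_width, frames)
    return p_up, p_lo


# ----------------------------------------------------------- APL, thickness

def area_per_lipid(traj: Trajectory) -> MeanSd:
    """Projected area per lipid, 2·Lx·Ly / N_lipids, mean ± sd over frames.

    With asymmetric leaflet populations the per-leaflet formula
    Lx·Ly/N_leaflet is used instead (mean of the two) and both values are
    attached as ``result.per_leaflet``.
    """
    upper, resids, _ = _leaflet_masks(traj)
    n = len(resids)
    if n == 0:
        raise ValueError("no lipids in trajectory")
    areas = traj.boxes[:, 0] * traj.boxes[:, 1]
    n_up = int(upper[0].sum())
    n_lo = n - n_up
    if n_up == n_lo:
        apl = 2.0 * areas / n
        return MeanSd(float(apl.mean()), float(apl.std()))
    if n_up == 0 or n_lo == 0:
        raise ValueError("all lipids in one leaflet; APL undefined")
    warn(f"asymmetric leaflets ({n_up} vs {n_lo}); using per-leaflet APL")
    apl_up, apl_lo = areas / n_up, areas / n_lo
    both = 0.5 * (apl_up + apl_lo)
    res = MeanSd(float(both.mean()), float(both.std()))
    res.per_leaflet = {  # type: ignore[attr-defined]
        "upper": MeanSd(float(apl_up.mean()), float(apl_up.std())),
        "lower": MeanSd(float(apl_lo.mean()), float(apl_lo.std())),
    }
    return res


def bilayer_thickness(traj: Trajectory) -> MeanSd:
    """Inter-leaflet distance of the reference planes, mean ± sd over frames.

    The reference role is ``phosphate`` when present, else ``head_ref``.
    Translation-invariant by construction (difference of mean z values).
    """
    atoms = traj.atoms
    role = "phosphate" if (atoms["role"] == "phosphate").any() else "head_ref"
    refs = atoms[(atoms["role"] == role) & (atoms["molecule_class"] == "lipid")]
    if refs.empty:
        raise ValueError("no reference atoms for thickness")
    upper, resids, _ = _leaflet_masks(traj)
    up_res = set(resids[upper[0]])
    ref_rows = refs.index.to_numpy()
    ref_upper = refs["residue_id"].isin(up_res).to_numpy()
    if not ref_upper.any() or ref_upper.all():
        raise ValueError("reference atoms present in only one leaflet")
    z = traj.coords[:, ref_rows, 2]
    thick = z[:, ref_upper].mean(axis=1) - z[:, ~ref_upper].mean(axis=1)
    return MeanSd(float(thick.mean()), float(thick.std()))


# ----------------------------------------------------------- interdigitation

def interdigitation_fraction(profile_upper: DensityProfile,
                             profile_lower: DensityProfile,
                             label: str = "tails") -> float:
    """Mass-overlap fraction of the two leaflets' tail densities.

    f_ov = ∫min(ρ_U, ρ_L)dz / (½∫(ρ_U+ρ_L)dz), trapezoidal on the shared
    grid. 1 for identical profiles, 0 for disjoint supports.
    """
    if (len(profile_upper.bin_centers) != len(profile_lower.bin_centers)
            or not np.allclose(profile_upper.bin_centers, profile_lower.bin_centers)):
        raise ValueError("profiles must share the same z grid")
    z = profile_upper.bin_centers
    rho_u = profile_upper.densities[label]
    rho_l = profile_lower.densities[label]
    total = 0.5 * np.trapezoid(rho_u + rho_l, z)
    if total <= 0:
        raise ValueError("zero total tail mass; overlap fraction undefined")
    return float(np.trapezoid(np.minimum(rho_u, rho_l), z) / total)


@dataclass
class InterdigitationRatio:
    d_int: float
    treated_f_ov: float
    control_f_ov: float


def interdigitation_ratio(treated_f_ov: float, control_f_ov: float) -> InterdigitationRatio:
    """D_int = f_ov(treated) / f_ov(control)."""
    if control_f_ov <= 0:
        raise ValueError("control overlap fraction is zero; D_int undefined")
    return InterdigitationRatio(d_int=treated_f_ov / control_f_ov,
                                treated_f_ov=treated_f_ov,
                                control_f_ov=control_f_ov)


# ------------------------------------------------------------------- |SCD|

@dataclass
class ScdProfile:
    """|S_CD| per tail chain and carbon index.

    ``values`` maps a chain label (sn-1, sn-2) to {carbon index k: |SCD_k|};
    ``omitted`` lists (chain, k) pairs skipped for lack of hydrogens.
    """

    values: dict[str, dict[int, float]]
    omitted: list[tuple[str, int]] = field(default_factory=list)

    def as_frame(self) -> pd.DataFrame:
        rows = [{"chain": ch, "carbon": k, "abs_scd": v}
                for ch, d in self.values.items() for k, v in sorted(d.items())]
        return pd.DataFrame(rows)


def order_parameters(traj: Trajectory) -> ScdProfile:
    """Deuterium order parameter |SCD_k| = |⟨(3cos²θ − 1)/2⟩| per carbon.

    θ is the angle between each C→H bond and the +z axis; the average runs
    over frames, lipids and the carbon's hydrogens, separately per chain
    label. 0.5 means C–H bonds locked perpendicular to the normal
    (all-trans untilted chains); 0 means isotropic orientations.
    """
    atoms = traj.atoms
    carbons = atoms[atoms["role"] == "tail_carbon"]
    hydro = atoms[atoms["role"] == "tail_hydrogen"]
    key = ["residue_id", "chain", "carbon_index"]
    merged = hydro.reset_index().merge(
        carbons.reset_index(), on=key, suffixes=("_h", "_c"))
    values: dict[str, dict[int, float]] = {}
    omitted: list[tuple[str, int]] = []
    have_h = set(zip(merged["chain"], merged["carbon_index"]))
    for (ch, k), _ in carbons.groupby(["chain", "carbon_index"]):
        if (ch, k) not in have_h:
            omitted.append((ch, int(k)))
    if omitted:
        warn(f"tail carbons without hydrogens omitted from SCD: {omitted[:5]}")
    if merged.empty:
        return ScdProfile(values={}, omitted=omitted)
    h_rows = merged["index_h"].to_numpy()
    c_rows = merged["index_c"].to_numpy()
    vec = traj.coords[:, h_rows, :] - traj.coords[:, c_rows, :]
    cos2 = vec[:, :, 2] ** 2 / np.sum(vec ** 2, axis=2)
    scd_pair = 0.5 * (3.0 * cos2 - 1.0)          # (n_frames, n_pairs)
    per_pair = scd_pair.mean(axis=0)
    df = pd.DataFrame({"chain": merged["chain"], "k": merged["carbon_index"],
                       "scd": per_pair})
    for (ch, k), grp in df.groupby(["chain", "k"]):
        values.setdefault(str(ch), {})[int(k)] = float(abs(grp["scd"].mean()))
    return ScdProfile(values=values, omitted=omitted)


# ---------------------------------------------------------- hydrogen bonds

def count_hydrogen_bonds(traj: Trajectory, donors, acceptors,
                         cutoff: float = 3.5, angle_deg: float = 30.0,
                         h_bond_max: float = 1.2) -> MeanSd:
    """Geometric hydrogen-bond count, mean ± sd over frames.

    A (D, H, A) triplet counts when the D–A distance is ≤ ``cutoff`` Å and
    the H–D–A angle is ≤ ``angle_deg``°, with the minimum-image convention
    applied laterally (xy). Donor hydrogens are the H-element atoms of the
    donor's residue within ``h_bond_max`` Å of it in the first frame.
    """
    atoms = traj.atoms
    d_mask = _resolve_selection(atoms, donors)
    a_mask = _resolve_selection(atoms, acceptors)
    d_rows = np.flatnonzero(d_mask)
    a_rows = np.flatnonzero(a_mask)
    if len(d_rows) == 0 or len(a_rows) == 0:
        return MeanSd(0.0, 0.0)

    # donor -> attached hydrogen rows, resolved on the first frame
    h_cand = np.flatnonzero((atoms["element"] == "H").to_numpy())
    pairs: list[tuple[int, int]] = []
    c0 = traj.coords[0]
    resid = atoms["residue_id"].to_numpy()
    for d in d_rows:
        same_res = h_cand[resid[h_cand] == resid[d]]
        if len(same_res) == 0:
            continue
        dist = np.linalg.norm(c0[same_res] - c0[d], axis=1)
        for h in same_res[dist <= h_bond_max]:
            pairs.append((int(d), int(h)))
    if not pairs:
        return MeanSd(0.0, 0.0)

    cos_min = np.cos(np.radians(angle_deg))
    counts = np.empty(traj.n_frames)
    for f in range(traj.n_frames):
        c = traj.coords[f]
        box = traj.boxes[f]
        n = 0
        for d, h in pairs:
            da = c[a_rows] - c[d]
            da[:, :2] -= box[:2] * np.round(da[:, :2] / box[:2])  # xy minimum image
            r = np.linalg.norm(da, axis=1)
            ok = (r <= cutoff) & (r > 1e-9)
            if not ok.any():
                continue
            dh = c[h] - c[d]
            dh[:2] -= box[:2] * np.round(dh[:2] / box[:2])
            nh = np.linalg.norm(dh)
            cosang = (da[ok] @ dh) / (r[ok] * nh)
            n += int(np.sum(cosang >= cos_min))
        counts[f] = n
    return MeanSd(float(counts.mean()), float(counts.std()))


# ---------------------------------------------------------------- summary

@dataclass
class StructureConfig:
    discard_fraction: float = 0.2
    bin_width: float = 0.5
    hbond_donors: object | None = None
    hbond_acceptors: object | None = None
    hbond_cutoff: float = 3.5
    hbond_angle_deg: float = 30.0

    def validate(self) -> None:
        if not 0.0 <= self.discard_fraction <= 0.9:
            raise ValueError("discard_fraction must be in [0, 0.9]")
        if self.bin_width <= 0:
            raise ValueError("bin_width must be positive")


@dataclass
class StructureSummary:
    apl: MeanSd
    thickness: MeanSd
    f_ov: MeanSd
    hbond_count: MeanSd | None
    discard_fraction_applied: float
    n_frames_used: int = 0

    def to_dict(self) -> dict:
        d = {
            "apl_mean": self.apl.mean, "apl_sd": self.apl.sd,
            "thickness_mean": self.thickness.mean, "thickness_sd": self.thickness.sd,
            "f_ov_mean": self.f_ov.mean, "f_ov_sd": self.f_ov.sd,
            "discard_fraction_applied": self.discard_fraction_applied,
            "n_frames_used": self.n_frames_used,
        }
        if self.hbond_count is not None:
            d["hbond_mean"] = self.hbond_count.mean
            d["hbond_sd"] = self.hbond_count.sd
        else:
            d["hbond_mean"] = d["hbond_sd"] = None
        return d


def discard_window(n_frames: int, fraction: float) -> int:
    """Number of initial frames to drop (equilibration window)."""
    n_drop = int(round(fraction * n_frames))
    if n_drop >= n_frames:
        raise ValueError("discard window removes every frame")
    return n_drop


def structure_summary(traj: Trajectory,
                      config: StructureConfig | None = None) -> StructureSummary:
    """All structural metrics over the post-equilibration window.

    The first ``discard_fraction`` of frames (default 20%, mirroring a
    20-ns discard of a 100-ns run) is dropped; each metric is then a
    mean ± sd over the remaining frames. f_ov is computed per frame from
    single-frame leaflet tail profiles.
    """
    cfg = config or StructureConfig()
    cfg.validate()
    n_drop = discard_window(traj.n_frames, cfg.discard_fraction)
    sub = traj.frame_slice(n_drop)

    apl = area_per_lipid(sub)
    thick = bilayer_thickness(sub)

    fovs = np.empty(sub.n_frames)
    for f in range(sub.n_frames):
        one = sub.frame_slice(f, f + 1)
        p_up, p_lo = leaflet_tail_profiles(one, cfg.bin_width)
        fovs[f] = interdigitation_fraction(p_up, p_lo)
    f_ov = MeanSd(float(fovs.mean()), float(fovs.std()))

    hb = None
    if cfg.hbond_donors is not None and cfg.hbond_acceptors is not None:
        hb = count_hydrogen_bonds(sub, cfg.hbond_donors, cfg.hbond_acceptors,
                                  cfg.hbond_cutoff, cfg.hbond_angle_deg)
    return StructureSummary(apl=apl, thickness=thick, f_ov=f_ov, hbond_count=hb,
                            discard_fraction_applied=cfg.discard_fraction,
                            n_frames_used=sub.n_frames)


def structure_delta(treated: StructureSummary, control: StructureSummary) -> dict:
    """Treated-minus-control differences of the headline structure metrics.

    The reporting convention of drug-vs-control comparisons: positive
    ``d_apl`` is lateral expansion, negative ``d_thickness`` is thinning.
    """
    return {
        "d_apl": treated.apl.mean - control.apl.mean,
        "d_thickness": treated.thickness.mean - control.thickness.mean,
        "d_f_ov": treated.f_ov.mean - control.f_ov.mean,
    }
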