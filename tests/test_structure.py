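"""Structural observables: closed forms, conservation laws, invariances."""
import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from membkit import (BilayerSpec, DensityProfile, LipidType, StructureConfig,
                     area_per_lipid, assign_leaflets, bilayer_thickness,
                     build_bilayer, count_hydrogen_bonds, density_profile,
                     interdigitation_fraction, interdigitation_ratio,
                     leaflet_tail_profiles, order_parameters,
                     structure_summary)
from membkit.structure import discard_window, structure_delta

from conftest import make_traj, tail_masks, two_lipid_rows


# ---------------------------------------------------------------- leaflets

def test_two_lipids_split_by_head_height():
    traj = two_lipid_rows(z_upper=20.0, z_lower=-20.0)
    labels = assign_leaflets(traj)
    assert labels.loc[1] == "upper" and labels.loc[2] == "lower"


def test_symmetric_bilayer_splits_evenly(gel_bilayer):
    labels = assign_leaflets(gel_bilayer)
    assert (labels == "upper").sum() == (labels == "lower").sum() == 60


def test_head_at_midplane_goes_lower_with_warning():
    rows = [dict(residue_id=i, role="head_ref", element="P", mass=224.0)
            for i in (1, 2, 3)]
    coords = [[0, 0, 60.0], [0, 0, 40.0], [0, 0, 50.0]]  # third at the midplane
    traj = make_traj(rows, coords)
    with pytest.warns(UserWarning, match="midplane"):
        labels = assign_leaflets(traj)
    assert labels.loc[3] == "lower"


def test_lipid_without_head_ref_is_an_error():
    rows = [dict(residue_id=1, role="head_ref", element="P", mass=224.0),
            dict(residue_id=2, residue_name="DOPC", role="tail_carbon",
                 chain="sn-1", carbon_index=1)]
    traj = make_traj(rows, [[0, 0, 70.0], [0, 0, 30.0]])
    with pytest.raises(ValueError, match="DOPC"):
        assign_leaflets(traj)


# --------------------------------------------------------- density profile

def test_uniform_atoms_give_flat_profile():
    rng = np.random.default_rng(0)
    n = 4000
    rows = ([dict(residue_id=1, role="head_ref", mass=1.0),
             dict(residue_id=2, role="head_ref", mass=1.0)]
            + [dict(residue_id=3 + i, molecule_class="solvent", mass=10.0)
               for i in range(n)])
    coords = np.vstack([[[0, 0, 99.0], [0, 0, 1.0]],
                        rng.uniform(0, 100.0, size=(n, 3)) * [0.6, 0.6, 1.0]])
    traj = make_traj(rows, coords, box=(60.0, 60.0, 100.0))
    sel = np.zeros(n + 2, dtype=bool)
    sel[2:] = True
    prof = density_profile(traj, {"w": sel}, bin_width=10.0)
    rho = prof.densities["w"]
    expected = n * 10.0 / (60.0 * 60.0 * 100.0)
    inner = rho[(np.abs(prof.bin_centers) < 40.0)]
    assert np.all(np.abs(inner - expected) < 5 * expected / np.sqrt(n / 10))


def test_profile_integral_conserves_selected_mass(noisy_bilayer):
    heads, tails = tail_masks(noisy_bilayer)
    prof = density_profile(noisy_bilayer, {"heads": heads, "tails": tails},
                           bin_width=0.5)
    atoms = noisy_bilayer.atoms
    for label, mask in (("heads", heads), ("tails", tails)):
        mass = atoms.loc[mask, "mass"].sum()
        got = prof.integral(label) * prof.lateral_area
        assert got == pytest.approx(mass, rel=1e-3)


def test_doubling_bin_width_conserves_integral(gel_bilayer):
    _, tails = tail_masks(gel_bilayer)
    a = density_profile(gel_bilayer, {"t": tails}, bin_width=0.5)
    b = density_profile(gel_bilayer, {"t": tails}, bin_width=1.0)
    assert a.integral("t") == pytest.approx(b.integral("t"), rel=1e-12)


def test_head_density_peaks_outside_tail_density(gel_bilayer):
    heads, tails = tail_masks(gel_bilayer)
    prof = density_profile(gel_bilayer, {"heads": heads, "tails": tails})
    z = prof.bin_centers
    z_head = abs(z[np.argmax(prof.densities["heads"])])
    thick = bilayer_thickness(gel_bilayer).mean
    assert z_head == pytest.approx(thick / 2, abs=prof.bin_width)
    # tail mass concentrated strictly inside the head planes
    tail_inside = prof.densities["tails"][np.abs(z) < z_head].sum()
    assert tail_inside > 0.99 * prof.densities["tails"].sum()


def test_empty_selection_warns_and_returns_zeros(gel_bilayer):
    sel = np.zeros(gel_bilayer.n_atoms, dtype=bool)
    with pytest.warns(UserWarning, match="empty"):
        prof = density_profile(gel_bilayer, {"none": sel})
    assert np.all(prof.densities["none"] == 0)


# --------------------------------------------------------- APL & thickness

def test_apl_trivial_box_arithmetic():
    rows = [dict(residue_id=i, role="head_ref", mass=224.0) for i in range(1, 121)]
    coords = [[0, 0, 70.0]] * 60 + [[0, 0, 30.0]] * 60
    traj = make_traj(rows, coords, box=(60.0, 60.0, 100.0))
    apl = area_per_lipid(traj)
    assert apl.mean == pytest.approx(60.0) and apl.sd == 0.0


def test_apl_round_trips_builder_target():
    spec = BilayerSpec(lipid_types=[LipidType(count_per_leaflet=25)],
                       target_apl=42.42, n_frames=2, thermal_jitter_sd=0.0)
    apl = area_per_lipid(build_bilayer(spec))
    assert apl.mean == pytest.approx(42.42, rel=1e-12) and apl.sd == 0.0


def test_asymmetric_leaflets_use_per_leaflet_formula():
    rows = [dict(residue_id=i, role="head_ref", mass=224.0) for i in range(1, 4)]
    coords = [[0, 0, 70.0], [10, 10, 70.0], [0, 0, 30.0]]
    traj = make_traj(rows, coords, box=(60.0, 60.0, 100.0))
    with pytest.warns(UserWarning, match="asymmetric"):
        apl = area_per_lipid(traj)
    assert apl.per_leaflet["upper"].mean == pytest.approx(1800.0)
    assert apl.per_leaflet["lower"].mean == pytest.approx(3600.0)


def test_thickness_from_reference_planes():
    traj = two_lipid_rows(z_upper=23.21, z_lower=-23.21)
    assert bilayer_thickness(traj).mean == pytest.approx(46.42)


def test_thickness_translation_invariant(noisy_bilayer):
    base = bilayer_thickness(noisy_bilayer).mean
    shifted = noisy_bilayer.frame_slice(0, noisy_bilayer.n_frames)
    shifted.coords = shifted.coords + np.array([0.0, 0.0, 5.0])
    assert bilayer_thickness(shifted).mean == pytest.approx(base, rel=1e-12)


def test_thickness_round_trips_builder_geometry():
    spec = BilayerSpec(lipid_types=[LipidType(count_per_leaflet=9, n_tail_carbons=8)],
                       n_frames=1, thermal_jitter_sd=0.0,
                       interdigitation_offset=-1.0)
    traj = build_bilayer(spec)
    # head plane height: chain extent + head halfwidth - offset, mirrored
    expect = 2 * ((8 - 1) * spec.carbon_spacing + spec.head_region_halfwidth + 1.0)
    assert bilayer_thickness(traj).mean == pytest.approx(expect, rel=1e-12)


# -------------------------------------------------------- interdigitation

def _profile(z, rho, label="tails"):
    return DensityProfile(bin_centers=z, bin_width=float(z[1] - z[0]),
                          densities={label: rho}, frame_count=1,
                          lateral_area=1.0)


def test_overlap_closed_forms():
    z = np.arange(-5.0, 5.0, 0.01)
    h = 2.5
    same = _profile(z, np.where(np.abs(z) < 2, h, 0.0))
    assert interdigitation_fraction(same, same) == pytest.approx(1.0)

    upper = _profile(z, np.where((z >= 0) & (z < 2), h, 0.0))
    lower = _profile(z, np.where((z >= 1) & (z < 3), h, 0.0))
    assert interdigitation_fraction(upper, lower) == pytest.approx(0.5, abs=0.01)

    disjoint = _profile(z, np.where(z < -3, h, 0.0))
    assert interdigitation_fraction(upper, disjoint) == pytest.approx(0.0, abs=1e-9)


def test_overlap_agrees_with_fine_binning_oracle(gel_bilayer):
    """Convention robustness: f_ov at 10x finer bins matches within 1%."""
    coarse = leaflet_tail_profiles(gel_bilayer, bin_width=0.5)
    fine = leaflet_tail_profiles(gel_bilayer, bin_width=0.05)
    f_c = interdigitation_fraction(*coarse)
    f_f = interdigitation_fraction(*fine)
    assert f_c == pytest.approx(f_f, abs=0.01)


def test_overlap_monotone_in_builder_offset():
    # thermal jitter smears the bead planes into smooth densities (the
    # overlap statistic is defined on physical, continuous profiles)
    vals = []
    for off in (-3.0, -1.0, 0.0, 1.0, 3.0):
        spec = BilayerSpec(lipid_types=[LipidType(count_per_leaflet=16,
                                                  n_tail_carbons=8)],
                           interdigitation_offset=off, n_frames=5,
                           thermal_jitter_sd=1.0, seed=3)
        vals.append(interdigitation_fraction(*leaflet_tail_profiles(build_bilayer(spec))))
    assert all(b >= a for a, b in zip(vals, vals[1:]))
    assert vals[-1] > vals[0]


def test_interdigitation_ratio_arithmetic_and_errors():
    assert interdigitation_ratio(0.24, 0.10).d_int == pytest.approx(2.4)
    assert interdigitation_ratio(0.1, 0.1).d_int == pytest.approx(1.0)
    with pytest.raises(ValueError, match="undefined"):
        interdigitation_ratio(0.2, 0.0)


def test_zero_mass_overlap_is_an_error():
    z = np.arange(-5.0, 5.0, 0.1)
    empty = _profile(z, np.zeros_like(z))
    with pytest.raises(ValueError, match="zero total"):
        interdigitation_fraction(empty, empty)


# ------------------------------------------------------------------ |SCD|

def _ch_system(theta_deg, n=1):
    """One carbon with one H at polar angle theta from +z."""
    th = np.radians(theta_deg)
    rows, coords = [], []
    for i in range(n):
        rows += [dict(residue_id=i + 1, role="head_ref", element="P", mass=224.0),
                 dict(residue_id=i + 1, role="tail_carbon", chain="sn-1",
                      carbon_index=1, element="C"),
                 dict(residue_id=i + 1, role="tail_hydrogen", chain="sn-1",
                      carbon_index=1, element="H", mass=1.008)]
        c = [10.0 + i, 10.0, 45.0]
        h = [c[0] + np.sin(th) * 1.09, c[1], c[2] + np.cos(th) * 1.09]
        coords += [[10.0 + i, 10.0, 60.0], c, h]
    # add one lower-leaflet lipid so the leaflet machinery is happy
    rows.append(dict(residue_id=n + 1, role="head_ref", element="P", mass=224.0))
    coords.append([0.0, 0.0, 30.0])
    return make_traj(rows, coords)


def test_scd_perpendicular_bond_is_half():
    scd = order_parameters(_ch_system(90.0))
    assert scd.values["sn-1"][1] == pytest.approx(0.5)


def test_scd_magic_angle_is_zero():
    scd = order_parameters(_ch_system(np.degrees(np.arccos(1 / np.sqrt(3)))))
    assert scd.values["sn-1"][1] == pytest.approx(0.0, abs=1e-12)


def test_scd_isotropic_orientations_average_to_zero():
    rng = np.random.default_rng(42)
    n = 100_000
    u = rng.normal(size=(n, 3))
    u /= np.linalg.norm(u, axis=1, keepdims=True)
    scd = 0.5 * (3 * u[:, 2] ** 2 - 1)
    assert abs(scd.mean()) < 0.01
    # same statistic through the trajectory path on a random subset
    traj = _ch_system(90.0, n=1)
    frames = np.repeat(traj.coords, 200, axis=0)
    c_row, h_row = 1, 2
    frames[:, h_row, :] = frames[:, c_row, :] + 1.09 * u[:200]
    traj.coords = frames
    traj.times = 10.0 * np.arange(200)
    traj.boxes = np.tile(traj.boxes[0], (200, 1))
    got = order_parameters(traj).values["sn-1"][1]
    assert got == pytest.approx(abs(scd[:200].mean()), abs=1e-9)


def test_missing_hydrogen_omitted_with_report():
    traj = _ch_system(90.0)
    atoms = traj.atoms.copy()
    extra = atoms.iloc[[1]].copy()
    extra["carbon_index"] = 2
    extra["atom_id"] = atoms["atom_id"].max() + 1
    import pandas as pd
    from membkit import Trajectory
    atoms2 = pd.concat([atoms, extra], ignore_index=True)
    coords2 = np.concatenate([traj.coords, traj.coords[:, -1:, :]], axis=1)
    traj2 = Trajectory(atoms=atoms2, times=traj.times, coords=coords2,
                       boxes=traj.boxes)
    with pytest.warns(UserWarning, match="omitted"):
        scd = order_parameters(traj2)
    assert ("sn-1", 2) in scd.omitted
    assert 2 not in scd.values["sn-1"]


@settings(max_examples=20, deadline=None, derandomize=True)
@given(angle=st.floats(0.0, 2 * np.pi), dx=st.floats(-30.0, 30.0),
       dy=st.floats(-30.0, 30.0))
def test_scd_invariant_under_z_rotation_and_xy_translation(angle, dx, dy):
    traj = _ch_system(40.0)
    base = order_parameters(traj).values["sn-1"][1]
    rot = np.array([[np.cos(angle), -np.sin(angle), 0],
                    [np.sin(angle), np.cos(angle), 0], [0, 0, 1.0]])
    moved = traj.frame_slice(0, 1)
    moved.coords = traj.coords @ rot.T + np.array([dx, dy, 0.0])
    got = order_parameters(moved).values["sn-1"][1]
    assert got == pytest.approx(base, abs=1e-9)


# ---------------------------------------------------------- hydrogen bonds

def _water_pair(oo_dist, hda_angle_deg):
    """Two waters: donor O-H aimed off the O..O axis by the given angle."""
    th = np.radians(hda_angle_deg)
    rows = [
        dict(residue_id=1, atom_name="OW", element="O", mass=15.999,
             molecule_class="solvent"),
        dict(residue_id=1, atom_name="HW1", element="H", mass=1.008,
             molecule_class="solvent"),
        dict(residue_id=2, atom_name="OW", element="O", mass=15.999,
             molecule_class="solvent"),
    ]
    d = [10.0, 10.0, 50.0]
    a = [10.0 + oo_dist, 10.0, 50.0]
    h = [d[0] + 0.97 * np.cos(th), d[1] + 0.97 * np.sin(th), d[2]]
    return make_traj(rows, [d, h, a])


@pytest.mark.parametrize("oo,angle,expected", [
    (2.8, 0.0, 1),    # linear, inside cutoff
    (4.0, 0.0, 0),    # distance cutoff
    (3.0, 35.0, 0),   # angular cutoff exceeded
    (3.0, 25.0, 1),   # inside the angular cutoff
])
def test_hbond_geometric_criterion(oo, angle, expected):
    traj = _water_pair(oo, angle)
    donors = (traj.atoms["atom_name"] == "OW") & (traj.atoms["residue_id"] == 1)
    acceptors = (traj.atoms["atom_name"] == "OW") & (traj.atoms["residue_id"] == 2)
    got = count_hydrogen_bonds(traj, donors.to_numpy(), acceptors.to_numpy())
    assert got.mean == expected


def test_hbond_empty_sets_count_zero(gel_bilayer):
    none = np.zeros(gel_bilayer.n_atoms, dtype=bool)
    got = count_hydrogen_bonds(gel_bilayer, none, none)
    assert got.mean == 0.0 and got.sd == 0.0


def test_hbond_minimum_image_across_xy_boundary():
    traj = _water_pair(2.8, 0.0)
    # move the acceptor across the periodic x boundary
    traj.coords[0, 2, 0] = traj.coords[0, 0, 0] - 2.8 + traj.boxes[0, 0]
    donors = (traj.atoms["residue_id"] == 1) & (traj.atoms["element"] == "O")
    acceptors = (traj.atoms["residue_id"] == 2) & (traj.atoms["element"] == "O")
    # H points toward -x to follow the image
    traj.coords[0, 1] = traj.coords[0, 0] + np.array([-0.97, 0.0, 0.0])
    got = count_hydrogen_bonds(traj, donors.to_numpy(), acceptors.to_numpy())
    assert got.mean == 1


# ----------------------------------------------------------------- summary

def test_discard_window_arithmetic():
    assert discard_window(100, 0.2) == 20
    assert discard_window(1, 0.2) == 0
    with pytest.raises(ValueError):
        discard_window(1, 0.6)  # all frames discarded


def test_summary_discard_matches_manual_window(noisy_bilayer):
    full = structure_summary(noisy_bilayer, StructureConfig(discard_fraction=0.0))
    cut = structure_summary(noisy_bilayer, StructureConfig(discard_fraction=0.2))
    manual = structure_summary(noisy_bilayer.frame_slice(2),
                               StructureConfig(discard_fraction=0.0))
    assert cut.n_frames_used == 8
    assert cut.thickness.mean == pytest.approx(manual.thickness.mean, rel=1e-12)
    assert full.n_frames_used == 10


def test_stationary_input_summary_matches_single_frame(gel_bilayer):
    s = structure_summary(gel_bilayer, StructureConfig(discard_fraction=0.0))
    assert s.apl.sd == 0.0 and s.thickness.sd == 0.0
    assert s.apl.mean == pytest.approx(47.0)


def test_structure_delta_reports_treated_minus_control(noisy_bilayer, gel_bilayer):
    a = structure_summary(gel_bilayer, StructureConfig(discard_fraction=0.0))
    d = structure_delta(a, a)
    assert d["d_apl"] == 0.0 and d["d_thickness"] == 0.0
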