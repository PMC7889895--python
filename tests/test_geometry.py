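"""Distances, superposition, plane fits, and macrocycle distortion."""

import numpy as np
import pytest
from hypothesis import given
from hypothesis import strategies as st

from conftest import make_structure
from oracles import grid_search_rmsd
from redoxpath.atoms import AtomRecord, CofactorGroup, coords
from redoxpath.geometry import (
    bfactor_profile,
    deviation_profile,
    distance,
    edge_to_edge,
    fit_plane,
    group_center,
    macrocycle_distortion,
    plane_angle,
    superpose,
)
from redoxpath.synthetic import apply_rigid_noise, make_porphyrin


def _group(points, label="g", element="C"):
    atoms = [
        AtomRecord(i + 1, f"X{i+1}", element, "LIG", "A", i + 1, np.asarray(p, float))
        for i, p in enumerate(points)
    ]
    return CofactorGroup(label, atoms, center_atoms=atoms, edge_atoms=atoms)


def test_distance_is_euclidean_and_symmetric():
    assert distance((0, 0, 0), (3, 4, 0)) == pytest.approx(5.0)
    assert distance((1, 1, 1), (1, 1, 1)) == 0.0
    a, b = (1.0, -2.0, 0.5), (4.4, 0.0, -1.0)
    assert distance(a, b) == distance(b, a)


def test_group_center_single_metal_and_cube():
    heme = _group([(1.0, 2.0, 3.0)], element="Fe")
    np.testing.assert_allclose(group_center(heme), [1, 2, 3])
    cube = _group([(x, y, z) for x in (0, 1) for y in (0, 1) for z in (0, 1)], element="Fe")
    np.testing.assert_allclose(group_center(cube), [0.5, 0.5, 0.5])


def test_group_center_matches_brute_force_mean(random_cloud):
    g = _group(random_cloud)
    np.testing.assert_allclose(group_center(g), random_cloud.mean(axis=0))


def test_group_center_requires_center_atoms():
    g = _group([(0, 0, 0)])
    g.center_atoms = []
    with pytest.raises(ValueError, match="center atoms"):
        group_center(g)


def test_edge_to_edge_reduces_to_distance_and_is_symmetric():
    ga = _group([(0, 0, 0)])
    gb = _group([(0, 0, 7.5)])
    d, (pa, pb) = edge_to_edge(ga, gb)
    assert d == pytest.approx(7.5)
    d2, _ = edge_to_edge(gb, ga)
    assert d2 == pytest.approx(d)


def test_edge_to_edge_argmin_pair(random_cloud):
    ga = _group(random_cloud[:20])
    gb = _group(random_cloud[20:] + np.array([20.0, 0, 0]))
    d, (pa, pb) = edge_to_edge(ga, gb)
    brute = min(
        np.linalg.norm(x.position - y.position)
        for x in ga.edge_atoms
        for y in gb.edge_atoms
    )
    assert d == pytest.approx(brute)
    assert np.linalg.norm(pa.position - pb.position) == pytest.approx(d)


def test_edge_to_edge_rejects_empty_edge_set():
    ga = _group([(0, 0, 0)])
    gb = _group([(1, 0, 0)])
    gb.edge_atoms = []
    with pytest.raises(ValueError, match="empty edge"):
        edge_to_edge(ga, gb)


# --- superposition --------------------------------------------------------


def test_superpose_identity_gives_zero_rmsd(random_cloud):
    r = superpose(random_cloud, random_cloud)
    assert r.rmsd == pytest.approx(0.0, abs=1e-9)
    assert np.linalg.det(r.rotation) == pytest.approx(1.0)


def test_superpose_removes_rigid_motion(random_cloud):
    s = make_structure(random_cloud)
    moved = apply_rigid_noise(s, seed=21, noise_sigma=0.0)
    r = superpose(coords(s.atoms), coords(moved.atoms))
    assert r.rmsd <= 1e-6


def test_superpose_rmsd_matches_rotation_grid_oracle():
    rng = np.random.default_rng(17)
    for trial in range(3):
        ref = rng.normal(size=(5, 3)) * 3.0
        mov = rng.normal(size=(5, 3)) * 3.0
        ours = superpose(ref, mov).rmsd
        oracle = grid_search_rmsd(ref, mov)
        assert ours == pytest.approx(oracle, abs=1e-3)


def test_superpose_invariant_under_rigid_pretransformation(random_cloud):
    s = make_structure(random_cloud)
    mov = apply_rigid_noise(s, seed=3, noise_sigma=0.4)
    base = superpose(coords(s.atoms), coords(mov.atoms)).rmsd
    pre = apply_rigid_noise(mov, seed=99, noise_sigma=0.0)  # extra rigid motion
    again = superpose(coords(s.atoms), coords(pre.atoms)).rmsd
    assert again == pytest.approx(base, abs=1e-8)


def test_superpose_noise_recovery_matches_sigma_sqrt3():
    rng = np.random.default_rng(8)
    s = make_structure(rng.normal(size=(500, 3)) * 8.0)
    moved = apply_rigid_noise(s, seed=23, noise_sigma=0.5)
    r = superpose(coords(s.atoms), coords(moved.atoms))
    expected = 0.5 * np.sqrt(3.0)
    assert abs(r.rmsd - expected) / expected < 0.10


def test_superpose_rejects_degenerate_input():
    line = np.array([[0.0, 0, 0], [1, 0, 0], [2, 0, 0], [3, 0, 0]])
    with pytest.raises(ValueError):
        superpose(line, line)
    with pytest.raises(ValueError, match="shape"):
        superpose(np.zeros((4, 3)), np.zeros((5, 3)))


def test_rmsd_consistent_with_per_atom_deviations(random_cloud):
    s = make_structure(random_cloud)
    mov = apply_rigid_noise(s, seed=5, noise_sigma=0.3)
    r = superpose(coords(s.atoms), coords(mov.atoms))
    assert r.rmsd == pytest.approx(np.sqrt(np.mean(r.per_atom_deviation**2)))


# --- deviation profiles ---------------------------------------------------


def test_deviation_profile_zero_for_rigidly_moved_copy(random_cloud):
    ref = make_structure(random_cloud)
    mov = apply_rigid_noise(ref, seed=31, noise_sigma=0.0)
    table = deviation_profile(ref, mov, align_on={"chain": "A"}, report_on={"chain": "A"})
    assert table["max_deviation"].max() < 1e-6


def test_deviation_profile_anchored_alignment_sees_domain_motion():
    # two rigid blocks; block B shifted by 2 A in the "moving" structure
    rng = np.random.default_rng(12)
    block_a = rng.normal(size=(30, 3)) * 3.0
    block_b = rng.normal(size=(30, 3)) * 3.0 + np.array([20.0, 0, 0])
    atoms = []
    for i, p in enumerate(np.vstack([block_a, block_b])):
        chain = "A" if i < 30 else "B"
        atoms.append(AtomRecord(i + 1, "CA", "C", "GLY", chain, i + 1, p, het=False))
    from redoxpath.atoms import Structure

    ref = Structure(atoms)
    moved_pts = np.vstack([block_a, block_b + np.array([0.0, 2.0, 0.0])])
    mov = Structure(
        [a.moved_to(p) for a, p in zip(atoms, moved_pts)], metadata={}
    )
    table = deviation_profile(ref, mov, align_on={"chain": "A"}, report_on={"chain": "B"})
    np.testing.assert_allclose(table["max_deviation"], 2.0, atol=1e-9)


def test_deviation_profile_reports_unmatched_atoms():
    ref = make_structure(np.eye(3) * 4)
    mov = make_structure(np.eye(4, 3) * 4)
    with pytest.raises(ValueError, match="unmatched"):
        deviation_profile(ref, mov, align_on={"chain": "A"}, report_on={"chain": "A"})


# --- planes ---------------------------------------------------------------


def test_fit_plane_exact_for_coplanar_points():
    pts = np.array([[0, 0, 1.0], [1, 0, 1.0], [0, 1, 1.0], [1, 1, 1.0]])
    fit = fit_plane(pts)
    assert fit.rms_residual == pytest.approx(0.0, abs=1e-12)
    np.testing.assert_allclose(np.abs(fit.normal), [0, 0, 1], atol=1e-12)


def test_fit_plane_symmetric_jitter_keeps_z_normal():
    rng = np.random.default_rng(3)
    xy = rng.normal(size=(40, 2)) * 3
    dz = rng.uniform(0.1, 0.4, size=40)
    pts = np.vstack(
        [np.column_stack([xy, dz]), np.column_stack([xy, -dz])]
    )
    fit = fit_plane(pts)
    np.testing.assert_allclose(fit.normal, [0, 0, 1], atol=1e-9)


def test_fit_plane_rejects_collinear_points():
    with pytest.raises(ValueError):
        fit_plane([[0, 0, 0], [1, 1, 1], [2, 2, 2]])


def test_plane_angle_limits_and_fold():
    flat = fit_plane([[0, 0, 0], [1, 0, 0], [0, 1, 0], [1, 1, 0.0]])
    wall = fit_plane([[0, 0, 0], [0, 1, 0], [0, 0, 1], [0, 1, 1.0]])
    assert plane_angle(flat, flat) == pytest.approx(0.0, abs=1e-9)
    assert plane_angle(flat, wall) == pytest.approx(90.0)


@given(st.floats(min_value=0.0, max_value=89.0))
def test_plane_angle_invariant_under_normal_flip(theta):
    t = np.radians(theta)
    p = fit_plane([[0, 0, 0], [1, 0, 0], [0, 1, 0], [1, 1, 0.0]])
    qn = np.array([np.sin(t), 0.0, np.cos(t)])
    q1 = type(p)(centroid=np.zeros(3), normal=qn, rms_residual=0.0)
    q2 = type(p)(centroid=np.zeros(3), normal=-qn, rms_residual=0.0)
    assert plane_angle(p, q1) == pytest.approx(plane_angle(p, q2))
    assert plane_angle(p, q1) == pytest.approx(theta, abs=1e-6)


# --- macrocycle distortion ------------------------------------------------


def test_flat_porphyrin_has_no_distortion():
    _, group = make_porphyrin(0.0)
    profile = macrocycle_distortion(group, reference_ring="I")
    assert profile.max_deviation == pytest.approx(0.0, abs=1e-9)
    assert profile.bend_angle == pytest.approx(0.0, abs=1e-9)


@pytest.mark.parametrize("bend", [2.0, 5.0, 10.0, 20.0])
def test_bend_angle_recovery(bend):
    _, group = make_porphyrin(bend)
    profile = macrocycle_distortion(group, reference_ring="I")
    assert abs(profile.bend_angle - bend) < 0.5


def test_bend_recovery_mean_error_across_range():
    errors = []
    for bend in (2.0, 5.0, 10.0, 20.0):
        _, group = make_porphyrin(bend)
        errors.append(abs(macrocycle_distortion(group, "I").bend_angle - bend))
    assert np.mean(errors) < 0.5


def test_distortion_max_is_max_abs_out_of_plane():
    _, group = make_porphyrin(15.0)
    profile = macrocycle_distortion(group, "I")
    assert profile.max_deviation == pytest.approx(
        max(abs(v) for v in profile.per_atom_out_of_plane.values())
    )
    # the far edge of the rotated half moves the most
    assert profile.per_atom_out_of_plane[profile.max_deviation_atom] != 0.0


def test_distortion_requires_ring_map():
    _, group = make_porphyrin(5.0)
    group.pyrrole_rings = {}
    with pytest.raises(ValueError, match="ring map"):
        macrocycle_distortion(group, "I")


# --- B-factor profile -----------------------------------------------------


def test_bfactor_ranking_matches_designed_gradient(two_body):
    structure, truth = two_body
    table = bfactor_profile(structure, chain="A")
    # designed law: B grows with distance from the interface; ranking ascends
    assert table["mean_b"].is_monotonic_increasing
    brute = {}
    for a in structure.select(chain="A"):
        brute.setdefault(a.res_seq, []).append(a.b_factor)
    for row in table.itertuples():
        assert row.mean_b == pytest.approx(np.mean(brute[row.res_seq]))


def test_bfactor_uniform_ties_break_by_residue_number():
    s = make_structure(np.arange(15).reshape(5, 3) * 3.0, b=7.5)
    table = bfactor_profile(s)
    assert list(table["res_seq"]) == [1, 2, 3, 4, 5]
    assert (table["mean_b"] == 7.5).all()
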