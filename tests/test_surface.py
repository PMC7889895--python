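"""Solvent-accessible surface areas against analytic and Monte-Carlo oracles."""

import numpy as np
import pytest

from conftest import make_structure
from oracles import monte_carlo_sasa
from redoxpath.atoms import AtomRecord, coords
from redoxpath.surface import (
    SasaParams,
    buried_area,
    interface_residues,
    sasa,
    sphere_points,
)
from redoxpath.synthetic import apply_rigid_noise, make_two_body_complex


def _atoms(points, element="C"):
    return [
        AtomRecord(i + 1, "CA", element, "GLY", "A", i + 1, np.asarray(p, float), het=False)
        for i, p in enumerate(points)
    ]


def test_single_atom_matches_analytic_sphere():
    area = sasa(_atoms([(0, 0, 0)])).total
    analytic = 4 * np.pi * (1.70 + 1.4) ** 2
    assert abs(area - analytic) / analytic < 0.01


def test_two_distant_atoms_do_not_occlude():
    area = sasa(_atoms([(0, 0, 0), (100.0, 0, 0)])).total
    assert area == pytest.approx(2 * 4 * np.pi * 3.1**2, rel=1e-6)


@pytest.mark.parametrize("separation", [1.0, 2.5, 4.0, 5.5])
def test_two_overlapping_spheres_match_monte_carlo(separation):
    pts = [(0.0, 0, 0), (separation, 0, 0)]
    ours = sasa(_atoms(pts)).total
    mc = monte_carlo_sasa(pts, [1.70, 1.70], probe=1.4, n_points=500_000, seed=42)
    assert abs(ours - mc) / mc < 0.02


def test_sphere_points_are_unit_and_well_spread():
    pts = sphere_points(960)
    np.testing.assert_allclose(np.linalg.norm(pts, axis=1), 1.0, atol=1e-12)
    # centroid of a quasi-uniform sample is near the origin
    assert np.linalg.norm(pts.mean(axis=0)) < 1e-3


def test_area_converges_with_point_count(two_body):
    structure, _ = two_body
    atoms = structure.select(chain="A")
    coarse = sasa(atoms, SasaParams(n_points=960)).total
    fine = sasa(atoms, SasaParams(n_points=4000)).total
    assert abs(coarse - fine) / fine < 0.01


def test_unknown_element_is_named_in_error():
    with pytest.raises(KeyError, match="Xx"):
        sasa(_atoms([(0, 0, 0)], element="Xx"))


def test_buried_area_zero_when_far_apart():
    s, _ = make_two_body_complex(50.0, 9, 2.3, seed=2)
    buried, contact = buried_area(s.select(chain="A"), s.select(chain="B"))
    assert buried == pytest.approx(0.0, abs=1e-6)
    assert contact == pytest.approx(0.0, abs=1e-6)


def test_buried_area_monotone_in_separation():
    values = []
    for sep in (2.0, 4.0, 8.0, 16.0, 40.0):
        s, _ = make_two_body_complex(sep, 9, 2.3, seed=6)
        buried, _ = buried_area(s.select(chain="A"), s.select(chain="B"))
        values.append(buried)
    assert values[0] > 0
    assert all(a >= b - 1e-9 for a, b in zip(values, values[1:]))
    assert values[-1] == pytest.approx(0.0, abs=1e-6)


def test_symmetric_dimer_buries_equal_area_per_side():
    # mirror-image monomers: each side must lose the same SASA
    rng = np.random.default_rng(14)
    pts = rng.uniform(0.6, 6.0, size=(20, 3))
    left = _atoms(pts * np.array([-1.0, 1.0, 1.0]))
    right = [
        AtomRecord(100 + i, "CA", "C", "GLY", "B", i + 1, p, het=False)
        for i, p in enumerate(pts)
    ]
    iso_l = sasa(left).total
    iso_r = sasa(right).total
    combined = sasa(left + right).total
    delta_l = iso_l - sasa(left + right).per_atom_area[: len(left)].sum()
    # per-side losses from the combined run
    res = sasa(left + right)
    loss_left = iso_l - res.per_atom_area[: len(left)].sum()
    loss_right = iso_r - res.per_atom_area[len(left):].sum()
    assert loss_left == pytest.approx(loss_right, rel=0.02, abs=0.5)
    assert iso_l + iso_r - combined == pytest.approx(loss_left + loss_right, abs=1e-9)


def test_areas_invariant_under_rigid_motion(two_body):
    structure, _ = two_body
    a = structure.select(chain="A")
    b = structure.select(chain="B")
    buried0, _ = buried_area(a, b)
    moved = apply_rigid_noise(structure, seed=77, noise_sigma=0.0)
    buried1, _ = buried_area(moved.select(chain="A"), moved.select(chain="B"))
    assert buried1 == pytest.approx(buried0, rel=0.02, abs=1.0)


def test_interface_residues_are_the_designed_contact_layer(two_body):
    structure, truth = two_body
    table = interface_residues(
        structure.select(chain="A"), structure.select(chain="B"), min_delta=1.0
    )
    found_a = {
        (r.chain, r.res_seq, r.insertion_code)
        for r in table.itertuples()
        if r.side == "a"
    }
    face_a = set(map(tuple, truth["face_residues"]["A"]))
    # every flagged residue belongs to the designed face layer, and the face
    # center (the designed H-bond donor) is flagged
    assert found_a <= face_a
    assert truth["designed_pair"][0] in found_a


def test_interface_residues_empty_cases():
    s, _ = make_two_body_complex(50.0, 9, 2.3, seed=2)
    a, b = s.select(chain="A"), s.select(chain="B")
    assert interface_residues(a, b).empty
    near, _ = make_two_body_complex(3.0, 9, 2.3, seed=2)
    assert interface_residues(
        near.select(chain="A"), near.select(chain="B"), min_delta=np.inf
    ).empty


def test_overlapping_identity_sets_rejected(two_body):
    structure, _ = two_body
    a = structure.select(chain="A")
    with pytest.raises(ValueError, match="share"):
        buried_area(a, a)


def test_cross_check_against_independent_shrake_rupley(two_body):
    """Our implementation vs biotite's Shrake-Rupley with identical radii."""
    biotite_struc = pytest.importorskip("biotite.structure")
    structure, _ = two_body
    atoms = structure.select(chain="A")
    arr = biotite_struc.AtomArray(len(atoms))
    arr.coord = coords(atoms).astype(np.float32)
    for i, a in enumerate(atoms):
        arr.chain_id[i] = a.chain_id
        arr.res_id[i] = a.res_seq
        arr.res_name[i] = a.res_name
        arr.atom_name[i] = a.name
        arr.element[i] = a.element.upper()
    radii = np.full(len(atoms), 1.70, dtype=np.float32)
    theirs = biotite_struc.sasa(arr, probe_radius=1.4, vdw_radii=radii, point_number=1000).sum()
    ours = sasa(atoms).total
    assert abs(ours - theirs) / theirs < 0.02
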