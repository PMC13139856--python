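"""Inter-chain contact maps: brute-force oracle equivalence and threshold semantics."""

import numpy as np
import pytest
from scipy.spatial.transform import Rotation

from optosite import (
    AtomRecord,
    ComplexSpec,
    ContactParams,
    ResidueRecord,
    SegmentBlueprint,
    StructureModel,
    build_complex,
    interchain_distances,
    interface_profile,
    refine_contact_map,
)


def _ca_model(coords_a, coords_b):
    def chain(cid, coords):
        return [
            ResidueRecord(cid, i + 1, "A",
                          [AtomRecord("CA", "C", np.asarray(c, float), 90.0)], 90.0)
            for i, c in enumerate(coords)
        ]

    return StructureModel(chains={"A": chain("A", coords_a), "B": chain("B", coords_b)})


def _brute_force(coords_a, coords_b, contact=8.0, refine=10.0):
    """Oracle: independent double-loop distance matrix, contacts and refined set."""
    na, nb = len(coords_a), len(coords_b)
    dist = np.empty((na, nb))
    for i in range(na):
        for j in range(nb):
            dist[i, j] = np.sqrt(((np.asarray(coords_a[i]) - np.asarray(coords_b[j])) ** 2).sum())
    contacts = {(i + 1, j + 1) for i in range(na) for j in range(nb) if dist[i, j] < contact}
    refined = [j + 1 for j in range(nb) if min(dist[i, j] for i in range(na)) <= refine]
    return dist, contacts, refined


def test_hand_placed_three_residue_chains_match_oracle():
    a = [(0, 0, 0), (3.8, 0, 0), (7.6, 0, 0)]
    b = [(0, 5, 0), (3.8, 9, 0), (20, 20, 20)]
    cmap = interchain_distances(_ca_model(a, b), "A", "B")
    dist, contacts, refined = _brute_force(a, b)
    assert np.allclose(cmap.distances, dist, atol=1e-9)
    assert cmap.contacts == contacts
    assert cmap.refined_partner_residues == refined


def test_random_complexes_match_brute_force_exactly(rng):
    for _ in range(25):
        na, nb = rng.integers(2, 31, size=2)
        a = rng.uniform(-12, 12, size=(int(na), 3))
        b = rng.uniform(-12, 12, size=(int(nb), 3))
        cmap = interchain_distances(_ca_model(a, b), "A", "B")
        dist, contacts, refined = _brute_force(a, b)
        assert np.array_equal(cmap.distances, dist) or np.allclose(cmap.distances, dist, atol=1e-12)
        assert cmap.contacts == contacts
        assert cmap.refined_partner_residues == refined
        refined_map = refine_contact_map(cmap)
        assert refined_map.partner_residues == refined
        assert refined_map.contacts == contacts  # refinement never drops contacts


def test_separated_chains_have_no_contacts(far_complex):
    cmap = interchain_distances(far_complex, "A", "B")
    assert cmap.contacts == set()
    assert cmap.refined_partner_residues == []
    assert all(not flag for _, _, flag in interface_profile(cmap).entries)


def test_threshold_semantics_at_nine_and_seven_angstrom():
    """9 A: beyond contact (strict <8) but kept by refinement (<=10); 7 A: contact."""
    a = [(0.0, 0.0, 0.0)]
    cmap9 = interchain_distances(_ca_model(a, [(9.0, 0, 0), (30, 0, 0)]), "A", "B")
    assert cmap9.contacts == set()
    assert cmap9.refined_partner_residues == [1]
    cmap7 = interchain_distances(_ca_model(a, [(7.0, 0, 0)]), "A", "B")
    assert cmap7.contacts == {(1, 1)}
    # boundary values: exactly 8 is not a contact, exactly 10 is retained
    cmap8 = interchain_distances(_ca_model(a, [(8.0, 0, 0), (10.0, 0, 0)]), "A", "B")
    assert cmap8.contacts == set()
    assert cmap8.refined_partner_residues == [1, 2]


def test_engineered_complex_min_separation_nine(rng):
    model = build_complex(
        ComplexSpec([SegmentBlueprint("H", 6, 95.0)], [SegmentBlueprint("H", 6, 95.0)],
                    min_separation=9.0, seed=31)
    )
    cmap = interchain_distances(model, "A", "B")
    assert cmap.distances.min() == pytest.approx(9.0, abs=1e-5)
    assert cmap.contacts == set()
    assert cmap.refined_partner_residues != []


def test_refinement_extremes():
    a = [(0.0, 0.0, 0.0)]
    far = interchain_distances(_ca_model(a, [(20, 0, 0), (30, 0, 0)]), "A", "B")
    assert refine_contact_map(far).partner_residues == []
    near = interchain_distances(_ca_model(a, [(3, 0, 0), (5, 0, 0)]), "A", "B")
    refined = refine_contact_map(near)
    assert refined.partner_residues == [1, 2]
    assert refined.contacts == near.contacts


def test_interface_profile_row_minima():
    cmap = interchain_distances(_ca_model([(0, 0, 0)], [(7.9, 0, 0), (12, 0, 0)]), "A", "B")
    prof = interface_profile(cmap)
    assert prof.entries == [(1, pytest.approx(7.9), True)]


def test_rigid_body_invariance_of_outputs(rng):
    a = rng.uniform(-10, 10, size=(8, 3))
    b = rng.uniform(-10, 10, size=(10, 3))
    ref = interchain_distances(_ca_model(a, b), "A", "B")
    R = Rotation.random(rng=rng).as_matrix()
    t = rng.uniform(-50, 50, size=3)
    moved = interchain_distances(_ca_model(a @ R.T + t, b @ R.T + t), "A", "B")
    assert np.allclose(ref.distances, moved.distances, atol=1e-9)
    assert ref.contacts == moved.contacts
    assert ref.refined_partner_residues == moved.refined_partner_residues


def test_contact_set_grows_with_threshold(rng):
    a = rng.uniform(-10, 10, size=(6, 3))
    b = rng.uniform(-10, 10, size=(6, 3))
    model = _ca_model(a, b)
    prev = set()
    for thr in (4.0, 8.0, 12.0, 16.0):
        now = interchain_distances(model, "A", "B", ContactParams(thr, thr)).contacts
        assert prev <= now
        prev = now


def test_role_symmetry_transposes(rng):
    a = rng.uniform(-10, 10, size=(5, 3))
    b = rng.uniform(-10, 10, size=(7, 3))
    model = _ca_model(a, b)
    fwd = interchain_distances(model, "A", "B")
    rev = interchain_distances(model, "B", "A")
    assert np.allclose(fwd.distances, rev.distances.T)
    assert {(j, i) for i, j in fwd.contacts} == rev.contacts


def test_cb_mode_falls_back_to_ca_for_glycine():
    res_a = ResidueRecord("A", 1, "G", [AtomRecord("CA", "C", np.zeros(3), 90.0)], 90.0)
    res_b = ResidueRecord(
        "B", 1, "A",
        [AtomRecord("CA", "C", np.array([6.0, 0, 0]), 90.0),
         AtomRecord("CB", "C", np.array([5.0, 0, 0]), 90.0)],
        90.0,
    )
    model = StructureModel(chains={"A": [res_a], "B": [res_b]})
    cmap = interchain_distances(model, "A", "B", ContactParams(atom_mode="CB"))
    assert cmap.distances[0, 0] == pytest.approx(5.0)


def test_min_heavy_mode_uses_closest_atoms():
    res_a = ResidueRecord(
        "A", 1, "A",
        [AtomRecord("CA", "C", np.zeros(3), 90.0),
         AtomRecord("O", "O", np.array([2.0, 0, 0]), 90.0)],
        90.0,
    )
    res_b = ResidueRecord("B", 1, "A", [AtomRecord("CA", "C", np.array([9.0, 0, 0]), 90.0)], 90.0)
    model = StructureModel(chains={"A": [res_a], "B": [res_b]})
    cmap = interchain_distances(model, "A", "B", ContactParams(atom_mode="min_heavy"))
    assert cmap.distances[0, 0] == pytest.approx(7.0)


def test_param_validation_and_unknown_chain():
    with pytest.raises(ValueError):
        ContactParams(contact_threshold=12.0, refine_threshold=10.0)
    model = _ca_model([(0, 0, 0)], [(5, 0, 0)])
    with pytest.raises(KeyError):
        interchain_distances(model, "A", "Z")
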