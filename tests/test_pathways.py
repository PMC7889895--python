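"""Tunneling-coupling graphs and maximum-coupling path search."""

import math

import networkx as nx
import numpy as np
import pytest

from oracles import enumerate_best_path, random_molecular_graph
from redoxpath.atoms import AtomRecord, CofactorGroup
from redoxpath.pathways import (
    CouplingParams,
    PathwayResult,
    best_path,
    bridging_residues,
    build_molecular_graph,
    donor_atom_ranking,
)
from redoxpath.synthetic import make_chain_molecule, make_donor_bridge_acceptor

PARAMS = CouplingParams()


def test_chain_has_exactly_n_covalent_edges_and_no_hbonds():
    g = build_molecular_graph(make_chain_molecule(3))
    types = [d["type"] for _, _, d in g.edges(data=True)]
    assert types.count("covalent") == 3
    assert types.count("hbond") == 0


def test_epsilon_values_at_reference_distances():
    # through-space at its 1.4 A offset and an H-bond at its 2.8 A offset
    assert PARAMS.epsilon("space", 1.4) == pytest.approx(0.3)
    assert PARAMS.epsilon("hbond", 2.8) == pytest.approx(0.36)
    assert PARAMS.epsilon("covalent", 1.54) == pytest.approx(0.6)


def test_epsilon_decays_with_distance():
    for etype in ("space", "hbond"):
        d = np.linspace(2.0, 6.0, 20)
        eps = [PARAMS.epsilon(etype, x) for x in d]
        assert all(a > b for a, b in zip(eps, eps[1:]))


def test_unique_path_coupling_is_covalent_power():
    s = make_chain_molecule(3)
    g = build_molecular_graph(s)
    res = best_path(g, [1], [4])
    assert res.total_coupling == pytest.approx(0.6**3)
    assert res.n_covalent == 3 and res.n_space == 0
    assert res.log10_coupling == pytest.approx(3 * math.log10(0.6))


def test_bridge_beats_direct_jump_iff_decay_predicts_it():
    # two 3.5 A hops vs one 7.0 A jump: eps_ts(3.5)^2 > eps_ts(7.0)
    s, truth = make_donor_bridge_acceptor(7.0, bridge=True)
    g = build_molecular_graph(s)
    res = best_path(g, [truth["donor_serial"]], [truth["acceptor_serial"]])
    path_serials = [a.serial for a in res.atom_sequence]
    assert truth["bridge_serial"] in path_serials
    eps_hop = PARAMS.epsilon("space", 3.5)
    assert eps_hop**2 > PARAMS.epsilon("space", 7.0)
    # and the full result agrees with exhaustive enumeration
    oracle_path, oracle_coupling = enumerate_best_path(
        g, [truth["donor_serial"]], [truth["acceptor_serial"]]
    )
    assert tuple(path_serials) == oracle_path
    assert res.total_coupling == pytest.approx(oracle_coupling)


def test_direct_jump_used_when_gap_is_short():
    s, truth = make_donor_bridge_acceptor(2.8, bridge=False)
    g = build_molecular_graph(s)
    res = best_path(g, [truth["donor_serial"]], [truth["acceptor_serial"]])
    assert res.n_space == 1


def test_search_equals_enumeration_on_seeded_random_graphs():
    agree = 0
    for seed in range(60):
        g, _ = random_molecular_graph(seed)
        donors = [min(g.nodes)]
        acceptors = [max(g.nodes)]
        res = best_path(g, donors, acceptors)
        oracle = enumerate_best_path(g, donors, acceptors)
        if oracle is None:
            assert not res.connected
        else:
            assert res.connected
            assert tuple(a.serial for a in res.atom_sequence) == oracle[0]
            assert res.total_coupling == pytest.approx(oracle[1], rel=1e-12)
        agree += 1
    assert agree == 60


def test_disconnected_graph_yields_explicit_result():
    s, truth = make_donor_bridge_acceptor(8.0, bridge=False)
    params = CouplingParams(through_space_cutoff=4.0)  # gap no longer bridgeable
    g = build_molecular_graph(s, params)
    res = best_path(g, [truth["donor_serial"]], [truth["acceptor_serial"]])
    assert not res.connected
    assert res.total_coupling == 0.0
    assert res.log10_coupling == -math.inf


def test_enlarging_cutoff_never_decreases_coupling():
    s, truth = make_donor_bridge_acceptor(7.0, bridge=True)
    couplings = []
    for cutoff in (4.0, 5.0, 6.0, 8.0):
        g = build_molecular_graph(s, CouplingParams(through_space_cutoff=cutoff))
        res = best_path(g, [truth["donor_serial"]], [truth["acceptor_serial"]])
        couplings.append(res.total_coupling if res.connected else 0.0)
    assert all(b >= a - 1e-15 for a, b in zip(couplings, couplings[1:]))


def test_removing_off_path_edge_preserves_best_path():
    g, _ = random_molecular_graph(5)
    donors, acceptors = [min(g.nodes)], [max(g.nodes)]
    res = best_path(g, donors, acceptors)
    if not res.connected:
        pytest.skip("seed 5 drew a disconnected cloud")
    on_path = set(zip(
        [a.serial for a in res.atom_sequence], [a.serial for a in res.atom_sequence][1:]
    ))
    on_path |= {(b, a) for a, b in on_path}
    for u, v in list(g.edges):
        if (u, v) not in on_path:
            h = g.copy()
            h.remove_edge(u, v)
            res2 = best_path(h, donors, acceptors)
            assert res2.total_coupling == pytest.approx(res.total_coupling)
            break


def test_invalid_donor_acceptor_sets_rejected():
    g = build_molecular_graph(make_chain_molecule(2))
    with pytest.raises(ValueError):
        best_path(g, [], [1])
    with pytest.raises(ValueError, match="disjoint"):
        best_path(g, [1], [1, 3])


def test_unknown_element_named_in_graph_error():
    s = make_chain_molecule(2)
    s.atoms[0].element = "Xq"
    with pytest.raises(KeyError, match="Xq"):
        build_molecular_graph(s)


# --- donor-atom ranking ---------------------------------------------------


def _toy_cluster_vs_acceptor(shift):
    """Square donor 'cluster' and a distant single-atom acceptor.

    ``shift`` moves one cluster atom toward the acceptor along x.
    """
    pts = [(-1.0, -1.0, 0.0), (-1.0, 1.0, 0.0), (1.0 + shift, 1.0, 0.0), (1.0, -1.0, 0.0)]
    donor_atoms = [
        AtomRecord(i + 1, f"S{i+1}", "S", "SF4", "A", 1, np.asarray(p)) for i, p in enumerate(pts)
    ]
    acceptor_atom = AtomRecord(9, "FE", "Fe", "HEM", "B", 1, np.array([6.0, 0.0, 0.0]))
    donor = CofactorGroup("cluster", donor_atoms, center_atoms=donor_atoms, edge_atoms=donor_atoms)
    acceptor = CofactorGroup(
        "heme", [acceptor_atom], center_atoms=[acceptor_atom], edge_atoms=[acceptor_atom]
    )
    from redoxpath.atoms import Structure

    return Structure(donor_atoms + [acceptor_atom]), donor, acceptor


def test_symmetric_cluster_atoms_couple_equally():
    s, donor, acceptor = _toy_cluster_vs_acceptor(shift=0.0)
    g = build_molecular_graph(s)
    table = donor_atom_ranking(g, donor, acceptor)
    near = table[table["donor_atom"].isin(["S3", "S4"])]["coupling"]
    assert near.nunique() == 1 or np.allclose(near, near.iloc[0])


def test_closer_cluster_atom_ranks_first():
    s, donor, acceptor = _toy_cluster_vs_acceptor(shift=2.0)
    g = build_molecular_graph(s)
    table = donor_atom_ranking(g, donor, acceptor)
    assert table.iloc[0]["donor_atom"] == "S3"
    # independent check: its solo coupling beats each alternative's
    for _, row in table.iloc[1:].iterrows():
        assert table.iloc[0]["coupling"] >= row["coupling"] - 1e-15


# --- bridging residues ----------------------------------------------------


def test_bridging_residues_single_residue_path():
    s = make_chain_molecule(3)
    for a in s.atoms:  # collapse the chain into one residue
        a.res_seq = 1
    s2 = type(s)(s.atoms)
    g = build_molecular_graph(s2)
    res = best_path(g, [1], [4])
    table = bridging_residues(res)
    assert len(table) == 1 and table.iloc[0]["n_path_atoms"] == 4


def test_bridging_residues_reports_designed_bridge():
    s, truth = make_donor_bridge_acceptor(7.0, bridge=True)
    g = build_molecular_graph(s)
    res = best_path(g, [truth["donor_serial"]], [truth["acceptor_serial"]])
    table = bridging_residues(res)
    assert "BRG" in set(table["res_name"])


def test_bridging_residues_rejects_disconnected():
    with pytest.raises(ValueError):
        bridging_residues(PathwayResult.disconnected())
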