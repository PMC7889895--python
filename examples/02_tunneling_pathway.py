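"""Find the best electron-tunneling route through a donor-bridge-acceptor toy.

Two short covalent chains face each other across a 7 A gap with a lone
"sidechain" carbon poised midway, 3.5 A from each side — the classic geometry
where a bridging residue wins over a direct through-space jump because the
decay-product model scores two short hops (eps_TS(3.5)^2) higher than one
long one (eps_TS(7.0)).
"""

from redoxpath.pathways import CouplingParams, best_path, bridging_residues, build_molecular_graph
from redoxpath.synthetic import make_donor_bridge_acceptor

structure, truth = make_donor_bridge_acceptor(gap=7.0, bridge=True)
params = CouplingParams()
graph = build_molecular_graph(structure, params)

print(f"graph: {graph.number_of_nodes()} atoms, {graph.number_of_edges()} edges")
result = best_path(graph, [truth["donor_serial"]], [truth["acceptor_serial"]])

print(f"\nbest path coupling : {result.total_coupling:.3e} "
      f"(log10 {result.log10_coupling:.2f})")
print(f"steps              : {result.n_covalent} covalent, "
      f"{result.n_hbond} H-bond, {result.n_space} through-space")
print(result.steps_table().to_string(index=False))

print("\nbridging residues along the path:")
print(bridging_residues(result).to_string(index=False))

two_hops = params.epsilon("space", 3.5) ** 2
one_jump = params.epsilon("space", 7.0)
print(f"\nwhy the bridge wins: eps(3.5)^2 = {two_hops:.2e} > eps(7.0) = {one_jump:.2e}")
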