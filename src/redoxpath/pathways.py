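"""Electron-tunneling pathway search on a typed molecular graph.

The decay-product (Beratan-Onuchic "Pathways") model scores a tunneling route
as the product of per-step decay factors ε: a constant ε_C per covalent bond,
and exponentially distance-penalized factors for hydrogen-bond and
through-space steps.  The best route between a donor and an acceptor atom set
maximizes the product ∏ε, equivalently minimizes the additive weight
Σ(-ln ε) — a shortest-path problem with strictly positive weights, solved by
a deterministic label-setting Dijkstra whose exact ties (frequent, because
all covalent steps share ε_C) are broken by the lexicographically smallest
atom-serial sequence.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from heapq import heappop, heappush
from typing import Sequence

import networkx as nx
import numpy as np
import pandas as pd
from scipy.spatial import cKDTree

from .atoms import AtomRecord, CofactorGroup, Structure, coords
from .contacts import HBOND_ELEMENTS
from .data import COVALENT_RADII
from .geometry import group_center

__all__ = [
    "CouplingParams",
    "build_molecular_graph",
    "PathwayResult",
    "best_path",
    "donor_atom_ranking",
    "bridging_residues",
]


@dataclass
class CouplingParams:
    """Decay-factor parameterization of the tunneling model.

    Per-step decay factors:

    * covalent bond:      ε = eps_covalent                       (0.6)
    * hydrogen bond:      ε = eps_covalent² · exp(-β (d - d_HB)) (0.36 at 2.8 Å)
    * through-space jump: ε = ½ eps_covalent · exp(-β (d - d_S)) (0.3 at 1.4 Å)

    with β = beta_space (Å⁻¹), d the heavy-atom distance, d_HB = hbond_offset
    and d_S = space_offset.  These are the standard parameter values of the
    model; all are exposed because published analyses occasionally tune them.
    through_space_cutoff bounds graph size; enlarging it can only add edges
    and therefore never decreases the best coupling.  covalent_slack pads the
    covalent-radius sum when detecting bonds from geometry alone.
    """

    eps_covalent: float = 0.6
    beta_space: float = 1.7
    space_offset: float = 1.4
    space_prefactor: float = 0.5
    hbond_offset: float = 2.8
    through_space_cutoff: float = 6.0
    covalent_slack: float = 0.4
    hbond_min: float = 2.2
    hbond_max: float = 3.5
    covalent_radii: dict[str, float] = field(default_factory=lambda: dict(COVALENT_RADII))

    def __post_init__(self) -> None:
        for name in (
            "eps_covalent",
            "beta_space",
            "space_offset",
            "space_prefactor",
            "hbond_offset",
            "through_space_cutoff",
            "covalent_slack",
        ):
            if getattr(self, name) <= 0:
                raise ValueError(f"{name} must be positive")
        if not self.eps_covalent < 1:
            raise ValueError("eps_covalent must be < 1 for weights to stay positive")

    def epsilon(self, edge_type: str, dist: float) -> float:
        if edge_type == "covalent":
            return self.eps_covalent
        if edge_type == "hbond":
            return self.eps_covalent**2 * math.exp(-self.beta_space * (dist - self.hbond_offset))
        if edge_type == "space":
            return (
                self.space_prefactor
                * self.eps_covalent
                * math.exp(-self.beta_space * (dist - self.space_offset))
            )
        raise ValueError(f"unknown edge type {edge_type!r}")


def build_molecular_graph(
    structure: Structure | Sequence[AtomRecord], params: CouplingParams | None = None
) -> nx.Graph:
    """Typed molecular graph of a heavy-atom structure.

    Nodes are atom serials (each node stores its :class:`AtomRecord`);
    every edge carries ``type`` ("covalent" | "hbond" | "space"),
    ``distance`` (Å) and ``epsilon``.  Covalent edges are detected from
    geometry (distance ≤ covalent-radius sum + slack; metal-ligand Fe-S and
    Fe-N coordination included by construction of the radii table); N/O/S
    pairs of *different residues* inside the H-bond window and not already
    bonded become hbond edges; all remaining pairs within the through-space
    cutoff become space edges.
    """
    params = params or CouplingParams()
    atoms = [a for a in structure if not a.is_hydrogen]
    if not atoms:
        raise ValueError("no heavy atoms to build a graph from")
    for a in atoms:
        if a.element not in params.covalent_radii:
            raise KeyError(f"element {a.element!r} missing from the covalent radii table")

    xyz = coords(atoms)
    radii = np.array([params.covalent_radii[a.element] for a in atoms])
    g = nx.Graph()
    for a in atoms:
        g.add_node(a.serial, atom=a)

    tree = cKDTree(xyz)
    reach = max(params.through_space_cutoff, 2 * radii.max() + params.covalent_slack)
    for i, j in sorted(tree.query_pairs(reach)):
        d = float(np.linalg.norm(xyz[i] - xyz[j]))
        ai, aj = atoms[i], atoms[j]
        if d <= radii[i] + radii[j] + params.covalent_slack:
            etype = "covalent"
        elif (
            ai.element in HBOND_ELEMENTS
            and aj.element in HBOND_ELEMENTS
            and ai.residue_key != aj.residue_key
            and params.hbond_min <= d <= params.hbond_max
        ):
            etype = "hbond"
        elif d <= params.through_space_cutoff:
            etype = "space"
        else:
            continue
        eps = params.epsilon(etype, d)
        if eps >= 1.0:  # extreme short contact: clamp so weights stay positive
            eps = 1.0 - 1e-12
        g.add_edge(ai.serial, aj.serial, type=etype, distance=d, epsilon=eps)
    return g


@dataclass
class PathwayResult:
    """Best tunneling route between donor and acceptor atom sets."""

    atom_sequence: list[AtomRecord]
    edge_sequence: list[dict]
    total_coupling: float
    connected: bool = True

    @property
    def log10_coupling(self) -> float:
        return math.log10(self.total_coupling) if self.connected else -math.inf

    @property
    def n_covalent(self) -> int:
        return sum(e["type"] == "covalent" for e in self.edge_sequence)

    @property
    def n_hbond(self) -> int:
        return sum(e["type"] == "hbond" for e in self.edge_sequence)

    @property
    def n_space(self) -> int:
        return sum(e["type"] == "space" for e in self.edge_sequence)

    @classmethod
    def disconnected(cls) -> "PathwayResult":
        return cls(atom_sequence=[], edge_sequence=[], total_coupling=0.0, connected=False)

    def steps_table(self) -> pd.DataFrame:
        rows = []
        for a, b, e in zip(self.atom_sequence, self.atom_sequence[1:], self.edge_sequence):
            rows.append(
                {
                    "from_atom": f"{a.residue_label}/{a.name}",
                    "to_atom": f"{b.residue_label}/{b.name}",
                    "type": e["type"],
                    "distance": round(e["distance"], 2),
                    "epsilon": e["epsilon"],
                }
            )
        return pd.DataFrame(rows, columns=["from_atom", "to_atom", "type", "distance", "epsilon"])


def best_path(
    g: nx.Graph,
    donors: Sequence[AtomRecord] | Sequence[int],
    acceptors: Sequence[AtomRecord] | Sequence[int],
) -> PathwayResult:
    """Maximum-product tunneling path from any donor to any acceptor atom.

    Runs a multi-source Dijkstra under the additive weight -ln ε (strictly
    positive since every ε < 1), so the returned path is simple.  Exact
    coupling ties are resolved to the lexicographically smallest atom-serial
    sequence, making the result deterministic and reproducible.

    A graph with no donor-acceptor route yields
    ``PathwayResult.disconnected()`` rather than an exception.
    """
    donor_ids = _serials(donors)
    acceptor_ids = _serials(acceptors)
    if not donor_ids or not acceptor_ids:
        raise ValueError("donor and acceptor sets must be non-empty")
    if donor_ids & acceptor_ids:
        raise ValueError("donor and acceptor sets must be disjoint")
    donor_ids = {s for s in donor_ids if s in g}
    acceptor_ids = {s for s in acceptor_ids if s in g}
    if not donor_ids or not acceptor_ids:
        return PathwayResult.disconnected()

    # label-setting Dijkstra; heap priority (cost, path) so that among
    # equal-cost labels the lexicographically smallest serial sequence wins
    settled: dict[int, tuple[float, tuple[int, ...]]] = {}
    heap: list[tuple[float, tuple[int, ...], int]] = []
    for s in sorted(donor_ids):
        heappush(heap, (0.0, (s,), s))
    while heap:
        cost, path, node = heappop(heap)
        if node in settled:
            continue
        settled[node] = (cost, path)
        if acceptor_ids <= settled.keys():
            break
        for nb in g.neighbors(node):
            if nb in settled or nb in donor_ids:
                continue
            eps = g.edges[node, nb]["epsilon"]
            heappush(heap, (cost - math.log(eps), path + (nb,), nb))

    reached = [(settled[s][0], settled[s][1]) for s in acceptor_ids if s in settled]
    if not reached:
        return PathwayResult.disconnected()
    cost, path = min(reached)
    atom_seq = [g.nodes[s]["atom"] for s in path]
    edge_seq = [dict(g.edges[u, v]) for u, v in zip(path, path[1:])]
    coupling = math.prod(e["epsilon"] for e in edge_seq) if edge_seq else 1.0
    return PathwayResult(atom_sequence=atom_seq, edge_sequence=edge_seq, total_coupling=coupling)


def _serials(atoms_or_serials) -> set[int]:
    out = set()
    for x in atoms_or_serials:
        out.add(x.serial if isinstance(x, AtomRecord) else int(x))
    return out


def donor_atom_ranking(
    g: nx.Graph,
    donor_group: CofactorGroup,
    acceptor_group: CofactorGroup,
) -> pd.DataFrame:
    """Rank candidate donor atoms of a cofactor by their exit coupling.

    Each edge atom of the donor group is scored by the best coupling of a
    path from it alone to the acceptor edge set, with the *other* donor-group
    atoms removed from the graph — so an atom is credited for its own exit
    route, not for conduction through the cluster to a better-placed
    neighbour.  Also reports each atom's distance to the acceptor center.
    Sorted by coupling descending (disconnected atoms last), ties by distance.
    """
    if not donor_group.edge_atoms or not acceptor_group.edge_atoms:
        raise ValueError("both groups need non-empty edge sets")
    acceptor_center = group_center(acceptor_group)
    acceptor_ids = _serials(acceptor_group.edge_atoms)
    group_ids = _serials(donor_group.atoms)

    rows = []
    for atom in donor_group.edge_atoms:
        drop = (group_ids - {atom.serial}) & set(g.nodes)
        sub = g.subgraph(set(g.nodes) - drop)
        res = best_path(sub, [atom.serial], acceptor_ids - {atom.serial})
        rows.append(
            {
                "donor_atom": atom.name,
                "serial": atom.serial,
                "coupling": res.total_coupling if res.connected else 0.0,
                "log10_coupling": res.log10_coupling,
                "distance_to_acceptor_center": float(
                    np.linalg.norm(atom.position - acceptor_center)
                ),
            }
        )
    table = pd.DataFrame(rows)
    return table.sort_values(
        ["coupling", "distance_to_acceptor_center"],
        ascending=[False, True],
        kind="stable",
    ).reset_index(drop=True)


def bridging_residues(p: PathwayResult) -> pd.DataFrame:
    """Residues the path traverses, in path order, with per-residue atom counts."""
    if not p.connected:
        raise ValueError("disconnected pathway has no bridging residues")
    order: list[tuple] = []
    counts: dict[tuple, int] = {}
    names: dict[tuple, str] = {}
    for a in p.atom_sequence:
        k = a.residue_key
        if k not in counts:
            order.append(k)
        counts[k] = counts.get(k, 0) + 1
        names[k] = a.res_name
    return pd.DataFrame(
        [
            {
                "chain": k[0],
                "res_seq": k[1],
                "res_name": names[k],
                "n_path_atoms": counts[k],
            }
            for k in order
        ]
    )
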