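"""Independent brute-force oracles used by the test suite.

Each oracle re-derives an expected value by a method unrelated to the
implementation it checks: exhaustive simple-path enumeration for the
maximum-coupling search, a refined SO(3) grid scan for rigid superposition,
and seeded Monte-Carlo surface integration for accessible areas.
"""

from __future__ import annotations

import math

import networkx as nx
import numpy as np


def enumerate_best_path(g: nx.Graph, donors, acceptors):
    """Exhaustive maximum-product path by simple-path enumeration.

    Accumulates the additive cost -ln ε left-to-right along each path (the
    same association order a sequential relaxation uses) and returns
    ``(path_tuple, coupling)`` minimizing ``(cost, path_tuple)``, or None if
    no route exists.
    """
    donors = sorted(set(donors) & set(g.nodes))
    acceptors = sorted(set(acceptors) & set(g.nodes))
    best = None
    for d in donors:
        for a in acceptors:
            if d == a:
                continue
            for path in nx.all_simple_paths(g, d, a):
                if any(p in donors for p in path[1:]):
                    continue  # routes through another donor are dominated
                cost = 0.0
                for u, v in zip(path, path[1:]):
                    cost -= math.log(g.edges[u, v]["epsilon"])
                key = (cost, tuple(path))
                if best is None or key < best:
                    best = key
    if best is None:
        return None
    cost, path = best
    coupling = math.prod(g.edges[u, v]["epsilon"] for u, v in zip(path, path[1:]))
    return path, coupling


def grid_search_rmsd(ref: np.ndarray, mov: np.ndarray, levels: int = 8) -> float:
    """Minimum RMSD over rigid motions by refined scan of rotation space.

    Coarse 20-degree Euler-angle grid followed by local 5x5x5 refinements
    with halving step; the optimal translation for a fixed rotation is the
    centroid difference, applied in closed form.
    """
    ref_c = ref - ref.mean(axis=0)
    mov_c = mov - mov.mean(axis=0)

    def rmsd_for(angles):
        a, b, c = angles
        ca, sa = math.cos(a), math.sin(a)
        cb, sb = math.cos(b), math.sin(b)
        cc, sc = math.cos(c), math.sin(c)
        rz = np.array([[ca, -sa, 0], [sa, ca, 0], [0, 0, 1]])
        ry = np.array([[cb, 0, sb], [0, 1, 0], [-sb, 0, cb]])
        rx = np.array([[1, 0, 0], [0, cc, -sc], [0, sc, cc]])
        rot = rz @ ry @ rx
        diff = mov_c @ rot.T - ref_c
        return math.sqrt((diff**2).sum() / len(ref))

    step = math.radians(20.0)
    best_angles, best = None, math.inf
    grid = np.arange(-math.pi, math.pi, step)
    half = np.arange(-math.pi / 2, math.pi / 2 + 1e-9, step)
    for a in grid:
        for b in half:
            for c in grid:
                r = rmsd_for((a, b, c))
                if r < best:
                    best, best_angles = r, (a, b, c)
    for _ in range(levels):
        step /= 2.0
        a0, b0, c0 = best_angles
        for da in (-step, -step / 2, 0, step / 2, step):
            for db in (-step, -step / 2, 0, step / 2, step):
                for dc in (-step, -step / 2, 0, step / 2, step):
                    r = rmsd_for((a0 + da, b0 + db, c0 + dc))
                    if r < best:
                        best, best_angles = r, (a0 + da, b0 + db, c0 + dc)
    return best


def monte_carlo_sasa(centers, radii, probe, n_points, seed=1234):
    """Seeded Monte-Carlo accessible area of a set of spheres."""
    rng = np.random.default_rng(seed)
    centers = np.asarray(centers, float)
    expanded = np.asarray(radii, float) + probe
    total = 0.0
    for i, (c, r) in enumerate(zip(centers, expanded)):
        pts = rng.normal(size=(n_points, 3))
        pts /= np.linalg.norm(pts, axis=1)[:, None]
        pts = c + r * pts
        accessible = np.ones(n_points, dtype=bool)
        for j, (cj, rj) in enumerate(zip(centers, expanded)):
            if j == i:
                continue
            accessible &= ((pts - cj) ** 2).sum(axis=1) >= rj * rj
        total += accessible.mean() * 4.0 * math.pi * r * r
    return total


def random_molecular_graph(seed: int):
    """Random small atom cloud with a typed coupling graph, for enumeration.

    Box size is chosen so the average degree stays low enough that simple-path
    enumeration on <= 12 nodes is cheap; some draws are disconnected, which is
    a valid case (both search and oracle must report no route).
    """
    from redoxpath.atoms import AtomRecord, Structure
    from redoxpath.pathways import build_molecular_graph

    rng = np.random.default_rng(seed)
    n = int(rng.integers(4, 13))
    pts = rng.uniform(0.0, 14.0, size=(n, 3))
    atoms = [
        AtomRecord(i + 1, "CA", "C", "GLY", "A", i + 1, p) for i, p in enumerate(pts)
    ]
    structure = Structure(atoms)
    return build_molecular_graph(structure), structure
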