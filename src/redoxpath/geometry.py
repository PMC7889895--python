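"""Distance geometry: centers, edge-to-edge distances, superposition, plane
fitting, and tetrapyrrole macrocycle distortion.

These are the measurements used to characterize a redox co-complex: how far
apart two prosthetic groups sit (center-to-center and edge-to-edge), how much
a subunit moves on binding (Kabsch superposition with deviations reported on
atoms *not* used for the fit), and how a heme macrocycle bends out of plane.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy.spatial.distance import cdist
from scipy.spatial.transform import Rotation

from .atoms import AtomRecord, CofactorGroup, Structure, coords, select_atoms

__all__ = [
    "distance",
    "group_center",
    "edge_to_edge",
    "superpose",
    "SuperpositionResult",
    "deviation_profile",
    "fit_plane",
    "PlaneFit",
    "plane_angle",
    "macrocycle_distortion",
    "DistortionProfile",
    "bfactor_profile",
]


def distance(a, b) -> float:
    """Euclidean distance (Å) between two points or two atoms."""
    pa = a.position if isinstance(a, AtomRecord) else np.asarray(a, float)
    pb = b.position if isinstance(b, AtomRecord) else np.asarray(b, float)
    if not (np.all(np.isfinite(pa)) and np.all(np.isfinite(pb))):
        raise ValueError("non-finite coordinates")
    return float(np.linalg.norm(pa - pb))


def group_center(group: CofactorGroup) -> np.ndarray:
    """Center of a cofactor group: the centroid of its designated center atoms.

    With the conventional role tagging this yields the Fe position for a heme
    (one center atom), the Fe4 centroid for a cubane cluster, the Mg for a
    (bacterio)chlorophyll and the Mg-Mg midpoint for a special pair.
    """
    if not group.center_atoms:
        raise ValueError(f"cofactor group {group.label!r} has no center atoms")
    return coords(group.center_atoms).mean(axis=0)


def edge_to_edge(
    group_a: CofactorGroup, group_b: CofactorGroup
) -> tuple[float, tuple[AtomRecord, AtomRecord]]:
    """Minimum heavy-atom distance between two cofactor edge sets.

    Returns the distance and the arg-min atom pair; exact ties are broken by
    the lowest (serial_a, serial_b).  This is the distance that enters the
    empirical tunneling rate ruler.
    """
    for g in (group_a, group_b):
        if not g.edge_atoms:
            raise ValueError(f"cofactor group {g.label!r} has an empty edge set")
    d = cdist(coords(group_a.edge_atoms), coords(group_b.edge_atoms))
    best = None
    for i in range(d.shape[0]):
        for j in range(d.shape[1]):
            key = (d[i, j], group_a.edge_atoms[i].serial, group_b.edge_atoms[j].serial)
            if best is None or key < best:
                best = key
                pair = (group_a.edge_atoms[i], group_b.edge_atoms[j])
    return float(best[0]), pair


@dataclass
class SuperpositionResult:
    """Optimal rigid-body fit of a moving point set onto a reference."""

    rotation: np.ndarray  # 3x3 proper rotation applied to the moving set
    translation: np.ndarray  # so that fitted = R @ mov + t
    rmsd: float
    per_atom_deviation: np.ndarray

    def apply(self, points: np.ndarray) -> np.ndarray:
        return points @ self.rotation.T + self.translation


def superpose(ref_coords, mov_coords) -> SuperpositionResult:
    """Least-squares rigid superposition (Kabsch) of mov onto ref.

    A proper rotation is enforced (no reflection).  Raises on length mismatch,
    fewer than 3 points, or collinear input.
    """
    ref = np.asarray(ref_coords, float)
    mov = np.asarray(mov_coords, float)
    if ref.shape != mov.shape:
        raise ValueError(f"coordinate sets differ in shape: {ref.shape} vs {mov.shape}")
    if ref.ndim != 2 or ref.shape[1] != 3 or ref.shape[0] < 3:
        raise ValueError("need at least 3 points of dimension 3")
    ref_c = ref.mean(axis=0)
    mov_c = mov.mean(axis=0)
    ref0 = ref - ref_c
    mov0 = mov - mov_c
    if np.linalg.matrix_rank(ref0, tol=1e-8) < 2 or np.linalg.matrix_rank(mov0, tol=1e-8) < 2:
        raise ValueError("degenerate (collinear) geometry; superposition is ill-defined")
    rot, _ = Rotation.align_vectors(ref0, mov0)
    R = rot.as_matrix()
    t = ref_c - R @ mov_c
    fitted = mov @ R.T + t
    dev = np.linalg.norm(fitted - ref, axis=1)
    return SuperpositionResult(
        rotation=R,
        translation=t,
        rmsd=float(np.sqrt(np.mean(dev**2))),
        per_atom_deviation=dev,
    )


def _match_atoms(ref: Structure, mov: Structure, query: dict):
    """Pair atoms between two structures by (chain, res_seq, icode, name)."""
    ra = select_atoms(ref, **query)
    ma = select_atoms(mov, **query)
    key = lambda a: (a.chain_id, a.res_seq, a.insertion_code, a.name)
    ref_index = {key(a): a for a in ra}
    mov_index = {key(a): a for a in ma}
    common = [k for k in ref_index if k in mov_index]
    missing = sorted(set(ref_index) ^ set(mov_index))
    return [ref_index[k] for k in common], [mov_index[k] for k in common], missing


def deviation_profile(
    ref: Structure,
    mov: Structure,
    align_on: dict,
    report_on: dict,
    strict: bool = True,
) -> pd.DataFrame:
    """Per-residue deviations of ``report_on`` atoms after aligning on
    ``align_on`` atoms only.

    The superposition is computed from the anchor selection and *applied*,
    never re-fitted, to the reported selection — so that genuine motion of the
    reported region (e.g. a subunit shifting on a rigid scaffold) survives.

    Returns a DataFrame with chain, res_seq, res_name, n_atoms, mean and max
    deviation (Å), sorted by chain then residue number.
    """
    ref_anchor, mov_anchor, missing = _match_atoms(ref, mov, align_on)
    if strict and missing:
        raise ValueError(f"alignment atoms unmatched between structures: {missing[:10]}")
    if len(ref_anchor) < 3:
        raise ValueError("fewer than 3 matched alignment atoms")
    sup = superpose(coords(ref_anchor), coords(mov_anchor))

    ref_rep, mov_rep, missing_rep = _match_atoms(ref, mov, report_on)
    if strict and missing_rep:
        raise ValueError(f"report atoms unmatched between structures: {missing_rep[:10]}")
    if not ref_rep:
        raise ValueError("report selection matched no atom pairs")
    fitted = sup.apply(coords(mov_rep))
    dev = np.linalg.norm(fitted - coords(ref_rep), axis=1)

    rows: dict[tuple, list[float]] = {}
    names: dict[tuple, str] = {}
    for a, d in zip(ref_rep, dev):
        rows.setdefault(a.residue_key, []).append(float(d))
        names[a.residue_key] = a.res_name
    table = pd.DataFrame(
        [
            {
                "chain": k[0],
                "res_seq": k[1],
                "insertion_code": k[2],
                "res_name": names[k],
                "n_atoms": len(v),
                "mean_deviation": float(np.mean(v)),
                "max_deviation": float(np.max(v)),
            }
            for k, v in rows.items()
        ]
    )
    return table.sort_values(["chain", "res_seq", "insertion_code"]).reset_index(drop=True)


@dataclass
class PlaneFit:
    """Total-least-squares plane through a point cloud."""

    centroid: np.ndarray
    normal: np.ndarray  # unit vector; sign convention: positive z, ties by x then y
    rms_residual: float

    def signed_distance(self, points: np.ndarray) -> np.ndarray:
        pts = np.atleast_2d(np.asarray(points, float))
        return (pts - self.centroid) @ self.normal


def fit_plane(points) -> PlaneFit:
    """Best-fit plane by smallest principal axis of the centered cloud."""
    pts = np.asarray(points, float)
    if pts.ndim != 2 or pts.shape[1] != 3 or pts.shape[0] < 3:
        raise ValueError("need at least 3 points of dimension 3")
    centroid = pts.mean(axis=0)
    centered = pts - centroid
    if np.linalg.matrix_rank(centered, tol=1e-10) < 2:
        raise ValueError("collinear points do not define a plane")
    _, _, vt = np.linalg.svd(centered, full_matrices=False)
    normal = vt[-1]
    # deterministic sign: positive z component, ties broken by x, then y
    for comp in (2, 0, 1):
        if abs(normal[comp]) > 1e-12:
            if normal[comp] < 0:
                normal = -normal
            break
    residuals = centered @ normal
    return PlaneFit(
        centroid=centroid,
        normal=normal / np.linalg.norm(normal),
        rms_residual=float(np.sqrt(np.mean(residuals**2))),
    )


def plane_angle(p: PlaneFit, q: PlaneFit) -> float:
    """Dihedral inclination between two planes, folded to [0, 90] degrees."""
    c = abs(float(np.dot(p.normal, q.normal)))
    return float(np.degrees(np.arccos(np.clip(c, -1.0, 1.0))))


_OPPOSITE_RING = {"I": "III", "II": "IV", "III": "I", "IV": "II"}


@dataclass
class DistortionProfile:
    """Out-of-plane distortion of a macrocycle relative to a reference ring."""

    per_atom_out_of_plane: dict[str, float]  # atom name -> signed Å
    bend_axis: np.ndarray
    bend_angle: float  # degrees between reference ring plane and opposite ring plane
    max_deviation_atom: str
    max_deviation: float

    def __post_init__(self) -> None:
        assert abs(self.max_deviation - max(abs(v) for v in self.per_atom_out_of_plane.values())) < 1e-9


def macrocycle_distortion(group: CofactorGroup, reference_ring: str = "I") -> DistortionProfile:
    """Bend of a tetrapyrrole macrocycle measured against one pyrrole ring.

    Fits a plane to the reference ring, reports the signed out-of-plane
    deviation of every macrocycle atom, and quantifies the bend as the angle
    between the reference-ring plane and the plane of the diagonally opposite
    ring (rings I-III or II-IV).  The bend axis is the intersection line of
    those two planes.
    """
    if reference_ring not in group.pyrrole_rings:
        raise ValueError(
            f"group {group.label!r} has no ring map entry for {reference_ring!r}"
        )
    opposite = _OPPOSITE_RING.get(reference_ring)
    if opposite is None or opposite not in group.pyrrole_rings:
        raise ValueError(f"group {group.label!r} lacks the opposite ring {opposite!r}")
    if not group.macrocycle_atoms:
        raise ValueError(f"group {group.label!r} has no macrocycle atoms")

    ref_plane = fit_plane(coords(group.pyrrole_rings[reference_ring]))
    opp_plane = fit_plane(coords(group.pyrrole_rings[opposite]))
    angle = plane_angle(ref_plane, opp_plane)

    axis = np.cross(ref_plane.normal, opp_plane.normal)
    n = np.linalg.norm(axis)
    if n < 1e-9:  # coplanar rings: bend axis undefined, use in-plane diagonal
        diag = fit_plane(coords(group.macrocycle_atoms)).centroid - ref_plane.centroid
        axis = diag if np.linalg.norm(diag) > 1e-9 else np.array([1.0, 0.0, 0.0])
        n = np.linalg.norm(axis)
    axis = axis / n

    signed = ref_plane.signed_distance(coords(group.macrocycle_atoms))
    per_atom = {a.name: float(d) for a, d in zip(group.macrocycle_atoms, signed)}
    worst = max(per_atom, key=lambda k: (abs(per_atom[k]), k))
    return DistortionProfile(
        per_atom_out_of_plane=per_atom,
        bend_axis=axis,
        bend_angle=angle,
        max_deviation_atom=worst,
        max_deviation=abs(per_atom[worst]),
    )


def bfactor_profile(structure: Structure, **selection) -> pd.DataFrame:
    """Per-residue mean heavy-atom B-factor, ranked ascending.

    Low-B residues come first: in a crystal structure these are the most
    ordered residues, and on a binding interface they mark rigidified
    contacts.  Ties are broken by residue number.
    """
    atoms = select_atoms(structure, **selection) if selection else list(structure.atoms)
    atoms = [a for a in atoms if not a.is_hydrogen]
    if not atoms:
        raise ValueError("selection matched no heavy atoms")
    groups: dict[tuple, list[float]] = {}
    names: dict[tuple, str] = {}
    for a in atoms:
        groups.setdefault(a.residue_key, []).append(a.b_factor)
        names[a.residue_key] = a.res_name
    table = pd.DataFrame(
        [
            {
                "chain": k[0],
                "res_seq": k[1],
                "insertion_code": k[2],
                "res_name": names[k],
                "n_atoms": len(v),
                "mean_b": float(np.mean(v)),
            }
            for k, v in groups.items()
        ]
    )
    return table.sort_values(
        ["mean_b", "chain", "res_seq"], kind="stable"
    ).reset_index(drop=True)
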