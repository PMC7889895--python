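"""Synthetic coordinate fixtures with known ground truth.

Every downstream stage of the package (bond detection, pathway search,
surface burial, H-bond detection, superposition, macrocycle distortion) is
exercised on structures built here, where the designed answer is known by
construction: a linear alkane-like chain whose only tunneling route is
through its bonds, a donor-bridge-acceptor toy with one tunable through-space
gap, an idealized planar porphyrin bent by a chosen angle about its I-III
diagonal, a two-body pseudo-protein complex with a designed hydrogen-bond
pair and B-factor gradient, and rigid+noise perturbed copies with known
expected RMSD.

All generators are deterministic under a fixed seed (one
``numpy.random.default_rng(seed)`` stream per call, consumed in documented
order) and emit structures that round-trip through the PDB writer.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np
from scipy.spatial.transform import Rotation

from .atoms import AtomRecord, CofactorGroup, Structure

__all__ = [
    "FixtureSpec",
    "make_chain_molecule",
    "make_donor_bridge_acceptor",
    "make_porphyrin",
    "make_two_body_complex",
    "apply_rigid_noise",
    "make_fixture",
]


@dataclass
class FixtureSpec:
    """Declarative request for one synthetic fixture (used by the CLI)."""

    kind: str  # chain_molecule | donor_bridge_acceptor | porphyrin | two_body_complex
    parameters: dict = field(default_factory=dict)
    seed: int = 0


def _atom(serial, name, element, res_name, chain, res_seq, pos, b=10.0, het=True):
    return AtomRecord(
        serial=serial,
        name=name,
        element=element,
        res_name=res_name,
        chain_id=chain,
        res_seq=res_seq,
        position=np.asarray(pos, float),
        b_factor=b,
        het=het,
    )


def make_chain_molecule(n_bonds: int, bond_length: float = 1.54) -> Structure:
    """Linear chain of ``n_bonds + 1`` carbons at exactly ``bond_length``.

    Consecutive atoms are covalently bonded; all other pairwise distances
    exceed twice the bond length, so geometric bond detection must find
    exactly ``n_bonds`` bonds.  The unique donor-to-acceptor tunneling path
    between the chain ends is the chain itself, with coupling ε_C^n_bonds.
    """
    if n_bonds < 1:
        raise ValueError("n_bonds must be >= 1")
    if not (1.0 <= bond_length <= 2.0):
        raise ValueError("bond_length must lie in [1.0, 2.0] Å")
    atoms = [
        _atom(i + 1, f"C{i + 1}", "C", "LIG", "A", i + 1, (i * bond_length, 0.0, 0.0))
        for i in range(n_bonds + 1)
    ]
    return Structure(atoms)


def make_donor_bridge_acceptor(
    gap: float,
    bridge: bool = False,
    chain_bonds: int = 2,
    bond_length: float = 1.54,
) -> tuple[Structure, dict]:
    """Two short covalent chains separated by one through-space gap.

    The designated edge atoms of the two chains sit exactly ``gap`` Å apart
    along x.  With ``bridge=True`` a lone carbon is placed midway, ``gap/2``
    from each edge atom, mimicking a sidechain relay poised between donor and
    acceptor cofactors.  Returns the structure plus a ground-truth dict with
    the donor/acceptor terminal serials, the gap edge serials and the bridge
    serial (or None).
    """
    if not (2.0 <= gap <= 8.0):
        raise ValueError("gap must lie in [2.0, 8.0] Å")
    if bridge and gap < 4.2:
        raise ValueError("a bridge atom needs gap >= 4.2 Å to stay non-covalent")
    atoms: list[AtomRecord] = []
    serial = 1
    # chain A ends with its edge atom at the origin
    for i in range(chain_bonds + 1):
        x = -(chain_bonds - i) * bond_length
        atoms.append(_atom(serial, f"C{serial}", "C", "LIG", "A", serial, (x, 0, 0)))
        serial += 1
    edge_a = atoms[-1].serial
    bridge_serial = None
    if bridge:
        atoms.append(_atom(serial, "CB", "C", "BRG", "M", serial, (gap / 2.0, 0, 0)))
        bridge_serial = serial
        serial += 1
    # chain B starts with its edge atom at x = gap
    edge_b = serial
    for i in range(chain_bonds + 1):
        x = gap + i * bond_length
        atoms.append(_atom(serial, f"C{serial}", "C", "LIG", "B", serial, (x, 0, 0)))
        serial += 1
    truth = {
        "donor_serial": atoms[0].serial,
        "acceptor_serial": atoms[-1].serial,
        "edge_serials": (edge_a, edge_b),
        "bridge_serial": bridge_serial,
        "gap": gap,
    }
    return Structure(atoms), truth


_RING_LABELS = ("I", "II", "III", "IV")
_RING_SUFFIX = {"I": "A", "II": "B", "III": "C", "IV": "D"}
_RING_AZIMUTH = {"I": 0.0, "II": 90.0, "III": 180.0, "IV": 270.0}


def make_porphyrin(bend_deg: float) -> tuple[Structure, CofactorGroup]:
    """Idealized 24-atom porphyrin-like macrocycle with a controlled bend.

    Four planar five-membered rings (N + 4 C each) plus four meso carbons are
    laid out in the z = 0 plane; rings III and IV and the meso carbon between
    them are then rigidly rotated by ``bend_deg`` about the x axis — the
    diagonal through rings I and III — so the angle between the ring-I and
    ring-III planes equals the applied bend exactly.

    Returns the structure and a :class:`CofactorGroup` with the full
    macrocycle and the ring I-IV atom map.
    """
    if not (0.0 <= bend_deg <= 30.0):
        raise ValueError("bend_deg must lie in [0, 30] degrees")
    ring_radius = 1.15
    ring_center_dist = 3.0
    meso_dist = 3.4

    atoms: list[AtomRecord] = []
    ring_map: dict[str, list[AtomRecord]] = {}
    serial = 1
    for label in _RING_LABELS:
        suffix = _RING_SUFFIX[label]
        theta = math.radians(_RING_AZIMUTH[label])
        center = ring_center_dist * np.array([math.cos(theta), math.sin(theta), 0.0])
        u = -center / np.linalg.norm(center)  # toward the macrocycle center
        v = np.array([-u[1], u[0], 0.0])
        names = [f"N{suffix}", f"C1{suffix}", f"C2{suffix}", f"C3{suffix}", f"C4{suffix}"]
        angles = [0.0, 72.0, 144.0, -144.0, -72.0]
        ring_atoms = []
        for name, ang in zip(names, angles):
            a = math.radians(ang)
            pos = center + ring_radius * (math.cos(a) * u + math.sin(a) * v)
            element = "N" if name.startswith("N") else "C"
            rec = _atom(serial, name, element, "POR", "A", 1, pos)
            atoms.append(rec)
            ring_atoms.append(rec)
            serial += 1
        ring_map[label] = ring_atoms
    for name, az in (("CHA", 45.0), ("CHB", 135.0), ("CHC", 225.0), ("CHD", 315.0)):
        t = math.radians(az)
        pos = meso_dist * np.array([math.cos(t), math.sin(t), 0.0])
        atoms.append(_atom(serial, name, "C", "POR", "A", 1, pos))
        serial += 1

    if bend_deg > 0:
        theta = math.radians(bend_deg)
        rot = np.array(
            [
                [1.0, 0.0, 0.0],
                [0.0, math.cos(theta), -math.sin(theta)],
                [0.0, math.sin(theta), math.cos(theta)],
            ]
        )
        movers = {a.serial for a in ring_map["III"] + ring_map["IV"]}
        movers.add(next(a.serial for a in atoms if a.name == "CHC"))
        for a in atoms:
            if a.serial in movers:
                a.position = rot @ a.position

    structure = Structure(atoms)
    group = CofactorGroup(
        label="porphyrin",
        atoms=list(atoms),
        center_atoms=list(atoms),
        edge_atoms=list(atoms),
        macrocycle_atoms=list(atoms),
        pyrrole_rings=ring_map,
    )
    return structure, group


def make_two_body_complex(
    separation: float,
    n_contact_pairs: int = 9,
    hbond_distance: float = 2.8,
    seed: int = 0,
) -> tuple[Structure, dict]:
    """Two compact pseudo-protein blobs facing each other across a gap.

    Each body is a jittered cubic lattice (3.5 Å spacing, jitter ±0.15 Å, so
    heavy atoms stay >= 2.9 Å apart) of single-carbon "residues"; the facing
    surfaces are k×k grids with k² >= ``n_contact_pairs``.  Exactly one
    designed donor/acceptor pair — a Thr-like hydroxyl oxygen on side A and a
    Trp-like indole nitrogen on side B — is placed at the face centers; when
    the bodies are close enough for the pair to protrude no more than ~1 Å
    it is realized at exactly ``hbond_distance``, otherwise the two atoms sit
    flush on their faces (no spurious bond at large separations).  Per-residue
    B-factors increase linearly with distance from the interface midplane.

    Returns the structure and a ground-truth dict (designed pair, face
    residue keys, B-factor law).
    """
    if separation < 0:
        raise ValueError("separation must be non-negative")
    if not (2.2 <= hbond_distance <= 3.5):
        raise ValueError("hbond_distance must lie in [2.2, 3.5] Å")
    rng = np.random.default_rng(seed)
    spacing = 3.5
    k = max(2, math.ceil(math.sqrt(n_contact_pairs)))
    depth = 3
    offsets = (np.arange(k) - (k - 1) / 2.0) * spacing

    atoms: list[AtomRecord] = []
    face_keys: dict[str, list] = {"A": [], "B": []}
    serial = 1

    def add_body(chain: str, sign: float):
        nonlocal serial
        res_seq = 1
        for layer in range(depth):
            x = sign * (separation / 2.0 + layer * spacing)
            for yi in offsets:
                for zi in offsets:
                    if layer == 0 and abs(yi) < 1e-9 and abs(zi) < 1e-9:
                        continue  # face center reserved for the designed pair
                    jitter = rng.uniform(-0.15, 0.15, size=3)
                    pos = np.array([x, yi, zi]) + jitter
                    b = 5.0 + 2.0 * abs(pos[0])
                    atoms.append(
                        _atom(serial, "CA", "C", "GLY", chain, res_seq, pos, b=b, het=False)
                    )
                    if layer == 0:
                        face_keys[chain].append((chain, res_seq, ""))
                    serial += 1
                    res_seq += 1
        return res_seq

    # designed H-bond pair at the face centers; atoms stay chain-contiguous
    max_protrusion = 1.0
    if separation <= hbond_distance + 2 * max_protrusion:
        xd, xa = -hbond_distance / 2.0, +hbond_distance / 2.0
        realized = hbond_distance
    else:
        xd, xa = -separation / 2.0, +separation / 2.0
        realized = separation

    next_a = add_body("A", -1.0)
    donor = _atom(serial, "OG1", "O", "THR", "A", next_a, (xd, 0.0, 0.0),
                  b=5.0 + 2.0 * abs(xd), het=False)
    atoms.append(donor)
    serial += 1
    next_b = add_body("B", +1.0)
    acceptor = _atom(serial, "NE1", "N", "TRP", "B", next_b, (xa, 0.0, 0.0),
                     b=5.0 + 2.0 * abs(xa), het=False)
    atoms.append(acceptor)
    face_keys["A"].append(donor.residue_key)
    face_keys["B"].append(acceptor.residue_key)

    truth = {
        "designed_pair": (donor.residue_key, acceptor.residue_key),
        "designed_pair_atoms": ("OG1", "NE1"),
        "designed_distance": realized,
        "hbond_realized": separation <= hbond_distance + 2 * max_protrusion,
        "face_residues": face_keys,
        "b_law": "B = 5 + 2 |x|, x = distance from interface midplane",
    }
    return Structure(atoms), truth


def apply_rigid_noise(structure: Structure, seed: int, noise_sigma: float) -> Structure:
    """Random rigid motion plus isotropic Gaussian coordinate noise.

    Draws, in order, a uniform random rotation (quaternion method), a uniform
    translation in [-10, 10]³ Å, and per-coordinate Gaussian displacements of
    standard deviation ``noise_sigma``.  With ``noise_sigma = 0`` the motion
    is exactly rigid and superposition recovers RMSD 0; with noise, the
    expected recovered RMSD is ``noise_sigma * sqrt(3)`` for large n.
    """
    if noise_sigma < 0:
        raise ValueError("noise_sigma must be non-negative")
    rng = np.random.default_rng(seed)
    quat = rng.normal(size=4)
    rot = Rotation.from_quat(quat / np.linalg.norm(quat)).as_matrix()
    trans = rng.uniform(-10.0, 10.0, size=3)
    noise = rng.normal(0.0, noise_sigma, size=(len(structure), 3)) if noise_sigma > 0 else 0.0
    moved = structure.transformed(rot, trans)
    if noise_sigma > 0:
        moved = Structure(
            [a.moved_to(a.position + n) for a, n in zip(moved.atoms, noise)],
            metadata=dict(moved.metadata),
        )
    return moved


def make_fixture(spec: FixtureSpec) -> tuple[Structure, dict]:
    """Dispatch a :class:`FixtureSpec` to its generator.

    Returns the structure and a JSON-serializable ground-truth dict.
    """
    p = dict(spec.parameters)
    if spec.kind == "chain_molecule":
        s = make_chain_molecule(int(p.get("n_bonds", 3)), float(p.get("bond_length", 1.54)))
        return s, {"n_bonds": int(p.get("n_bonds", 3))}
    if spec.kind == "donor_bridge_acceptor":
        s, truth = make_donor_bridge_acceptor(
            float(p.get("gap", 7.0)), bool(p.get("bridge", True))
        )
        return s, truth
    if spec.kind == "porphyrin":
        s, group = make_porphyrin(float(p.get("bend_deg", 10.0)))
        return s, {
            "bend_deg": float(p.get("bend_deg", 10.0)),
            "rings": {k: [a.name for a in v] for k, v in group.pyrrole_rings.items()},
        }
    if spec.kind == "two_body_complex":
        s, truth = make_two_body_complex(
            float(p.get("separation", 3.0)),
            int(p.get("n_contact_pairs", 9)),
            float(p.get("hbond_distance", 2.8)),
            seed=spec.seed,
        )
        truth = dict(truth)
        truth["designed_pair"] = [list(truth["designed_pair"][0]), list(truth["designed_pair"][1])]
        truth["face_residues"] = {
            c: [list(k) for k in keys] for c, keys in truth["face_residues"].items()
        }
        return s, truth
    raise ValueError(f"unknown fixture kind {spec.kind!r}")
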