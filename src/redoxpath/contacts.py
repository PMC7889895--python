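"""Hydrogen-bond detection and interprotein contact tables.

The criterion is purely geometric on heavy atoms: an N/O/S–N/O/S pair across
the interface within a distance window counts as a hydrogen bond, classified
strong (≤ 3.0 Å) or weak.  Crystal structures at moderate resolution carry no
hydrogens, so no donor-H-acceptor angle term is applied; donor/acceptor roles
are assigned from sidechain chemistry templates where known and labelled
"ambiguous" otherwise.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Sequence

import numpy as np
import pandas as pd
from scipy.spatial import cKDTree

from .atoms import AtomRecord, ResidueKey, Structure, coords, select_atoms
from .data import hbond_role

__all__ = [
    "HBond",
    "detect_hbonds",
    "closest_contact",
    "interface_bfactor_summary",
]

HBOND_ELEMENTS = frozenset({"N", "O", "S"})
STRONG_MAX = 3.0  # Å; configurable boundary between strong and weak


@dataclass
class HBond:
    donor_atom: AtomRecord
    acceptor_atom: AtomRecord
    distance: float
    strength_class: str  # "strong" (<= 3.0 Å) or "weak"
    role_assignment: str  # "template" or "ambiguous"

    @property
    def donor_residue(self) -> str:
        return self.donor_atom.residue_label

    @property
    def acceptor_residue(self) -> str:
        return self.acceptor_atom.residue_label

    def as_row(self) -> dict:
        return {
            "donor_residue": self.donor_residue,
            "donor_atom": self.donor_atom.name,
            "acceptor_residue": self.acceptor_residue,
            "acceptor_atom": self.acceptor_atom.name,
            "distance": round(self.distance, 2),
            "strength": self.strength_class,
            "roles": self.role_assignment,
        }


def detect_hbonds(
    a: Sequence[AtomRecord],
    b: Sequence[AtomRecord],
    max_distance: float = 3.5,
    min_distance: float = 2.2,
    strong_max: float = STRONG_MAX,
) -> list[HBond]:
    """Geometric hydrogen bonds across the interface between two atom sets.

    Every N/O/S pair (one atom from each side) with distance inside
    [min_distance, max_distance] is reported, sorted by distance.  Where the
    sidechain templates determine a unique donor/acceptor assignment it is
    used; otherwise the pair is kept with roles in input order and labelled
    "ambiguous".
    """
    if max_distance < min_distance:
        raise ValueError("max_distance < min_distance")
    ca = [at for at in a if at.element in HBOND_ELEMENTS and not at.is_hydrogen]
    cb = [at for at in b if at.element in HBOND_ELEMENTS and not at.is_hydrogen]
    if not ca or not cb:
        return []
    tree = cKDTree(coords(cb))
    bonds: list[HBond] = []
    for at_a in ca:
        for j in tree.query_ball_point(at_a.position, max_distance):
            at_b = cb[j]
            d = float(np.linalg.norm(at_a.position - at_b.position))
            if d < min_distance or d > max_distance:
                continue
            donor, acceptor, how = _assign_roles(at_a, at_b)
            bonds.append(
                HBond(
                    donor_atom=donor,
                    acceptor_atom=acceptor,
                    distance=d,
                    strength_class="strong" if d <= strong_max else "weak",
                    role_assignment=how,
                )
            )
    bonds.sort(key=lambda h: (h.distance, h.donor_atom.serial, h.acceptor_atom.serial))
    return bonds


def _assign_roles(at_a: AtomRecord, at_b: AtomRecord):
    role_a = hbond_role(at_a.res_name, at_a.name)
    role_b = hbond_role(at_b.res_name, at_b.name)
    a_donates = role_a in ("donor", "both")
    a_accepts = role_a in ("acceptor", "both")
    b_donates = role_b in ("donor", "both")
    b_accepts = role_b in ("acceptor", "both")
    if a_donates and b_accepts and not (b_donates and a_accepts):
        return at_a, at_b, "template"
    if b_donates and a_accepts and not (a_donates and b_accepts):
        return at_b, at_a, "template"
    return at_a, at_b, "ambiguous"


def hbond_table(bonds: Sequence[HBond]) -> pd.DataFrame:
    """H-bond list as a DataFrame mirroring the usual supplementary layout."""
    return pd.DataFrame(
        [h.as_row() for h in bonds],
        columns=[
            "donor_residue",
            "donor_atom",
            "acceptor_residue",
            "acceptor_atom",
            "distance",
            "strength",
            "roles",
        ],
    )


def closest_contact(
    a: Sequence[AtomRecord], b: Sequence[AtomRecord]
) -> tuple[float, tuple[AtomRecord, AtomRecord]]:
    """Global minimum heavy-atom distance across the interface.

    Ties are broken by the lowest (serial_a, serial_b) pair.
    """
    ha = [at for at in a if not at.is_hydrogen]
    hb = [at for at in b if not at.is_hydrogen]
    if not ha or not hb:
        raise ValueError("both atom sets must contain heavy atoms")
    tree = cKDTree(coords(hb))
    dists, idx = tree.query(coords(ha))
    best = None
    for i, (d, j) in enumerate(zip(dists, idx)):
        key = (float(d), ha[i].serial, hb[int(j)].serial)
        if best is None or key < best:
            best = key
            pair = (ha[i], hb[int(j)])
    # re-scan side b for exact ties with a smaller b-serial
    d_best = best[0]
    for i, at_a in enumerate(ha):
        for j in tree.query_ball_point(at_a.position, d_best + 1e-9):
            d = float(np.linalg.norm(at_a.position - hb[j].position))
            key = (d, at_a.serial, hb[j].serial)
            if key < best:
                best = key
                pair = (at_a, hb[j])
    return best[0], pair


def interface_bfactor_summary(
    structure: Structure,
    side: dict,
    interface_set: Sequence[ResidueKey],
    k_lowest: int = 2,
) -> dict:
    """Compare B-factors of interface vs non-interface residues on one side.

    ``side`` is a selection query (e.g. ``{"chain": "Z"}``) naming one binding
    partner; ``interface_set`` lists its interface residues as
    (chain, res_seq, insertion_code) keys.  Returns group means/medians and
    the ``k_lowest`` lowest-B residues of the interface — in a complex whose
    interface rigidifies on binding these are the anchor residues.
    """
    atoms = select_atoms(structure, **side)
    atoms = [a for a in atoms if not a.is_hydrogen]
    keys = set(interface_set)
    side_keys = {a.residue_key for a in atoms}
    if not keys <= side_keys:
        raise ValueError(f"interface residues outside the side selection: {sorted(keys - side_keys)[:5]}")

    per_res: dict[ResidueKey, list[float]] = {}
    names: dict[ResidueKey, str] = {}
    for a in atoms:
        per_res.setdefault(a.residue_key, []).append(a.b_factor)
        names[a.residue_key] = a.res_name
    means = {k: float(np.mean(v)) for k, v in per_res.items()}
    inside = {k: v for k, v in means.items() if k in keys}
    outside = {k: v for k, v in means.items() if k not in keys}
    if not inside or not outside:
        raise ValueError("both interface and non-interface groups must be non-empty")

    ranked = sorted(inside, key=lambda k: (inside[k], k[1]))
    return {
        "interface_mean_b": float(np.mean(list(inside.values()))),
        "interface_median_b": float(np.median(list(inside.values()))),
        "noninterface_mean_b": float(np.mean(list(outside.values()))),
        "noninterface_median_b": float(np.median(list(outside.values()))),
        "lowest_b_residues": [
            {"chain": k[0], "res_seq": k[1], "res_name": names[k], "mean_b": inside[k]}
            for k in ranked[:k_lowest]
        ],
    }
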