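"""Solvent-accessible surface area and buried interface area.

A deterministic Shrake-Rupley implementation: each atom carries a
quasi-uniform golden-spiral point sphere of radius r_vdw + probe; points not
buried inside any neighbour's expanded sphere count as accessible.  No random
numbers are involved, so areas are exactly reproducible.

Buried area of a two-body complex is the SASA lost on association,
``sasa(A) + sasa(B) - sasa(A∪B)``; the contact area is its per-interface
half.  Both conventions are reported because published interface sizes use
either.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Iterable, Sequence

import numpy as np
import pandas as pd
from scipy.spatial import cKDTree

from .atoms import WATER_RESIDUES, AtomRecord, coords
from .data import VDW_RADII

__all__ = [
    "SasaParams",
    "SasaResult",
    "sphere_points",
    "sasa",
    "buried_area",
    "interface_residues",
]


@dataclass
class SasaParams:
    """Parameters of the surface computation.

    probe_radius: solvent probe, Å (1.4 Å water probe by default).
    n_points: sphere sample points per atom; 960 gives < 1% error on
        convex fixtures and is stable to within ~1% of a 4000-point run.
    radii_table: element -> van der Waals radius, Å.
    include_hydrogens / include_waters: excluded by default — the intended
        inputs are heavy-atom crystal structures where modelled waters are
        not part of either binding partner.
    """

    probe_radius: float = 1.4
    n_points: int = 960
    radii_table: dict[str, float] = field(default_factory=lambda: dict(VDW_RADII))
    include_hydrogens: bool = False
    include_waters: bool = False

    def __post_init__(self) -> None:
        if self.probe_radius < 0:
            raise ValueError("probe_radius must be non-negative")
        if self.n_points < 60:
            raise ValueError("n_points < 60 gives unusable sampling error")
        if any(r <= 0 for r in self.radii_table.values()):
            raise ValueError("all van der Waals radii must be positive")

    def radius(self, element: str) -> float:
        try:
            return self.radii_table[element]
        except KeyError:
            raise KeyError(
                f"element {element!r} missing from the van der Waals radii table"
            ) from None


@dataclass
class SasaResult:
    per_atom_area: np.ndarray  # Å², aligned to the filtered atom list
    atoms: list[AtomRecord]

    @property
    def total(self) -> float:
        return float(self.per_atom_area.sum())


def sphere_points(n: int) -> np.ndarray:
    """n quasi-uniform unit-sphere points on a golden-section spiral."""
    i = np.arange(n, dtype=float) + 0.5
    phi = np.arccos(1.0 - 2.0 * i / n)
    theta = np.pi * (1.0 + np.sqrt(5.0)) * i
    return np.column_stack(
        (np.sin(phi) * np.cos(theta), np.sin(phi) * np.sin(theta), np.cos(phi))
    )


def _filter(atoms: Iterable[AtomRecord], params: SasaParams) -> list[AtomRecord]:
    out = []
    for a in atoms:
        if not params.include_hydrogens and a.is_hydrogen:
            continue
        if not params.include_waters and a.res_name in WATER_RESIDUES:
            continue
        out.append(a)
    return out


def sasa(atoms: Sequence[AtomRecord], params: SasaParams | None = None) -> SasaResult:
    """Shrake-Rupley solvent-accessible surface area of an atom set."""
    params = params or SasaParams()
    kept = _filter(atoms, params)
    if not kept:
        raise ValueError("no atoms left after filtering; nothing to measure")
    xyz = coords(kept)
    radii = np.array([params.radius(a.element) for a in kept]) + params.probe_radius
    unit = sphere_points(params.n_points)

    tree = cKDTree(xyz)
    areas = np.zeros(len(kept))
    for i, (center, r) in enumerate(zip(xyz, radii)):
        pts = center + r * unit
        neighbours = [j for j in tree.query_ball_point(center, r + radii.max()) if j != i]
        if neighbours:
            nb_xyz = xyz[neighbours]
            nb_r = radii[neighbours]
            d2 = ((pts[:, None, :] - nb_xyz[None, :, :]) ** 2).sum(axis=2)
            buried = (d2 < (nb_r**2)[None, :]).any(axis=1)
            frac = 1.0 - buried.mean()
        else:
            frac = 1.0
        areas[i] = frac * 4.0 * np.pi * r * r
    return SasaResult(per_atom_area=areas, atoms=kept)


def buried_area(
    a: Sequence[AtomRecord], b: Sequence[AtomRecord], params: SasaParams | None = None
) -> tuple[float, float]:
    """SASA buried on association of two atom sets.

    Returns ``(buried_total, contact_area)`` with
    ``buried_total = sasa(a) + sasa(b) - sasa(a ∪ b)`` and
    ``contact_area = buried_total / 2`` (the area of one face of the
    interface).  The two sets must be disjoint.
    """
    params = params or SasaParams()
    _check_disjoint(a, b)
    total_a = sasa(a, params).total
    total_b = sasa(b, params).total
    total_ab = sasa(list(a) + list(b), params).total
    buried = max(0.0, total_a + total_b - total_ab)
    return buried, buried / 2.0


def interface_residues(
    a: Sequence[AtomRecord],
    b: Sequence[AtomRecord],
    params: SasaParams | None = None,
    min_delta: float = 1.0,
) -> pd.DataFrame:
    """Residues losing at least ``min_delta`` Å² of SASA on association.

    One row per residue with its side ("a" or "b"), summed per-residue
    ΔASA, sorted by ΔASA descending.
    """
    params = params or SasaParams()
    _check_disjoint(a, b)
    iso_a = sasa(a, params)
    iso_b = sasa(b, params)
    combined = sasa(list(a) + list(b), params)
    per_atom_complexed = {
        _atom_id(at): area for at, area in zip(combined.atoms, combined.per_atom_area)
    }

    rows = []
    for side, iso in (("a", iso_a), ("b", iso_b)):
        delta_by_res: dict[tuple, float] = {}
        names: dict[tuple, str] = {}
        for at, iso_area in zip(iso.atoms, iso.per_atom_area):
            delta = iso_area - per_atom_complexed[_atom_id(at)]
            delta_by_res[at.residue_key] = delta_by_res.get(at.residue_key, 0.0) + delta
            names[at.residue_key] = at.res_name
        for key, delta in delta_by_res.items():
            if delta >= min_delta:
                rows.append(
                    {
                        "side": side,
                        "chain": key[0],
                        "res_seq": key[1],
                        "insertion_code": key[2],
                        "res_name": names[key],
                        "delta_asa": float(delta),
                    }
                )
    table = pd.DataFrame(
        rows, columns=["side", "chain", "res_seq", "insertion_code", "res_name", "delta_asa"]
    )
    return table.sort_values("delta_asa", ascending=False, kind="stable").reset_index(
        drop=True
    )


def _atom_id(a: AtomRecord) -> tuple:
    return (a.chain_id, a.res_seq, a.insertion_code, a.name, a.alt_loc)


def _check_disjoint(a: Sequence[AtomRecord], b: Sequence[AtomRecord]) -> None:
    overlap = {_atom_id(x) for x in a} & {_atom_id(x) for x in b}
    if overlap:
        raise ValueError(f"atom sets share identities: {sorted(overlap)[:5]}")
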