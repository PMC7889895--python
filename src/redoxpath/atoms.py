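"""Core coordinate containers: atoms, structures, and cofactor groups.

An :class:`AtomRecord` is the universal currency of the package: every
downstream computation (surface area, hydrogen bonds, tunneling graphs,
superposition) consumes plain lists of atom records, so analyses compose
freely with :func:`select_atoms`.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from typing import Iterable, Mapping, Sequence

import numpy as np

__all__ = [
    "AtomRecord",
    "Structure",
    "CofactorGroup",
    "ResidueKey",
    "select_atoms",
    "coords",
]

#: standard amino-acid residue names (used to set ATOM vs HETATM on write)
STANDARD_RESIDUES = frozenset(
    "ALA ARG ASN ASP CYS GLN GLU GLY HIS ILE LEU LYS MET PHE PRO SER THR TRP TYR VAL".split()
)

WATER_RESIDUES = frozenset({"HOH", "WAT", "DOD"})

ResidueKey = tuple[str, int, str]  # (chain_id, res_seq, insertion_code)


@dataclass(slots=True)
class AtomRecord:
    """One atom of a coordinate file.

    Positions are Cartesian ångström exactly as deposited; ``b_factor`` is the
    isotropic displacement parameter in Å².
    """

    serial: int
    name: str
    element: str
    res_name: str
    chain_id: str
    res_seq: int
    position: np.ndarray
    alt_loc: str = ""
    insertion_code: str = ""
    occupancy: float = 1.0
    b_factor: float = 0.0
    het: bool = False

    def __post_init__(self) -> None:
        self.position = np.asarray(self.position, dtype=float)
        if self.position.shape != (3,):
            raise ValueError(f"position must be a 3-vector, got {self.position.shape}")
        if not np.all(np.isfinite(self.position)):
            raise ValueError(f"non-finite coordinates for atom {self.name}")
        if not (0.0 <= self.occupancy <= 1.0):
            raise ValueError(f"occupancy {self.occupancy} outside [0, 1] for atom {self.name}")
        if not self.element:
            self.element = _element_from_name(self.name)
        self.element = self.element.strip().capitalize()

    @property
    def residue_key(self) -> ResidueKey:
        return (self.chain_id, self.res_seq, self.insertion_code)

    @property
    def residue_label(self) -> str:
        icode = self.insertion_code.strip()
        return f"{self.res_name}{self.res_seq}{icode}:{self.chain_id}"

    @property
    def is_hydrogen(self) -> bool:
        return self.element in ("H", "D")

    def moved_to(self, position: np.ndarray) -> "AtomRecord":
        return replace(self, position=np.asarray(position, dtype=float))


def _element_from_name(name: str) -> str:
    """Infer the element from a PDB atom name (columns 13-16 convention)."""
    stripped = name.strip()
    if not stripped:
        raise ValueError("cannot infer element from empty atom name")
    two = {"FE", "MG", "ZN", "MN", "CU", "NA", "CL", "BR", "CA"}
    head = stripped[:2].upper()
    # PDB convention: two-char elements occupy column 13; atom names like
    # "CA " (C-alpha) start in column 14.  Without column info we treat a
    # leading digit as remoteness and fall back to the first letter, except
    # for the unambiguous metal names.
    if head in two and (len(stripped) <= 2 or not stripped[2:].isalpha()):
        if head in ("CA", "NA") and len(stripped) == 2:
            # "CA"/"NA" are almost always C-alpha / N in protein files
            return stripped[0]
        return head.capitalize()
    for ch in stripped:
        if ch.isalpha():
            return ch.upper()
    raise ValueError(f"cannot infer element from atom name {name!r}")


@dataclass
class Structure:
    """An ordered list of atoms plus file-level metadata.

    ``metadata`` may carry ``title``, ``accession``, ``cell`` (a, b, c, alpha,
    beta, gamma in Å / degrees) and ``space_group`` when the source file
    provides them.
    """

    atoms: list[AtomRecord]
    metadata: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        seen: set[tuple] = set()
        for a in self.atoms:
            key = (a.chain_id, a.res_seq, a.insertion_code, a.name, a.alt_loc)
            if key in seen:
                raise ValueError(f"duplicate atom identity {key}")
            seen.add(key)

    def __len__(self) -> int:
        return len(self.atoms)

    def __iter__(self):
        return iter(self.atoms)

    @property
    def chain_ids(self) -> list[str]:
        out: list[str] = []
        for a in self.atoms:
            if a.chain_id not in out:
                out.append(a.chain_id)
        return out

    def residues(self) -> dict[ResidueKey, list[AtomRecord]]:
        """Residue index in file order: (chain, res_seq, icode) -> atoms."""
        out: dict[ResidueKey, list[AtomRecord]] = {}
        for a in self.atoms:
            out.setdefault(a.residue_key, []).append(a)
        return out

    def select(self, **query) -> list[AtomRecord]:
        return select_atoms(self, **query)

    def transformed(self, rotation: np.ndarray, translation: np.ndarray) -> "Structure":
        """Return a copy with positions mapped through x -> R x + t."""
        R = np.asarray(rotation, float)
        t = np.asarray(translation, float)
        new = [a.moved_to(R @ a.position + t) for a in self.atoms]
        return Structure(new, metadata=dict(self.metadata))


def select_atoms(
    structure: Structure | Iterable[AtomRecord],
    chain: str | Sequence[str] | None = None,
    res_name: str | Sequence[str] | None = None,
    res_seq: int | tuple[int, int] | Sequence[int] | None = None,
    name: str | Sequence[str] | None = None,
    element: str | Sequence[str] | None = None,
    het: bool | None = None,
) -> list[AtomRecord]:
    """Atoms matching the conjunction of all given criteria, in file order.

    ``res_seq`` accepts a single number, an inclusive ``(lo, hi)`` range, or an
    explicit list.  An empty result is valid, not an error.
    """

    def as_set(v):
        if v is None:
            return None
        if isinstance(v, str):
            return {v}
        return set(v)

    chains = as_set(chain)
    res_names = as_set(res_name)
    names = as_set(name)
    elements = {e.capitalize() for e in as_set(element)} if element is not None else None

    res_range: tuple[int, int] | None = None
    res_set: set[int] | None = None
    if res_seq is not None:
        if isinstance(res_seq, int):
            res_set = {res_seq}
        elif isinstance(res_seq, tuple) and len(res_seq) == 2:
            res_range = (int(res_seq[0]), int(res_seq[1]))
        else:
            res_set = {int(r) for r in res_seq}

    out = []
    for a in structure:
        if chains is not None and a.chain_id not in chains:
            continue
        if res_names is not None and a.res_name not in res_names:
            continue
        if res_set is not None and a.res_seq not in res_set:
            continue
        if res_range is not None and not (res_range[0] <= a.res_seq <= res_range[1]):
            continue
        if names is not None and a.name not in names:
            continue
        if elements is not None and a.element not in elements:
            continue
        if het is not None and a.het != het:
            continue
        out.append(a)
    return out


def coords(atoms: Iterable[AtomRecord]) -> np.ndarray:
    """(n, 3) coordinate array for a list of atoms."""
    pts = [a.position for a in atoms]
    if not pts:
        return np.empty((0, 3))
    return np.vstack(pts)


@dataclass
class CofactorGroup:
    """A named prosthetic group with role-tagged atom subsets.

    ``center_atoms`` define the group center (the Fe of a heme, the four Fe of
    a cubane cluster, the two Mg of a bacteriochlorophyll special pair);
    ``edge_atoms`` define the conjugated edge entering edge-to-edge tunneling
    distances; ``pyrrole_rings`` optionally maps ring labels ("I".."IV") to
    atom subsets of a tetrapyrrole macrocycle.
    """

    label: str
    atoms: list[AtomRecord]
    center_atoms: list[AtomRecord] = field(default_factory=list)
    edge_atoms: list[AtomRecord] = field(default_factory=list)
    macrocycle_atoms: list[AtomRecord] = field(default_factory=list)
    pyrrole_rings: Mapping[str, list[AtomRecord]] = field(default_factory=dict)

    def __post_init__(self) -> None:
        ids = {id(a) for a in self.atoms}
        for role, subset in (
            ("center_atoms", self.center_atoms),
            ("edge_atoms", self.edge_atoms),
            ("macrocycle_atoms", self.macrocycle_atoms),
        ):
            if not all(id(a) in ids for a in subset):
                raise ValueError(f"{role} of group {self.label!r} is not a subset of atoms")
        ring_ids: set[int] = set()
        for ring, subset in self.pyrrole_rings.items():
            sub_ids = {id(a) for a in subset}
            if ring_ids & sub_ids:
                raise ValueError(f"pyrrole rings of group {self.label!r} overlap at ring {ring}")
            ring_ids |= sub_ids
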