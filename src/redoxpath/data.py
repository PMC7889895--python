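"""Shared parameter tables: van der Waals radii, covalent radii, H-bond roles.

Both radii tables are deliberately small, explicit and editable: the analyses
only ever meet heavy atoms of proteins and their common prosthetic groups
(hemes, iron-sulfur cubanes, (bacterio)chlorophylls), and results should not
depend on an opaque vendored force field.
"""

from __future__ import annotations

__all__ = ["VDW_RADII", "COVALENT_RADII", "hbond_role"]

#: van der Waals radii (Å) used for solvent-accessible surface areas.
VDW_RADII: dict[str, float] = {
    "C": 1.70,
    "N": 1.55,
    "O": 1.52,
    "S": 1.80,
    "P": 1.80,
    "Fe": 1.40,
    "Mg": 1.73,
    "Ca": 1.97,
    "Zn": 1.39,
    "H": 1.20,
}

#: single-bond covalent radii (Å) used for bonded-graph detection.  Metal
#: entries are tuned so that Fe-S (cluster) and Fe-N (porphyrin) coordination
#: bonds fall inside radius-sum + slack and are treated as covalent.
COVALENT_RADII: dict[str, float] = {
    "C": 0.77,
    "N": 0.70,
    "O": 0.66,
    "S": 1.04,
    "P": 1.07,
    "Fe": 1.25,
    "Mg": 1.30,
    "Ca": 1.74,
    "Zn": 1.22,
    "H": 0.31,
}

# Hydrogen-bond capability of protein heavy atoms: "donor", "acceptor" or
# "both".  Backbone N donates, backbone O/OXT accept.  Sidechain entries cover
# the standard residues; anything absent is treated as role-unknown and the
# bond is labelled "ambiguous" rather than guessed.
_BACKBONE_ROLES = {"N": "donor", "O": "acceptor", "OXT": "acceptor"}

_SIDECHAIN_ROLES: dict[tuple[str, str], str] = {
    ("SER", "OG"): "both",
    ("THR", "OG1"): "both",
    ("TYR", "OH"): "both",
    ("CYS", "SG"): "both",
    ("MET", "SD"): "acceptor",
    ("ASP", "OD1"): "acceptor",
    ("ASP", "OD2"): "acceptor",
    ("GLU", "OE1"): "acceptor",
    ("GLU", "OE2"): "acceptor",
    ("ASN", "OD1"): "acceptor",
    ("ASN", "ND2"): "donor",
    ("GLN", "OE1"): "acceptor",
    ("GLN", "NE2"): "donor",
    ("LYS", "NZ"): "donor",
    ("ARG", "NE"): "donor",
    ("ARG", "NH1"): "donor",
    ("ARG", "NH2"): "donor",
    ("HIS", "ND1"): "both",
    ("HIS", "NE2"): "both",
    ("TRP", "NE1"): "donor",
}


def hbond_role(res_name: str, atom_name: str) -> str | None:
    """H-bond role of a heavy atom: 'donor', 'acceptor', 'both', or None.

    None means the template does not cover the atom (hetero groups, waters);
    callers should fall back to an "ambiguous" assignment.
    """
    if atom_name in _BACKBONE_ROLES and res_name in _PROTEIN_LIKE:
        return _BACKBONE_ROLES[atom_name]
    return _SIDECHAIN_ROLES.get((res_name, atom_name))


_PROTEIN_LIKE = frozenset(
    "ALA ARG ASN ASP CYS GLN GLU GLY HIS ILE LEU LYS MET PHE PRO SER THR TRP TYR VAL".split()
)
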