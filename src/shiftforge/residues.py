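"""Static chemistry tables for the 20 standard amino acids.

Atom vocabularies are stored in the modern (PDB v3 / BMRB) spelling; the
older PDB v2 spelling (leading-digit hydrogens such as ``2HB``) is derived
from the prochiral-group table below.  Everything downstream — nomenclature
conversion, super-class assignment, force-field typing, the synthetic
structure builder — keys into these tables.
"""

from __future__ import annotations

THREE_TO_ONE = {
    "ALA": "A", "ARG": "R", "ASN": "N", "ASP": "D", "CYS": "C",
    "GLN": "Q", "GLU": "E", "GLY": "G", "HIS": "H", "ILE": "I",
    "LEU": "L", "LYS": "K", "MET": "M", "PHE": "F", "PRO": "P",
    "SER": "S", "THR": "T", "TRP": "W", "TYR": "Y", "VAL": "V",
}
ONE_TO_THREE = {v: k for k, v in THREE_TO_ONE.items()}
STANDARD_RESIDUES = frozenset(THREE_TO_ONE)

# Nucleic-acid residue names, used to flag non-protein polymers.
NUCLEIC_RESIDUES = frozenset(
    {"A", "C", "G", "U", "I", "DA", "DC", "DG", "DT", "DU", "DI"}
)

WATER_RESIDUES = frozenset({"HOH", "WAT", "H2O", "DOD"})

# Heavy atoms per residue (v3 spelling; identical in v2).
HEAVY_ATOMS = {
    "ALA": ["N", "CA", "C", "O", "CB"],
    "ARG": ["N", "CA", "C", "O", "CB", "CG", "CD", "NE", "CZ", "NH1", "NH2"],
    "ASN": ["N", "CA", "C", "O", "CB", "CG", "OD1", "ND2"],
    "ASP": ["N", "CA", "C", "O", "CB", "CG", "OD1", "OD2"],
    "CYS": ["N", "CA", "C", "O", "CB", "SG"],
    "GLN": ["N", "CA", "C", "O", "CB", "CG", "CD", "OE1", "NE2"],
    "GLU": ["N", "CA", "C", "O", "CB", "CG", "CD", "OE1", "OE2"],
    "GLY": ["N", "CA", "C", "O"],
    "HIS": ["N", "CA", "C", "O", "CB", "CG", "ND1", "CD2", "CE1", "NE2"],
    "ILE": ["N", "CA", "C", "O", "CB", "CG1", "CG2", "CD1"],
    "LEU": ["N", "CA", "C", "O", "CB", "CG", "CD1", "CD2"],
    "LYS": ["N", "CA", "C", "O", "CB", "CG", "CD", "CE", "NZ"],
    "MET": ["N", "CA", "C", "O", "CB", "CG", "SD", "CE"],
    "PHE": ["N", "CA", "C", "O", "CB", "CG", "CD1", "CD2", "CE1", "CE2", "CZ"],
    "PRO": ["N", "CA", "C", "O", "CB", "CG", "CD"],
    "SER": ["N", "CA", "C", "O", "CB", "OG"],
    "THR": ["N", "CA", "C", "O", "CB", "OG1", "CG2"],
    "TRP": ["N", "CA", "C", "O", "CB", "CG", "CD1", "CD2", "NE1", "CE2",
            "CE3", "CZ2", "CZ3", "CH2"],
    "TYR": ["N", "CA", "C", "O", "CB", "CG", "CD1", "CD2", "CE1", "CE2",
            "CZ", "OH"],
    "VAL": ["N", "CA", "C", "O", "CB", "CG1", "CG2"],
}

# Hydrogens per residue (v3 spelling).
HYDROGEN_ATOMS = {
    "ALA": ["H", "HA", "HB1", "HB2", "HB3"],
    "ARG": ["H", "HA", "HB2", "HB3", "HG2", "HG3", "HD2", "HD3", "HE",
            "HH11", "HH12", "HH21", "HH22"],
    "ASN": ["H", "HA", "HB2", "HB3", "HD21", "HD22"],
    "ASP": ["H", "HA", "HB2", "HB3"],
    "CYS": ["H", "HA", "HB2", "HB3", "HG"],
    "GLN": ["H", "HA", "HB2", "HB3", "HG2", "HG3", "HE21", "HE22"],
    "GLU": ["H", "HA", "HB2", "HB3", "HG2", "HG3"],
    "GLY": ["H", "HA2", "HA3"],
    "HIS": ["H", "HA", "HB2", "HB3", "HD1", "HD2", "HE1", "HE2"],
    "ILE": ["H", "HA", "HB", "HG12", "HG13", "HG21", "HG22", "HG23",
            "HD11", "HD12", "HD13"],
    "LEU": ["H", "HA", "HB2", "HB3", "HG", "HD11", "HD12", "HD13",
            "HD21", "HD22", "HD23"],
    "LYS": ["H", "HA", "HB2", "HB3", "HG2", "HG3", "HD2", "HD3",
            "HE2", "HE3", "HZ1", "HZ2", "HZ3"],
    "MET": ["H", "HA", "HB2", "HB3", "HG2", "HG3", "HE1", "HE2", "HE3"],
    "PHE": ["H", "HA", "HB2", "HB3", "HD1", "HD2", "HE1", "HE2", "HZ"],
    "PRO": ["HA", "HB2", "HB3", "HG2", "HG3", "HD2", "HD3"],
    "SER": ["H", "HA", "HB2", "HB3", "HG"],
    "THR": ["H", "HA", "HB", "HG1", "HG21", "HG22", "HG23"],
    "TRP": ["H", "HA", "HB2", "HB3", "HD1", "HE1", "HE3", "HZ2", "HZ3",
            "HH2"],
    "TYR": ["H", "HA", "HB2", "HB3", "HD1", "HD2", "HE1", "HE2", "HH"],
    "VAL": ["H", "HA", "HB", "HG11", "HG12", "HG13",
            "HG21", "HG22", "HG23"],
}

# Prochiral / equivalent hydrogen groups.  ``methylene`` groups carry v3
# digits {2,3} and map to v2 {1,2} prefixes (HB2 -> 1HB, HB3 -> 2HB);
# ``methyl`` ({1,2,3}) and ``nh2`` ({1,2}) groups keep their digit
# (ALA HB2 -> 2HB, ASN HD21 -> 1HD2).
HYDROGEN_GROUPS = {
    "ALA": [("B", "methyl")],
    "ARG": [("B", "methylene"), ("G", "methylene"), ("D", "methylene"),
            ("H1", "nh2"), ("H2", "nh2")],
    "ASN": [("B", "methylene"), ("D2", "nh2")],
    "ASP": [("B", "methylene")],
    "CYS": [("B", "methylene")],
    "GLN": [("B", "methylene"), ("G", "methylene"), ("E2", "nh2")],
    "GLU": [("B", "methylene"), ("G", "methylene")],
    "GLY": [("A", "methylene")],
    "HIS": [("B", "methylene")],
    "ILE": [("G1", "methylene"), ("G2", "methyl"), ("D1", "methyl")],
    "LEU": [("B", "methylene"), ("D1", "methyl"), ("D2", "methyl")],
    "LYS": [("B", "methylene"), ("G", "methylene"), ("D", "methylene"),
            ("E", "methylene"), ("Z", "methyl")],
    "MET": [("B", "methylene"), ("G", "methylene"), ("E", "methyl")],
    "PHE": [("B", "methylene")],
    "PRO": [("B", "methylene"), ("G", "methylene"), ("D", "methylene")],
    "SER": [("B", "methylene")],
    "THR": [("G2", "methyl")],
    "TRP": [("B", "methylene")],
    "TYR": [("B", "methylene")],
    "VAL": [("G1", "methyl"), ("G2", "methyl")],
}

# Aromatic ring definitions: residue -> list of (member heavy atoms,
# relative ring-current intensity).  TRP contributes two fused rings.
AROMATIC_RINGS = {
    "PHE": [(("CG", "CD1", "CE1", "CZ", "CE2", "CD2"), 1.00)],
    "TYR": [(("CG", "CD1", "CE1", "CZ", "CE2", "CD2"), 0.84)],
    "HIS": [(("CG", "ND1", "CE1", "NE2", "CD2"), 0.90)],
    "TRP": [(("CG", "CD1", "NE1", "CE2", "CD2"), 1.04),
            (("CD2", "CE2", "CZ2", "CH2", "CZ3", "CE3"), 1.02)],
}

VDW_RADII = {"H": 1.20, "C": 1.70, "N": 1.55, "O": 1.52, "S": 1.80}
COVALENT_RADII = {"H": 0.31, "C": 0.76, "N": 0.71, "O": 0.66, "S": 1.05}

# Minimal partial-charge table (elementary charges) for the electric-field
# term and the nonbonded pseudo-energy: backbone amide/carbonyl dipoles plus
# charged side-chain termini.  Keys are (residue or "*", atom name).
PARTIAL_CHARGES = {
    ("*", "C"): 0.60, ("*", "O"): -0.55,
    ("*", "N"): -0.40, ("*", "H"): 0.25,
    ("ASP", "OD1"): -0.50, ("ASP", "OD2"): -0.50,
    ("GLU", "OE1"): -0.50, ("GLU", "OE2"): -0.50,
    ("LYS", "NZ"): 0.40, ("LYS", "HZ1"): 0.20, ("LYS", "HZ2"): 0.20,
    ("LYS", "HZ3"): 0.20,
    ("ARG", "NH1"): 0.35, ("ARG", "NH2"): 0.35, ("ARG", "NE"): 0.30,
}


def atom_vocabulary(residue_type: str) -> list[str]:
    """All standard atom names (v3 spelling) of ``residue_type``."""
    try:
        return HEAVY_ATOMS[residue_type] + HYDROGEN_ATOMS[residue_type]
    except KeyError:
        raise KeyError(f"not a standard amino acid: {residue_type!r}") from None


def partial_charge(residue_type: str, atom_name: str) -> float:
    """Partial charge in e; 0.0 for atoms outside the minimal table."""
    if (residue_type, atom_name) in PARTIAL_CHARGES:
        return PARTIAL_CHARGES[(residue_type, atom_name)]
    return PARTIAL_CHARGES.get(("*", atom_name), 0.0)


_AROMATIC_MEMBERS = {
    (res, name)
    for res, rings in AROMATIC_RINGS.items()
    for members, _ in rings
    for name in members
}


def force_field_atom_type(residue_type: str, atom_name: str) -> str:
    """Amber-flavoured atom type for a standard protein atom.

    A coarse rule-based typing (backbone types plus element/context classes
    for side chains); it exists to key super-class clustering and to serve
    as a categorical feature, not to parameterize an actual force field.
    """
    n = atom_name
    if n == "N":
        return "N"
    if n == "C":
        return "C"
    if n == "O" or n == "OXT":
        return "O"
    if n == "CA" and residue_type != "UNK":
        return "CT"
    if n == "H" or n == "HN":
        return "H"
    element = atom_element(residue_type, n)
    if element == "H":
        # hydrogens: polar (on N/O/S) vs aromatic vs aliphatic
        parent = _hydrogen_parent_element(residue_type, n)
        if parent in ("N",):
            return "H"
        if parent in ("O",):
            return "HO"
        if parent in ("S",):
            return "HS"
        if _hydrogen_on_aromatic(residue_type, n):
            return "HA"
        if n == "HA" or n in ("HA2", "HA3"):
            return "H1"
        return "HC"
    if element == "C":
        if (residue_type, n) in _AROMATIC_MEMBERS:
            return "CA"
        if residue_type in ("ASN", "GLN", "ASP", "GLU") and n in ("CG", "CD"):
            return "C"
        return "CT"
    if element == "N":
        if residue_type == "LYS" and n == "NZ":
            return "N3"
        if residue_type == "ARG" and n in ("NE", "NH1", "NH2"):
            return "N2"
        if (residue_type, n) in _AROMATIC_MEMBERS:
            return "NB"
        return "N"
    if element == "O":
        if n in ("OG", "OG1", "OH"):
            return "OH"
        return "O2"
    if element == "S":
        return "SH" if residue_type == "CYS" else "S"
    return element


def atom_element(residue_type: str, atom_name: str) -> str:
    """Element symbol inferred from a (possibly v2-spelled) atom name."""
    stripped = atom_name.lstrip("0123456789")
    if not stripped:
        raise ValueError(f"unintelligible atom name: {atom_name!r}")
    first = stripped[0]
    if first == "H" or (atom_name[0].isdigit() and first == "H"):
        return "H"
    if first in ("C", "N", "O", "S"):
        # two-letter false friends do not occur in the standard vocabulary
        return first
    raise ValueError(f"unknown element for atom name {atom_name!r}")


def _hydrogen_parent_element(residue_type: str, h_name: str) -> str:
    """Element of the heavy atom carrying hydrogen ``h_name``."""
    parent = hydrogen_parent(residue_type, h_name)
    return atom_element(residue_type, parent) if parent else "C"


_PARENT_OVERRIDES = {
    ("ARG", "HE"): "NE",
    ("ARG", "HH11"): "NH1", ("ARG", "HH12"): "NH1",
    ("ARG", "HH21"): "NH2", ("ARG", "HH22"): "NH2",
    ("ASN", "HD21"): "ND2", ("ASN", "HD22"): "ND2",
    ("GLN", "HE21"): "NE2", ("GLN", "HE22"): "NE2",
    ("CYS", "HG"): "SG",
    ("SER", "HG"): "OG",
    ("THR", "HG1"): "OG1",
    ("TYR", "HH"): "OH",
    ("HIS", "HD1"): "ND1", ("HIS", "HE2"): "NE2",
    ("TRP", "HE1"): "NE1",
    ("LYS", "HZ1"): "NZ", ("LYS", "HZ2"): "NZ", ("LYS", "HZ3"): "NZ",
    ("GLY", "HA2"): "CA", ("GLY", "HA3"): "CA",
    ("TRP", "HH2"): "CH2",
}


def hydrogen_parent(residue_type: str, h_name: str) -> str | None:
    """Name of the heavy atom bonded to hydrogen ``h_name`` (v3 spelling)."""
    if h_name == "H" or h_name == "HN":
        return "N"
    key = (residue_type, h_name)
    if key in _PARENT_OVERRIDES:
        return _PARENT_OVERRIDES[key]
    heavy = set(HEAVY_ATOMS.get(residue_type, ()))
    # strip trailing group digit(s): HB2 -> CB, HD11 -> CD1, HE3 -> CE
    stem = h_name[1:]
    for candidate in ("C" + stem, "N" + stem, "O" + stem, "S" + stem):
        if candidate in heavy:
            return candidate
    while stem and stem[-1].isdigit():
        stem = stem[:-1]
        for candidate in ("C" + stem, "N" + stem, "O" + stem, "S" + stem):
            if candidate in heavy:
                return candidate
    return None


def _hydrogen_on_aromatic(residue_type: str, h_name: str) -> bool:
    parent = hydrogen_parent(residue_type, h_name)
    return parent is not None and (residue_type, parent) in _AROMATIC_MEMBERS


def is_heavy(element: str) -> bool:
    return element != "H"
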