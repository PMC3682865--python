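"""Atom-name translation between the NMRStar/PDB-v3 and PDB-v2 dialects.

The BMRB (NMRStar) names hydrogens with a trailing digit (``HB2``,
``HD11``); older PDB files put the group digit in front (``2HB``,
``1HD1``).  The two dialects do not differ by a blind digit move: prochiral
methylene pairs are numbered {2,3} in v3 but {1,2} in v2, while methyl and
amino groups keep their digit.  The per-residue tables in
:mod:`shiftforge.residues` drive an explicit bijection per residue type.
"""

from __future__ import annotations

from . import residues


class UnknownAtomNameError(KeyError):
    """Atom name not in the residue's standard vocabulary."""

    def __init__(self, residue_type: str, atom_name: str, known: list[str]):
        super().__init__(atom_name)
        self.residue_type = residue_type
        self.atom_name = atom_name
        self.known = known

    def __str__(self) -> str:  # pragma: no cover - cosmetic
        return (
            f"unknown atom name {self.atom_name!r} for residue "
            f"{self.residue_type!r}; known names: {', '.join(self.known)}"
        )


def _build_maps() -> dict[str, dict[str, str]]:
    """Per-residue v3 -> v2 hydrogen name maps."""
    out: dict[str, dict[str, str]] = {}
    for res, groups in residues.HYDROGEN_GROUPS.items():
        m: dict[str, str] = {}
        for stem, kind in groups:
            if kind == "methylene":
                m[f"H{stem}2"] = f"1H{stem}"
                m[f"H{stem}3"] = f"2H{stem}"
            elif kind == "methyl":
                for i in (1, 2, 3):
                    m[f"H{stem}{i}"] = f"{i}H{stem}"
            elif kind == "nh2":
                for i in (1, 2):
                    m[f"H{stem}{i}"] = f"{i}H{stem}"
            else:  # pragma: no cover - table integrity
                raise AssertionError(kind)
        vocab = set(residues.HYDROGEN_ATOMS[res])
        missing = set(m) - vocab
        if missing:  # pragma: no cover - table integrity
            raise AssertionError(f"{res}: group names not in vocabulary {missing}")
        out[res] = m
    return out


_V3_TO_V2 = _build_maps()
_V2_TO_V3 = {res: {v: k for k, v in m.items()} for res, m in _V3_TO_V2.items()}


def v2_vocabulary(residue_type: str) -> list[str]:
    """All standard names of the residue in the PDB-v2 dialect."""
    m = _V3_TO_V2[residue_type]
    return [
        m.get(name, name) for name in residues.atom_vocabulary(residue_type)
    ]


def to_pdb_v2(residue_type: str, name: str) -> str:
    """Translate an NMRStar/v3 (or already-v2) atom name to PDB v2.

    ``HN`` is accepted as an alias for the backbone amide ``H``.
    """
    if residue_type not in residues.STANDARD_RESIDUES:
        raise UnknownAtomNameError(residue_type, name, [])
    if name == "HN":
        name = "H"
    m = _V3_TO_V2[residue_type]
    if name in m:
        return m[name]
    vocab = set(residues.atom_vocabulary(residue_type))
    if name in vocab:
        return name  # identical in both dialects
    if name in _V2_TO_V3[residue_type]:
        return name  # already v2-spelled
    raise UnknownAtomNameError(
        residue_type, name, sorted(vocab | set(m.values()))
    )


def to_nmrstar(residue_type: str, name: str) -> str:
    """Inverse of :func:`to_pdb_v2`: translate to the NMRStar/v3 spelling."""
    if residue_type not in residues.STANDARD_RESIDUES:
        raise UnknownAtomNameError(residue_type, name, [])
    if name == "HN":
        return "H"
    m = _V2_TO_V3[residue_type]
    if name in m:
        return m[name]
    vocab = set(residues.atom_vocabulary(residue_type))
    if name in vocab:
        return name
    raise UnknownAtomNameError(
        residue_type, name, sorted(vocab | set(m.keys()))
    )


def dialect_variants(residue_type: str, name: str) -> set[str]:
    """Both spellings of the given atom name, plus the name itself."""
    out = {name}
    try:
        out.add(to_pdb_v2(residue_type, name))
        out.add(to_nmrstar(residue_type, name))
    except UnknownAtomNameError:
        pass
    return out


# public aliases matching the operation names used elsewhere
convert_atom_name = to_pdb_v2
convert_atom_name_inverse = to_nmrstar
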