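"""Protein structure container, PDB reading, and basic geometry.

PDB files are parsed through :mod:`gemmi`; only the first model of an NMR
ensemble is kept.  Covalent bonds are inferred from inter-atomic distances
against covalent-radius sums, which is robust for the idealized and
experimental geometries this package handles.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np
from scipy.spatial import cKDTree

from . import residues


class PDBParseError(ValueError):
    """Fatal problem reading a structure file."""


@dataclass
class Atom:
    name: str
    element: str
    pos: np.ndarray  # (3,) in Angstrom
    index: int = -1  # flat index within the structure
    residue: "Residue" = None  # back-reference, set on finalize

    @property
    def is_heavy(self) -> bool:
        return self.element != "H"


@dataclass
class Residue:
    index: int  # 1-based position within the chain after re-indexing
    name: str  # 3-letter code
    original_index: int | None = None  # author numbering from the file
    atoms: dict[str, Atom] = field(default_factory=dict)
    chain: "Chain" = None

    def get(self, name: str) -> Atom | None:
        return self.atoms.get(name)

    def __iter__(self):
        return iter(self.atoms.values())


@dataclass
class Chain:
    index: int  # 1-based file-order index
    original_id: str
    residues: list[Residue] = field(default_factory=list)

    @property
    def sequence(self) -> str:
        """One-letter sequence; 'X' for non-standard residues."""
        return "".join(
            residues.THREE_TO_ONE.get(r.name, "X") for r in self.residues
        )

    def __iter__(self):
        return iter(self.residues)


class ProteinStructure:
    """Chains of residues of atoms, plus an inferred covalent bond graph."""

    def __init__(self, pdb_id: str, chains: list[Chain]):
        self.pdb_id = pdb_id
        self.chains = chains
        self.atoms: list[Atom] = []
        for chain in chains:
            for res in chain.residues:
                res.chain = chain
                for atom in res.atoms.values():
                    atom.index = len(self.atoms)
                    atom.residue = res
                    self.atoms.append(atom)
        self._bonds: list[set[int]] | None = None
        self._tree: cKDTree | None = None

    @property
    def coords(self) -> np.ndarray:
        return np.array([a.pos for a in self.atoms])

    def kdtree(self) -> cKDTree:
        if self._tree is None:
            self._tree = cKDTree(self.coords)
        return self._tree

    def bonds(self) -> list[set[int]]:
        """Adjacency sets, atom index -> set of bonded atom indices."""
        if self._bonds is None:
            self._bonds = self._infer_bonds()
        return self._bonds

    def bonded(self, atom: Atom) -> list[Atom]:
        return [self.atoms[j] for j in sorted(self.bonds()[atom.index])]

    def _infer_bonds(self, tolerance: float = 0.45) -> list[set[int]]:
        adj: list[set[int]] = [set() for _ in self.atoms]
        if not self.atoms:
            return adj
        tree = self.kdtree()
        max_bond = 2 * max(residues.COVALENT_RADII.values()) + tolerance
        for i, j in tree.query_pairs(max_bond):
            a, b = self.atoms[i], self.atoms[j]
            if a.element == "H" and b.element == "H":
                continue
            limit = (
                residues.COVALENT_RADII.get(a.element, 0.8)
                + residues.COVALENT_RADII.get(b.element, 0.8)
                + tolerance
            )
            if np.linalg.norm(a.pos - b.pos) <= limit:
                adj[i].add(j)
                adj[j].add(i)
        return adj

    def neighbors_within_bonds(self, atom: Atom, n_bonds: int) -> set[int]:
        """Atom indices reachable in at most ``n_bonds`` covalent bonds."""
        seen = {atom.index}
        frontier = {atom.index}
        adj = self.bonds()
        for _ in range(n_bonds):
            frontier = {j for i in frontier for j in adj[i]} - seen
            seen |= frontier
        return seen

    def transformed(self, rotation: np.ndarray, translation: np.ndarray
                    ) -> "ProteinStructure":
        """A copy under the rigid motion ``x -> R x + t``."""
        new_chains = []
        for chain in self.chains:
            nc = Chain(chain.index, chain.original_id)
            for res in chain.residues:
                nr = Residue(res.index, res.name, res.original_index)
                for name, atom in res.atoms.items():
                    nr.atoms[name] = Atom(
                        atom.name, atom.element,
                        rotation @ atom.pos + translation,
                    )
                nc.residues.append(nr)
            new_chains.append(nc)
        return ProteinStructure(self.pdb_id, new_chains)


def parse_pdb(path: str, pdb_id: str | None = None) -> ProteinStructure:
    """Read a PDB-format file; keep the first model of an ensemble.

    Raises :class:`PDBParseError` when the file contains no polymer
    (standard amino acid) atoms.
    """
    import gemmi

    try:
        st = gemmi.read_pdb(str(path), split_chain_on_ter=False)
    except (RuntimeError, ValueError, OSError) as exc:
        raise PDBParseError(f"cannot read PDB file {path}: {exc}") from exc
    if len(st) == 0:
        raise PDBParseError(f"no models in {path}")
    model = st[0]  # MODEL 1 only
    chains: list[Chain] = []
    for ci, gchain in enumerate(model, start=1):
        chain = Chain(index=ci, original_id=gchain.name or " ")
        ri = 0
        for gres in gchain:
            if gres.name not in residues.STANDARD_RESIDUES:
                continue  # heteroatoms, waters, non-protein polymers
            ri += 1
            res = Residue(index=ri, name=gres.name,
                          original_index=gres.seqid.num)
            for gatom in gres:
                name = gatom.name.strip()
                element = gatom.element.name.upper()
                if element in ("", "X"):
                    element = residues.atom_element(gres.name, name)
                res.atoms[name] = Atom(
                    name=name, element=element,
                    pos=np.array([gatom.pos.x, gatom.pos.y, gatom.pos.z]),
                )
            chain.residues.append(res)
        if chain.residues:
            chains.append(chain)
    # re-index chains 1..k in file order over the kept (polymer) chains
    for i, chain in enumerate(chains, start=1):
        chain.index = i
    if not chains:
        raise PDBParseError(f"no polymer atoms in {path}")
    return ProteinStructure(pdb_id or (st.name or "XXXX")[:4].upper(), chains)


# ---------------------------------------------------------------------------
# geometry primitives


def dihedral(p1: np.ndarray, p2: np.ndarray, p3: np.ndarray, p4: np.ndarray
             ) -> float:
    """Signed dihedral angle in degrees, IUPAC convention, in (-180, 180]."""
    b1 = p2 - p1
    b2 = p3 - p2
    b3 = p4 - p3
    n1 = np.cross(b1, b2)
    n2 = np.cross(b2, b3)
    m1 = np.cross(n1, b2 / np.linalg.norm(b2))
    x = n1 @ n2
    y = m1 @ n2
    ang = math.degrees(math.atan2(y, x))
    if ang <= -180.0:
        ang += 360.0
    return ang


def bond_angle(p1: np.ndarray, p2: np.ndarray, p3: np.ndarray) -> float:
    """Angle p1-p2-p3 in degrees."""
    v1 = p1 - p2
    v2 = p3 - p2
    c = (v1 @ v2) / (np.linalg.norm(v1) * np.linalg.norm(v2))
    return math.degrees(math.acos(max(-1.0, min(1.0, c))))


def place_atom(a: np.ndarray, b: np.ndarray, c: np.ndarray,
               bond: float, angle: float, torsion: float) -> np.ndarray:
    """Natural-extension (NeRF) placement of atom D bonded to C.

    Returns D with |CD| = ``bond`` (Angstrom), angle(B,C,D) = ``angle``
    (degrees) and dihedral(A,B,C,D) = ``torsion`` (degrees).
    """
    ang = math.radians(angle)
    tor = math.radians(torsion)
    bc = c - b
    bc /= np.linalg.norm(bc)
    ab = b - a
    n = np.cross(ab, bc)
    norm = np.linalg.norm(n)
    if norm < 1e-10:
        raise ValueError("collinear reference atoms in place_atom")
    n /= norm
    m = np.cross(n, bc)
    d_local = np.array([
        -bond * math.cos(ang),
        bond * math.sin(ang) * math.cos(tor),
        -bond * math.sin(ang) * math.sin(tor),
    ])
    return c + d_local[0] * bc + d_local[1] * m + d_local[2] * n
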