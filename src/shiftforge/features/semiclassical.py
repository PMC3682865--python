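"""Semi-classical chemical-shift contributions.

Four physically motivated terms enter the feature table alongside the
statistical descriptors: a random-coil baseline (table lookup), an
aromatic ring-current term (point-dipole approximation), a uniaxial
electric-field term, and a distance-based hydrogen-bond term.  Functional
forms are the standard semi-classical ones from the shift-prediction
literature:

* ring current:  delta = sum_rings  B * i * (1 - 3 cos^2 theta) / r^3
* electric field:  delta = eps * E_z,  E_z = sum_q q cos(alpha) / r^2
* hydrogen bond:  delta = a / r^3 - b  for the nearest acceptor in range

with r in Angstrom throughout.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .. import residues
from ..structure import Atom, ProteinStructure

# Random-coil chemical shifts (ppm) of backbone nuclei, after Wishart et
# al. (1995) J. Biomol. NMR 5:67 (pH 5 peptide values; CYS reduced).
# Columns: CA, CB, C', N, H(N), HA.  GLY has no CB, PRO no amide H.
RANDOM_COIL_PPM: dict[tuple[str, str], float] = {}


def _rc(res: str, ca, cb, c, n, h, ha) -> None:
    vals = {"CA": ca, "CB": cb, "C": c, "N": n, "H": h, "HA": ha}
    for atom, v in vals.items():
        if v is not None:
            RANDOM_COIL_PPM[(res, atom)] = v


_rc("ALA", 52.5, 19.1, 177.8, 123.8, 8.24, 4.32)
_rc("ARG", 56.0, 30.9, 176.3, 120.5, 8.23, 4.34)
_rc("ASN", 53.4, 38.7, 175.2, 118.7, 8.40, 4.74)
_rc("ASP", 54.2, 41.1, 176.3, 120.4, 8.34, 4.64)
_rc("CYS", 58.2, 28.0, 174.6, 118.8, 8.32, 4.55)
_rc("GLN", 55.7, 29.4, 176.0, 119.8, 8.32, 4.34)
_rc("GLU", 56.6, 29.9, 176.6, 120.2, 8.42, 4.35)
_rc("GLY", 45.1, None, 174.9, 108.8, 8.33, 3.96)
_rc("HIS", 55.0, 29.0, 174.1, 118.2, 8.42, 4.73)
_rc("ILE", 61.1, 38.8, 176.4, 119.9, 8.00, 4.17)
_rc("LEU", 55.1, 42.4, 177.6, 121.8, 8.16, 4.34)
_rc("LYS", 56.2, 33.1, 176.6, 120.4, 8.29, 4.32)
_rc("MET", 55.4, 32.9, 176.3, 119.6, 8.28, 4.48)
_rc("PHE", 57.7, 39.6, 175.8, 120.3, 8.30, 4.62)
_rc("PRO", 63.3, 31.7, 177.3, 128.1, None, 4.42)
_rc("SER", 58.3, 63.8, 174.6, 115.7, 8.31, 4.47)
_rc("THR", 61.8, 69.8, 174.7, 113.6, 8.15, 4.35)
_rc("TRP", 57.5, 29.6, 176.1, 121.3, 8.25, 4.66)
_rc("TYR", 57.9, 38.8, 175.9, 120.3, 8.28, 4.55)
_rc("VAL", 62.2, 32.9, 176.3, 119.2, 8.03, 4.12)


@dataclass
class RingSystem:
    """One aromatic ring: centroid, unit normal and relative intensity."""

    residue_type: str
    member_names: tuple[str, ...]
    centroid: np.ndarray
    normal: np.ndarray
    intensity: float
    residue_key: tuple[int, int] | None = None  # (chain_index, residue_index)

    def __post_init__(self) -> None:
        if len(self.member_names) < 5:
            raise ValueError("a ring needs at least 5 member atoms")
        if self.intensity <= 0:
            raise ValueError("ring intensity must be positive")
        n = np.linalg.norm(self.normal)
        if abs(n - 1.0) > 1e-8:
            raise ValueError("ring normal must be a unit vector")


@dataclass
class SemiClassicalParams:
    """Coefficients of the semi-classical terms.

    ring_b: ppm * A^3 target factor of the point-dipole ring model.
    efield_eps: ppm per field unit (e / A^2) of the uniaxial term.
    hbond_a / hbond_b: ppm * A^3 and ppm of the distance form a/r^3 - b.
    hbond_range: maximal H...acceptor distance considered (A).
    ring_intensities: per-(residue, ring) relative intensities; the
        defaults live in :data:`shiftforge.residues.AROMATIC_RINGS`.
    """

    ring_b: float = 30.42
    efield_eps: float = 1.0
    hbond_a: float = 19.2
    hbond_b: float = 2.3
    hbond_range: float = 3.5
    min_ring_distance: float = 0.5
    random_coil_table: dict = field(
        default_factory=lambda: dict(RANDOM_COIL_PPM))


DEFAULT_PARAMS = SemiClassicalParams()


class MissingRandomCoilEntry(KeyError):
    def __init__(self, residue_type: str, atom_name: str):
        super().__init__((residue_type, atom_name))
        self.pair = (residue_type, atom_name)

    def __str__(self) -> str:
        return f"no random-coil entry for {self.pair}"


def random_coil_shift(residue_type: str, atom_name: str,
                      params: SemiClassicalParams = DEFAULT_PARAMS) -> float:
    """Baseline shift (ppm) of an atom type in an unstructured peptide."""
    try:
        return params.random_coil_table[(residue_type, atom_name)]
    except KeyError:
        raise MissingRandomCoilEntry(residue_type, atom_name) from None


def build_ring(residue_type: str, member_names: tuple[str, ...],
               positions: np.ndarray, intensity: float,
               residue_key: tuple[int, int] | None = None) -> RingSystem:
    """Ring geometry from member coordinates; rejects degenerate rings."""
    centroid = positions.mean(axis=0)
    rel = positions - centroid
    normal = np.zeros(3)
    for k in range(len(rel)):
        normal += np.cross(rel[k], rel[(k + 1) % len(rel)])
    norm = np.linalg.norm(normal)
    if norm < 1e-6:
        raise ValueError(
            f"degenerate (collinear) ring in {residue_type}: {member_names}"
        )
    return RingSystem(residue_type, member_names, centroid, normal / norm,
                      intensity, residue_key)


def rings_of_structure(structure: ProteinStructure) -> list[RingSystem]:
    """All aromatic rings of a structure with complete ring atoms."""
    rings: list[RingSystem] = []
    for chain in structure.chains:
        for res in chain.residues:
            for members, intensity in residues.AROMATIC_RINGS.get(
                    res.name, ()):
                atoms = [res.get(m) for m in members]
                if any(a is None for a in atoms):
                    continue
                pos = np.array([a.pos for a in atoms])
                rings.append(build_ring(res.name, members, pos, intensity,
                                        (chain.index, res.index)))
    return rings


def ring_current_shift(position: np.ndarray, rings: list[RingSystem],
                       params: SemiClassicalParams = DEFAULT_PARAMS
                       ) -> float:
    """Point-dipole ring-current shift (ppm) at ``position``.

    theta is the angle between the ring normal and the centroid-to-atom
    vector; the term changes sign across the magic-angle cone
    (cos^2 theta = 1/3) and decays as r^-3.
    """
    total = 0.0
    for ring in rings:
        v = position - ring.centroid
        r = float(np.linalg.norm(v))
        if r < params.min_ring_distance:
            raise ValueError(
                f"atom {r:.2f} A from ring centroid of "
                f"{ring.residue_type}; geometry implausible"
            )
        cos_t = float(v @ ring.normal) / r
        total += (params.ring_b * ring.intensity
                  * (1.0 - 3.0 * cos_t * cos_t) / r ** 3)
    return total


class UnbondedTargetError(ValueError):
    pass


def electric_field_shift(atom: Atom, structure: ProteinStructure,
                         params: SemiClassicalParams = DEFAULT_PARAMS,
                         charge_fn=residues.partial_charge) -> float:
    """Uniaxial electric-field shift (ppm) at a singly bonded atom.

    The field of the partial charges is projected onto the covalent bond
    axis of the target (pointing from the bonded partner towards the
    target); sources within two covalent bonds are excluded.
    """
    bonded = structure.bonded(atom)
    if len(bonded) != 1:
        raise UnbondedTargetError(
            f"electric-field target {atom.name} has {len(bonded)} bonds, "
            "needs exactly 1"
        )
    partner = bonded[0]
    axis = atom.pos - partner.pos
    axis = axis / np.linalg.norm(axis)
    excluded = structure.neighbors_within_bonds(atom, 2)
    e_z = 0.0
    for src in structure.atoms:
        if src.index in excluded:
            continue
        q = charge_fn(src.residue.name, src.name)
        if q == 0.0:
            continue
        d = src.pos - atom.pos
        r = float(np.linalg.norm(d))
        if r < 1e-6:
            continue
        e_z += q * float(d @ axis) / (r * r * r)  # q cos(alpha) / r^2
    return params.efield_eps * e_z


def hbond_effect_shift(hydrogen: Atom, structure: ProteinStructure,
                       params: SemiClassicalParams = DEFAULT_PARAMS
                       ) -> float:
    """Distance-based hydrogen-bond shift (ppm) for a donor hydrogen.

    a / r^3 - b for the nearest N/O/S acceptor within ``hbond_range`` A
    (the donor's own heavy atom and its 2-bond environment excluded);
    0.0 when no acceptor is in range.
    """
    excluded = structure.neighbors_within_bonds(hydrogen, 2)
    best = None
    tree = structure.kdtree()
    for j in tree.query_ball_point(hydrogen.pos, params.hbond_range):
        if j in excluded:
            continue
        other = structure.atoms[j]
        if other.element not in ("N", "O", "S"):
            continue
        r = float(np.linalg.norm(other.pos - hydrogen.pos))
        if best is None or r < best:
            best = r
    if best is None:
        return 0.0
    return params.hbond_a / best ** 3 - params.hbond_b
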