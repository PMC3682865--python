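"""Geometric structural features.

All features here are pure functions of coordinates and are invariant
under rigid-body motion of the whole structure.  The surface area uses the
Shrake-Rupley sphere-sampling construction with a fixed deterministic
point set, and secondary structure is assigned from the backbone
hydrogen-bond pattern (Kabsch-Sander-style electrostatic criterion with
n-turn and bridge rules).
"""

from __future__ import annotations

import math

import numpy as np
from scipy.spatial import cKDTree

from .. import residues
from ..records import MISSING
from ..structure import Chain, ProteinStructure, Residue, dihedral

PROBE_RADIUS = 1.4  # water probe, Angstrom
DENSITY_RADIUS = 5.0  # heavy-atom density sphere, Angstrom

_GAMMA_ATOMS = ("CG", "CG1", "OG", "OG1", "SG")


def torsion_angles(chain: Chain, position: int) -> dict[str, float | str]:
    """phi, psi, chi1 (degrees, IUPAC sign) of residue ``position`` (0-based).

    Angles whose defining atoms are absent (chain termini, missing side
    chains) are reported as the missing marker, never as an error.
    """
    res = chain.residues[position]
    prev_res = chain.residues[position - 1] if position > 0 else None
    next_res = (chain.residues[position + 1]
                if position + 1 < len(chain.residues) else None)
    out: dict[str, float | str] = {"phi": MISSING, "psi": MISSING,
                                   "chi1": MISSING}
    n, ca, c = res.get("N"), res.get("CA"), res.get("C")
    if prev_res is not None and prev_res.get("C") is not None and \
            all(a is not None for a in (n, ca, c)):
        out["phi"] = dihedral(prev_res.get("C").pos, n.pos, ca.pos, c.pos)
    if next_res is not None and next_res.get("N") is not None and \
            all(a is not None for a in (n, ca, c)):
        out["psi"] = dihedral(n.pos, ca.pos, c.pos, next_res.get("N").pos)
    cb = res.get("CB")
    gamma = next((res.get(g) for g in _GAMMA_ATOMS
                  if res.get(g) is not None), None)
    if all(a is not None for a in (n, ca, cb)) and gamma is not None:
        out["chi1"] = dihedral(n.pos, ca.pos, cb.pos, gamma.pos)
    return out


# ---------------------------------------------------------------------------
# secondary structure

_HB_ENERGY_CUTOFF = -0.5  # kcal/mol
_KS_FACTOR = 0.084 * 332.0  # Kabsch-Sander q1*q2*f


def _backbone_hbonds(chain: Chain) -> set[tuple[int, int]]:
    """(donor_position, acceptor_position) backbone H-bonds within a chain.

    Kabsch-Sander electrostatic criterion between the amide of the donor
    residue and the carbonyl of the acceptor residue; adjacent residues
    are never counted.
    """
    out: set[tuple[int, int]] = set()
    rs = chain.residues
    for di, don in enumerate(rs):
        n_at, h_at = don.get("N"), don.get("H") or don.get("HN")
        if n_at is None or h_at is None:
            continue
        for ai, acc in enumerate(rs):
            if abs(di - ai) < 2:
                continue
            c_at, o_at = acc.get("C"), acc.get("O")
            if c_at is None or o_at is None:
                continue
            r_on = np.linalg.norm(o_at.pos - n_at.pos)
            r_ch = np.linalg.norm(c_at.pos - h_at.pos)
            r_oh = np.linalg.norm(o_at.pos - h_at.pos)
            r_cn = np.linalg.norm(c_at.pos - n_at.pos)
            if min(r_on, r_ch, r_oh, r_cn) < 0.5:
                continue
            energy = _KS_FACTOR * (1 / r_on + 1 / r_ch - 1 / r_oh - 1 / r_cn)
            if energy < _HB_ENERGY_CUTOFF:
                out.add((di, ai))
    return out


def secondary_structure(chain: Chain) -> list[str]:
    """Per-residue labels in {"helix", "strand", "coil"}.

    A residue belongs to a helix when it sits inside two consecutive
    i -> i+4 turns (the amide of residue i+4 binds the carbonyl of i), and
    to a strand when it takes part in a parallel or antiparallel bridge;
    everything else is coil.  Deterministic; helix wins over strand.
    """
    n = len(chain.residues)
    labels = ["coil"] * n
    hb = _backbone_hbonds(chain)

    def turn4(i: int) -> bool:
        return (i + 4, i) in hb

    strand = [False] * n
    for i in range(n):
        for j in range(n):
            if abs(i - j) < 3:
                continue
            anti = ((i, j) in hb and (j, i) in hb) or \
                   ((i - 1, j + 1) in hb and (j - 1, i + 1) in hb)
            para = ((i - 1, j) in hb and (j, i + 1) in hb) or \
                   ((j - 1, i) in hb and (i, j + 1) in hb)
            if anti or para:
                strand[i] = True
    for i in range(n):
        if strand[i]:
            labels[i] = "strand"
    for i in range(1, n):
        if turn4(i - 1) and turn4(i):
            for k in range(i, min(i + 4, n)):
                labels[k] = "helix"
    return labels


# ---------------------------------------------------------------------------
# solvent accessible surface


def _sphere_points(n: int) -> np.ndarray:
    """Deterministic quasi-uniform points on the unit sphere (golden spiral)."""
    k = np.arange(n) + 0.5
    phi = np.arccos(1.0 - 2.0 * k / n)
    theta = math.pi * (1.0 + math.sqrt(5.0)) * k
    return np.column_stack(
        (np.cos(theta) * np.sin(phi),
         np.sin(theta) * np.sin(phi),
         np.cos(phi))
    )


def _symmetric_sphere_points(n: int) -> np.ndarray:
    """Antipodally symmetric point set: buried-cap counts are then exactly
    equal for mirror-image neighbour configurations."""
    if n % 2:
        n += 1
    half = _sphere_points(n // 2)
    return np.vstack((half, -half))


_N_SPHERE_POINTS = 960
_SPHERE = _symmetric_sphere_points(_N_SPHERE_POINTS)


def _canonical_frame(coords: np.ndarray) -> np.ndarray:
    """Express coordinates in a deterministic principal-axes frame.

    Axis signs are fixed by rotation-covariant statistics (projection
    skewness, falling back to the most distal atom's projection), so the
    canonical coordinates — and everything sampled in them — are identical
    for any proper rigid motion of the input.
    """
    center = coords.mean(axis=0)
    x = coords - center
    cov = x.T @ x
    _, v = np.linalg.eigh(cov)
    axes = v[:, ::-1]  # descending variance
    proj = x @ axes
    skew = (proj ** 3).sum(axis=0)
    distal = int(np.argmax((x ** 2).sum(axis=1)))
    for k in range(3):
        s = skew[k]
        if abs(s) < 1e-9:
            s = proj[distal, k]
        if s < 0:
            axes[:, k] = -axes[:, k]
    if np.linalg.det(axes) < 0:
        # restore a proper rotation by flipping the least-decisive axis
        k = int(np.argmin(np.abs(skew)))
        axes[:, k] = -axes[:, k]
    return x @ axes


def solvent_accessible_surface(
    structure: ProteinStructure,
    probe: float = PROBE_RADIUS,
    n_points: int = _N_SPHERE_POINTS,
) -> tuple[np.ndarray, dict]:
    """Shrake-Rupley SAS area per atom (A^2) plus per-residue sums.

    A fixed quasi-uniform point set makes the result deterministic; the
    fraction of points on each atom's probe-expanded sphere not buried
    inside any neighbour's sphere times the sphere area is the atom's SAS.
    """
    pts = (_SPHERE if n_points == _N_SPHERE_POINTS
           else _symmetric_sphere_points(n_points))
    atoms = structure.atoms
    if not atoms:
        return np.zeros(0), {}
    radii = np.empty(len(atoms))
    for i, a in enumerate(atoms):
        try:
            radii[i] = residues.VDW_RADII[a.element]
        except KeyError:
            raise KeyError(
                f"no van der Waals radius for element {a.element!r}"
            ) from None
    radii = radii + probe
    # canonical principal-axes frame: the sampled area is then exactly
    # invariant under rigid motion of the structure (up to principal-axis
    # degeneracy, where any frame gives the same sphere coverage anyway)
    coords = _canonical_frame(structure.coords)
    tree = cKDTree(coords)
    max_r = radii.max()
    areas = np.empty(len(atoms))
    for i in range(len(atoms)):
        sphere = coords[i] + radii[i] * pts
        neighbors = [j for j in tree.query_ball_point(coords[i],
                                                      radii[i] + max_r)
                     if j != i]
        exposed = np.ones(len(pts), dtype=bool)
        for j in neighbors:
            d2 = np.sum((sphere - coords[j]) ** 2, axis=1)
            exposed &= d2 > radii[j] ** 2
        areas[i] = 4.0 * math.pi * radii[i] ** 2 * exposed.mean()
    per_residue: dict = {}
    for i, a in enumerate(atoms):
        key = (a.residue.chain.index, a.residue.index)
        per_residue[key] = per_residue.get(key, 0.0) + areas[i]
    return areas, per_residue


# ---------------------------------------------------------------------------
# densities and bonds


def atomic_density(structure: ProteinStructure, atom,
                   radius: float = DENSITY_RADIUS) -> int:
    """Number of heavy atoms within ``radius`` A (self and bonded excluded)."""
    if radius <= 0:
        raise ValueError("radius must be positive")
    tree = structure.kdtree()
    bonded = structure.bonds()[atom.index]
    count = 0
    for j in tree.query_ball_point(atom.pos, radius):
        if j == atom.index or j in bonded:
            continue
        if structure.atoms[j].is_heavy:
            count += 1
    return count


HBOND_MAX_HA = 2.5  # A, H...acceptor
HBOND_MIN_ANGLE = 120.0  # degrees, donor-H-acceptor
SS_RANGE = (1.8, 2.5)  # A, SG-SG


def detect_hbonds_and_disulfides(structure: ProteinStructure
                                 ) -> tuple[list, list]:
    """Geometric hydrogen bonds and disulfide bridges.

    H-bond: H...acceptor(N/O/S) < 2.5 A with donor-H-acceptor > 120 deg.
    Disulfide: SG-SG distance within [1.8, 2.5] A.
    Returns ([(h_index, acceptor_index)], [(sg_index, sg_index)]).
    """
    hbonds: list[tuple[int, int]] = []
    disulfides: list[tuple[int, int]] = []
    tree = structure.kdtree()
    adj = structure.bonds()
    for atom in structure.atoms:
        if atom.element != "H":
            continue
        donors = [structure.atoms[j] for j in adj[atom.index]]
        if not donors:
            continue
        donor = donors[0]
        for j in tree.query_ball_point(atom.pos, HBOND_MAX_HA):
            other = structure.atoms[j]
            if other.element not in ("N", "O", "S"):
                continue
            if j == donor.index or j in adj[atom.index]:
                continue
            if j in adj[donor.index]:
                continue
            v1 = donor.pos - atom.pos
            v2 = other.pos - atom.pos
            cosang = (v1 @ v2) / (np.linalg.norm(v1) * np.linalg.norm(v2))
            angle = math.degrees(math.acos(max(-1.0, min(1.0, cosang))))
            if angle > HBOND_MIN_ANGLE:
                hbonds.append((atom.index, j))
    sg = [a for a in structure.atoms if a.name == "SG"]
    for i in range(len(sg)):
        for j in range(i + 1, len(sg)):
            d = float(np.linalg.norm(sg[i].pos - sg[j].pos))
            if SS_RANGE[0] <= d <= SS_RANGE[1]:
                disulfides.append((sg[i].index, sg[j].index))
    return hbonds, disulfides


_BACKBONE_DISTANCES = (
    ("d_n_ca", "N", "CA", 0),
    ("d_ca_c", "CA", "C", 0),
    ("d_c_o", "C", "O", 0),
    ("d_c_n_next", "C", "N", +1),
    ("d_ca_ca_prev", "CA", "CA", -1),
    ("d_ca_ca_next", "CA", "CA", +1),
)


def explicit_backbone_distances(chain: Chain, position: int
                                ) -> dict[str, float | str]:
    """Named Euclidean distances between backbone atoms of a residue and
    its sequence neighbours; absent atoms yield the missing marker."""
    res = chain.residues[position]
    out: dict[str, float | str] = {}
    for name, a_name, b_name, offset in _BACKBONE_DISTANCES:
        other: Residue | None = res
        if offset:
            idx = position + offset
            other = (chain.residues[idx]
                     if 0 <= idx < len(chain.residues) else None)
        a = res.get(a_name)
        b = other.get(b_name) if other is not None else None
        out[name] = (float(np.linalg.norm(a.pos - b.pos))
                     if a is not None and b is not None else MISSING)
    return out
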