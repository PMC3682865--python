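"""Synthetic test fixtures: toy structures, shift files, corrupted variants.

Structures are built from ideal peptide geometry (bond lengths/angles
below) by natural-extension placement from a per-residue backbone dihedral
program, with hydrogens at idealized positions and PHE side chains in a
fixed rotamer — so every geometric feature has a closed-form expectation.
Shifts are generated from a known ground-truth function

    shift = random_coil + ring_current + beta * atomic_density + N(0, sigma^2)

and written as NMRStar files (2.1 dialect by default, 3.1 on request),
with deterministic corruption modes emulating the syntax errors found in
deposited files.  Same spec + seed => byte-identical outputs.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np

from . import residues
from .features import geometry, semiclassical
from .records import MISSING
from .structure import Atom, Chain, PDBParseError, ProteinStructure, \
    Residue, place_atom

# ideal backbone geometry (Angstrom / degrees)
BOND_N_CA = 1.458
BOND_CA_C = 1.525
BOND_C_N = 1.329
BOND_C_O = 1.231
BOND_N_H = 1.010
BOND_C_H = 1.090
ANGLE_N_CA_C = 111.0
ANGLE_CA_C_N = 116.6
ANGLE_C_N_CA = 121.9
ANGLE_CA_C_O = 120.5
ANGLE_C_N_H = 119.0
OMEGA = 180.0

HELIX = (-57.0, -47.0)
EXTENDED = (-139.0, 135.0)

#: ground-truth coefficient on the atomic-density feature (ppm per atom)
BETA_DENSITY = 0.02

#: atoms that receive synthetic shifts (random-coil-covered backbone set)
SHIFT_ATOMS = ("N", "CA", "CB", "C", "H", "HA")

CORRUPTION_MODES = ("stray_token", "duplicate_frame", "nonnumeric_shift",
                    "dialect_v3_names", "one_residue_insertion")


@dataclass
class FixtureSpec:
    """Recipe for one synthetic protein and its shift list."""

    pdb_id: str
    sequence: str  # over the supported alphabet A/G/F
    phi_psi: list[tuple[float, float]] | None = None  # per residue; helix default
    noise_sigma: float = 0.0  # ppm
    seed: int = 0
    corruptions: list[str] = field(default_factory=list)
    n_models: int = 1  # >1 writes a multi-model (NMR ensemble) PDB file
    bmrb_id: str = "10001"
    shift_offset: float = 0.0  # systematic mis-referencing emulation (ppm)

    def __post_init__(self) -> None:
        self.sequence = self.sequence.upper()
        if len(self.sequence) < 2:
            raise ValueError("fixture sequence must have >= 2 residues")
        if self.noise_sigma < 0:
            raise ValueError("noise sigma must be >= 0")
        bad = set(self.sequence) - {"A", "G", "F"}
        if bad:
            raise ValueError(
                f"unsupported fixture residues {sorted(bad)}; "
                "the builder covers A, G and F"
            )
        if self.phi_psi is None:
            self.phi_psi = [HELIX] * len(self.sequence)
        if len(self.phi_psi) != len(self.sequence):
            raise ValueError("phi_psi program length != sequence length")
        unknown = set(self.corruptions) - set(CORRUPTION_MODES)
        if unknown:
            raise ValueError(f"unknown corruption mode(s): {sorted(unknown)}")


# ---------------------------------------------------------------------------
# structure construction


def _unit(v: np.ndarray) -> np.ndarray:
    return v / np.linalg.norm(v)


def build_structure(spec: FixtureSpec) -> ProteinStructure:
    """Idealized structure from the dihedral program; clash-checked."""
    seq3 = [residues.ONE_TO_THREE[c] for c in spec.sequence]
    n_res = len(seq3)
    N = [None] * n_res
    CA = [None] * n_res
    C = [None] * n_res

    N[0] = np.zeros(3)
    CA[0] = np.array([BOND_N_CA, 0.0, 0.0])
    ang = math.radians(180.0 - ANGLE_N_CA_C)
    C[0] = CA[0] + BOND_CA_C * np.array([math.cos(ang), math.sin(ang), 0.0])
    for i in range(1, n_res):
        psi_prev = spec.phi_psi[i - 1][1]
        N[i] = place_atom(N[i - 1], CA[i - 1], C[i - 1],
                          BOND_C_N, ANGLE_CA_C_N, psi_prev)
        CA[i] = place_atom(CA[i - 1], C[i - 1], N[i],
                           BOND_N_CA, ANGLE_C_N_CA, OMEGA)
        phi = spec.phi_psi[i][0]
        C[i] = place_atom(C[i - 1], N[i], CA[i],
                          BOND_CA_C, ANGLE_N_CA_C, phi)

    chain = Chain(index=1, original_id="A")
    placed: list[np.ndarray] = []

    def add(res, pos_name: str, pos: np.ndarray) -> None:
        res.atoms[pos_name] = Atom(
            name=pos_name,
            element=residues.atom_element(res.name, pos_name),
            pos=pos,
        )
        placed.append(pos)

    # pass 1: backbone with carbonyl O, amide H and alpha hydrogens
    for i, res3 in enumerate(seq3):
        res = Residue(index=i + 1, name=res3, original_index=i + 1)
        add(res, "N", N[i])
        add(res, "CA", CA[i])
        add(res, "C", C[i])
        # carbonyl O: bisector of the two C bonds for interior residues,
        # NeRF from the final psi for the C-terminal one
        if i + 1 < n_res:
            d = _unit(_unit(C[i] - CA[i]) + _unit(C[i] - N[i + 1]))
            add(res, "O", C[i] + BOND_C_O * d)
        else:
            add(res, "O", place_atom(N[i], CA[i], C[i], BOND_C_O,
                                     ANGLE_CA_C_O,
                                     spec.phi_psi[i][1] + 180.0))
        if i > 0:
            # trans peptide: H is cis to the previous CA across C-N,
            # i.e. anti to the carbonyl O
            add(res, "H", place_atom(CA[i - 1], C[i - 1], N[i],
                                     BOND_N_H, ANGLE_C_N_H, 0.0))
        else:
            add(res, "H", place_atom(C[i], CA[i], N[i], BOND_N_H,
                                     ANGLE_C_N_H, 180.0))
        chain.residues.append(res)

    # pass 2: side chains, with a deterministic rotamer search for PHE
    for i, res in enumerate(chain.residues):
        res3 = res.name
        if res3 == "GLY":
            u_n = _unit(N[i] - CA[i])
            u_c = _unit(C[i] - CA[i])
            b = -_unit(u_n + u_c)
            p = _unit(np.cross(u_n, u_c))
            add(res, "HA2", CA[i] + BOND_C_H * _unit(b + 0.9 * p))
            add(res, "HA3", CA[i] + BOND_C_H * _unit(b - 0.9 * p))
            continue
        cb = place_atom(N[i], C[i], CA[i], 1.53, 110.1, 122.6)
        add(res, "CB", cb)
        u_n = _unit(N[i] - CA[i])
        u_c = _unit(C[i] - CA[i])
        u_b = _unit(cb - CA[i])
        add(res, "HA", CA[i] + BOND_C_H * -_unit(u_n + u_c + u_b))
        if res3 == "ALA":
            for k, chi in (("HB1", 60.0), ("HB2", 180.0), ("HB3", -60.0)):
                add(res, k, place_atom(N[i], CA[i], cb, BOND_C_H, 109.5,
                                       chi))
        elif res3 == "PHE":
            _add_phe_side_chain(res, N[i], CA[i], cb, placed, add)

    structure = ProteinStructure(spec.pdb_id, [chain])
    _check_clashes(structure)
    return structure


_PHE_CHI1_ROTAMERS = (-65.0, 180.0, 60.0, -100.0, 140.0, 20.0)


def _phe_ring_atoms(n_pos, ca_pos, cb, chi1: float) -> dict[str, np.ndarray]:
    cg = place_atom(n_pos, ca_pos, cb, 1.50, 114.0, chi1)
    cd1 = place_atom(ca_pos, cb, cg, 1.39, 120.0, 90.0)
    cd2 = place_atom(ca_pos, cb, cg, 1.39, 120.0, -90.0)
    ce1 = place_atom(cb, cg, cd1, 1.39, 120.0, 180.0)
    ce2 = place_atom(cb, cg, cd2, 1.39, 120.0, 180.0)
    cz = place_atom(cg, cd1, ce1, 1.39, 120.0, 0.0)
    out = {"CG": cg, "CD1": cd1, "CD2": cd2, "CE1": ce1, "CE2": ce2,
           "CZ": cz}
    centroid = sum(out.values()) / 6.0
    for cname, hname in (("CD1", "HD1"), ("CD2", "HD2"), ("CE1", "HE1"),
                         ("CE2", "HE2"), ("CZ", "HZ")):
        out[hname] = out[cname] + 1.08 * _unit(out[cname] - centroid)
    return out


def _add_phe_side_chain(res, n_pos, ca_pos, cb, placed, add) -> None:
    """PHE ring with the first (most-favoured) chi1 rotamer that stays
    clash-free against everything already placed; chi2 fixed at 90."""
    existing = np.array(placed)
    best = None  # (min_distance, atoms) fallback
    for chi1 in _PHE_CHI1_ROTAMERS:
        atoms = _phe_ring_atoms(n_pos, ca_pos, cb, chi1)
        pos = np.array(list(atoms.values()))
        d = np.sqrt(
            ((existing[None, :, :] - pos[:, None, :]) ** 2).sum(axis=2)
        )
        min_d = float(d.min())  # the bonded CB-CG pair sits at 1.50 A
        if best is None or min_d > best[0]:
            best = (min_d, atoms)
        if min_d > 1.2:
            best = (min_d, atoms)
            break
    for name, pos in best[1].items():
        add(res, name, pos)
    cg = best[1]["CG"]
    u_b = _unit(cb - ca_pos)
    u_g = _unit(cg - cb)
    b = -_unit(_unit(ca_pos - cb) + u_g)
    p = _unit(np.cross(u_b, u_g))
    add(res, "HB2", cb + BOND_C_H * _unit(b + 0.9 * p))
    add(res, "HB3", cb + BOND_C_H * _unit(b - 0.9 * p))


def _check_clashes(structure: ProteinStructure,
                   threshold: float = 0.6) -> None:
    coords = structure.coords
    tree = structure.kdtree()
    for i, j in tree.query_pairs(threshold):
        raise PDBParseError(
            f"impossible geometry: atoms {structure.atoms[i].name} and "
            f"{structure.atoms[j].name} are "
            f"{np.linalg.norm(coords[i] - coords[j]):.2f} A apart"
        )


# ---------------------------------------------------------------------------
# PDB writing


def write_pdb(structure: ProteinStructure, n_models: int = 1,
              seed: int = 0) -> str:
    """PDB-format text; >1 model writes an NMR-style ensemble whose extra
    members carry small deterministic coordinate perturbations."""
    rng = np.random.default_rng(seed)
    out = [f"HEADER    SYNTHETIC FIXTURE                       {structure.pdb_id:>4s}"]
    for m in range(1, n_models + 1):
        if n_models > 1:
            out.append(f"MODEL     {m:4d}")
        serial = 1
        for chain in structure.chains:
            for res in chain.residues:
                for atom in res.atoms.values():
                    x, y, z = atom.pos
                    if m > 1:
                        dx = rng.normal(0.0, 0.05, 3)
                        x, y, z = x + dx[0], y + dx[1], z + dx[2]
                    name = atom.name
                    field = (f" {name:<3s}" if len(name) < 4 else name)
                    out.append(
                        f"ATOM  {serial:5d} {field}{'':1s}{res.name:>3s} "
                        f"{chain.original_id}{res.original_index or res.index:4d}"
                        f"    {x:8.3f}{y:8.3f}{z:8.3f}{1.00:6.2f}{0.00:6.2f}"
                        f"          {atom.element:>2s}"
                    )
                    serial += 1
            out.append(f"TER   {serial:5d}      {chain.residues[-1].name:>3s} "
                       f"{chain.original_id}"
                       f"{chain.residues[-1].original_index or 0:4d}")
            serial += 1
        if n_models > 1:
            out.append("ENDMDL")
    out.append("END")
    return "\n".join(out) + "\n"


# ---------------------------------------------------------------------------
# ground-truth shifts and NMRStar writing


def ground_truth_shifts(structure: ProteinStructure, spec: FixtureSpec
                        ) -> dict[tuple, float]:
    """(chain_index, residue_index, v3 atom name) -> noiseless truth (ppm).

    The truth is a known function of features the pipeline computes:
    random coil + ring current + BETA_DENSITY * heavy-atom density.
    """
    rings = semiclassical.rings_of_structure(structure)
    truth: dict[tuple, float] = {}
    for chain in structure.chains:
        for res in chain.residues:
            for name in SHIFT_ATOMS:
                atoms = ([res.get("HA2"), res.get("HA3")]
                         if name == "HA" and res.name == "GLY"
                         else [res.get(name)])
                for atom in atoms:
                    if atom is None:
                        continue
                    key = (res.name, name)
                    if key not in semiclassical.RANDOM_COIL_PPM:
                        continue
                    own = (chain.index, res.index)
                    other_rings = [r for r in rings if r.residue_key != own]
                    ring = semiclassical.ring_current_shift(
                        atom.pos, other_rings)
                    dens = geometry.atomic_density(structure, atom)
                    truth[(chain.index, res.index, atom.name)] = (
                        semiclassical.RANDOM_COIL_PPM[key]
                        + ring + BETA_DENSITY * dens
                    )
    return truth


def build_shifts(structure: ProteinStructure, spec: FixtureSpec,
                 dialect: str = "2.1") -> tuple[str, dict[tuple, float]]:
    """NMRStar text plus the retained noiseless ground truth."""
    truth = ground_truth_shifts(structure, spec)
    rng = np.random.default_rng(spec.seed)
    observed: list[tuple[int, str, str, float]] = []
    for chain in structure.chains:
        for res in chain.residues:
            for atom in res.atoms.values():
                key = (chain.index, res.index, atom.name)
                if key not in truth:
                    continue
                value = (truth[key] + spec.shift_offset
                         + (rng.normal(0.0, spec.noise_sigma)
                            if spec.noise_sigma > 0 else 0.0))
                observed.append((res.index, res.name, atom.name, value))
    text = (_write_nmrstar_21(spec, observed) if dialect == "2.1"
            else _write_nmrstar_31(spec, observed))
    return text, truth


_CONDITIONS = (("temperature", "298.0", "K"), ("pH", "6.5", "n/a"),
               ("pressure", "1.0", "atm"))


def _element_of(res3: str, atom: str) -> str:
    return residues.atom_element(res3, atom)


def _write_nmrstar_21(spec: FixtureSpec, observed) -> str:
    lines = [f"data_synthetic_{spec.bmrb_id}", ""]
    lines += ["save_sample_conditions",
              "_Saveframe_category  sample_conditions", "loop_",
              "_Variable_type", "_Variable_value", "_Variable_value_units"]
    lines += [f"{t} {v} {u}" for t, v, u in _CONDITIONS]
    lines += ["stop_", "save_", ""]
    lines += ["_Solvent_system  '90% H2O/10% D2O'",
              "_Spectrometer_model  'Avance 600'", ""]
    lines += ["save_assigned_chemical_shifts",
              "_Saveframe_category  assigned_chemical_shifts", "loop_",
              "_Atom_shift_assign_ID", "_Residue_seq_code",
              "_Residue_label", "_Atom_name", "_Atom_type",
              "_Chem_shift_value", "_Chem_shift_value_error",
              "_Chem_shift_ambiguity_code"]
    for k, (seq, res3, atom, value) in enumerate(observed, start=1):
        lines.append(
            f"{k} {seq} {res3} {atom} {_element_of(res3, atom)} "
            f"{value:.4f} 0.05 1"
        )
    lines += ["stop_", "save_", ""]
    return "\n".join(lines) + "\n"


def _write_nmrstar_31(spec: FixtureSpec, observed) -> str:
    lines = [f"data_synthetic_{spec.bmrb_id}", ""]
    lines += ["save_sample_conditions_1",
              "_Sample_condition_list.Sf_category  sample_conditions",
              "loop_", "_Sample_condition_variable.Type",
              "_Sample_condition_variable.Val",
              "_Sample_condition_variable.Val_units"]
    lines += [f"{t} {v} {u}" for t, v, u in _CONDITIONS]
    lines += ["stop_", "save_", ""]
    lines += ["_Sample.Solvent_system  '90% H2O/10% D2O'",
              "_NMR_spectrometer.Model  'Avance 600'", ""]
    lines += ["save_assigned_chem_shift_list_1",
              "_Assigned_chem_shift_list.Sf_category  assigned_chemical_shifts",
              "loop_", "_Atom_chem_shift.ID",
              "_Atom_chem_shift.Entity_assembly_ID",
              "_Atom_chem_shift.Seq_ID", "_Atom_chem_shift.Comp_ID",
              "_Atom_chem_shift.Atom_ID", "_Atom_chem_shift.Atom_type",
              "_Atom_chem_shift.Val", "_Atom_chem_shift.Val_err",
              "_Atom_chem_shift.Ambiguity_code"]
    for k, (seq, res3, atom, value) in enumerate(observed, start=1):
        lines.append(
            f"{k} 1 {seq} {res3} {atom} {_element_of(res3, atom)} "
            f"{value:.4f} 0.05 1"
        )
    lines += ["stop_", "save_", ""]
    return "\n".join(lines) + "\n"


# ---------------------------------------------------------------------------
# deterministic corruption


def corrupt(text: str, mode: str, row: int = 4) -> str:
    """Apply one corruption mode to NMRStar text (deterministic).

    Everything outside the corrupted span stays byte-identical (the
    insertion-renumbering mode rewrites row numbering by design).
    """
    if mode not in CORRUPTION_MODES:
        raise ValueError(f"unknown corruption mode {mode!r}; "
                         f"supported: {CORRUPTION_MODES}")
    lines = text.splitlines()
    data_rows = _shift_loop_rows(lines)
    if mode == "stray_token":
        idx = data_rows[min(row, len(data_rows) - 1)]
        lines[idx] = lines[idx] + " XXX"
    elif mode == "nonnumeric_shift":
        idx = data_rows[min(row, len(data_rows) - 1)]
        toks = lines[idx].split()
        toks[_value_column(lines)] = "not_a_number"
        lines[idx] = " ".join(toks)
    elif mode == "duplicate_frame":
        start, end = _shift_frame_span(lines)
        lines = lines + [""] + lines[start:end]
    elif mode == "dialect_v3_names":
        from . import nomenclature

        comp_col, atom_col = _name_columns(lines)
        for idx in data_rows:
            toks = lines[idx].split()
            try:
                toks[atom_col] = nomenclature.to_pdb_v2(
                    toks[comp_col], toks[atom_col])
            except nomenclature.UnknownAtomNameError:
                pass
            lines[idx] = " ".join(toks)
    elif mode == "one_residue_insertion":
        seq_col = _seq_column(lines)
        seqs = sorted({int(lines[i].split()[seq_col]) for i in data_rows})
        pivot = seqs[len(seqs) // 2]
        for idx in data_rows:
            toks = lines[idx].split()
            if int(toks[seq_col]) >= pivot:
                toks[seq_col] = str(int(toks[seq_col]) + 1)
            lines[idx] = " ".join(toks)
    return "\n".join(lines) + "\n"


def _loop_spans(lines):
    """(tag_names, first_data_line, stop_line) for every loop."""
    spans = []
    i = 0
    while i < len(lines):
        if lines[i].strip().lower() == "loop_":
            j = i + 1
            tags = []
            while j < len(lines) and lines[j].strip().startswith("_"):
                tags.append(lines[j].strip())
                j += 1
            k = j
            while k < len(lines) and lines[k].strip().lower() != "stop_":
                k += 1
            spans.append((tags, j, k))
            i = k
        i += 1
    return spans


def _shift_loop(lines):
    for tags, start, stop in _loop_spans(lines):
        low = [t.lower() for t in tags]
        if any(t in ("_chem_shift_value", "_atom_chem_shift.val")
               for t in low):
            return tags, start, stop
    raise ValueError("no shift loop in fixture text")


def _shift_loop_rows(lines) -> list[int]:
    _, start, stop = _shift_loop(lines)
    return [i for i in range(start, stop) if lines[i].strip()]


def _column(lines, names) -> int:
    tags, _, _ = _shift_loop(lines)
    low = [t.lower() for t in tags]
    for k, t in enumerate(low):
        if t in names:
            return k
    raise ValueError(f"no column {names} in shift loop")


def _value_column(lines) -> int:
    return _column(lines, ("_chem_shift_value", "_atom_chem_shift.val"))


def _seq_column(lines) -> int:
    return _column(lines, ("_residue_seq_code", "_atom_chem_shift.seq_id"))


def _name_columns(lines) -> tuple[int, int]:
    comp = _column(lines, ("_residue_label", "_atom_chem_shift.comp_id"))
    atom = _column(lines, ("_atom_name", "_atom_chem_shift.atom_id"))
    return comp, atom


def _shift_frame_span(lines) -> tuple[int, int]:
    _, start, stop = _shift_loop(lines)
    s = start
    while s > 0 and not lines[s].strip().lower().startswith("save_"):
        s -= 1
    e = stop
    while e < len(lines) and lines[e].strip().lower() != "save_":
        e += 1
    return s, e + 1


# ---------------------------------------------------------------------------
# corpora for end-to-end runs


def default_corpus_specs(n_structures: int = 16, length: int = 14,
                         noise_sigma: float = 0.0, seed: int = 0
                         ) -> list[FixtureSpec]:
    """Study-condition corpus: helix/extended/mixed toy proteins with one
    or two ring-bearing residues each.

    Every returned spec is guaranteed buildable: programs whose jitter
    produces a steric clash are redrawn (deterministically) until the
    structure passes the builder's clash check.
    """
    rng = np.random.default_rng(seed)
    specs = []
    for k in range(n_structures):
        letters = list(rng.choice(["A", "G"], size=length,
                                  p=[0.7, 0.3]))
        # one or two PHE at interior positions
        n_phe = 1 + (k % 2)
        positions = rng.choice(range(2, length - 2), size=n_phe,
                               replace=False)
        for p in positions:
            letters[int(p)] = "F"
        for _attempt in range(20):
            program: list[tuple[float, float]] = []
            for i in range(length):
                if k % 3 == 0:
                    base = HELIX
                elif k % 3 == 1:
                    base = EXTENDED
                else:
                    base = HELIX if i < length // 2 else EXTENDED
                jitter = rng.normal(0.0, 4.0, 2)
                program.append((base[0] + float(jitter[0]),
                                base[1] + float(jitter[1])))
            spec = FixtureSpec(
                pdb_id=f"S{k:03d}",
                sequence="".join(letters),
                phi_psi=program,
                noise_sigma=noise_sigma,
                seed=int(rng.integers(0, 2 ** 31 - 1)),
                bmrb_id=str(10000 + k),
            )
            try:
                build_structure(spec)
            except PDBParseError:
                continue
            specs.append(spec)
            break
        else:  # pragma: no cover - 20 redraws never all clash in practice
            raise PDBParseError(
                f"could not draw a clash-free program for structure {k}")
    return specs
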