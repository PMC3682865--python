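"""Experiment-to-structure mapping and its restriction filters.

Type-1 filters act on the PDB<->BMRB mapping itself (protein-only entries,
perfect sequence agreement, homology culling); type-2 filters evaluate
individual structure files (a structure-quality pseudo-energy against a
kJ/mol cutoff).  All filters are pure predicates: applying them in any
order yields the same surviving set.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np

from . import residues
from .alignment import AlignmentResult, global_align, percent_identity
from .structure import ProteinStructure

log = logging.getLogger("shiftforge")

DEFAULT_HOMOLOGY_CUTOFF = 10.0  # percent identity
DEFAULT_ENERGY_CUTOFF = 1000.0  # kJ/mol


@dataclass
class MappingEntry:
    """One line of the PDB-ID <-> BMRB accession mapping."""

    pdb_id: str
    bmrb_id: str
    chain_id: str | None = None  # optional per-chain expansion
    protein_only: bool | None = None
    alignment: AlignmentResult | None = None
    notes: list[str] = field(default_factory=list)

    def __post_init__(self) -> None:
        if not self.pdb_id or not self.bmrb_id:
            raise ValueError("pdb_id and bmrb_id must be non-empty")

    @property
    def alignment_identity(self) -> float | None:
        return self.alignment.identity if self.alignment else None


class MappingParseError(ValueError):
    def __init__(self, line_number: int, line: str, reason: str):
        super().__init__(
            f"malformed mapping line {line_number}: {reason}: {line!r}"
        )
        self.line_number = line_number


def read_mapping(source: str) -> list[MappingEntry]:
    """Parse a two-column whitespace-separated PDB-ID/BMRB-ID table.

    ``source`` may be a path or the text itself (anything containing a
    newline or failing to resolve as a file is treated as text).  ``#``
    starts a comment; order of data lines is preserved.
    """
    import os

    if "\n" not in source and os.path.exists(source):
        with open(source) as fh:
            text = fh.read()
    else:
        text = source
    entries: list[MappingEntry] = []
    for lineno, raw in enumerate(text.splitlines(), start=1):
        line = raw.split("#", 1)[0].strip()
        if not line:
            continue
        tokens = line.split()
        if len(tokens) < 2:
            raise MappingParseError(lineno, raw, "expected two columns")
        entries.append(MappingEntry(pdb_id=tokens[0], bmrb_id=tokens[1]))
    return entries


# ---------------------------------------------------------------------------
# type-1 filters


def filter_perfect_alignment(
    entries: list[MappingEntry],
) -> list[MappingEntry]:
    """Keep exactly the entries whose sequences align at 100 % identity."""
    kept = []
    for e in entries:
        if e.alignment is None:
            raise ValueError(f"entry {e.pdb_id}/{e.bmrb_id} has no alignment")
        if e.alignment.identity == 100.0:
            kept.append(e)
        else:
            log.info(
                "perfect-alignment filter dropped %s/%s (identity %.3f%%)",
                e.pdb_id, e.bmrb_id, e.alignment.identity,
            )
    return kept


def cull_homologs(
    sequences: dict,
    identity_cutoff: float = DEFAULT_HOMOLOGY_CUTOFF,
) -> list:
    """Greedy homology culling: retain a maximal low-identity subset.

    ``sequences`` maps an entry key to its one-letter sequence.  Keys are
    visited longest-sequence-first (ties by input order) and a key is
    retained iff its pairwise identity to every already-retained sequence
    is <= ``identity_cutoff`` (percent).  Deterministic given input order.
    """
    if not 0.0 < identity_cutoff <= 100.0:
        raise ValueError(f"cutoff must be in (0, 100], got {identity_cutoff}")
    order = sorted(
        sequences.keys(),
        key=lambda k: (-len(sequences[k]),
                       list(sequences.keys()).index(k)),
    )
    retained: list = []
    for key in order:
        seq = sequences[key]
        ok = all(
            percent_identity(seq, sequences[r]) <= identity_cutoff
            for r in retained
        )
        if ok:
            retained.append(key)
        else:
            log.info("homology culling dropped %s", key)
    return retained


@dataclass
class EntityMetadata:
    """Polymer / heteroatom content of a PDB entry.

    Mirrors what the original pipeline read from the PDB's REST service;
    here it is extracted from a local file or injected directly.
    """

    polymer_types: list[str] = field(default_factory=list)  # "protein"/"nucleic"
    ligands: list[str] = field(default_factory=list)  # non-water HET components
    n_waters: int = 0


def extract_entity_metadata(path: str) -> EntityMetadata:
    """Scan a local PDB file for polymer and heteroatom components."""
    import gemmi

    st = gemmi.read_pdb(str(path), split_chain_on_ter=False)
    meta = EntityMetadata()
    if len(st) == 0:
        return meta
    seen_polymers = set()
    for chain in st[0]:
        for res in chain:
            name = res.name.strip()
            if name in residues.STANDARD_RESIDUES:
                seen_polymers.add(("protein", chain.name))
            elif name in residues.NUCLEIC_RESIDUES:
                seen_polymers.add(("nucleic", chain.name))
            elif name in residues.WATER_RESIDUES:
                meta.n_waters += 1
            else:
                meta.ligands.append(name)
    meta.polymer_types = sorted({t for t, _ in seen_polymers})
    return meta


def filter_protein_only(
    entry: MappingEntry, metadata: EntityMetadata | None
) -> tuple[bool, str]:
    """Drop entries with non-protein polymers or non-water heteroatoms.

    Returns ``(keep, reason)``.  Missing metadata keeps the entry flagged
    as undetermined with a warning.
    """
    if metadata is None:
        log.warning(
            "protein-only filter: no metadata for %s, kept undetermined",
            entry.pdb_id,
        )
        entry.notes.append("protein-only: undetermined")
        return True, "undetermined"
    if any(t != "protein" for t in metadata.polymer_types):
        return False, "nucleic polymer"
    if metadata.ligands:
        return False, "ligand"
    return True, "protein and water only"


# ---------------------------------------------------------------------------
# type-2 filter: structure-quality pseudo-energy

_SCORERS: dict[str, object] = {}


def register_scorer(name: str, fn, replace: bool = False) -> None:
    if name in _SCORERS and not replace:
        raise ValueError(f"scorer already registered: {name!r}")
    _SCORERS[name] = fn


def get_scorer(name: str):
    try:
        return _SCORERS[name]
    except KeyError:
        raise KeyError(
            f"unknown scorer {name!r}; registered: {sorted(_SCORERS)}"
        ) from None


COULOMB_KJ = 1389.35  # kJ/mol * Angstrom / e^2


def nonbonded_pseudo_energy(structure: ProteinStructure,
                            cutoff_radius: float = 6.0) -> float:
    """Simple nonbonded structure-quality score in kJ/mol.

    Lennard-Jones clash term (well depth 0.4 kJ/mol, minimum at van der
    Waals contact) plus Coulomb interactions over the built-in minimal
    partial-charge table, summed over atom pairs separated by more than
    three covalent bonds (the customary 1-4 exclusion) and closer than
    ``cutoff_radius`` Angstrom.  It ranks
    clash-riddled geometries far above relaxed ones on the same kJ/mol
    scale the 1000 kJ/mol default cutoff expects.
    """
    eps = 0.4
    atoms = structure.atoms
    if not atoms:
        return 0.0
    tree = structure.kdtree()
    excluded = [structure.neighbors_within_bonds(a, 3) for a in atoms]
    energy = 0.0
    for i, j in tree.query_pairs(cutoff_radius):
        if j in excluded[i]:
            continue
        a, b = atoms[i], atoms[j]
        r = float(np.linalg.norm(a.pos - b.pos))
        if r < 1e-6:
            return float("inf")
        sigma = (
            residues.VDW_RADII.get(a.element, 1.7)
            + residues.VDW_RADII.get(b.element, 1.7)
        ) * 2.0 ** (-1.0 / 6.0)
        sr6 = (sigma / r) ** 6
        energy += 4.0 * eps * (sr6 * sr6 - sr6)
        qa = residues.partial_charge(a.residue.name, a.name)
        qb = residues.partial_charge(b.residue.name, b.name)
        if qa and qb:
            energy += COULOMB_KJ * qa * qb / r
    return energy


register_scorer("default-nb", nonbonded_pseudo_energy)


def filter_energy(
    structure: ProteinStructure,
    cutoff: float = DEFAULT_ENERGY_CUTOFF,
    scorer="default-nb",
) -> tuple[bool, float | None, str]:
    """Keep iff the structure-quality score is <= ``cutoff`` kJ/mol.

    Returns ``(keep, score, reason)``; a scorer failure drops the entry
    with reason ``"unscorable"``.
    """
    fn = get_scorer(scorer) if isinstance(scorer, str) else scorer
    try:
        score = float(fn(structure))
    except Exception as exc:  # scorer failure policy: drop, do not crash
        log.warning("energy filter: scorer failed on %s: %s",
                    structure.pdb_id, exc)
        return False, None, "unscorable"
    if score <= cutoff:
        return True, score, "ok"
    return False, score, f"score {score:.1f} above cutoff {cutoff:.1f}"


def align_entry(entry: MappingEntry, seq_pdb: str, seq_bmrb: str
                ) -> MappingEntry:
    """Attach the global alignment of the two sequences to the entry."""
    entry.alignment = global_align(seq_pdb, seq_bmrb)
    return entry
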