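"""Linking experimental shifts to structure atoms.

The two record systems disagree on chain identifiers, residue numbering
and atom nomenclature.  Matching proceeds top-down: each shift entity is
paired with the best-aligning structure chain (ties go to the first chain
in file order), residues are re-anchored through the global alignment (so
single-residue indels do not shear the mapping), and atom names are
translated between dialects.  Every shift ends up attached to exactly one
atom or in the unmatched report with a reason — the two counts always add
up to the parsed total.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

from . import nomenclature, residues
from .alignment import AlignmentResult, alignment_column_map, global_align
from .nmrstar import ExperimentalConditions, ShiftEntry, ShiftList
from .records import AtomShiftRecord, ChainMappingRecord
from .structure import ProteinStructure

log = logging.getLogger("shiftforge")


@dataclass
class ChainPairing:
    """One shift entity paired with one structure chain."""

    entity_id: int
    chain_index: int
    alignment: AlignmentResult
    residue_map: dict[int, int]  # entity seq position -> chain residue index
    first_seq_code: int


@dataclass
class UnmatchedShift:
    entry: ShiftEntry
    entity_id: int
    reason: str  # no chain | no residue | residue type mismatch |
    #              name conversion failure | no atom | duplicate


@dataclass
class AssignmentResult:
    records: list[AtomShiftRecord]
    unmatched: list[UnmatchedShift]
    pairings: list[ChainPairing] = field(default_factory=list)

    def unmatched_csv(self) -> str:
        lines = ["pdb_id,chain,residue,atom,reason"]
        for u in self.unmatched:
            lines.append(
                f",{u.entity_id},{u.entry.seq_code},"
                f"{u.entry.atom_name},{u.reason}"
            )
        return "\n".join(lines) + "\n"


def match_chains(
    structure: ProteinStructure,
    shift_lists: list[ShiftList],
    identity_floor: float = 0.0,
) -> tuple[list[ChainPairing], list[ShiftList]]:
    """Pair each shift entity with its best-aligning structure chain.

    Chains are already re-indexed 1..k in file order; with equal best
    alignment scores the first chain in file order wins.  Entities whose
    best identity falls below ``identity_floor`` stay unmatched (the
    default floor of 0 never rejects).
    """
    if not structure.chains:
        raise ValueError("structure has no chains")
    pairings: list[ChainPairing] = []
    unmatched: list[ShiftList] = []
    for sl in shift_lists:
        seq = sl.sequence()
        if not seq:
            unmatched.append(sl)
            continue
        best: tuple[int, int, AlignmentResult] | None = None
        for chain in structure.chains:
            if not chain.sequence:
                continue
            aln = global_align(seq, chain.sequence)
            # strictly-better score wins; ties keep the earlier chain
            if best is None or aln.score > best[2].score:
                best = (sl.entity_id, chain.index, aln)
        if best is None or best[2].identity < identity_floor:
            log.warning("shift entity %d matched no chain", sl.entity_id)
            unmatched.append(sl)
            continue
        aln = best[2]
        pairings.append(ChainPairing(
            entity_id=sl.entity_id,
            chain_index=best[1],
            alignment=aln,
            residue_map=alignment_column_map(aln.aligned_a, aln.aligned_b),
            first_seq_code=sl.first_seq_code,
        ))
    return pairings, unmatched


def assign_shifts(
    structure: ProteinStructure,
    shift_lists: list[ShiftList],
    pairings: list[ChainPairing],
) -> AssignmentResult:
    """Attach each shift to exactly one atom or report it unmatched."""
    by_entity = {p.entity_id: p for p in pairings}
    chains = {c.index: c for c in structure.chains}
    records: list[AtomShiftRecord] = []
    unmatched: list[UnmatchedShift] = []
    taken: set[tuple] = set()

    for sl in shift_lists:
        pairing = by_entity.get(sl.entity_id)
        for entry in sl.entries:
            if pairing is None:
                unmatched.append(UnmatchedShift(entry, sl.entity_id,
                                                "no chain"))
                continue
            chain = chains[pairing.chain_index]
            pos = entry.seq_code - pairing.first_seq_code + 1
            res_idx = pairing.residue_map.get(pos)
            if res_idx is None or not 1 <= res_idx <= len(chain.residues):
                unmatched.append(UnmatchedShift(entry, sl.entity_id,
                                                "no residue"))
                continue
            res = chain.residues[res_idx - 1]
            if res.name != entry.residue_type and \
                    entry.residue_type in residues.STANDARD_RESIDUES:
                unmatched.append(UnmatchedShift(
                    entry, sl.entity_id, "residue type mismatch"))
                continue
            try:
                v2_name = nomenclature.to_pdb_v2(res.name, entry.atom_name)
            except nomenclature.UnknownAtomNameError:
                unmatched.append(UnmatchedShift(
                    entry, sl.entity_id, "name conversion failure"))
                continue
            atom = None
            for candidate in (v2_name,
                              nomenclature.to_nmrstar(res.name, v2_name),
                              entry.atom_name):
                atom = res.get(candidate)
                if atom is not None:
                    break
            if atom is None:
                unmatched.append(UnmatchedShift(entry, sl.entity_id,
                                                "no atom"))
                continue
            key = (structure.pdb_id, chain.index, res.index, v2_name)
            if key in taken:
                unmatched.append(UnmatchedShift(entry, sl.entity_id,
                                                "duplicate"))
                continue
            taken.add(key)
            try:
                ff_type = residues.force_field_atom_type(res.name, atom.name)
            except (KeyError, ValueError):
                ff_type = "UNK"
            records.append(AtomShiftRecord(
                pdb_id=structure.pdb_id,
                chain_index=chain.index,
                residue_index=res.index,
                residue_type=res.name,
                atom_name=v2_name,
                force_field_atom_type=ff_type,
                experimental_shift=entry.shift,
                original_residue_index=res.original_index,
            ))
    return AssignmentResult(records, unmatched, pairings)


#: No-op hook where shift re-referencing (correcting systematic offsets in
#: deposited shifts) can be inserted; the default transform is identity.
def rereference_shifts(shift_lists: list[ShiftList],
                       transform=None) -> list[ShiftList]:
    if transform is None:
        return shift_lists
    for sl in shift_lists:
        for e in sl.entries:
            e.shift = transform(e)
    return shift_lists


def build_mapping_record(
    pdb_id: str,
    bmrb_id: str,
    pairing: ChainPairing,
    structure: ProteinStructure,
    conditions: ExperimentalConditions,
    shift_list: ShiftList,
) -> ChainMappingRecord:
    """Chain-mapping row for one paired chain, with shift availability."""
    elements = set()
    for e in shift_list.entries:
        try:
            elements.add(residues.atom_element(e.residue_type, e.atom_name))
        except ValueError:
            pass
    chain = next(c for c in structure.chains
                 if c.index == pairing.chain_index)
    return ChainMappingRecord(
        pdb_id=pdb_id,
        chain_index=pairing.chain_index,
        original_chain_id=chain.original_id,
        bmrb_id=bmrb_id,
        alignment_identity=pairing.alignment.identity,
        has_h_shifts="H" in elements,
        has_c_shifts="C" in elements,
        has_n_shifts="N" in elements,
        temperature=conditions.temperature,
        ph=conditions.ph,
        pressure=conditions.pressure,
        solvent=conditions.solvent,
        spectrometer=conditions.spectrometer,
    )
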