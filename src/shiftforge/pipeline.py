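"""End-to-end orchestration: files -> filtered mapping -> feature table ->
trained models -> evaluation.

Mirrors the pipeline stages: (a) initial experiment-to-structure mapping,
(b) type-1/type-2 filtering, (c) shift-to-atom assignment, (d) feature
computation into the two-table store, (e) training and evaluation.  Every
filter and parser decision is logged to the package logger.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from pathlib import Path

from . import assign as assign_mod
from . import mapping as mapping_mod
from . import nmrstar as nmrstar_mod
from . import store as store_mod
from .features import FeatureContext, compute_features, \
    default_feature_definition
from .records import AtomShiftRecord, ChainMappingRecord, Dataset, \
    FeatureDefinition
from .structure import ProteinStructure, parse_pdb
from .superclass import SuperClassScheme, default_scheme

log = logging.getLogger("shiftforge")


@dataclass
class PipelineInput:
    """One PDB/NMRStar pair (paths or raw text)."""

    pdb_id: str
    bmrb_id: str
    pdb_source: str
    star_source: str


@dataclass
class BuildReport:
    """What happened to each input while building the dataset."""

    accepted: list[str] = field(default_factory=list)
    rejected: dict[str, str] = field(default_factory=dict)  # pdb_id -> reason
    parse_anomalies: dict[str, int] = field(default_factory=dict)
    unmatched_shifts: int = 0
    assigned_shifts: int = 0


def build_dataset(
    inputs: list[PipelineInput],
    feature_definition: FeatureDefinition | None = None,
    scheme: SuperClassScheme | None = None,
    protein_only: bool = True,
    homology_cutoff: float | None = mapping_mod.DEFAULT_HOMOLOGY_CUTOFF,
    energy_cutoff: float | None = mapping_mod.DEFAULT_ENERGY_CUTOFF,
    energy_scorer: str = "default-nb",
    require_perfect_alignment: bool = True,
    store_path: str | Path | None = None,
) -> tuple[Dataset, list[ChainMappingRecord], BuildReport]:
    """Run stages (a)-(d) over a set of structure/shift pairs.

    Filters may be disabled by passing None for their cutoffs (or False
    for ``protein_only`` / ``require_perfect_alignment``).
    """
    feature_definition = feature_definition or default_feature_definition()
    scheme = scheme or default_scheme()
    report = BuildReport()

    parsed = []  # (input, structure, shift_lists, conditions, pairings)
    for inp in inputs:
        try:
            structure = parse_pdb(inp.pdb_source, pdb_id=inp.pdb_id) \
                if _looks_like_path(inp.pdb_source) \
                else _parse_pdb_text(inp.pdb_source, inp.pdb_id)
        except Exception as exc:
            report.rejected[inp.pdb_id] = f"structure parse failure: {exc}"
            log.warning("dropped %s: %s", inp.pdb_id, exc)
            continue
        if protein_only:
            meta = _metadata_from_source(inp.pdb_source)
            keep, reason = mapping_mod.filter_protein_only(
                mapping_mod.MappingEntry(inp.pdb_id, inp.bmrb_id), meta)
            if not keep:
                report.rejected[inp.pdb_id] = f"protein-only: {reason}"
                continue
        try:
            shift_lists, conditions, parse_report = \
                nmrstar_mod.parse_nmrstar(inp.star_source)
        except nmrstar_mod.NMRStarError as exc:
            report.rejected[inp.pdb_id] = f"shift parse failure: {exc}"
            log.warning("dropped %s: %s", inp.pdb_id, exc)
            continue
        report.parse_anomalies[inp.pdb_id] = parse_report.total_anomalies
        pairings, _ = assign_mod.match_chains(structure, shift_lists)
        if not pairings:
            report.rejected[inp.pdb_id] = "no chain pairing"
            continue
        if require_perfect_alignment:
            entries = []
            for p in pairings:
                e = mapping_mod.MappingEntry(inp.pdb_id, inp.bmrb_id)
                e.alignment = p.alignment
                entries.append((e, p))
            surviving = mapping_mod.filter_perfect_alignment(
                [e for e, _ in entries])
            pairings = [p for e, p in entries if e in surviving]
            if not pairings:
                report.rejected[inp.pdb_id] = "alignment below 100%"
                continue
        if energy_cutoff is not None:
            keep, score, reason = mapping_mod.filter_energy(
                structure, energy_cutoff, energy_scorer)
            if not keep:
                report.rejected[inp.pdb_id] = f"energy filter: {reason}"
                continue
        parsed.append((inp, structure, shift_lists, conditions, pairings))

    if homology_cutoff is not None and parsed:
        seqs = {p[0].pdb_id: p[1].chains[0].sequence for p in parsed}
        retained = set(mapping_mod.cull_homologs(seqs, homology_cutoff))
        for p in parsed:
            if p[0].pdb_id not in retained:
                report.rejected[p[0].pdb_id] = "homology culled"
        parsed = [p for p in parsed if p[0].pdb_id in retained]

    mapping_records: list[ChainMappingRecord] = []
    atom_records: list[AtomShiftRecord] = []
    for inp, structure, shift_lists, conditions, pairings in parsed:
        result = assign_mod.assign_shifts(structure, shift_lists, pairings)
        report.unmatched_shifts += len(result.unmatched)
        report.assigned_shifts += len(result.records)
        by_entity = {sl.entity_id: sl for sl in shift_lists}
        chain_map: dict[int, ChainMappingRecord] = {}
        for p in pairings:
            rec = assign_mod.build_mapping_record(
                inp.pdb_id, inp.bmrb_id, p, structure,
                conditions, by_entity[p.entity_id])
            chain_map[p.chain_index] = rec
            mapping_records.append(rec)
        ctx = FeatureContext(structure, chain_map)
        atom_index = {
            (c.index, r.index): r
            for c in structure.chains for r in c.residues
        }
        for rec in result.records:
            res = atom_index[(rec.chain_index, rec.residue_index)]
            atom = res.get(rec.atom_name)
            if atom is None:  # record carries v2 names, file may be v3
                from . import nomenclature

                atom = res.get(nomenclature.to_nmrstar(res.name,
                                                       rec.atom_name))
            rec.super_class = scheme.assign(rec.atom_name, rec.residue_type)
            rec.features = compute_features(atom, ctx, feature_definition)
            atom_records.append(rec)
        report.accepted.append(inp.pdb_id)

    if store_path is not None:
        store_mod.write_store(mapping_records, atom_records, store_path,
                              feature_definition)
    dataset = Dataset(records=atom_records, provenance={
        "n_inputs": len(inputs),
        "accepted": report.accepted,
        "filters": {
            "protein_only": protein_only,
            "perfect_alignment": require_perfect_alignment,
            "homology_cutoff": homology_cutoff,
            "energy_cutoff": energy_cutoff,
        },
    })
    return dataset, mapping_records, report


def dataset_from_store(path: str | Path) -> Dataset:
    _, atom_records, _ = store_mod.read_store(path)
    return Dataset(records=atom_records)


def _looks_like_path(source: str) -> bool:
    return "\n" not in source and Path(source).exists()


def _parse_pdb_text(text: str, pdb_id: str) -> ProteinStructure:
    import tempfile

    with tempfile.NamedTemporaryFile("w", suffix=".pdb",
                                     delete=False) as fh:
        fh.write(text)
        name = fh.name
    try:
        return parse_pdb(name, pdb_id=pdb_id)
    finally:
        Path(name).unlink(missing_ok=True)


def _metadata_from_source(source: str):
    if _looks_like_path(source):
        return mapping_mod.extract_entity_metadata(source)
    import tempfile

    with tempfile.NamedTemporaryFile("w", suffix=".pdb",
                                     delete=False) as fh:
        fh.write(source)
        name = fh.name
    try:
        return mapping_mod.extract_entity_metadata(name)
    finally:
        Path(name).unlink(missing_ok=True)
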