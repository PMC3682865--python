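"""Applying a saved model vector to a new structure.

Runs the same preparation steps used for dataset construction — structure
parsing, super-class assignment, feature computation — then predicts one
shift per atom whose name maps to a modeled super class and writes the
result as CSV.  Atoms without a modeled class are skipped and counted.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from .features import FeatureContext, compute_features, resolve_features
from .model import SuperClassRandomForest
from .records import ChainMappingRecord, FeatureDefinition, PredictionRecord
from .structure import ProteinStructure, parse_pdb
from .superclass import SuperClassScheme, default_scheme

CSV_HEADER = ("pdb_id,chain,residue_index,residue_type,atom_name,"
              "super_class,predicted_shift_ppm")


class FeatureMismatchError(ValueError):
    def __init__(self, missing, extra):
        super().__init__(
            f"feature definition does not match the model sidecar; "
            f"missing from definition: {sorted(missing)}; "
            f"not in model: {sorted(extra)}"
        )
        self.missing = missing
        self.extra = extra


@dataclass
class PredictionOutput:
    records: list[PredictionRecord]
    skipped: int  # atoms without a modeled super class
    csv: str = field(repr=False, default="")


def predict_structure(
    structure: ProteinStructure | str | Path,
    model: SuperClassRandomForest,
    feature_definition: FeatureDefinition | None = None,
    scheme: SuperClassScheme | None = None,
    conditions: dict | None = None,
) -> PredictionOutput:
    """Predict shifts for every classifiable atom of a structure.

    ``conditions`` may supply prediction-time experimental conditions
    (temperature, ph, pressure, solvent, spectrometer); absent ones enter
    the feature table as missing.  The alignment-score feature is fixed to
    100 since no reference sequence exists at prediction time.
    """
    if not isinstance(structure, ProteinStructure):
        structure = parse_pdb(structure)
    scheme = scheme or default_scheme()
    if feature_definition is None:
        feature_definition = resolve_features(model.feature_names_in_)
    def_names = set(feature_definition.names)
    model_names = set(model.feature_names_in_)
    if def_names != model_names:
        raise FeatureMismatchError(model_names - def_names,
                                   def_names - model_names)

    conditions = conditions or {}
    mapping_records = {
        chain.index: ChainMappingRecord(
            pdb_id=structure.pdb_id,
            chain_index=chain.index,
            original_chain_id=chain.original_id,
            bmrb_id="",
            alignment_identity=100.0,
            temperature=conditions.get("temperature"),
            ph=conditions.get("ph"),
            pressure=conditions.get("pressure"),
            solvent=conditions.get("solvent"),
            spectrometer=conditions.get("spectrometer"),
        )
        for chain in structure.chains
    }
    ctx = FeatureContext(structure, mapping_records)

    atoms = []
    rows = []
    skipped = 0
    for chain in structure.chains:
        for res in chain.residues:
            for atom in res.atoms.values():
                label = scheme.assign(atom.name, res.name)
                if label is None or label not in model.models_:
                    skipped += 1
                    continue
                row = {"super_class": label}
                row.update(compute_features(atom, ctx, feature_definition))
                atoms.append((chain, res, atom, label))
                rows.append(row)

    records: list[PredictionRecord] = []
    if rows:
        frame = pd.DataFrame(rows)
        frame = frame[["super_class"] + model.feature_names_in_]
        pred = model.predict(frame)
        for (chain, res, atom, label), value in zip(atoms, pred):
            if np.isnan(value):
                skipped += 1
                continue
            records.append(PredictionRecord(
                pdb_id=structure.pdb_id,
                chain_index=chain.index,
                residue_index=res.index,
                residue_type=res.name,
                atom_name=atom.name,
                super_class=label,
                predicted_shift=float(value),
            ))
    return PredictionOutput(records, skipped, to_csv(records))


def to_csv(records: list[PredictionRecord]) -> str:
    """Fixed-column CSV ('.' decimal point, comma separated)."""
    lines = [CSV_HEADER]
    for r in records:
        lines.append(
            f"{r.pdb_id},{r.chain_index},{r.residue_index},"
            f"{r.residue_type},{r.atom_name},{r.super_class},"
            f"{r.predicted_shift:.6f}"
        )
    return "\n".join(lines) + "\n"


def write_csv(records: list[PredictionRecord], path: str | Path) -> None:
    Path(path).write_text(to_csv(records))
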