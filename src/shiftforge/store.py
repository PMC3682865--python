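"""Two-table SQLite store for chain mappings and atomic properties.

The on-disk data model mirrors the in-memory records exactly: one
``chain_mapping`` table (one row per PDB-chain/BMRB pairing, including the
named boolean filter-flag columns) and one ``atomic_property`` table (one
row per atom with its experimental shift and feature values).  Feature
columns are stored under quoted ``feat:<name>`` identifiers so arbitrary
feature names round-trip unchanged; missing values are SQL NULLs and come
back as the package-wide :data:`~shiftforge.records.MISSING` sentinel.
"""

from __future__ import annotations

import numbers
import sqlite3
from pathlib import Path

from .records import MISSING, AtomShiftRecord, ChainMappingRecord, \
    FeatureDefinition

SCHEMA_VERSION = 1

_MAPPING_COLUMNS = [
    ("pdb_id", "TEXT NOT NULL"),
    ("chain_index", "INTEGER NOT NULL"),
    ("original_chain_id", "TEXT"),
    ("bmrb_id", "TEXT"),
    ("alignment_identity", "REAL"),
    ("has_h_shifts", "INTEGER"),
    ("has_c_shifts", "INTEGER"),
    ("has_n_shifts", "INTEGER"),
    ("temperature", "REAL"),
    ("ph", "REAL"),
    ("pressure", "REAL"),
    ("solvent", "TEXT"),
    ("spectrometer", "TEXT"),
]

_ATOM_COLUMNS = [
    ("pdb_id", "TEXT NOT NULL"),
    ("chain_index", "INTEGER NOT NULL"),
    ("residue_index", "INTEGER NOT NULL"),
    ("residue_type", "TEXT NOT NULL"),
    ("atom_name", "TEXT NOT NULL"),
    ("force_field_atom_type", "TEXT"),
    ("super_class", "TEXT"),
    ("experimental_shift", "REAL NOT NULL"),
    ("original_residue_index", "INTEGER"),
]


class DuplicateKeyError(ValueError):
    """Two records share a primary key; the offending key is reported."""

    def __init__(self, table: str, key: tuple):
        super().__init__(f"duplicate primary key in {table}: {key}")
        self.table = table
        self.key = key


class ColumnCollisionError(ValueError):
    """A filter column with this name already exists."""

    def __init__(self, column: str):
        super().__init__(f"filter column already exists: {column!r}")
        self.column = column


def _q(name: str) -> str:
    return '"' + name.replace('"', '""') + '"'


def write_store(
    mapping_records: list[ChainMappingRecord],
    atom_records: list[AtomShiftRecord],
    path: str | Path,
    feature_definition: FeatureDefinition | None = None,
) -> None:
    """Create (or overwrite) the store at ``path``."""
    if feature_definition is None:
        feature_definition = _infer_definition(atom_records)

    seen: set = set()
    for rec in mapping_records:
        if rec.key in seen:
            raise DuplicateKeyError("chain_mapping", rec.key)
        seen.add(rec.key)
    seen = set()
    for arec in atom_records:
        if arec.key in seen:
            raise DuplicateKeyError("atomic_property", arec.key)
        seen.add(arec.key)
        missing_feats = [n for n in feature_definition
                         if n not in arec.features]
        if missing_feats:
            raise ValueError(
                f"record {arec.key} lacks features {missing_feats}"
            )

    flag_names = sorted({n for r in mapping_records for n in r.filter_flags})

    path = Path(path)
    if path.exists():
        path.unlink()
    con = sqlite3.connect(path)
    try:
        con.execute(f"PRAGMA user_version = {SCHEMA_VERSION}")
        map_cols = [f"{_q(n)} {t}" for n, t in _MAPPING_COLUMNS]
        map_cols += [f"{_q('flag:' + n)} INTEGER" for n in flag_names]
        con.execute(
            "CREATE TABLE chain_mapping ("
            + ", ".join(map_cols)
            + ", PRIMARY KEY (pdb_id, chain_index))"
        )
        atom_cols = [f"{_q(n)} {t}" for n, t in _ATOM_COLUMNS]
        for name in feature_definition:
            sqltype = ("REAL" if feature_definition.kinds[name] == "numeric"
                       else "TEXT")
            atom_cols.append(f"{_q('feat:' + name)} {sqltype}")
        con.execute(
            "CREATE TABLE atomic_property ("
            + ", ".join(atom_cols)
            + ", PRIMARY KEY (pdb_id, chain_index, residue_index, atom_name))"
        )

        ncols = len(_MAPPING_COLUMNS) + len(flag_names)
        ins = ("INSERT INTO chain_mapping VALUES ("
               + ",".join("?" * ncols) + ")")
        for rec in mapping_records:
            row = [
                rec.pdb_id, rec.chain_index, rec.original_chain_id,
                rec.bmrb_id, rec.alignment_identity,
                int(rec.has_h_shifts), int(rec.has_c_shifts),
                int(rec.has_n_shifts),
                rec.temperature, rec.ph, rec.pressure,
                rec.solvent, rec.spectrometer,
            ] + [int(bool(rec.filter_flags.get(n, False)))
                 for n in flag_names]
            con.execute(ins, row)

        ncols = len(_ATOM_COLUMNS) + len(feature_definition)
        ins = ("INSERT INTO atomic_property VALUES ("
               + ",".join("?" * ncols) + ")")
        for arec in atom_records:
            row = [
                arec.pdb_id, arec.chain_index, arec.residue_index,
                arec.residue_type, arec.atom_name,
                arec.force_field_atom_type, arec.super_class,
                arec.experimental_shift, arec.original_residue_index,
            ]
            for name in feature_definition:
                v = arec.features[name]
                row.append(None if _is_missing(v) else v)
            con.execute(ins, row)
        con.commit()
    finally:
        con.close()


def read_store(path: str | Path) -> tuple[
        list[ChainMappingRecord], list[AtomShiftRecord], FeatureDefinition]:
    """Read the store back into value-identical records."""
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(path)
    con = sqlite3.connect(path)
    try:
        map_info = con.execute("PRAGMA table_info(chain_mapping)").fetchall()
        flag_names = [r[1][5:] for r in map_info
                      if r[1].startswith("flag:")]
        mapping_records = []
        cur = con.execute("SELECT * FROM chain_mapping")
        cols = [d[0] for d in cur.description]
        for row in cur:
            d = dict(zip(cols, row))
            mapping_records.append(ChainMappingRecord(
                pdb_id=d["pdb_id"], chain_index=d["chain_index"],
                original_chain_id=d["original_chain_id"],
                bmrb_id=d["bmrb_id"],
                alignment_identity=d["alignment_identity"],
                has_h_shifts=bool(d["has_h_shifts"]),
                has_c_shifts=bool(d["has_c_shifts"]),
                has_n_shifts=bool(d["has_n_shifts"]),
                temperature=d["temperature"], ph=d["ph"],
                pressure=d["pressure"], solvent=d["solvent"],
                spectrometer=d["spectrometer"],
                filter_flags={n: bool(d["flag:" + n]) for n in flag_names},
            ))

        atom_info = con.execute("PRAGMA table_info(atomic_property)").fetchall()
        feat_cols = [(r[1][5:], r[2]) for r in atom_info
                     if r[1].startswith("feat:")]
        kinds = {n: ("numeric" if t.upper() == "REAL" else "categorical")
                 for n, t in feat_cols}
        definition = FeatureDefinition([n for n, _ in feat_cols], kinds)
        atom_records = []
        cur = con.execute("SELECT * FROM atomic_property")
        cols = [d[0] for d in cur.description]
        for row in cur:
            d = dict(zip(cols, row))
            feats = {}
            for name, _ in feat_cols:
                v = d["feat:" + name]
                feats[name] = MISSING if v is None else v
            atom_records.append(AtomShiftRecord(
                pdb_id=d["pdb_id"], chain_index=d["chain_index"],
                residue_index=d["residue_index"],
                residue_type=d["residue_type"], atom_name=d["atom_name"],
                force_field_atom_type=d["force_field_atom_type"] or "",
                super_class=d["super_class"],
                experimental_shift=d["experimental_shift"],
                original_residue_index=d["original_residue_index"],
                features=feats,
            ))
        return mapping_records, atom_records, definition
    finally:
        con.close()


def add_filter_column(path: str | Path, column_name: str,
                      values) -> None:
    """Add a named boolean filter column to the chain-mapping table.

    ``values`` is either a single boolean applied to every row or a mapping
    from ``(pdb_id, chain_index)`` to booleans (absent keys default False).
    Existing cells are never touched; a name collision raises
    :class:`ColumnCollisionError`.
    """
    con = sqlite3.connect(Path(path))
    try:
        info = con.execute("PRAGMA table_info(chain_mapping)").fetchall()
        existing = {r[1] for r in info}
        col = "flag:" + column_name
        if col in existing or column_name in existing:
            raise ColumnCollisionError(column_name)
        con.execute(
            f"ALTER TABLE chain_mapping ADD COLUMN {_q(col)} INTEGER"
        )
        rows = con.execute(
            "SELECT pdb_id, chain_index FROM chain_mapping").fetchall()
        for pdb_id, chain_index in rows:
            if isinstance(values, bool):
                v = values
            else:
                v = bool(values.get((pdb_id, chain_index), False))
            con.execute(
                f"UPDATE chain_mapping SET {_q(col)} = ? "
                "WHERE pdb_id = ? AND chain_index = ?",
                (int(v), pdb_id, chain_index),
            )
        con.commit()
    finally:
        con.close()


def _is_missing(v) -> bool:
    return v is None or (isinstance(v, str) and v == MISSING)


def _infer_definition(atom_records: list[AtomShiftRecord]
                      ) -> FeatureDefinition:
    names: list[str] = []
    kinds: dict[str, str] = {}
    for rec in atom_records:
        for name, v in rec.features.items():
            if name not in kinds:
                names.append(name)
                kinds[name] = "categorical"
            if isinstance(v, numbers.Number) and not isinstance(v, bool):
                kinds[name] = "numeric"
    return FeatureDefinition(names, kinds)
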