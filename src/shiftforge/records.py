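"""Domain record types shared by every pipeline stage."""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Any, Iterable

#: Sentinel stored for absent experimental-condition / feature values.
MISSING = "missing"


@dataclass
class ChainMappingRecord:
    """One PDB-chain <-> BMRB pairing with its experimental metadata.

    One row of the store's chain-mapping table.  ``filter_flags`` holds the
    named boolean filter columns; new columns may be added but existing ones
    are never silently dropped.
    """

    pdb_id: str
    chain_index: int
    original_chain_id: str
    bmrb_id: str
    alignment_identity: float
    has_h_shifts: bool = False
    has_c_shifts: bool = False
    has_n_shifts: bool = False
    temperature: float | None = None  # kelvin
    ph: float | None = None
    pressure: float | None = None  # atm
    solvent: str | None = None
    spectrometer: str | None = None
    filter_flags: dict[str, bool] = field(default_factory=dict)

    def __post_init__(self) -> None:
        if not 0.0 <= self.alignment_identity <= 100.0:
            raise ValueError(
                f"alignment_identity must be in [0, 100], got "
                f"{self.alignment_identity}"
            )

    @property
    def key(self) -> tuple[str, int]:
        return (self.pdb_id, self.chain_index)


@dataclass
class AtomShiftRecord:
    """One atom: identity, experimental shift (ppm) and feature values."""

    pdb_id: str
    chain_index: int
    residue_index: int  # 1-based in sequence order after re-indexing
    residue_type: str  # 3-letter code
    atom_name: str  # canonical PDB-v2 spelling
    force_field_atom_type: str = ""
    super_class: str | None = None
    experimental_shift: float = 0.0
    original_residue_index: int | None = None  # author numbering
    features: dict[str, Any] = field(default_factory=dict)

    def __post_init__(self) -> None:
        if not math.isfinite(self.experimental_shift):
            raise ValueError(
                f"experimental shift must be finite, got "
                f"{self.experimental_shift} for {self.key}"
            )

    @property
    def key(self) -> tuple[str, int, int, str]:
        return (self.pdb_id, self.chain_index, self.residue_index,
                self.atom_name)


class FeatureDefinition:
    """Ordered set of feature names with their value kinds.

    Mirrors the plain-text feature-definition file: one name per line,
    ``#`` comments out a feature.
    """

    def __init__(self, names: Iterable[str], kinds: dict[str, str]):
        self.names = list(names)
        if len(set(self.names)) != len(self.names):
            dupes = {n for n in self.names if self.names.count(n) > 1}
            raise ValueError(f"duplicate feature names: {sorted(dupes)}")
        self.kinds = dict(kinds)
        unknown = [n for n in self.names if n not in self.kinds]
        if unknown:
            raise ValueError(f"features without a value kind: {unknown}")
        bad = {k: v for k, v in self.kinds.items()
               if v not in ("numeric", "categorical")}
        if bad:
            raise ValueError(f"invalid value kinds: {bad}")

    def __iter__(self):
        return iter(self.names)

    def __len__(self) -> int:
        return len(self.names)

    def __contains__(self, name: str) -> bool:
        return name in self.names

    def __eq__(self, other: object) -> bool:
        return (
            isinstance(other, FeatureDefinition)
            and self.names == other.names
            and {n: self.kinds[n] for n in self.names}
            == {n: other.kinds[n] for n in other.names}
        )

    @classmethod
    def from_text(cls, text: str, kinds: dict[str, str]) -> "FeatureDefinition":
        """Parse the feature-definition file format."""
        names = []
        for line in text.splitlines():
            line = line.strip()
            if not line or line.startswith("#"):
                continue
            names.append(line.split()[0])
        return cls(names, {n: kinds[n] for n in names})

    def to_text(self) -> str:
        return "\n".join(self.names) + "\n"


TRAIN, TEST, UNASSIGNED = "train", "test", "unassigned"


@dataclass
class Dataset:
    """Atom records plus a train/test partition and provenance."""

    records: list[AtomShiftRecord]
    partition: dict[tuple, str] = field(default_factory=dict)
    provenance: dict[str, Any] = field(default_factory=dict)

    def __post_init__(self) -> None:
        if not self.partition:
            self.partition = {r.key: UNASSIGNED for r in self.records}

    def subset(self, label: str) -> list[AtomShiftRecord]:
        return [r for r in self.records if self.partition[r.key] == label]

    @property
    def train_records(self) -> list[AtomShiftRecord]:
        return self.subset(TRAIN)

    @property
    def test_records(self) -> list[AtomShiftRecord]:
        return self.subset(TEST)

    def check_partition(self) -> None:
        labels = {self.partition[r.key] for r in self.records}
        if not labels <= {TRAIN, TEST, UNASSIGNED}:
            raise ValueError(f"bad partition labels: {labels}")
        missing = [r.key for r in self.records if r.key not in self.partition]
        if missing:
            raise ValueError(f"records without partition label: {missing[:5]}")


@dataclass
class PredictionRecord:
    """One predicted per-atom chemical shift."""

    pdb_id: str
    chain_index: int
    residue_index: int
    residue_type: str
    atom_name: str
    super_class: str
    predicted_shift: float

    def __post_init__(self) -> None:
        if not math.isfinite(self.predicted_shift):
            raise ValueError(f"predicted shift not finite for {self}")
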