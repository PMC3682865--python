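"""String-keyed feature registry and per-structure feature computation.

Every feature the training table can contain is registered under a plain
string name; a :class:`~shiftforge.records.FeatureDefinition` (usually read
from the feature-definition file) selects which ones to compute.  Features
either return a numeric value, a category string, or the package-wide
``MISSING`` marker — never an absent key.

A :class:`FeatureContext` caches per-structure quantities (rings, surface
areas, hydrogen bonds, secondary structure, torsions) so per-atom lookups
stay cheap and, being pure functions of coordinates, bit-reproducible.
"""

from __future__ import annotations

from typing import Callable

from .. import residues
from ..records import MISSING, ChainMappingRecord, FeatureDefinition
from ..structure import Atom, ProteinStructure
from . import geometry, semiclassical
from .semiclassical import (
    DEFAULT_PARAMS,
    SemiClassicalParams,
    electric_field_shift,
    hbond_effect_shift,
    random_coil_shift,
    ring_current_shift,
)

__all__ = [
    "FeatureContext", "feature_registry", "register_feature",
    "resolve_features", "compute_features", "default_feature_definition",
    "DEFAULT_PARAMS", "SemiClassicalParams", "random_coil_shift",
    "ring_current_shift", "electric_field_shift", "hbond_effect_shift",
]


class FeatureContext:
    """Lazy per-structure caches shared by all feature computers."""

    def __init__(
        self,
        structure: ProteinStructure,
        mapping_records: dict[int, ChainMappingRecord] | None = None,
        params: SemiClassicalParams = DEFAULT_PARAMS,
    ):
        self.structure = structure
        self.mapping_records = mapping_records or {}
        self.params = params
        self._rings = None
        self._sasa = None
        self._hbonds = None
        self._torsions: dict[tuple[int, int], dict] = {}
        self._bb_dists: dict[tuple[int, int], dict] = {}
        self._ss: dict[int, list[str]] = {}
        self._energy = None

    @property
    def rings(self):
        if self._rings is None:
            self._rings = semiclassical.rings_of_structure(self.structure)
        return self._rings

    def sasa(self):
        if self._sasa is None:
            self._sasa = geometry.solvent_accessible_surface(self.structure)
        return self._sasa

    def hbonds(self):
        if self._hbonds is None:
            hb, ss = geometry.detect_hbonds_and_disulfides(self.structure)
            h_atoms = {i for i, _ in hb} | {j for _, j in hb}
            ss_atoms = {i for pair in ss for i in pair}
            self._hbonds = (h_atoms, ss_atoms)
        return self._hbonds

    def chain_of(self, atom: Atom):
        return atom.residue.chain

    def position_of(self, atom: Atom) -> int:
        return atom.residue.index - 1  # residues are 1-based in sequence

    def torsions(self, atom: Atom) -> dict:
        chain = self.chain_of(atom)
        key = (chain.index, atom.residue.index)
        if key not in self._torsions:
            self._torsions[key] = geometry.torsion_angles(
                chain, self.position_of(atom))
        return self._torsions[key]

    def backbone_distances(self, atom: Atom) -> dict:
        chain = self.chain_of(atom)
        key = (chain.index, atom.residue.index)
        if key not in self._bb_dists:
            self._bb_dists[key] = geometry.explicit_backbone_distances(
                chain, self.position_of(atom))
        return self._bb_dists[key]

    def secondary_structure(self, atom: Atom) -> str:
        chain = self.chain_of(atom)
        if chain.index not in self._ss:
            self._ss[chain.index] = geometry.secondary_structure(chain)
        return self._ss[chain.index][self.position_of(atom)]

    def structure_energy(self) -> float:
        if self._energy is None:
            from ..mapping import nonbonded_pseudo_energy

            self._energy = nonbonded_pseudo_energy(self.structure)
        return self._energy

    def mapping_record(self, atom: Atom) -> ChainMappingRecord | None:
        return self.mapping_records.get(self.chain_of(atom).index)


# ---------------------------------------------------------------------------
# registry

_REGISTRY: dict[str, tuple[Callable[[Atom, FeatureContext], object], str]] = {}


class FeatureConfigurationError(ValueError):
    pass


def register_feature(name: str, fn: Callable, kind: str,
                     replace: bool = False) -> None:
    """Register a feature computer under a string name."""
    if kind not in ("numeric", "categorical"):
        raise ValueError(f"kind must be numeric|categorical, got {kind!r}")
    if name in _REGISTRY and not replace:
        raise FeatureConfigurationError(
            f"feature already registered: {name!r}")
    _REGISTRY[name] = (fn, kind)


def feature_registry() -> dict[str, tuple[Callable, str]]:
    """The active name -> (computer, kind) mapping (a copy)."""
    return dict(_REGISTRY)


def resolve_features(names) -> FeatureDefinition:
    """Validate names against the registry; unknown names are rejected."""
    unknown = [n for n in names if n not in _REGISTRY]
    if unknown:
        raise FeatureConfigurationError(
            f"unknown feature name(s): {unknown}; "
            f"registered: {sorted(_REGISTRY)}"
        )
    return FeatureDefinition(list(names),
                             {n: _REGISTRY[n][1] for n in names})


def compute_features(atom: Atom, ctx: FeatureContext,
                     definition: FeatureDefinition) -> dict[str, object]:
    """All requested feature values for one atom; complete by construction."""
    out = {}
    for name in definition:
        fn, _ = _REGISTRY[name]
        out[name] = fn(atom, ctx)
    return out


# ---------------------------------------------------------------------------
# built-in features


def _feature(name: str, kind: str):
    def deco(fn):
        register_feature(name, fn, kind)
        return fn
    return deco


@_feature("res_type", "categorical")
def _res_type(atom, ctx):
    return atom.residue.name


@_feature("prev_res_type", "categorical")
def _prev_res_type(atom, ctx):
    chain = ctx.chain_of(atom)
    pos = ctx.position_of(atom)
    return chain.residues[pos - 1].name if pos > 0 else "NTER"


@_feature("next_res_type", "categorical")
def _next_res_type(atom, ctx):
    chain = ctx.chain_of(atom)
    pos = ctx.position_of(atom)
    return (chain.residues[pos + 1].name
            if pos + 1 < len(chain.residues) else "CTER")


@_feature("sequence_length", "numeric")
def _sequence_length(atom, ctx):
    return float(len(ctx.chain_of(atom).residues))


@_feature("alignment_score", "numeric")
def _alignment_score(atom, ctx):
    rec = ctx.mapping_record(atom)
    return rec.alignment_identity if rec is not None else MISSING


@_feature("phi", "numeric")
def _phi(atom, ctx):
    return ctx.torsions(atom)["phi"]


@_feature("psi", "numeric")
def _psi(atom, ctx):
    return ctx.torsions(atom)["psi"]


@_feature("chi1", "numeric")
def _chi1(atom, ctx):
    return ctx.torsions(atom)["chi1"]


@_feature("secondary_structure", "categorical")
def _secondary_structure(atom, ctx):
    return ctx.secondary_structure(atom)


def _bb(name):
    @_feature(name, "numeric")
    def _dist(atom, ctx, _name=name):
        return ctx.backbone_distances(atom)[_name]
    return _dist


for _n in ("d_n_ca", "d_ca_c", "d_c_o", "d_c_n_next",
           "d_ca_ca_prev", "d_ca_ca_next"):
    _bb(_n)


@_feature("atom_sas", "numeric")
def _atom_sas(atom, ctx):
    areas, _ = ctx.sasa()
    return float(areas[atom.index])


@_feature("residue_sas", "numeric")
def _residue_sas(atom, ctx):
    _, per_res = ctx.sasa()
    return float(per_res[(ctx.chain_of(atom).index, atom.residue.index)])


@_feature("atomic_density", "numeric")
def _atomic_density(atom, ctx):
    return float(geometry.atomic_density(ctx.structure, atom))


@_feature("hbonded", "numeric")
def _hbonded(atom, ctx):
    h_atoms, _ = ctx.hbonds()
    return 1.0 if atom.index in h_atoms else 0.0


@_feature("disulfide_bonded", "numeric")
def _disulfide(atom, ctx):
    _, ss_atoms = ctx.hbonds()
    return 1.0 if atom.index in ss_atoms else 0.0


@_feature("ff_atom_type", "categorical")
def _ff_atom_type(atom, ctx):
    try:
        return residues.force_field_atom_type(atom.residue.name, atom.name)
    except (KeyError, ValueError):
        return "UNK"


@_feature("structure_energy", "numeric")
def _structure_energy(atom, ctx):
    return float(ctx.structure_energy())


def _condition(name, attr, kind):
    @_feature(name, kind)
    def _cond(atom, ctx, _attr=attr):
        rec = ctx.mapping_record(atom)
        if rec is None:
            return MISSING
        v = getattr(rec, _attr)
        if isinstance(v, bool):
            return 1.0 if v else 0.0
        return v if v is not None else MISSING
    return _cond


for _n, _a, _k in (
    ("has_h_shifts", "has_h_shifts", "numeric"),
    ("has_c_shifts", "has_c_shifts", "numeric"),
    ("has_n_shifts", "has_n_shifts", "numeric"),
    ("temperature", "temperature", "numeric"),
    ("ph", "ph", "numeric"),
    ("pressure", "pressure", "numeric"),
    ("solvent", "solvent", "categorical"),
    ("spectrometer", "spectrometer", "categorical"),
):
    _condition(_n, _a, _k)


@_feature("random_coil", "numeric")
def _random_coil(atom, ctx):
    table = ctx.params.random_coil_table
    key = (atom.residue.name, atom.name)
    return table[key] if key in table else MISSING


@_feature("ring_current", "numeric")
def _ring_current(atom, ctx):
    # the atom's own residue's ring is excluded: ring members sit closer to
    # the centroid than the point-dipole form is valid for
    own = (atom.residue.chain.index, atom.residue.index)
    rings = [r for r in ctx.rings if r.residue_key != own]
    return ring_current_shift(atom.pos, rings, ctx.params)


@_feature("electric_field", "numeric")
def _electric_field(atom, ctx):
    try:
        return electric_field_shift(atom, ctx.structure, ctx.params)
    except semiclassical.UnbondedTargetError:
        return MISSING


@_feature("hbond_effect", "numeric")
def _hbond_effect(atom, ctx):
    if atom.element != "H" or not ctx.structure.bonds()[atom.index]:
        return MISSING
    return hbond_effect_shift(atom, ctx.structure, ctx.params)


DEFAULT_FEATURE_NAMES = [
    "res_type", "prev_res_type", "next_res_type",
    "sequence_length", "alignment_score",
    "phi", "psi", "chi1", "secondary_structure",
    "d_n_ca", "d_ca_c", "d_c_o", "d_c_n_next",
    "d_ca_ca_prev", "d_ca_ca_next",
    "atom_sas", "residue_sas", "atomic_density",
    "hbonded", "disulfide_bonded",
    "ff_atom_type", "structure_energy",
    "has_h_shifts", "has_c_shifts", "has_n_shifts",
    "temperature", "ph", "pressure", "solvent", "spectrometer",
    "random_coil", "ring_current", "electric_field", "hbond_effect",
]


def default_feature_definition() -> FeatureDefinition:
    return resolve_features(DEFAULT_FEATURE_NAMES)
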