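"""Atom super classes: the partition of atom names into model classes.

One regression model is trained per super class — an intermediate between
a single global model and one model per force-field atom type.  The
default scheme has exactly 10 classes (backbone N, CA, CB, C, amide H,
then HA/HB/HD/HG and the remaining-hydrogens class HEHZ), each defined by
an explicit atom-name vocabulary in the historical PDB-v2-flavoured
spelling; both dialect spellings of each listed atom are accepted and
normalized before lookup.  A scheme can also be auto-generated from the
data by clustering force-field atom types into classes of comparable size.
"""

from __future__ import annotations

from dataclasses import dataclass, field

from . import nomenclature, residues

# Default 10-class scheme.  The vocabularies are the published name lists
# (mixed v2/v3 dialect, as deposited); names not listed anywhere (e.g. O,
# side-chain carbons beyond CB, 3HB) belong to no class.
DEFAULT_CLASSES: dict[str, tuple[str, ...]] = {
    "N": ("N",),
    "CA": ("CA",),
    "CB": ("CB",),
    "C": ("C",),
    "H": ("H",),
    "HA": ("HA", "1HA", "2HA"),
    "HB": ("HB", "1HB", "2HB"),
    "HD": ("2HD", "HD1", "HD2", "1HD1", "1HD2", "2HD2"),
    "HG": ("HG", "1HG1", "1HG2", "2HG", "2HG1", "HG1"),
    "HEHZ": ("HE", "HE1", "HE2", "HE3", "2HE", "1HE", "1HE2", "2HE2",
             "HH2", "HZ", "1HZ", "HZ2", "HZ3"),
}

CLASS_ORDER = tuple(DEFAULT_CLASSES)


@dataclass
class SuperClassScheme:
    """Ordered class labels with per-class atom-name sets."""

    classes: dict[str, tuple[str, ...]]
    provenance: str = "default"  # default | user | auto
    _lookup: dict[str, str] = field(init=False, repr=False)

    def __post_init__(self) -> None:
        self._lookup = {}
        for label, names in self.classes.items():
            for name in names:
                if name in self._lookup:
                    raise ValueError(
                        f"atom name {name!r} in both "
                        f"{self._lookup[name]!r} and {label!r}"
                    )
                self._lookup[name] = label

    @property
    def labels(self) -> list[str]:
        return list(self.classes)

    def assign(self, atom_name: str, residue_type: str | None = None
               ) -> str | None:
        """Class label for an atom name, or None if unlisted.

        Accepts either dialect spelling: the raw name is tried first, then
        (when the residue type is known) its counterpart in the other
        dialect.
        """
        name = atom_name.upper()
        if name == "HN":
            name = "H"
        if name in self._lookup:
            return self._lookup[name]
        if residue_type and residue_type in residues.STANDARD_RESIDUES:
            for variant in nomenclature.dialect_variants(residue_type, name):
                if variant in self._lookup:
                    return self._lookup[variant]
        return None

    def to_text(self) -> str:
        lines = [f"{label}: {', '.join(names)}"
                 for label, names in self.classes.items()]
        return "\n".join(lines) + "\n"

    @classmethod
    def from_text(cls, text: str, provenance: str = "user"
                  ) -> "SuperClassScheme":
        classes: dict[str, tuple[str, ...]] = {}
        for line in text.splitlines():
            line = line.strip()
            if not line or line.startswith("#"):
                continue
            label, _, rest = line.partition(":")
            names = tuple(n.strip().upper() for n in rest.split(",")
                          if n.strip())
            classes[label.strip()] = names
        return cls(classes, provenance=provenance)


def default_scheme() -> SuperClassScheme:
    return SuperClassScheme(dict(DEFAULT_CLASSES), provenance="default")


def assign_super_class(atom_name: str, residue_type: str | None = None,
                       scheme: SuperClassScheme | None = None
                       ) -> str | None:
    """Assign an atom name to its super class (None when unlisted)."""
    return (scheme or default_scheme()).assign(atom_name, residue_type)


def auto_cluster_dataset(records, n_classes: int,
                         max_size_ratio: float = 4.0) -> SuperClassScheme:
    """Auto-generate a scheme from the force-field types of a record set.

    For auto schemes, :meth:`SuperClassScheme.assign` is keyed by the
    force-field atom type rather than the atom name.
    """
    counts: dict[str, int] = {}
    for r in records:
        t = r.force_field_atom_type
        if t:
            counts[t] = counts.get(t, 0) + 1
    return auto_cluster(counts, n_classes, max_size_ratio)


def auto_cluster(
    type_counts: dict[str, int],
    n_classes: int,
    max_size_ratio: float = 4.0,
) -> SuperClassScheme:
    """Cluster force-field atom types into classes of comparable size.

    ``type_counts`` maps a force-field atom type to its shift count in the
    dataset.  Types are segregated by element (H, C and N are never mixed)
    and greedily merged — each type, visited largest-first, joins the
    smallest open class of its element, a rare type thereby merging into an
    abundant neighbour rather than standing alone.  Class slots are spread
    over the elements proportionally to their shift counts, and the merge
    aims at per-class sizes within a factor ``max_size_ratio``.
    Deterministic given the input.
    """
    if n_classes < 1:
        raise ValueError("n_classes must be >= 1")
    if len(type_counts) < n_classes:
        raise ValueError(
            f"cannot form {n_classes} classes from "
            f"{len(type_counts)} atom types"
        )
    by_element: dict[str, dict[str, int]] = {}
    for t, c in type_counts.items():
        el = "H" if t.upper().startswith("H") else t[0].upper()
        by_element.setdefault(el, {})[t] = c

    # distribute class slots over elements by shift mass, at least one
    # (and at most the number of types) per element present
    totals = {el: sum(d.values()) for el, d in by_element.items()}
    grand = sum(totals.values()) or 1
    slots = {el: 1 for el in by_element}
    remaining = n_classes - len(slots)
    if remaining < 0:
        raise ValueError(
            f"{n_classes} classes but {len(by_element)} elements present"
        )
    quota = sorted(
        by_element,
        key=lambda el: (-totals[el] / grand, el),
    )
    k = 0
    while remaining > 0:
        el = quota[k % len(quota)]
        if slots[el] < len(by_element[el]):
            slots[el] += 1
            remaining -= 1
        k += 1
        if k > 10 * n_classes:  # all elements saturated
            raise ValueError("not enough atom types for requested classes")

    classes: dict[str, tuple[str, ...]] = {}
    for el in sorted(by_element):
        d = by_element[el]
        n_cl = slots[el]
        bins: list[list[str]] = [[] for _ in range(n_cl)]
        sizes = [0] * n_cl
        for t in sorted(d, key=lambda t: (-d[t], t)):
            j = min(range(n_cl), key=lambda j: (sizes[j], j))
            bins[j].append(t)
            sizes[j] += d[t]
        for j, members in enumerate(bins):
            label = f"{el}{j + 1}" if n_cl > 1 else el
            classes[label] = tuple(sorted(members))
    return SuperClassScheme(classes, provenance="auto")
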