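"""Fault-tolerant reader for NMRStar 2.1 and 3.1 chemical-shift files.

Deposited shift files are notoriously messy: stray tokens inside loops,
duplicated frames, non-numeric shift values, mixed naming dialects.  The
reader tokenizes the STAR grammar (quoted strings, ``;`` text blocks,
comments), locates every assigned-chemical-shift loop, and re-synchronizes
on malformed rows instead of aborting: recoverable anomalies are skipped
and counted per category in a :class:`ParseReport`, and every shift row
that is recovered parses exactly as it would from a clean file.  Only a
missing shift loop or an unreadable file is fatal.
"""

from __future__ import annotations

import math
import os
import re
from dataclasses import dataclass, field

MISSING_TOKENS = {".", "?", ""}


@dataclass
class ShiftEntry:
    """One assigned chemical shift from an NMRStar loop."""

    seq_code: int  # residue index as deposited
    residue_type: str  # 3-letter code
    atom_name: str  # NMRStar spelling
    shift: float  # ppm
    ambiguity: int | None = None

    def __post_init__(self) -> None:
        if not self.atom_name:
            raise ValueError("empty atom name in shift entry")
        if not math.isfinite(self.shift):
            raise ValueError(f"non-finite shift for {self.atom_name}")


@dataclass
class ShiftList:
    """Shift entries of one entity (chain), in deposition order."""

    entity_id: int
    entries: list[ShiftEntry] = field(default_factory=list)

    def sequence(self) -> str:
        """One-letter sequence implied by the shift rows ('X' for gaps)."""
        from .residues import THREE_TO_ONE

        if not self.entries:
            return ""
        by_seq: dict[int, str] = {}
        for e in self.entries:
            by_seq.setdefault(e.seq_code, e.residue_type)
        lo, hi = min(by_seq), max(by_seq)
        return "".join(
            THREE_TO_ONE.get(by_seq.get(i, "UNK"), "X")
            for i in range(lo, hi + 1)
        )

    @property
    def first_seq_code(self) -> int:
        return min(e.seq_code for e in self.entries)


@dataclass
class ExperimentalConditions:
    temperature: float | None = None  # kelvin
    ph: float | None = None
    pressure: float | None = None  # atm
    solvent: str | None = None
    spectrometer: str | None = None


@dataclass
class ParseReport:
    """Per-category counts of anomalies recovered while parsing."""

    anomalies: dict[str, int] = field(default_factory=dict)
    fatal: bool = False
    messages: list[str] = field(default_factory=list)

    def count(self, category: str, n: int = 1) -> None:
        self.anomalies[category] = self.anomalies.get(category, 0) + n

    @property
    def total_anomalies(self) -> int:
        return sum(self.anomalies.values())


class NMRStarError(ValueError):
    """Fatal parse failure; carries the report accumulated so far."""

    def __init__(self, message: str, report: ParseReport | None = None):
        super().__init__(message)
        self.report = report or ParseReport(messages=[message])
        self.report.fatal = True


# ---------------------------------------------------------------------------
# tokenizer


def _tokenize(text: str, report: ParseReport) -> list[tuple[str, int]]:
    """STAR tokenizer preserving line numbers.

    Handles quoted strings, ``;``-delimited text blocks and ``#`` comments.
    """
    tokens: list[tuple[str, int]] = []
    lines = text.splitlines()
    i = 0
    while i < len(lines):
        line = lines[i]
        if line.startswith(";"):
            start = i
            block = [line[1:]]
            i += 1
            while i < len(lines) and not lines[i].startswith(";"):
                block.append(lines[i])
                i += 1
            if i >= len(lines):
                report.count("unterminated_text_block")
            tokens.append(("\n".join(block).strip(), start))
            i += 1
            continue
        j = 0
        n = len(line)
        while j < n:
            c = line[j]
            if c in " \t":
                j += 1
                continue
            if c == "#":
                break
            if c in "'\"":
                quote = c
                k = j + 1
                buf = []
                while k < n:
                    if line[k] == quote and (k + 1 == n or
                                             line[k + 1] in " \t"):
                        break
                    buf.append(line[k])
                    k += 1
                if k >= n and (not buf or line[-1] != quote):
                    report.count("unterminated_quote")
                tokens.append(("".join(buf), i))
                j = k + 1
            else:
                k = j
                while k < n and line[k] not in " \t":
                    k += 1
                tokens.append((line[j:k], i))
                j = k
        i += 1
    return tokens


# tag names marking a chemical-shift loop, per dialect
_VALUE_TAGS = {"_chem_shift_value", "_atom_chem_shift.val"}
_SEQ_TAGS = {"_residue_seq_code", "_atom_chem_shift.seq_id",
             "_atom_chem_shift.comp_index_id"}
_COMP_TAGS = {"_residue_label", "_atom_chem_shift.comp_id"}
_ATOM_TAGS = {"_atom_name", "_atom_chem_shift.atom_id"}
_AMBIG_TAGS = {"_chem_shift_ambiguity_code",
               "_atom_chem_shift.ambiguity_code"}
_ENTITY_TAGS = {"_atom_chem_shift.entity_assembly_id",
                "_atom_chem_shift.entity_id"}

_RESIDUE_RE = re.compile(r"^[A-Z][A-Z0-9]{0,3}$", re.IGNORECASE)
_ATOM_RE = re.compile(r"^[0-9]?[A-Z][A-Z0-9'*]{0,4}$", re.IGNORECASE)


def _is_float(tok: str) -> bool:
    try:
        float(tok)
        return True
    except ValueError:
        return False


def _is_int(tok: str) -> bool:
    try:
        int(tok)
        return True
    except ValueError:
        return False


def parse_nmrstar(source: str) -> tuple[
        list[ShiftList], ExperimentalConditions, ParseReport]:
    """Parse an NMRStar 2.1 or 3.1 file (path or text).

    Returns shift lists grouped by entity, the experimental conditions
    found (absent fields None), and the anomaly report.  Raises
    :class:`NMRStarError` when no shift loop can be recovered.
    """
    if "\n" not in source and os.path.exists(source):
        try:
            with open(source, encoding="utf-8", errors="replace") as fh:
                text = fh.read()
        except OSError as exc:
            raise NMRStarError(f"cannot read {source}: {exc}") from exc
    else:
        text = source

    report = ParseReport()
    tokens = _tokenize(text, report)
    if not tokens:
        raise NMRStarError("empty NMRStar input", report)

    free_tags: dict[str, str] = {}
    loops: list[tuple[list[str], list[tuple[str, int]]]] = []
    seen_frames: set[str] = set()

    i = 0
    n = len(tokens)
    while i < n:
        tok, _ = tokens[i]
        low = tok.lower()
        if low.startswith("data_") or low.startswith("global_"):
            i += 1
            continue
        if low.startswith("save_"):
            name = low[5:]
            if name:
                if name in seen_frames:
                    report.count("duplicate_frame_name")
                seen_frames.add(name)
            i += 1
            continue
        if low == "loop_":
            i += 1
            tags: list[str] = []
            while i < n and tokens[i][0].startswith("_"):
                tags.append(tokens[i][0])
                i += 1
            data: list[tuple[str, int]] = []
            while i < n:
                t, ln = tokens[i]
                tl = t.lower()
                if tl == "stop_":
                    i += 1
                    break
                if tl == "loop_" or tl.startswith("save_") or \
                        tl.startswith("data_") or t.startswith("_"):
                    report.count("unterminated_loop")
                    break
                data.append((t, ln))
                i += 1
            loops.append((tags, data))
            continue
        if tok.startswith("_"):
            nxt = tokens[i + 1][0] if i + 1 < n else None
            if nxt is not None and not nxt.startswith("_") and \
                    nxt.lower() not in ("loop_", "stop_") and \
                    not nxt.lower().startswith("save_"):
                free_tags[low] = nxt
                i += 2
            else:
                free_tags[low] = ""
                i += 1
            continue
        report.count("stray_token")
        i += 1

    shift_lists = _extract_shift_lists(loops, report)
    if not any(sl.entries for sl in shift_lists):
        raise NMRStarError("no chemical-shift loop found", report)
    conditions = _extract_conditions(loops, free_tags)
    return shift_lists, conditions, report


def _extract_shift_lists(loops, report: ParseReport) -> list[ShiftList]:
    lists: dict[int, ShiftList] = {}
    seen_keys: set[tuple] = set()
    seen_loops: set[tuple] = set()
    implicit_entity = 0
    for tags, data in loops:
        low = [t.lower() for t in tags]
        if not set(low) & _VALUE_TAGS:
            continue
        fingerprint = (tuple(low), tuple(t for t, _ in data))
        if fingerprint in seen_loops:
            # an entire shift frame deposited twice: keep the first copy
            report.count("duplicate_frame")
            continue
        seen_loops.add(fingerprint)
        ncols = len(tags)

        def col(tagset) -> int | None:
            for k, t in enumerate(low):
                if t in tagset:
                    return k
            return None

        cols = {
            "val": col(_VALUE_TAGS),
            "seq": col(_SEQ_TAGS),
            "comp": col(_COMP_TAGS),
            "atom": col(_ATOM_TAGS),
            "amb": col(_AMBIG_TAGS),
            "ent": col(_ENTITY_TAGS),
        }
        if cols["seq"] is None or cols["comp"] is None or \
                cols["atom"] is None:
            report.count("unusable_shift_loop")
            report.messages.append(
                "shift loop lacks residue/atom columns; skipped")
            continue

        implicit_entity += 1
        n_rows, n_dupes = _consume_loop(
            data, ncols, cols, implicit_entity, lists, seen_keys, report)
        if n_rows == 0 and n_dupes > 0:
            report.count("duplicate_frame")
    return [lists[k] for k in sorted(lists)]


def _consume_loop(data, ncols, cols, implicit_entity, lists, seen_keys,
                  report) -> tuple[int, int]:
    """Row-wise consumption of one shift loop with re-synchronization.

    Rows are line-oriented; a buffer absorbs wrapped rows.  A buffer longer
    than one row is first tried as-is and then with every single-token
    deletion, which recovers rows broken by one stray token exactly.
    """
    n_rows = n_dupes = 0

    def shape_ok(row: list[str]) -> bool:
        if not _is_int(row[cols["seq"]]):
            return False
        if not _RESIDUE_RE.match(row[cols["comp"]] or ""):
            return False
        if not _ATOM_RE.match(row[cols["atom"]] or ""):
            return False
        return True

    def value_ok(row: list[str]) -> bool:
        v = row[cols["val"]]
        return v in MISSING_TOKENS or _is_float(v)

    def emit(row: list[str]) -> None:
        nonlocal n_rows, n_dupes
        val_tok = row[cols["val"]]
        if val_tok in MISSING_TOKENS:
            report.count("missing_shift_value")
            return
        if not _is_float(val_tok):
            report.count("nonnumeric_shift")
            return
        ent_id = implicit_entity
        if cols["ent"] is not None and _is_int(row[cols["ent"]]):
            ent_id = int(row[cols["ent"]])
        key = (ent_id, int(row[cols["seq"]]), row[cols["atom"]].upper())
        if key in seen_keys:
            n_dupes += 1
            report.count("duplicate_row")
            return
        seen_keys.add(key)
        amb = None
        if cols["amb"] is not None and _is_int(row[cols["amb"]]):
            amb = int(row[cols["amb"]])
        entry = ShiftEntry(
            seq_code=int(row[cols["seq"]]),
            residue_type=row[cols["comp"]].upper(),
            atom_name=row[cols["atom"]].upper(),
            shift=float(val_tok),
            ambiguity=amb,
        )
        lists.setdefault(ent_id, ShiftList(entity_id=ent_id))
        lists[ent_id].entries.append(entry)
        n_rows += 1

    # group data tokens into lines
    line_groups: list[list[str]] = []
    last_ln = None
    for tok, ln in data:
        if ln != last_ln:
            line_groups.append([])
            last_ln = ln
        line_groups[-1].append(tok)

    buffer: list[str] = []
    for group in line_groups:
        buffer.extend(group)
        while len(buffer) >= ncols:
            row = buffer[:ncols]
            if shape_ok(row) and (len(buffer) == ncols or value_ok(row)):
                # a full-width row whose value column fails to parse is
                # still consumed as a row (nonnumeric shift), not re-synced
                emit(row)
                del buffer[:ncols]
                continue
            if len(buffer) == ncols:
                if shape_ok(row):
                    emit(row)  # counts the bad value
                    del buffer[:ncols]
                    continue
                break  # wait for more tokens (wrapped/broken row)
            recovered = False
            for drop in range(ncols + 1):
                cand = buffer[:drop] + buffer[drop + 1:ncols + 1]
                if shape_ok(cand) and value_ok(cand):
                    report.count("stray_token")
                    emit(cand)
                    del buffer[:ncols + 1]
                    recovered = True
                    break
            if not recovered:
                report.count("stray_token")
                del buffer[0]
    if buffer:
        # trailing fragment: either a final broken row or stray residue
        if len(buffer) < ncols and shape_ok(
                buffer + [""] * (ncols - len(buffer))):
            report.count("truncated_row")
        else:
            report.count("stray_token", len(buffer))
    return n_rows, n_dupes


_CONDITION_NAMES = {
    "temperature": "temperature",
    "temp": "temperature",
    "ph": "ph",
    "ph*": "ph",
    "pressure": "pressure",
}


def _extract_conditions(loops, free_tags) -> ExperimentalConditions:
    cond = ExperimentalConditions()
    for tags, data in loops:
        low = [t.lower() for t in tags]
        type_col = val_col = None
        for k, t in enumerate(low):
            if t in ("_variable_type", "_sample_condition_variable.type"):
                type_col = k
            if t in ("_variable_value", "_sample_condition_variable.val"):
                val_col = k
        if type_col is None or val_col is None:
            continue
        ncols = len(tags)
        toks = [t for t, _ in data]
        for p in range(0, len(toks) - ncols + 1, ncols):
            row = toks[p:p + ncols]
            name = _CONDITION_NAMES.get(row[type_col].strip().lower())
            if name and _is_float(row[val_col]):
                setattr(cond, name, float(row[val_col]))
    for tag in ("_solvent_system", "_sample.solvent_system"):
        if free_tags.get(tag) not in (None, "", ".", "?"):
            cond.solvent = free_tags[tag]
            break
    for tag in ("_spectrometer_model", "_nmr_spectrometer.model",
                "_nmr_spectrometer.manufacturer"):
        if free_tags.get(tag) not in (None, "", ".", "?"):
            cond.spectrometer = free_tags[tag]
            break
    return cond
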