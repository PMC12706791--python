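"""Data model, validation and I/O for pyranoxanthone ¹³C shift assignments.

The package works on tabular ¹³C chemical-shift assignments: each compound is
a set of (carbon label, shift in ppm, carbon class) records, tagged as either
experimental (literature data) or calculated (GIAO/DFT output after Boltzmann
averaging).  Structures themselves are represented only by *subtype codes* —
the type letter A–D (prenylation at C-1…C-4 of the xanthone core) followed by
two digits (the xanthone carbon bonded to the pyran oxygen; the position of an
additional oxygenated substituent, 0 if none).  Compounds bearing two pyran
rings carry an ordered pair of codes.

Three curated fixtures ship with the package:

* ``registry.json``   — the 52-record revision registry (47 revised cases,
  including the 17-member synthetic R22 series, plus 5 unresolved ones);
* ``modeling_set.json`` — the 76-compound modeling-set catalog (ids + codes);
* ``markers.json``    — the subtype diagnostic-marker table used by
  :mod:`pyranoshift.subtype_rules`.
"""

from __future__ import annotations

import json
import re
from dataclasses import dataclass, field, replace
from importlib import resources
from pathlib import Path
from typing import Iterable, Mapping, Sequence, Union

import pandas as pd

__all__ = [
    "CARBON_CLASSES",
    "INTENSITY_NOTES",
    "ValidationError",
    "SubtypeFormatError",
    "ShiftRecord",
    "SubtypeCode",
    "CompoundEntry",
    "RegistryEntry",
    "normalize_label",
    "parse_subtype",
    "format_subtype",
    "read_shift_table",
    "write_shift_table",
    "load_registry",
    "load_modeling_catalog",
    "packaged_fixture",
]

CARBON_CLASSES = frozenset(
    {
        "core_CH",
        "core_Cq",
        "carbonyl",
        "pyran_olefinic_1p",
        "pyran_olefinic_2p",
        "pyran_O_Cq",
        "methyl",
        "methoxy",
        "other",
    }
)

INTENSITY_NOTES = frozenset({"normal", "weak", "double"})


class ValidationError(ValueError):
    """A record or entry violates the data-model invariants."""


class SubtypeFormatError(ValidationError):
    """A subtype code string does not match the letter+two-digit grammar."""


_PRIME_TRANSLATION = str.maketrans({"′": "'", "’": "'", "´": "'", "″": "''"})


def normalize_label(label: str) -> str:
    """Normalize a carbon-position token.

    Unicode primes and typographic apostrophes become ASCII ``'``; a double
    prime (however written) collapses to a single prime, so ``C-1''`` and
    ``C-1″`` both normalize to ``C-1'``.  Literature sources label the pyran
    olefinic carbons variously C-1′/C-1″; the correction factors and marker
    table are keyed to the single-prime form.
    """
    s = label.strip().translate(_PRIME_TRANSLATION)
    while "''" in s:
        s = s.replace("''", "'")
    return s


@dataclass(frozen=True)
class ShiftRecord:
    """One carbon's assignment: position label, δ in ppm, and carbon class."""

    label: str
    shift: float
    carbon_class: str
    intensity_note: str | None = None

    def __post_init__(self) -> None:
        if not str(self.label).strip():
            raise ValidationError("shift record label must be nonempty")
        if not (0.0 < float(self.shift) < 250.0):
            raise ValidationError(
                f"shift {self.shift!r} for {self.label!r} outside (0, 250) ppm"
            )
        if self.carbon_class not in CARBON_CLASSES:
            raise ValidationError(
                f"unknown carbon_class {self.carbon_class!r} for {self.label!r}"
            )
        if self.intensity_note is not None and self.intensity_note not in INTENSITY_NOTES:
            raise ValidationError(
                f"unknown intensity_note {self.intensity_note!r} for {self.label!r}"
            )


_CODE_RE = re.compile(r"^([A-Za-z])([0-9])([0-9])$")


@dataclass(frozen=True, order=True)
class SubtypeCode:
    """Structural proxy: type letter + pyran-oxygen digit + substituent digit."""

    type_letter: str
    oxygen_digit: int
    substituent_digit: int

    def __post_init__(self) -> None:
        if self.type_letter not in ("A", "B", "C", "D"):
            raise SubtypeFormatError(f"type letter {self.type_letter!r} not in A-D")
        for d in (self.oxygen_digit, self.substituent_digit):
            if not (0 <= int(d) <= 4):
                raise SubtypeFormatError(f"subtype digit {d!r} outside 0-4")

    @property
    def as_text(self) -> str:
        return f"{self.type_letter}{self.oxygen_digit}{self.substituent_digit}"


DualCode = tuple[SubtypeCode, SubtypeCode]
SubtypeLike = Union[SubtypeCode, DualCode]


def parse_subtype(text: str) -> SubtypeLike:
    """Parse a subtype code string into a :class:`SubtypeCode` or dual pair.

    Accepts bare codes (``"B31"``), normalized dual codes (``"B31-D32"``) and
    full catalog ids carrying sequence numbers (``"B31-19–D32-5"``); sequence
    numbers are ignored, en/em dashes are treated as hyphens.
    """
    s = str(text).strip().replace("–", "-").replace("—", "-")
    codes: list[SubtypeCode] = []
    for token in filter(None, (t.strip() for t in s.split("-"))):
        m = _CODE_RE.match(token)
        if m:
            codes.append(
                SubtypeCode(m.group(1).upper(), int(m.group(2)), int(m.group(3)))
            )
        elif re.fullmatch(r"[0-9]+[a-z]?", token):
            continue  # sequence number within a catalog id
        else:
            raise SubtypeFormatError(f"cannot parse subtype token {token!r} in {text!r}")
    if len(codes) == 1:
        return codes[0]
    if len(codes) == 2:
        return (codes[0], codes[1])
    raise SubtypeFormatError(f"expected one or two subtype codes in {text!r}")


def format_subtype(code: SubtypeLike | None) -> str:
    """Inverse of :func:`parse_subtype` on normalized codes ('' for None)."""
    if code is None:
        return ""
    if isinstance(code, SubtypeCode):
        return code.as_text
    return f"{code[0].as_text}-{code[1].as_text}"


@dataclass(frozen=True)
class CompoundEntry:
    """A named compound's shift set plus subtype code(s) and provenance."""

    id: str
    name: str
    subtype: SubtypeLike | None
    shifts: tuple[ShiftRecord, ...]
    kind: str = "experimental"
    solvent: str = "CDCl3"
    source_ref: str = ""

    def __post_init__(self) -> None:
        if not self.id.strip():
            raise ValidationError("compound id must be nonempty")
        if self.kind not in ("experimental", "calculated"):
            raise ValidationError(f"kind {self.kind!r} not in {{experimental, calculated}}")
        object.__setattr__(self, "shifts", tuple(self.shifts))
        seen: dict[str, ShiftRecord] = {}
        for rec in self.shifts:
            lab = normalize_label(rec.label)
            if lab in seen:
                if rec.intensity_note != "double" or seen[lab].intensity_note != "double":
                    raise ValidationError(
                        f"duplicate label {lab!r} in entry {self.id!r} without double flag"
                    )
            seen[lab] = rec

    @property
    def labels(self) -> tuple[str, ...]:
        return tuple(normalize_label(r.label) for r in self.shifts)

    @property
    def shift_values(self) -> tuple[float, ...]:
        return tuple(r.shift for r in self.shifts)

    def shift_map(self) -> dict[str, list[float]]:
        """Normalized label → list of shift values (doubles keep both rows)."""
        out: dict[str, list[float]] = {}
        for rec in self.shifts:
            out.setdefault(normalize_label(rec.label), []).append(rec.shift)
        return out

    def with_shifts(self, shifts: Iterable[ShiftRecord]) -> "CompoundEntry":
        return replace(self, shifts=tuple(shifts))


@dataclass(frozen=True)
class RegistryEntry:
    """One row of the revision registry (misassigned literature structure)."""

    revision_id: str
    name: str
    original_code: SubtypeLike
    revised_code: str | None
    revised_name: str = ""
    flags: frozenset[str] = field(default_factory=frozenset)
    parent: str | None = None

    def __post_init__(self) -> None:
        object.__setattr__(self, "flags", frozenset(self.flags))
        bad = self.flags - {"previously_unreported", "unresolved", "single_outlier_noted"}
        if bad:
            raise ValidationError(f"unknown registry flags {sorted(bad)} on {self.revision_id}")
        if "unresolved" in self.flags and self.revised_code is not None:
            raise ValidationError(f"unresolved entry {self.revision_id} has a revised code")
        if "unresolved" not in self.flags and self.revised_code is None:
            raise ValidationError(f"revised entry {self.revision_id} lacks a revised code")

    @property
    def is_revised(self) -> bool:
        return "unresolved" not in self.flags


# ---------------------------------------------------------------------------
# Tabular I/O
# ---------------------------------------------------------------------------

CSV_COLUMNS = [
    "compound_id",
    "name",
    "subtype",
    "kind",
    "label",
    "shift_ppm",
    "carbon_class",
    "intensity",
    "solvent",
    "source",
]


def _entry_from_rows(cid: str, rows: pd.DataFrame) -> CompoundEntry:
    first = rows.iloc[0]
    subtype_text = str(first.get("subtype", "") or "").strip()
    subtype = parse_subtype(subtype_text) if subtype_text else None
    records = []
    for idx, row in rows.iterrows():
        note = str(row.get("intensity", "") or "").strip() or None
        try:
            records.append(
                ShiftRecord(
                    label=str(row["label"]),
                    shift=float(row["shift_ppm"]),
                    carbon_class=str(row["carbon_class"]),
                    intensity_note=note,
                )
            )
        except (TypeError, ValueError) as exc:
            raise ValidationError(f"malformed row {idx} for compound {cid!r}: {exc}") from exc
    return CompoundEntry(
        id=cid,
        name=str(first.get("name", "") or ""),
        subtype=subtype,
        shifts=tuple(records),
        kind=str(first.get("kind", "experimental") or "experimental"),
        solvent=str(first.get("solvent", "") or "CDCl3"),
        source_ref=str(first.get("source", "") or ""),
    )


def read_shift_table(path_or_buf, format: str = "csv") -> list[CompoundEntry]:
    """Read a collection of compounds from CSV or JSON.

    CSV dialect: header ``compound_id,name,subtype,kind,label,shift_ppm,
    carbon_class,intensity,solvent,source``, UTF-8, ``.`` decimal separator.
    JSON: one document, entries keyed by id, shifts as arrays of records.
    """
    if format == "csv":
        df = pd.read_csv(path_or_buf, dtype=str, keep_default_na=False)
        missing = set(CSV_COLUMNS) - set(df.columns)
        if missing:
            raise ValidationError(f"CSV missing columns {sorted(missing)}")
        entries = []
        for cid, rows in df.groupby("compound_id", sort=False):
            entries.append(_entry_from_rows(str(cid), rows))
        return entries
    if format == "json":
        if isinstance(path_or_buf, (str, Path)):
            doc = json.loads(Path(path_or_buf).read_text())
        else:
            doc = json.load(path_or_buf)
        entries = []
        for cid, body in doc["entries"].items():
            subtype_text = (body.get("subtype") or "").strip()
            records = tuple(
                ShiftRecord(
                    label=r["label"],
                    shift=float(r["shift_ppm"]),
                    carbon_class=r["carbon_class"],
                    intensity_note=r.get("intensity") or None,
                )
                for r in body["shifts"]
            )
            entries.append(
                CompoundEntry(
                    id=cid,
                    name=body.get("name", ""),
                    subtype=parse_subtype(subtype_text) if subtype_text else None,
                    shifts=records,
                    kind=body.get("kind", "experimental"),
                    solvent=body.get("solvent", "CDCl3"),
                    source_ref=body.get("source", ""),
                )
            )
        return entries
    raise ValidationError(f"unknown format {format!r} (use 'csv' or 'json')")


def write_shift_table(entries: Sequence[CompoundEntry], path_or_buf, format: str = "csv") -> None:
    """Write a collection in the same dialect :func:`read_shift_table` reads."""
    if format == "csv":
        rows = []
        for e in entries:
            for rec in e.shifts:
                rows.append(
                    {
                        "compound_id": e.id,
                        "name": e.name,
                        "subtype": format_subtype(e.subtype),
                        "kind": e.kind,
                        "label": rec.label,
                        "shift_ppm": repr(rec.shift) if isinstance(rec.shift, float) else rec.shift,
                        "carbon_class": rec.carbon_class,
                        "intensity": rec.intensity_note or "",
                        "solvent": e.solvent,
                        "source": e.source_ref,
                    }
                )
        pd.DataFrame(rows, columns=CSV_COLUMNS).to_csv(path_or_buf, index=False)
        return
    if format == "json":
        doc = {"entries": {}}
        for e in entries:
            doc["entries"][e.id] = {
                "name": e.name,
                "subtype": format_subtype(e.subtype) or None,
                "kind": e.kind,
                "solvent": e.solvent,
                "source": e.source_ref,
                "shifts": [
                    {
                        "label": rec.label,
                        "shift_ppm": rec.shift,
                        "carbon_class": rec.carbon_class,
                        "intensity": rec.intensity_note,
                    }
                    for rec in e.shifts
                ],
            }
        text = json.dumps(doc, indent=1)
        if isinstance(path_or_buf, (str, Path)):
            Path(path_or_buf).write_text(text)
        else:
            path_or_buf.write(text)
        return
    raise ValidationError(f"unknown format {format!r} (use 'csv' or 'json')")


# ---------------------------------------------------------------------------
# Packaged fixtures
# ---------------------------------------------------------------------------


def packaged_fixture(name: str):
    """Load a packaged JSON fixture by file name."""
    try:
        text = resources.files("pyranoshift.data").joinpath(name).read_text()
    except (FileNotFoundError, ModuleNotFoundError) as exc:
        raise ValidationError(f"packaged fixture {name!r} missing or unreadable") from exc
    return json.loads(text)


def load_registry() -> list[RegistryEntry]:
    """Load the curated revision registry (deterministic, side-effect free)."""
    raw = packaged_fixture("registry.json")
    entries = []
    for row in raw["entries"]:
        entries.append(
            RegistryEntry(
                revision_id=row["revision_id"],
                name=row.get("name", ""),
                original_code=parse_subtype(row["original_code"]),
                revised_code=row.get("revised_code"),
                revised_name=row.get("revised_name", ""),
                flags=frozenset(row.get("flags", [])),
                parent=row.get("parent"),
            )
        )
    ids = [e.revision_id for e in entries]
    if len(ids) != len(set(ids)):
        raise ValidationError("registry fixture contains duplicate revision ids")
    return entries


@dataclass(frozen=True)
class CatalogEntry:
    """One modeling-set compound: catalog id, optional name, subtype code(s)."""

    id: str
    name: str | None
    subtype: SubtypeLike


def load_modeling_catalog() -> list[CatalogEntry]:
    """Load the 76-compound modeling-set catalog (ids + subtype codes)."""
    raw = packaged_fixture("modeling_set.json")
    out = []
    for row in raw["compounds"]:
        out.append(
            CatalogEntry(id=row["id"], name=row.get("name"), subtype=parse_subtype(row["id"]))
        )
    ids = [c.id for c in out]
    if len(ids) != len(set(ids)):
        raise ValidationError("modeling-set fixture contains duplicate ids")
    return out
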