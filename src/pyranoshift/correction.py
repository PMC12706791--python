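"""Boltzmann averaging of conformer shifts and empirical correction factors.

DFT-computed shieldings are conformer dependent; the predicted shift of a
flexible molecule is the population-weighted mean over its conformers, with
weights proportional to ``exp(-ΔE / RT)`` (relative energies in kJ/mol).

On top of that, GIAO predictions for pyranoxanthones show systematic residual
errors at specific positions: the carbonyl-peri carbons C-1/C-8 and the pyran
olefinic CH pair C-1'/C-2'.  These are corrected additively per *correction
class* with ``offset = mean(δ_exp − δ_calc)`` over a modeling set of
structures of known constitution, and ``δ_corrected = δ_calc + offset``.
The package ships the gathered-set defaults −2.9 (C-1/C-8, pooled), −3.7
(C-1') and +2.8 ppm (C-2'); deriving fresh factors from user pairs overrides
them.
"""

from __future__ import annotations

import json
import math
import warnings
from dataclasses import dataclass, field, replace
from pathlib import Path
from typing import Iterable, Mapping, Sequence

import numpy as np

from .shift_data import (
    CompoundEntry,
    ShiftRecord,
    ValidationError,
    normalize_label,
    packaged_fixture,
)

__all__ = [
    "R_GAS",
    "DEFAULT_TEMPERATURE",
    "CORRECTION_CLASS_C1_C8",
    "correction_class",
    "ConformerSet",
    "CorrectionFactors",
    "boltzmann_average",
    "derive_correction_factors",
    "apply_corrections",
    "default_correction_factors",
]

R_GAS = 8.314  # J/(mol*K); conformer energies are accepted in kJ/mol only
DEFAULT_TEMPERATURE = 298.15  # K

CORRECTION_CLASS_C1_C8 = "C1_C8"
DEFAULT_CORRECTION_CLASSES = (
    CORRECTION_CLASS_C1_C8,
    "pyran_olefinic_1p",
    "pyran_olefinic_2p",
)


def correction_class(record: ShiftRecord) -> str:
    """Correction-class key of a record.

    C-1 and C-8 occupy symmetric peri positions flanking the carbonyl and show
    near-identical systematic errors, so they are pooled into one class keyed
    ``"C1_C8"``; every other record is keyed by its ``carbon_class``.
    """
    if normalize_label(record.label) in ("C-1", "C-8"):
        return CORRECTION_CLASS_C1_C8
    return record.carbon_class


@dataclass(frozen=True)
class ConformerSet:
    """Per-conformer shift tables with relative energies in kJ/mol."""

    energies: tuple[float, ...]
    shift_tables: tuple[Mapping[str, float], ...]
    temperature: float = DEFAULT_TEMPERATURE

    def __post_init__(self) -> None:
        object.__setattr__(self, "energies", tuple(float(e) for e in self.energies))
        object.__setattr__(self, "shift_tables", tuple(dict(t) for t in self.shift_tables))
        if len(self.energies) == 0:
            raise ValidationError("conformer set needs at least one conformer")
        if len(self.energies) != len(self.shift_tables):
            raise ValidationError("one shift table required per conformer energy")
        if not all(math.isfinite(e) for e in self.energies):
            raise ValidationError("conformer energies must be finite")
        if not self.temperature > 0:
            raise ValidationError("temperature must be positive")
        labels = set(self.shift_tables[0])
        for i, table in enumerate(self.shift_tables[1:], start=2):
            if set(table) != labels:
                raise ValidationError(
                    f"conformer {i} label set differs from conformer 1"
                )

    @property
    def labels(self) -> tuple[str, ...]:
        return tuple(sorted(self.shift_tables[0]))


def boltzmann_average(conformers: ConformerSet) -> dict[str, float]:
    """Population-weighted mean shift per label.

    Weights are ``w_i ∝ exp(−(E_i − min E)/(R·T))`` with energies in kJ/mol,
    so the result is invariant to any constant energy offset.
    """
    energies = np.asarray(conformers.energies, dtype=float)
    beta = 1000.0 / (R_GAS * conformers.temperature)  # per kJ/mol
    log_w = -beta * (energies - energies.min())
    w = np.exp(log_w - log_w.max())
    w /= w.sum()
    out = {}
    for label in conformers.labels:
        values = np.array([t[label] for t in conformers.shift_tables], dtype=float)
        out[label] = float(np.dot(w, values))
    return out


@dataclass(frozen=True)
class CorrectionFactors:
    """Per-class additive ppm offsets with optional derivation statistics.

    ``per_class`` holds only classes for which data exist (never zero-filled);
    positive offsets are added to calculated shifts.
    """

    per_class: Mapping[str, float]
    n_per_class: Mapping[str, int] = field(default_factory=dict)
    sd_per_class: Mapping[str, float] = field(default_factory=dict)
    scope: str = "gathered"

    def __post_init__(self) -> None:
        object.__setattr__(self, "per_class", dict(self.per_class))
        object.__setattr__(self, "n_per_class", dict(self.n_per_class))
        object.__setattr__(self, "sd_per_class", dict(self.sd_per_class))
        for cls, n in self.n_per_class.items():
            if n < 1:
                raise ValidationError(f"class {cls!r} has sample size {n} < 1")

    def offset(self, cls: str) -> float:
        return float(self.per_class.get(cls, 0.0))

    def to_json(self, path=None) -> str:
        doc = {
            "scope": self.scope,
            "factors": [
                {
                    "class": cls,
                    "offset_ppm": off,
                    **({"n": self.n_per_class[cls]} if cls in self.n_per_class else {}),
                    **({"sd_ppm": self.sd_per_class[cls]} if cls in self.sd_per_class else {}),
                }
                for cls, off in sorted(self.per_class.items())
            ],
        }
        text = json.dumps(doc, indent=1)
        if path is not None:
            Path(path).write_text(text)
        return text

    @classmethod
    def from_json(cls, source) -> "CorrectionFactors":
        if isinstance(source, (str, Path)) and Path(source).exists():
            doc = json.loads(Path(source).read_text())
        elif isinstance(source, str):
            doc = json.loads(source)
        else:
            doc = source
        per, npc, sdpc = {}, {}, {}
        for row in doc["factors"]:
            per[row["class"]] = float(row["offset_ppm"])
            if "n" in row:
                npc[row["class"]] = int(row["n"])
            if "sd_ppm" in row:
                sdpc[row["class"]] = float(row["sd_ppm"])
        return cls(per_class=per, n_per_class=npc, sd_per_class=sdpc, scope=doc.get("scope", "gathered"))


def default_correction_factors() -> CorrectionFactors:
    """The packaged gathered-set factors: −2.9 (C-1/C-8), −3.7 (C-1'), +2.8 (C-2')."""
    return CorrectionFactors.from_json(packaged_fixture("corrections.json"))


def _matched_residuals(
    exp: CompoundEntry, calc: CompoundEntry, classes: Sequence[str]
) -> dict[str, list[float]]:
    """exp − calc residuals on shared labels, bucketed by correction class."""
    calc_map: dict[str, list[ShiftRecord]] = {}
    for rec in calc.shifts:
        calc_map.setdefault(normalize_label(rec.label), []).append(rec)
    out: dict[str, list[float]] = {}
    shared = 0
    for rec in exp.shifts:
        lab = normalize_label(rec.label)
        if lab not in calc_map:
            continue
        shared += 1
        cls = correction_class(rec)
        if cls not in classes:
            continue
        out.setdefault(cls, []).append(rec.shift - calc_map[lab][0].shift)
    if shared == 0:
        raise ValidationError(f"pair ({exp.id!r}, {calc.id!r}) shares no labels")
    return out


def derive_correction_factors(
    pairs: Iterable[tuple[CompoundEntry, CompoundEntry]],
    classes: Sequence[str] = DEFAULT_CORRECTION_CLASSES,
    scope: str = "gathered",
) -> CorrectionFactors:
    """Fit per-class offsets from (experimental, calculated) pairs.

    ``offset(class) = mean(δ_exp − δ_calc)`` over every matched carbon of the
    class; untrimmed mean, with per-class n and sd reported.  A requested
    class with no matched carbons is omitted with a warning, not an error.
    Applying the resulting factors back to the derivation set makes each
    class-wise mean residual exactly zero.
    """
    buckets: dict[str, list[float]] = {c: [] for c in classes}
    for exp, calc in pairs:
        for cls, residuals in _matched_residuals(exp, calc, classes).items():
            buckets[cls].extend(residuals)
    per, npc, sdpc = {}, {}, {}
    for cls in classes:
        values = buckets[cls]
        if not values:
            warnings.warn(f"no matched carbons for correction class {cls!r}; omitted")
            continue
        arr = np.asarray(values, dtype=float)
        per[cls] = float(arr.mean())
        npc[cls] = int(arr.size)
        sdpc[cls] = float(arr.std(ddof=1)) if arr.size > 1 else 0.0
    return CorrectionFactors(per_class=per, n_per_class=npc, sd_per_class=sdpc, scope=scope)


def apply_corrections(calculated: CompoundEntry, factors: CorrectionFactors | None) -> CompoundEntry:
    """Return a corrected copy of a calculated entry (original not mutated).

    ``δ_corrected = δ_calc + offset(class)`` for classes present in the
    factors; all other shifts pass through unchanged.
    """
    if factors is None or not factors.per_class:
        return calculated
    new_records = []
    for rec in calculated.shifts:
        off = factors.offset(correction_class(rec))
        new_records.append(replace(rec, shift=rec.shift + off) if off else rec)
    return calculated.with_shifts(new_records)
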