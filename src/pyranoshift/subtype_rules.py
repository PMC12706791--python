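"""Diagnostic-marker rule engine: subtype classification and consistency checks.

Each pyranoxanthone subtype has a small set of diagnostic ¹³C markers — the
carbons adjacent to the pyran ring (its oxygenated core carbon, the two
olefinic methines) plus the carbonyl and, where informative, an aromatic CH
between oxygenated positions.  A shift set is classified by greedily matching
each subtype's markers to the nearest unconsumed shift within tolerance and
ranking subtypes by (fraction matched, mean absolute marker deviation).

The carbonyl carbon doubles as a hydrogen-bond probe: ~176 ppm with no
intramolecular H-bond, rising to ~186 ppm when chelated by hydroxyls at both
C-1 and C-8; the banded classifier below uses interpolated boundaries.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Mapping, Sequence

from .shift_data import (
    CompoundEntry,
    SubtypeCode,
    SubtypeLike,
    ValidationError,
    format_subtype,
    packaged_fixture,
)

__all__ = [
    "DEFAULT_MARKER_TOLERANCE",
    "DiagnosticMarker",
    "SubtypeRanking",
    "SubtypeDiagnosis",
    "MarkerViolation",
    "load_marker_table",
    "classify",
    "classify_dual",
    "check_consistency",
    "carbonyl_hbond_state",
]

DEFAULT_MARKER_TOLERANCE = 1.5  # ppm

#: role token → carbon_class used when markers seed synthetic records
MARKER_ROLE_CLASSES = {
    "pyran_O_Cq": "pyran_O_Cq",
    "pyran_olefinic_1p": "pyran_olefinic_1p",
    "pyran_olefinic_2p": "pyran_olefinic_2p",
    "carbonyl": "carbonyl",
    "core_CH": "core_CH",
}


class MarkerLookupError(KeyError):
    """Requested subtype has no markers in the table."""


@dataclass(frozen=True)
class DiagnosticMarker:
    """Subtype-specific expected shift ± tolerance for one carbon role."""

    subtype: str
    role: str
    label: str
    expected: float
    tolerance: float = DEFAULT_MARKER_TOLERANCE

    def __post_init__(self) -> None:
        if not self.tolerance > 0:
            raise ValidationError("marker tolerance must be positive")
        if not (0.0 < self.expected < 250.0):
            raise ValidationError(f"marker expectation {self.expected} outside (0, 250) ppm")


MarkerTable = Mapping[str, tuple[DiagnosticMarker, ...]]


def load_marker_table() -> dict[str, tuple[DiagnosticMarker, ...]]:
    """Load the packaged marker table: subtype text → markers.

    Subtypes lacking ¹³C data in the source classification (B14, B30, C20,
    C42) are excluded from the table rather than given wide tolerances.
    """
    raw = packaged_fixture("markers.json")
    table: dict[str, list[DiagnosticMarker]] = {}
    for row in raw["markers"]:
        table.setdefault(row["subtype"], []).append(
            DiagnosticMarker(
                subtype=row["subtype"],
                role=row["role"],
                label=row["label"],
                expected=float(row["expected_ppm"]),
                tolerance=float(row["tolerance_ppm"]),
            )
        )
    return {sub: tuple(ms) for sub, ms in table.items()}


@dataclass(frozen=True)
class SubtypeRanking:
    subtype: str
    n_matched: int
    n_markers: int
    mean_abs_dev: float

    @property
    def fraction(self) -> float:
        return self.n_matched / self.n_markers


@dataclass(frozen=True)
class SubtypeDiagnosis:
    """Ranked subtype candidates; ``best`` is None below the assertion floor."""

    ranked: tuple[SubtypeRanking, ...]
    best: str | None

    def ranking_of(self, subtype: str) -> SubtypeRanking:
        for r in self.ranked:
            if r.subtype == subtype:
                return r
        raise MarkerLookupError(subtype)


def _greedy_match(
    shifts: Sequence[float], markers: Sequence[DiagnosticMarker]
) -> tuple[list[tuple[DiagnosticMarker, float]], list[float]]:
    """Greedy nearest matching with consumption (a shift satisfies one marker).

    Shifts are pre-sorted so the result is invariant to input row order; ties
    in distance break toward the lower shift value.
    """
    pool = sorted(shifts)
    matched: list[tuple[DiagnosticMarker, float]] = []
    for marker in markers:
        if not pool:
            break
        best_i = min(range(len(pool)), key=lambda i: (abs(pool[i] - marker.expected), pool[i]))
        if abs(pool[best_i] - marker.expected) <= marker.tolerance:
            matched.append((marker, pool.pop(best_i)))
    return matched, pool


def classify(
    entry: CompoundEntry,
    markers: MarkerTable | None = None,
    min_fraction: float = 0.6,
) -> SubtypeDiagnosis:
    """Rank subtypes for a shift set; deterministic and row-order invariant.

    Ranking key: fraction of markers matched (descending), then mean absolute
    marker deviation (ascending), then subtype code.  No subtype is asserted
    (``best=None``) when the top fraction falls below ``min_fraction``.
    """
    if markers is None:
        markers = load_marker_table()
    if not entry.shifts:
        raise ValidationError(f"entry {entry.id!r} has no shifts to classify")
    if not markers:
        raise ValidationError("marker table is empty")
    rankings = []
    for subtype in sorted(markers):
        ms = markers[subtype]
        matched, _ = _greedy_match(entry.shift_values, ms)
        if matched:
            mean_dev = sum(abs(v - m.expected) for m, v in matched) / len(matched)
        else:
            mean_dev = float("inf")
        rankings.append(SubtypeRanking(subtype, len(matched), len(ms), mean_dev))
    rankings.sort(key=lambda r: (-r.fraction, r.mean_abs_dev, r.subtype))
    best = rankings[0].subtype if rankings[0].fraction >= min_fraction else None
    return SubtypeDiagnosis(tuple(rankings), best)


def classify_dual(
    entry: CompoundEntry,
    markers: MarkerTable | None = None,
    min_fraction: float = 0.6,
) -> tuple[SubtypeDiagnosis, SubtypeDiagnosis]:
    """Classify an entry bearing two pyran rings.

    The engine runs twice: shifts consumed by the first winner's markers are
    removed before the second pass, so each ring is assigned once.
    """
    if markers is None:
        markers = load_marker_table()
    first = classify(entry, markers, min_fraction)
    remaining = list(entry.shift_values)
    if first.best is not None:
        matched, _ = _greedy_match(remaining, markers[first.best])
        for _, value in matched:
            remaining.remove(value)
    # keep records whose value survived consumption (multiset semantics)
    kept = []
    pool = list(remaining)
    for rec in entry.shifts:
        if rec.shift in pool:
            kept.append(rec)
            pool.remove(rec.shift)
    stub = entry.with_shifts(kept) if kept else entry
    second = classify(stub, markers, min_fraction)
    return first, second


@dataclass(frozen=True)
class MarkerViolation:
    """A claimed-subtype marker with no observed shift inside tolerance."""

    marker: DiagnosticMarker
    expected: float
    nearest_observed: float
    deviation: float


def check_consistency(
    entry: CompoundEntry,
    claimed: SubtypeLike | str,
    markers: MarkerTable | None = None,
) -> list[MarkerViolation]:
    """Check a claimed subtype: one violation per marker with no shift in range.

    An empty list means the data are consistent with the claim.  Unknown or
    data-less subtypes raise :class:`MarkerLookupError`.
    """
    if markers is None:
        markers = load_marker_table()
    key = claimed if isinstance(claimed, str) else format_subtype(claimed)
    if key not in markers:
        raise MarkerLookupError(f"no markers recorded for subtype {key!r}")
    if not entry.shifts:
        raise ValidationError(f"entry {entry.id!r} has no shifts to check")
    violations = []
    values = sorted(entry.shift_values)
    for marker in markers[key]:
        nearest = min(values, key=lambda v: abs(v - marker.expected))
        dev = abs(nearest - marker.expected)
        if dev > marker.tolerance:
            violations.append(MarkerViolation(marker, marker.expected, nearest, dev))
    return violations


def carbonyl_hbond_state(
    delta_c9: float,
    no_hbond_below: float = 178.0,
    two_hbond_above: float = 184.5,
) -> str:
    """Classify the C-9 carbonyl shift by intramolecular H-bond count.

    Bands interpolate between the ~176 ppm (free) and ~186 ppm (doubly
    chelated) anchors: <178 → ``no_hbond``; 178–184.5 → ``one_hbond``;
    >184.5 → ``two_hbond``.  Boundaries are configurable.
    """
    if not (150.0 < delta_c9 < 220.0):
        raise ValidationError(f"carbonyl shift {delta_c9} ppm outside (150, 220)")
    if delta_c9 < no_hbond_below:
        return "no_hbond"
    if delta_c9 <= two_hbond_above:
        return "one_hbond"
    return "two_hbond"
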